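"""Seed construction for DNA sequence comparison.

This module builds the three seed families the package compares:

* contiguous ``k``-mers,
* spaced ``k``-mers — ``k`` fixed (sampled) positions inside a longer
  window of span ``L``, the remaining positions being wildcards,
* strobemers — seeds of ``n`` linked ``ell``-mers ("strobes"), where the
  first strobe sits at the seed start and each later strobe is picked
  from a downstream window ``[w_min, w_max]`` (offsets relative to the
  previous window) by one of three hash-driven rules: *minstrobes*
  (independent window minimizers), *randstrobes* (each strobe minimizes
  a score conditioned on the previously chosen strobes) and
  *hybridstrobes* (minimizer within one of ``x`` subwindows, the
  subwindow selected by the previous strobe's hash remainder).

Every protocol emits exactly ``max(0, |s| - k + 1)`` seeds on a clean
ACGT string, one per admissible start position, where ``k`` is the total
sampled length.  Near the end of the sequence strobemer windows are
proportionally narrowed (default) so the final seeds degenerate to
contiguous ``k``-mers; narrowing can be disabled (useful when mapping
reads, where narrowed tail seeds differ between read and reference), in
which case tail positions lacking a full window emit no seed.  Seeds
whose sampled positions overlap a non-ACGT letter are skipped.

Hashing is a fixed 64-bit polynomial rolling hash over the letters
(odd multiplier, wrap-around arithmetic modulo 2**64) finalised with the
splitmix64 mixer.  It is deterministic across runs and platforms and is
not cryptographic.
"""

from __future__ import annotations

import enum
from collections.abc import Sequence as _SequenceABC
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Union

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Protocol",
    "SpacedMask",
    "Seed",
    "SeedSet",
    "SeedParams",
    "RANDSTROBE_MASK",
    "hash_dna",
    "precompute_strobe_hashes",
    "make_spaced_mask",
    "apply_spaced_mask",
    "strobemer_window",
    "generate_kmers",
    "generate_spaced_kmers",
    "generate_minstrobes",
    "generate_randstrobes",
    "generate_hybridstrobes",
    "generate_seeds",
    "combine_strobe_hashes",
]

_U64 = np.uint64

#: Bitmask applied to the conditional randstrobe score: ones at the 16
#: lowest-order bits.  The candidate strobe minimizing
#: ``(sum of previous strobe hashes + candidate hash) & RANDSTROBE_MASK``
#: is selected.
RANDSTROBE_MASK = 0xFFFF
_MASK16 = _U64(RANDSTROBE_MASK)
_INVALID_SCORE = _U64(0x10000)  # larger than any masked score
_HASH_MAX = _U64(0xFFFFFFFFFFFFFFFF)

# Polynomial base (odd, hence invertible modulo 2**64) and a fixed salt.
_BASE = 0x5851F42D4C957F2D
_BASE_INV = pow(_BASE, -1, 1 << 64)
_SALT = _U64(0x2545F4914F6CDD1D)

# Letter coefficients: A,C,G,T (either case) -> 1..4; any other byte b
# maps to b + 5 so hashing is defined for arbitrary ASCII strings.
_COEFF = np.arange(256, dtype=np.uint64) + _U64(5)
_AMBIG = np.ones(256, dtype=bool)
for _i, _c in enumerate(b"ACGT"):
    _COEFF[_c] = _i + 1
    _COEFF[_c + 32] = _i + 1  # lowercase
    _AMBIG[_c] = False
    _AMBIG[_c + 32] = False

# Lazily grown tables of BASE**j and BASE**-j (mod 2**64).
_POW = np.ones(1, dtype=np.uint64)
_POW_INV = np.ones(1, dtype=np.uint64)


def _grow_powers(table: np.ndarray, base: int, size: int) -> np.ndarray:
    out = np.empty(size, dtype=np.uint64)
    m = len(table)
    out[:m] = table
    tail = np.full(size - m, _U64(base & 0xFFFFFFFFFFFFFFFF), dtype=np.uint64)
    tail[0] = np.multiply(table[-1:], tail[:1])[0]  # wraps mod 2**64
    np.multiply.accumulate(tail, out=tail)
    out[m:] = tail
    return out


def _powers(n: int) -> tuple[np.ndarray, np.ndarray]:
    """Return tables of BASE**j and BASE**-j for j in [0, n]."""
    global _POW, _POW_INV
    if len(_POW) <= n:
        size = max(n + 1, 2 * len(_POW))
        _POW = _grow_powers(_POW, _BASE, size)
        _POW_INV = _grow_powers(_POW_INV, _BASE_INV, size)
    return _POW, _POW_INV


def _mix64(z: np.ndarray) -> np.ndarray:
    """splitmix64 finaliser, vectorised over uint64 arrays."""
    z = z ^ (z >> _U64(30))
    z = z * _U64(0xBF58476D1CE4E5B9)
    z = z ^ (z >> _U64(27))
    z = z * _U64(0x94D049BB133111EB)
    return z ^ (z >> _U64(31))


def _letter_coeffs(s: str) -> np.ndarray:
    data = np.frombuffer(s.encode("ascii"), dtype=np.uint8)
    return _COEFF[data]


def _lmer_hashes(s: str, ell: int) -> np.ndarray:
    """64-bit hash of every length-``ell`` substring of ``s``."""
    if ell < 1:
        raise ValueError("substring length must be >= 1")
    L = len(s)
    n = L - ell + 1
    if n <= 0:
        return np.empty(0, dtype=np.uint64)
    coeff = _letter_coeffs(s)
    pw, pinv = _powers(L)
    a = coeff * pinv[:L]
    prefix = np.zeros(L + 1, dtype=np.uint64)
    np.cumsum(a, out=prefix[1:])
    raw = (prefix[ell:] - prefix[:-ell]) * pw[ell - 1 : L]
    return _mix64(raw ^ _SALT)


def _lmer_valid(s: str, ell: int) -> np.ndarray:
    """Boolean mask: True where the ``ell``-mer at i contains only ACGT."""
    data = np.frombuffer(s.encode("ascii"), dtype=np.uint8)
    L = len(data)
    n = L - ell + 1
    if n <= 0:
        return np.empty(0, dtype=bool)
    amb = np.concatenate(([0], np.cumsum(_AMBIG[data], dtype=np.int64)))
    return (amb[ell:] - amb[:-ell]) == 0


def hash_dna(s: str) -> int:
    """Hash a whole string as a single unit (64-bit unsigned)."""
    if not s:
        raise ValueError("cannot hash the empty string")
    return int(_lmer_hashes(s, len(s))[0])


def precompute_strobe_hashes(s: str, ell: int) -> np.ndarray:
    """Hash every ``ell``-mer of ``s``; entry ``i`` is ``h(s[i:i+ell])``.

    Returns a uint64 array of length ``max(0, |s| - ell + 1)``.  The hash
    is deterministic across runs and platforms.
    """
    return _lmer_hashes(s, ell)


# ---------------------------------------------------------------------------
# Spaced masks
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SpacedMask:
    """Sampling pattern of a spaced k-mer.

    ``bits`` is a 0/1 pattern of span ``L``; ones mark the ``k`` fixed
    (sampled) positions.  The first and last positions are always fixed,
    which pins the span of the seed.
    """

    bits: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.bits) < 2:
            raise ValueError("a spaced mask needs span >= 2")
        if any(b not in (0, 1) for b in self.bits):
            raise ValueError("mask bits must be 0 or 1")
        if self.bits[0] != 1 or self.bits[-1] != 1:
            raise ValueError("first and last mask positions must be fixed (1)")

    @property
    def L(self) -> int:
        return len(self.bits)

    @property
    def k(self) -> int:
        return sum(self.bits)

    @property
    def offsets(self) -> np.ndarray:
        return np.flatnonzero(np.asarray(self.bits, dtype=np.int8))

    @classmethod
    def from_string(cls, pattern: str) -> "SpacedMask":
        return cls(tuple(int(c) for c in pattern))

    def __str__(self) -> str:
        return "".join(str(b) for b in self.bits)


def make_spaced_mask(k: int, density: str, rng_seed) -> SpacedMask:
    """Draw a random spaced mask with ``k`` fixed positions.

    ``density`` is ``"dense"`` (span ``L = round(1.5 k)``, roughly 2/3 of
    positions fixed) or ``"sparse"`` (span ``L = 3 k``, roughly 1/3
    fixed).  End positions are always fixed; the remaining ``k - 2``
    fixed positions are drawn uniformly without replacement from the
    interior, reproducibly from ``rng_seed``.
    """
    if k < 2:
        raise ValueError("spaced masks need k >= 2 to fix both endpoints")
    if density == "dense":
        L = round(1.5 * k)
    elif density == "sparse":
        L = 3 * k
    else:
        raise ValueError(f"unknown density {density!r}; use 'dense' or 'sparse'")
    rng = np.random.default_rng(rng_seed)
    bits = np.zeros(L, dtype=np.int8)
    bits[0] = bits[-1] = 1
    interior = rng.choice(np.arange(1, L - 1), size=k - 2, replace=False)
    bits[interior] = 1
    return SpacedMask(tuple(int(b) for b in bits))


def apply_spaced_mask(s: str, i: int, mask: SpacedMask) -> str:
    """Extract the fixed positions of ``mask`` anchored at ``i`` in ``s``."""
    if i < 0 or i + mask.L > len(s):
        raise ValueError(
            f"mask window [{i}, {i + mask.L}) exceeds sequence of length {len(s)}"
        )
    return "".join(s[i + int(o)] for o in mask.offsets)


# ---------------------------------------------------------------------------
# Parameters and seed containers
# ---------------------------------------------------------------------------


class Protocol(str, enum.Enum):
    KMER = "kmer"
    SPACED = "spaced"
    MINSTROBE = "minstrobe"
    RANDSTROBE = "randstrobe"
    HYBRIDSTROBE = "hybridstrobe"


_STROBE_PROTOCOLS = (Protocol.MINSTROBE, Protocol.RANDSTROBE, Protocol.HYBRIDSTROBE)


@dataclass
class SeedParams:
    """Seed protocol selector with its parameters.

    For strobemer protocols supply ``(n, ell, w_min, w_max)`` (and ``x``
    for hybridstrobes); the total sampled length is ``k = n * ell``.
    For ``kmer`` supply ``k``; for ``spaced`` supply a :class:`SpacedMask`.
    ``narrow_tail`` controls proportional window narrowing at the end of
    a sequence (on by default; when off, windows are clipped instead).
    """

    protocol: Union[Protocol, str]
    k: int | None = None
    n: int | None = None
    ell: int | None = None
    w_min: int | None = None
    w_max: int | None = None
    x: int = 3
    mask: SpacedMask | None = None
    narrow_tail: bool = True

    def __post_init__(self) -> None:
        self.protocol = Protocol(self.protocol)
        if self.protocol is Protocol.KMER:
            if self.k is None or self.k < 1:
                raise ValueError("k-mer protocol needs k >= 1")
        elif self.protocol is Protocol.SPACED:
            if self.mask is None:
                raise ValueError("spaced protocol needs a SpacedMask")
            if self.k is not None and self.k != self.mask.k:
                raise ValueError("k disagrees with mask weight")
            self.k = self.mask.k
        else:
            if self.n is None or self.n < 2:
                raise ValueError("strobemer protocols need order n >= 2")
            if self.ell is None or self.ell < 1:
                raise ValueError("strobe length ell must be >= 1")
            if self.w_min is None or self.w_max is None or not (
                1 <= self.w_min <= self.w_max
            ):
                raise ValueError("windows must satisfy 1 <= w_min <= w_max")
            expected = self.n * self.ell
            if self.k is not None and self.k != expected:
                raise ValueError("k must equal n * ell for strobemers")
            self.k = expected
            if self.protocol is Protocol.HYBRIDSTROBE:
                if self.x < 1:
                    raise ValueError("hybridstrobe subwindow count x must be >= 1")
                if self.x > 1 and (self.w_max - self.w_min) // self.x < 1:
                    raise ValueError(
                        "hybridstrobe windows too small: "
                        f"(w_max - w_min) // x = "
                        f"{(self.w_max - self.w_min) // self.x}; each of the x "
                        "subwindows must hold at least one strobe start"
                    )

    @property
    def span(self) -> int:
        """Maximal span W = (n - 1) * w_max + ell of one strobemer."""
        if self.protocol not in _STROBE_PROTOCOLS:
            raise ValueError("span is defined for strobemer protocols only")
        return (self.n - 1) * self.w_max + self.ell


@dataclass(frozen=True)
class Seed:
    """One sampled seed: 64-bit hash plus its strobe start positions.

    ``positions`` holds the 0-based start of every sampled component
    (``n`` strobes, the ``k`` fixed positions of a spaced k-mer, or the
    single start of a k-mer).  ``[span_start, span_end)`` is the covered
    half-open interval on the source sequence.
    """

    hash: int
    positions: tuple[int, ...]
    span_start: int
    span_end: int
    seq_id: str | None = None


class SeedSet(_SequenceABC):
    """Column-oriented, sequence-like container of :class:`Seed`.

    ``positions`` is an ``(N, m)`` array of component start positions
    (each component spans ``strobe_len`` letters), ``hashes`` the
    matching uint64 values.  Indexing with an int yields a
    :class:`Seed`; slices and index arrays yield a new :class:`SeedSet`.
    """

    def __init__(
        self,
        hashes: np.ndarray,
        positions: np.ndarray,
        strobe_len: int,
        seq_len: int,
        params: SeedParams | None = None,
        seq_id: str | None = None,
    ) -> None:
        self.hashes = np.ascontiguousarray(hashes, dtype=np.uint64)
        positions = np.asarray(positions, dtype=np.int64)
        if positions.ndim == 1:
            positions = positions[:, None]
        self.positions = positions
        if len(self.hashes) != len(self.positions):
            raise ValueError("hashes and positions disagree in length")
        self.strobe_len = int(strobe_len)
        self.seq_len = int(seq_len)
        self.params = params
        self.seq_id = seq_id

    @property
    def span_starts(self) -> np.ndarray:
        return self.positions[:, 0]

    @property
    def span_ends(self) -> np.ndarray:
        return self.positions[:, -1] + self.strobe_len

    def __len__(self) -> int:
        return len(self.hashes)

    def __getitem__(self, i):
        if isinstance(i, (int, np.integer)):
            row = self.positions[i]
            return Seed(
                hash=int(self.hashes[i]),
                positions=tuple(int(p) for p in row),
                span_start=int(row[0]),
                span_end=int(row[-1]) + self.strobe_len,
                seq_id=self.seq_id,
            )
        return self.subset(i)

    def __iter__(self) -> Iterator[Seed]:
        for i in range(len(self)):
            yield self[i]

    def subset(self, index) -> "SeedSet":
        return SeedSet(
            self.hashes[index],
            self.positions[index],
            self.strobe_len,
            self.seq_len,
            params=self.params,
            seq_id=self.seq_id,
        )

    def to_tsv(self, path) -> None:
        """Write seeds as TSV: seq_id, positions (comma-joined), span, hash."""
        with open(path, "w") as fh:
            fh.write("seq_id\tpositions\tspan_start\tspan_end\thash\n")
            for seed in self:
                fh.write(
                    f"{seed.seq_id or '.'}\t"
                    f"{','.join(str(p) for p in seed.positions)}\t"
                    f"{seed.span_start}\t{seed.span_end}\t{seed.hash:016x}\n"
                )


# ---------------------------------------------------------------------------
# Window geometry
# ---------------------------------------------------------------------------


def strobemer_window(i: int, j: int, params: SeedParams, seq_len: int) -> tuple[int, int]:
    """Inclusive interval of admissible start positions for strobe ``j``.

    For a seed anchored at ``i`` with full span ``W = (n-1) w_max + ell``
    fitting the sequence, strobe ``j >= 2`` is sampled from
    ``[i + w_min + (j-2) w_max, i + (j-1) w_max]``.  When the full span
    does not fit and narrowing is on, each window is shrunk to length
    ``(seq_len - i) // n``; once the shrunken window is no longer than a
    strobe, the strobes snap adjacent and the seed degenerates to the
    contiguous k-mer ``s[i:i+k)``.  With narrowing off such tail
    positions emit no seed and this function raises.
    """
    if params.protocol not in _STROBE_PROTOCOLS:
        raise ValueError("windows are defined for strobemer protocols only")
    if j < 2 or j > params.n:
        raise ValueError(f"strobe index j must be in [2, {params.n}]")
    if i < 0 or i > seq_len - params.k:
        raise ValueError(f"no seed starts at position {i} on length {seq_len}")
    n, ell, w_min, w_max = params.n, params.ell, params.w_min, params.w_max
    rem = seq_len - i
    if params.span <= rem:
        return i + w_min + (j - 2) * w_max, i + (j - 1) * w_max
    if not params.narrow_tail:
        raise ValueError(
            f"full span {params.span} does not fit at position {i} and "
            "window narrowing is disabled"
        )
    v = rem // n
    if v <= ell:
        p = i + (j - 1) * ell
        return p, p
    lo = i + min(w_min, v) + (j - 2) * v
    hi = i + (j - 1) * v
    return lo, hi


def _segments(lo: int, hi: int, x: int) -> list[tuple[int, int]]:
    """Split the inclusive window [lo, hi] into x disjoint subwindows.

    Subwindow r has width w_x = (hi - lo) // x except the last, which
    absorbs the remainder.  Degenerate windows (fewer positions than
    needed) collapse to a single subwindow.
    """
    if x <= 1:
        return [(lo, hi)]
    w_x = (hi - lo) // x
    if w_x < 1:
        return [(lo, hi)]
    segs = [(lo + r * w_x, lo + (r + 1) * w_x - 1) for r in range(x - 1)]
    segs.append((lo + (x - 1) * w_x, hi))
    return segs


# ---------------------------------------------------------------------------
# Seed generation
# ---------------------------------------------------------------------------


def _empty_seedset(params: SeedParams, seq_len: int, seq_id, strobe_len: int, m: int) -> SeedSet:
    return SeedSet(
        np.empty(0, dtype=np.uint64),
        np.empty((0, m), dtype=np.int64),
        strobe_len,
        seq_len,
        params=params,
        seq_id=seq_id,
    )


def generate_kmers(s: str, k: int, seq_id: str | None = None) -> SeedSet:
    """All contiguous k-mer seeds of ``s``, one per start position."""
    params = SeedParams(Protocol.KMER, k=k)
    N = len(s) - k + 1
    if N <= 0:
        return _empty_seedset(params, len(s), seq_id, k, 1)
    hashes = _lmer_hashes(s, k)
    valid = _lmer_valid(s, k)
    positions = np.arange(N, dtype=np.int64)[:, None]
    out = SeedSet(hashes, positions, k, len(s), params=params, seq_id=seq_id)
    return out if valid.all() else out.subset(valid)


def generate_spaced_kmers(
    s: str, mask: SpacedMask, seq_id: str | None = None, params: SeedParams | None = None
) -> SeedSet:
    """Spaced k-mer seeds of ``s``, one per start position.

    At starts where the mask window would run past the sequence end the
    seed degenerates to the contiguous k-mer at that start (mirroring
    strobemer window narrowing), so the protocol emits the same number
    of seeds as every other protocol.
    """
    if params is None:
        params = SeedParams(Protocol.SPACED, mask=mask)
    k, Lw = mask.k, mask.L
    L = len(s)
    N = L - k + 1
    if N <= 0:
        return _empty_seedset(params, L, seq_id, 1, k)
    N1 = min(N, max(0, L - Lw + 1))
    offsets = mask.offsets.astype(np.int64)
    positions = np.empty((N, k), dtype=np.int64)
    hashes = np.empty(N, dtype=np.uint64)
    if N1 > 0:
        positions[:N1] = np.arange(N1, dtype=np.int64)[:, None] + offsets
        coeff = _letter_coeffs(s)
        pw, _ = _powers(max(L, k))
        raw = np.zeros(N1, dtype=np.uint64)
        for j, o in enumerate(offsets):
            raw += coeff[o : o + N1] * pw[k - 1 - j]
        hashes[:N1] = _mix64(raw ^ _SALT)
    if N1 < N:
        positions[N1:] = np.arange(N1, N, dtype=np.int64)[:, None] + np.arange(
            k, dtype=np.int64
        )
        hashes[N1:] = _lmer_hashes(s, k)[N1:N]
    data = np.frombuffer(s.encode("ascii"), dtype=np.uint8)
    valid = ~_AMBIG[data][positions].any(axis=1)
    out = SeedSet(hashes, positions, 1, L, params=params, seq_id=seq_id)
    return out if valid.all() else out.subset(valid)


def _window_argmin(values: np.ndarray, width: int, lo_offset: int, count: int) -> np.ndarray:
    """Leftmost argmin of values[i+lo_offset : i+lo_offset+width], i < count."""
    view = sliding_window_view(values, width)[lo_offset : lo_offset + count]
    return lo_offset + np.arange(count, dtype=np.int64) + np.argmin(view, axis=1)


def _combine_columns(H: np.ndarray, pos: np.ndarray, n: int) -> np.ndarray:
    out = np.zeros(len(pos), dtype=np.uint64)
    for j in range(n):
        out += H[pos[:, j]] // _U64(n + j)
    return out


def _generate_strobemers(s: str, params: SeedParams, seq_id: str | None) -> SeedSet:
    n, ell, w_min, w_max, x = params.n, params.ell, params.w_min, params.w_max, params.x
    proto = params.protocol
    L = len(s)
    k = params.k
    N = L - k + 1
    if N <= 0:
        return _empty_seedset(params, L, seq_id, ell, n)
    H = _lmer_hashes(s, ell)
    V = _lmer_valid(s, ell)
    all_valid = bool(V.all())
    # invalid strobes lose every minimization so valid candidates win
    Hsel = H if all_valid else np.where(V, H, _HASH_MAX)
    W = params.span
    N_full = min(N, max(0, L - W + 1))
    if not params.narrow_tail:
        N = N_full  # tail positions without a full window emit no seed
        if N == 0:
            return _empty_seedset(params, L, seq_id, ell, n)
    pos = np.empty((N, n), dtype=np.int64)
    pos[:, 0] = np.arange(N, dtype=np.int64)

    if N_full > 0:
        width = w_max - w_min + 1
        if proto is Protocol.MINSTROBE:
            for j in range(2, n + 1):
                lo_off = w_min + (j - 2) * w_max
                pos[:N_full, j - 1] = _window_argmin(Hsel, width, lo_off, N_full)
        elif proto is Protocol.RANDSTROBE:
            prev = H[:N_full].copy()
            hview = sliding_window_view(H, width)
            vview = sliding_window_view(V, width) if not all_valid else None
            for j in range(2, n + 1):
                lo_off = w_min + (j - 2) * w_max
                block = hview[lo_off : lo_off + N_full]
                scores = (block + prev[:, None]) & _MASK16
                if vview is not None:
                    scores = np.where(
                        vview[lo_off : lo_off + N_full], scores, _INVALID_SCORE
                    )
                idx = np.argmin(scores, axis=1)
                pj = lo_off + np.arange(N_full, dtype=np.int64) + idx
                pos[:N_full, j - 1] = pj
                prev = prev + H[pj]
        else:  # hybridstrobe
            prev_hash = H[:N_full]
            for j in range(2, n + 1):
                lo_off = w_min + (j - 2) * w_max
                hi_off = (j - 1) * w_max
                segs = _segments(lo_off, hi_off, x)
                cand = np.empty((len(segs), N_full), dtype=np.int64)
                for r, (a, b) in enumerate(segs):
                    cand[r] = _window_argmin(Hsel, b - a + 1, a, N_full)
                r_idx = (prev_hash % _U64(len(segs))).astype(np.int64)
                pj = cand[r_idx, np.arange(N_full)]
                pos[:N_full, j - 1] = pj
                prev_hash = H[pj]

    # tail positions: narrowed (or clipped) windows, handled one by one
    for i in range(N_full, N):
        prev_sum = H[i]
        prev_hash = H[i]
        for j in range(2, n + 1):
            lo, hi = strobemer_window(i, j, params, L)
            window = Hsel[lo : hi + 1]
            if proto is Protocol.MINSTROBE:
                p = lo + int(np.argmin(window))
            elif proto is Protocol.RANDSTROBE:
                scores = (H[lo : hi + 1] + prev_sum) & _MASK16
                if not all_valid:
                    scores = np.where(V[lo : hi + 1], scores, _INVALID_SCORE)
                p = lo + int(np.argmin(scores))
                prev_sum = _U64((int(prev_sum) + int(H[p])) & 0xFFFFFFFFFFFFFFFF)
            else:
                segs = _segments(lo, hi, x)
                r = int(prev_hash % _U64(len(segs)))
                a, b = segs[r]
                p = a + int(np.argmin(Hsel[a : b + 1]))
                prev_hash = H[p]
            pos[i, j - 1] = p

    hashes = _combine_columns(H, pos, n)
    out = SeedSet(hashes, pos, ell, L, params=params, seq_id=seq_id)
    if all_valid:
        return out
    row_valid = V[pos].all(axis=1)
    return out if row_valid.all() else out.subset(row_valid)


def generate_minstrobes(s: str, params: SeedParams, seq_id: str | None = None) -> SeedSet:
    """Minstrobe seeds: each later strobe is the minimizer of its window."""
    if Protocol(params.protocol) is not Protocol.MINSTROBE:
        raise ValueError("params.protocol must be 'minstrobe'")
    return _generate_strobemers(s, params, seq_id)


def generate_randstrobes(s: str, params: SeedParams, seq_id: str | None = None) -> SeedSet:
    """Randstrobe seeds: strobe ``j`` minimizes the conditional score
    ``(h(m_1) + ... + h(m_{j-1}) + h(candidate)) & RANDSTROBE_MASK``."""
    if Protocol(params.protocol) is not Protocol.RANDSTROBE:
        raise ValueError("params.protocol must be 'randstrobe'")
    return _generate_strobemers(s, params, seq_id)


def generate_hybridstrobes(s: str, params: SeedParams, seq_id: str | None = None) -> SeedSet:
    """Hybridstrobe seeds: the window is split into ``x`` subwindows with
    independent minimizers; the previous strobe's hash remainder modulo
    ``x`` picks which subwindow supplies the strobe."""
    if Protocol(params.protocol) is not Protocol.HYBRIDSTROBE:
        raise ValueError("params.protocol must be 'hybridstrobe'")
    return _generate_strobemers(s, params, seq_id)


def generate_seeds(s: str, params: SeedParams, seq_id: str | None = None) -> SeedSet:
    """Dispatch to the generator for ``params.protocol``."""
    proto = Protocol(params.protocol)
    if proto is Protocol.KMER:
        return generate_kmers(s, params.k, seq_id=seq_id)
    if proto is Protocol.SPACED:
        return generate_spaced_kmers(s, params.mask, seq_id=seq_id, params=params)
    return _generate_strobemers(s, params, seq_id)


def combine_strobe_hashes(hashes: Iterable[int]) -> int:
    """Combine per-strobe hashes into one asymmetric 64-bit seed hash.

    Order 2 gives ``h(m1)//2 + h(m2)//3`` and order 3 gives
    ``h(m1)//3 + h(m2)//4 + h(m3)//5``; in general strobe ``j`` (0-based)
    of an order-``n`` seed is divided by ``n + j``.  Integer division
    keeps the sum below 2**64 and permuting the strobes changes the
    value.
    """
    hs = [int(h) for h in hashes]
    n = len(hs)
    if n < 2:
        raise ValueError("need at least two strobe hashes")
    for h in hs:
        if not 0 <= h < (1 << 64):
            raise ValueError("strobe hashes must be unsigned 64-bit")
    return sum(h // (n + j) for j, h in enumerate(hs))
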