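"""Match statistics between two seeded sequences.

Two seeds *match* when they produce the same 64-bit hash value.  Given
the matches between a query and a reference we compute:

* **fraction of matches** — fraction of query seed positions that take
  part in at least one match,
* **sequence coverage** — fraction of positions covered by the matched
  strobes (or sampled positions) themselves,
* **match coverage** — fraction of positions covered by full seed spans
  (first to last sampled nucleotide),
* **islands** — maximal runs of consecutive positions without match
  coverage, and their **E-size** ``E = (1/|s|) * sum(x**2)`` over island
  lengths ``x``: the expected island length observed at a uniformly
  random position of the string (covered positions count as islands of
  length zero),
* **uniqueness** — the percentage of seeds whose hash occurs exactly
  once,
* **overlap correctness** — the fraction of a mapped region's span that
  overlaps a known true interval.

Simulation parameters throughout the package are chosen so that false
(hash-collision or repeat) matches have negligible probability; the
statistics then measure the raw ability of a protocol to recover true
matches.
"""

from __future__ import annotations

import warnings
from collections.abc import Sequence as _SequenceABC
from dataclasses import dataclass
from typing import Iterator

import numpy as np

from .seeding import SeedSet

__all__ = [
    "Match",
    "MatchSet",
    "MatchMetrics",
    "find_matches",
    "sequence_coverage",
    "match_coverage",
    "islands",
    "island_e_size",
    "fraction_matches",
    "unique_fraction",
    "overlap_correctness",
    "evaluate_pair",
    "merge_intervals",
]


@dataclass(frozen=True)
class Match:
    """One hash-equal seed pair between query and reference."""

    q_positions: tuple[int, ...]
    r_positions: tuple[int, ...]
    q_span: tuple[int, int]
    r_span: tuple[int, int]
    hash: int


class MatchSet(_SequenceABC):
    """Column-oriented collection of matches between one sequence pair."""

    def __init__(
        self,
        q_positions: np.ndarray,
        r_positions: np.ndarray,
        hashes: np.ndarray,
        strobe_len: int,
        q_len: int,
        r_len: int,
    ) -> None:
        self.q_positions = np.atleast_2d(np.asarray(q_positions, dtype=np.int64))
        self.r_positions = np.atleast_2d(np.asarray(r_positions, dtype=np.int64))
        self.hashes = np.asarray(hashes, dtype=np.uint64)
        if self.q_positions.size == 0:
            self.q_positions = self.q_positions.reshape(0, max(1, self.r_positions.shape[1]))
            self.r_positions = self.r_positions.reshape(0, self.q_positions.shape[1])
        if not (len(self.q_positions) == len(self.r_positions) == len(self.hashes)):
            raise ValueError("match columns disagree in length")
        self.strobe_len = int(strobe_len)
        self.q_len = int(q_len)
        self.r_len = int(r_len)

    def __len__(self) -> int:
        return len(self.hashes)

    def __getitem__(self, i) -> Match:
        if not isinstance(i, (int, np.integer)):
            raise TypeError("MatchSet supports integer indexing only")
        q = self.q_positions[i]
        r = self.r_positions[i]
        return Match(
            q_positions=tuple(int(p) for p in q),
            r_positions=tuple(int(p) for p in r),
            q_span=(int(q[0]), int(q[-1]) + self.strobe_len),
            r_span=(int(r[0]), int(r[-1]) + self.strobe_len),
            hash=int(self.hashes[i]),
        )

    def __iter__(self) -> Iterator[Match]:
        for i in range(len(self)):
            yield self[i]

    def _positions(self, on: str) -> np.ndarray:
        if on == "query":
            return self.q_positions
        if on == "reference":
            return self.r_positions
        raise ValueError("on must be 'query' or 'reference'")


def find_matches(query_seeds: SeedSet, ref_seeds: SeedSet) -> MatchSet:
    """All hash-equal seed pairs between two seed sets.

    Both sets must come from the same protocol and parameters (their
    hashes are otherwise incomparable).
    """
    if query_seeds.strobe_len != ref_seeds.strobe_len or (
        query_seeds.positions.shape[1] != ref_seeds.positions.shape[1]
    ):
        raise ValueError("seed sets come from different protocols/parameters")
    qh = query_seeds.hashes
    order = np.argsort(ref_seeds.hashes, kind="stable")
    rh_sorted = ref_seeds.hashes[order]
    left = np.searchsorted(rh_sorted, qh, side="left")
    right = np.searchsorted(rh_sorted, qh, side="right")
    counts = right - left
    hit = counts > 0
    cnt = counts[hit]
    total = int(cnt.sum())
    q_idx = np.repeat(np.flatnonzero(hit), cnt)
    if total:
        offs = np.arange(total) - np.repeat(np.cumsum(cnt) - cnt, cnt)
        r_idx = order[np.repeat(left[hit], cnt) + offs]
    else:
        r_idx = np.empty(0, dtype=np.int64)
    return MatchSet(
        query_seeds.positions[q_idx],
        ref_seeds.positions[r_idx],
        qh[q_idx] if total else np.empty(0, dtype=np.uint64),
        query_seeds.strobe_len,
        query_seeds.seq_len,
        ref_seeds.seq_len,
    )


def merge_intervals(starts: np.ndarray, ends: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Union of half-open intervals as disjoint sorted intervals."""
    starts = np.asarray(starts, dtype=np.int64)
    ends = np.asarray(ends, dtype=np.int64)
    if starts.size == 0:
        return starts, ends
    order = np.argsort(starts, kind="stable")
    s, e = starts[order], ends[order]
    run_max = np.maximum.accumulate(e)
    new_run = np.ones(len(s), dtype=bool)
    new_run[1:] = s[1:] > run_max[:-1]
    idx = np.flatnonzero(new_run)
    merged_starts = s[idx]
    merged_ends = np.empty(len(idx), dtype=np.int64)
    merged_ends[:-1] = run_max[idx[1:] - 1]
    merged_ends[-1] = run_max[-1]
    return merged_starts, merged_ends


def _covered(matches: MatchSet, on: str, basis: str) -> tuple[np.ndarray, np.ndarray]:
    pos = matches._positions(on)
    if basis == "sequence":
        starts = pos.ravel()
        ends = starts + matches.strobe_len
    elif basis == "match":
        starts = pos[:, 0]
        ends = pos[:, -1] + matches.strobe_len
    else:
        raise ValueError("basis must be 'sequence' or 'match'")
    return merge_intervals(starts, ends)


def sequence_coverage(matches: MatchSet, seq_len: int, on: str = "query") -> float:
    """Fraction of positions covered by the matched strobes themselves."""
    if seq_len <= 0:
        raise ValueError("seq_len must be positive")
    s, e = _covered(matches, on, "sequence")
    return float((e - s).sum() / seq_len)


def match_coverage(matches: MatchSet, seq_len: int, on: str = "query") -> float:
    """Fraction of positions covered by full seed spans (first to last
    sampled nucleotide of each match)."""
    if seq_len <= 0:
        raise ValueError("seq_len must be positive")
    s, e = _covered(matches, on, "match")
    return float((e - s).sum() / seq_len)


def islands(
    matches: MatchSet, seq_len: int, on: str = "query", basis: str = "match"
) -> np.ndarray:
    """Lengths of maximal runs of positions without match coverage.

    By default islands are the complement of *match* coverage (full seed
    spans); pass ``basis='sequence'`` to use strobe-level coverage
    instead.  Covered length plus the island lengths always sums to
    ``seq_len``.
    """
    if seq_len <= 0:
        raise ValueError("seq_len must be positive")
    s, e = _covered(matches, on, basis)
    s = np.clip(s, 0, seq_len)
    e = np.clip(e, 0, seq_len)
    if s.size == 0:
        return np.array([seq_len], dtype=np.int64)
    gaps = np.concatenate(([s[0]], s[1:] - e[:-1], [seq_len - e[-1]]))
    return gaps[gaps > 0]


def island_e_size(island_lengths, seq_len: int) -> float:
    """Island E-size ``E = (1/|s|) * sum(x**2)`` over island lengths.

    ``E`` is the expected island length spanning a uniformly random
    position of the string (positions covered by matches contribute
    zero-length observations).
    """
    if seq_len <= 0:
        raise ValueError("seq_len must be positive")
    x = np.asarray(list(island_lengths), dtype=np.float64)
    if x.size == 0:
        return 0.0
    return float((x**2).sum() / seq_len)


def fraction_matches(query_seeds: SeedSet, matches: MatchSet) -> float:
    """Fraction of query seed positions participating in >= 1 match.

    Counting distinct matched query positions (not match pairs) keeps
    the value in [0, 1] even for repetitive sequences.
    """
    if len(query_seeds) == 0:
        warnings.warn("fraction_matches of an empty seed set is defined as 0.0")
        return 0.0
    matched = np.unique(matches.q_positions[:, 0]).size
    return matched / len(query_seeds)


def unique_fraction(seeds: SeedSet) -> float:
    """Percentage of seeds whose hash value occurs exactly once."""
    if len(seeds) == 0:
        warnings.warn("unique_fraction of an empty seed set is defined as 0%")
        return 0.0
    _, counts = np.unique(seeds.hashes, return_counts=True)
    return float(100.0 * counts[counts == 1].sum() / len(seeds))


def overlap_correctness(
    nam_interval: tuple[int, int], true_interval: tuple[int, int]
) -> float:
    """Fraction of ``nam_interval`` lying inside ``true_interval``.

    1.0 when the mapped region is fully within the true interval, 0.0
    when fully outside; both intervals are half-open.
    """
    ns, ne = nam_interval
    ts, te = true_interval
    if ne <= ns:
        raise ValueError("nam_interval must be non-empty")
    inter = max(0, min(ne, te) - max(ns, ts))
    return inter / (ne - ns)


@dataclass
class MatchMetrics:
    """Per-pair summary of the match statistics on one string."""

    fraction_matches: float
    sequence_coverage: float
    match_coverage: float
    island_lengths: np.ndarray
    e_size: float


def evaluate_pair(
    query_seeds: SeedSet,
    ref_seeds: SeedSet,
    seq_len: int | None = None,
    islands_basis: str = "match",
) -> MatchMetrics:
    """Match the two seed sets and summarise statistics on the query."""
    if seq_len is None:
        seq_len = query_seeds.seq_len
    m = find_matches(query_seeds, ref_seeds)
    isl = islands(m, seq_len, on="query", basis=islands_basis)
    return MatchMetrics(
        fraction_matches=fraction_matches(query_seeds, m),
        sequence_coverage=sequence_coverage(m, seq_len),
        match_coverage=match_coverage(m, seq_len),
        island_lengths=isl,
        e_size=island_e_size(isl, seq_len),
    )
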