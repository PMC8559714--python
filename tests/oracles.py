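"""Independent brute-force reference implementations used as test oracles.

Everything here recomputes results from first principles (per-window
scans, bitmaps, run-length encoding, exhaustive search) without reusing
the package's optimized code paths, so agreement is meaningful.
"""

from __future__ import annotations

import itertools

import numpy as np

from strobeseed.seeding import (
    RANDSTROBE_MASK,
    Protocol,
    SeedParams,
    precompute_strobe_hashes,
)

U64_MASK = (1 << 64) - 1


def naive_window(i: int, j: int, params: SeedParams, seq_len: int):
    """Strobe-j window from the definition: [i + w_min + (j-2) w_max,
    i + (j-1) w_max], proportionally narrowed at the tail."""
    n, ell = params.n, params.ell
    w_min, w_max = params.w_min, params.w_max
    rem = seq_len - i
    if (n - 1) * w_max + ell <= rem:
        return i + w_min + (j - 2) * w_max, i + (j - 1) * w_max
    v = rem // n
    if v <= ell:
        return i + (j - 1) * ell, i + (j - 1) * ell
    return i + min(w_min, v) + (j - 2) * v, i + (j - 1) * v


def naive_segments(lo: int, hi: int, x: int):
    if x <= 1 or (hi - lo) // x < 1:
        return [(lo, hi)]
    w_x = (hi - lo) // x
    segs = [(lo + r * w_x, lo + (r + 1) * w_x - 1) for r in range(x - 1)]
    segs.append((lo + (x - 1) * w_x, hi))
    return segs


def naive_strobemer_positions(s: str, params: SeedParams) -> list[tuple[int, ...]]:
    """Per-seed strobe positions via per-window recomputation (no queues,
    no vectorization, no caching beyond the per-position hash array)."""
    H = [int(h) for h in precompute_strobe_hashes(s, params.ell)]
    L = len(s)
    N = L - params.k + 1
    out = []
    for i in range(max(0, N)):
        if not params.narrow_tail and (params.n - 1) * params.w_max + params.ell > L - i:
            continue
        positions = [i]
        prev_sum = H[i]
        prev_hash = H[i]
        for j in range(2, params.n + 1):
            lo, hi = naive_window(i, j, params, L)
            cands = list(range(lo, hi + 1))
            if params.protocol is Protocol.MINSTROBE:
                p = min(cands, key=lambda c: (H[c], c))
            elif params.protocol is Protocol.RANDSTROBE:
                p = min(cands, key=lambda c: ((prev_sum + H[c]) & RANDSTROBE_MASK, c))
                prev_sum = (prev_sum + H[p]) & U64_MASK
            else:
                segs = naive_segments(lo, hi, params.x)
                a, b = segs[prev_hash % len(segs)]
                p = min(range(a, b + 1), key=lambda c: (H[c], c))
                prev_hash = H[p]
            positions.append(p)
        out.append(tuple(positions))
    return out


def bitmap_coverage(starts, ends, seq_len: int) -> int:
    """Covered-position count via an explicit position bitmap."""
    bitmap = np.zeros(seq_len, dtype=bool)
    for s, e in zip(starts, ends):
        bitmap[max(0, s) : min(seq_len, e)] = True
    return int(bitmap.sum())


def run_length_islands(starts, ends, seq_len: int) -> list[int]:
    """Uncovered-run lengths via run-length encoding of the bitmap."""
    bitmap = np.zeros(seq_len, dtype=bool)
    for s, e in zip(starts, ends):
        bitmap[max(0, s) : min(seq_len, e)] = True
    lengths = []
    run = 0
    for covered in bitmap:
        if covered:
            if run:
                lengths.append(run)
            run = 0
        else:
            run += 1
    if run:
        lengths.append(run)
    return lengths


def monte_carlo_e_size(island_lengths, seq_len: int, draws: int, rng) -> float:
    """Estimate the expected island size by sampling uniform positions.

    Islands are laid out left to right; a drawn position landing inside
    an island observes that island's length, otherwise zero.
    """
    lengths = np.asarray(island_lengths, dtype=np.int64)
    boundaries = np.cumsum(lengths)
    total = boundaries[-1] if len(boundaries) else 0
    pos = rng.integers(0, seq_len, size=draws)
    inside = pos < total
    idx = np.searchsorted(boundaries, pos[inside], side="right")
    observed = np.zeros(draws, dtype=np.float64)
    observed[inside] = lengths[idx]
    return float(observed.mean())


def exact_kmer_match_count(s: str, t: str, k: int) -> int:
    """Number of (i, i') pairs with s[i:i+k] == t[i':i'+k], by direct
    substring comparison."""
    from collections import Counter

    t_counts = Counter(t[i : i + k] for i in range(len(t) - k + 1))
    return sum(
        t_counts[s[i : i + k]] for i in range(len(s) - k + 1)
    )


def window_minimizer_indices(values, w: int) -> list[int]:
    """Retained indices from a direct scan of every length-w window."""
    values = list(values)
    N = len(values)
    if N == 0:
        return []
    if w >= N:
        windows = [range(N)]
    else:
        windows = [range(i, i + w) for i in range(N - w + 1)]
    keep = set()
    for window in windows:
        keep.add(min(window, key=lambda i: (values[i], i)))
    return sorted(keep)


def exhaustive_chain_score(nams) -> int:
    """Best covered-query-length over all strictly collinear NAM subsets,
    by explicit enumeration (exponential; for small inputs only)."""
    best = 0
    n = len(nams)
    for size in range(1, n + 1):
        for combo in itertools.combinations(range(n), size):
            ordered = sorted(combo, key=lambda i: (nams[i].q_start, nams[i].r_start))
            ok = all(
                nams[a].q_start < nams[b].q_start and nams[a].r_start < nams[b].r_start
                for a, b in zip(ordered, ordered[1:])
            )
            if not ok:
                continue
            covered = set()
            for i in ordered:
                covered.update(range(nams[i].q_start, nams[i].q_end))
            best = max(best, len(covered))
    return best
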