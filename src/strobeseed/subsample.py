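"""Minimizer-style thinning of a seed stream.

Any protocol's seeds can be subsampled by sliding a window of ``w``
consecutive seed start positions over the stream and retaining, per
window, the start with the lowest selection hash (ties broken by the
leftmost position).  For k-mers and spaced k-mers the selection hash is
the seed hash itself; for strobemers it is the hash of the *first
strobe*, and the full strobemer is then built from each retained start
under the normal protocol.  Retained starts are deduplicated across
overlapping windows, so the output is a subset of the unthinned seed
list; on random sequences the expected density is about ``2 / (w + 1)``.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .seeding import Protocol, SeedParams, SeedSet, generate_seeds, precompute_strobe_hashes

__all__ = ["minimizer_subsample", "thin_indices"]


def thin_indices(values: np.ndarray, w: int) -> np.ndarray:
    """Indices retained by minimizer thinning of a value stream.

    Every window of ``w`` consecutive entries keeps its leftmost
    minimum; a stream shorter than ``w`` forms a single window.  Returns
    sorted unique indices.
    """
    if w < 1:
        raise ValueError("window size w must be >= 1")
    values = np.asarray(values)
    N = len(values)
    if N == 0:
        return np.empty(0, dtype=np.int64)
    if w == 1:
        return np.arange(N, dtype=np.int64)
    if w >= N:
        return np.array([int(np.argmin(values))], dtype=np.int64)
    view = sliding_window_view(values, w)
    keep = np.arange(N - w + 1, dtype=np.int64) + np.argmin(view, axis=1)
    return np.unique(keep)


def minimizer_subsample(
    s: str, params: SeedParams, w: int, seq_id: str | None = None
) -> SeedSet:
    """Thin the seed stream of ``s`` with a minimizer window of ``w`` starts.

    ``w <= 1`` disables thinning and returns the full seed set.
    Retained seeds are bit-identical to the corresponding entries of the
    unthinned stream.
    """
    full = generate_seeds(s, params, seq_id=seq_id)
    if w <= 1 or len(full) == 0:
        return full
    if Protocol(params.protocol) in (Protocol.KMER, Protocol.SPACED):
        selection = full.hashes
    else:
        first_strobe_hashes = precompute_strobe_hashes(s, params.ell)
        selection = first_strobe_hashes[full.positions[:, 0]]
    return full.subset(thin_indices(selection, w))
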