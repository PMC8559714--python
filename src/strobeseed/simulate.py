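"""Sequence simulation and the replicated random-mutation experiment.

Two mutation regimes are provided.  The *fixed-spacing* regime places
one mutation at every ``d``-th position of the source string (a
controlled scenario that defeats contiguous k-mers of length > d by
construction).  The *random* regime mutates every position
independently with probability ``mu``.  In both regimes the mutation
type is drawn uniformly from insertion, deletion and substitution
(probability 1/3 each); a substitution always changes the letter, an
insertion adds one uniform base *before* the mutated position, and a
deletion removes the base.  Mutation positions refer to the original
string: positions are decided first and the edits are applied
right-to-left, so earlier edits never shift later ones.  Insertions and
deletions are equiprobable, hence the expected length of the mutated
string equals the original length for every ``mu``.

:func:`run_sim_r` reproduces the replicated random-mutation experiment:
draw a random string (10,000 nt by default), mutate it at rates
``mu in {0.01, 0.05, 0.1}``, seed both strings under each protocol and
average the match statistics over replicates (1000 by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple, Sequence, Union

import numpy as np
import pandas as pd

from . import metrics as _metrics
from .seeding import Protocol, SeedParams, generate_seeds, make_spaced_mask
from .subsample import minimizer_subsample

__all__ = [
    "Mutation",
    "MutationModel",
    "random_sequence",
    "mutate_fixed",
    "mutate_random",
    "simr_protocols",
    "SimRResult",
    "run_sim_r",
]

_BASES = np.array(list("ACGT"))


class Mutation(NamedTuple):
    """One mutation event: 0-based position on the original string and
    its kind ('ins', 'del' or 'sub')."""

    position: int
    kind: str


def random_sequence(L: int, rng_seed) -> str:
    """Uniform i.i.d. DNA string of length ``L``, reproducible from seed."""
    if L < 0:
        raise ValueError("length must be >= 0")
    if L == 0:
        return ""
    rng = np.random.default_rng(rng_seed)
    return "".join(_BASES[rng.integers(0, 4, size=L)])


_KINDS = ("ins", "del", "sub")


def _apply_mutations(s: str, positions: np.ndarray, rng) -> tuple[str, list[Mutation]]:
    kinds = rng.integers(0, 3, size=len(positions))
    events = [Mutation(int(p), _KINDS[k]) for p, k in zip(positions, kinds)]
    chars = list(s)
    # right-to-left so original-string coordinates stay valid
    for pos, kind in reversed(events):
        if kind == "del":
            del chars[pos]
        elif kind == "ins":
            chars.insert(pos, str(_BASES[rng.integers(0, 4)]))
        else:  # substitution: always a different letter
            alternatives = [b for b in "ACGT" if b != chars[pos]]
            chars[pos] = alternatives[rng.integers(0, 3)]
    return "".join(chars), events


def mutate_fixed(s: str, d: int, rng_seed) -> tuple[str, list[Mutation]]:
    """Mutate every ``d``-th position of ``s`` (positions d, 2d, ...).

    Each site receives an insertion, deletion or substitution with
    probability 1/3.  ``d`` larger than the string leaves it unchanged.
    """
    if d < 1:
        raise ValueError("spacing d must be >= 1")
    rng = np.random.default_rng(rng_seed)
    positions = np.arange(d - 1, len(s), d, dtype=np.int64)
    return _apply_mutations(s, positions, rng)


def mutate_random(s: str, mu: float, rng_seed) -> tuple[str, list[Mutation]]:
    """Mutate each position of ``s`` independently with probability ``mu``."""
    if not 0.0 <= mu <= 1.0:
        raise ValueError("mutation rate mu must be in [0, 1]")
    rng = np.random.default_rng(rng_seed)
    positions = np.flatnonzero(rng.random(len(s)) < mu)
    return _apply_mutations(s, positions, rng)


@dataclass
class MutationModel:
    """Mutation process selector.

    ``mode='fixed_spacing'`` uses spacing ``d``; ``mode='random'`` uses
    per-position rate ``mu``.  Insertion, deletion and substitution are
    equiprobable (1/3 each) in both modes.
    """

    mode: str
    d: int | None = None
    mu: float | None = None
    rng_seed: Union[int, None] = None
    type_probs: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)

    def __post_init__(self) -> None:
        if self.mode not in ("fixed_spacing", "random"):
            raise ValueError("mode must be 'fixed_spacing' or 'random'")
        if abs(sum(self.type_probs) - 1.0) > 1e-12:
            raise ValueError("type probabilities must sum to 1")
        if self.type_probs != (1 / 3, 1 / 3, 1 / 3):
            raise NotImplementedError("only equiprobable mutation types are supported")
        if self.mode == "fixed_spacing" and (self.d is None or self.d < 1):
            raise ValueError("fixed_spacing mode needs spacing d >= 1")
        if self.mode == "random" and (self.mu is None or not 0 <= self.mu <= 1):
            raise ValueError("random mode needs mu in [0, 1]")

    def apply(self, s: str, rng_seed=None) -> tuple[str, list[Mutation]]:
        seed = rng_seed if rng_seed is not None else self.rng_seed
        if self.mode == "fixed_spacing":
            return mutate_fixed(s, self.d, seed)
        return mutate_random(s, self.mu, seed)


# ---------------------------------------------------------------------------
# The replicated random-mutation experiment
# ---------------------------------------------------------------------------

#: Total sampled length shared by all default protocols.
_DEFAULT_K = 30


def simr_protocols(mask_seed=0, k: int = _DEFAULT_K) -> dict[str, SeedParams]:
    """The default protocol battery at total sampled length ``k``.

    Strobemers of order 2 use ``(2, k/2, k/2+1, 50)`` and order 3
    ``(3, k/3, k/3+1, 25)``, giving equal sampled length and comparable
    spans between orders; spaced masks are drawn (dense: span 1.5k,
    sparse: span 3k) reproducibly from ``mask_seed``.
    """
    if k % 6:
        raise ValueError("total length k must be divisible by 6 for the battery")
    ss = (
        mask_seed
        if isinstance(mask_seed, np.random.SeedSequence)
        else np.random.SeedSequence(mask_seed)
    )
    dense_seed, sparse_seed = ss.spawn(2)
    ell2, ell3 = k // 2, k // 3
    return {
        "kmer": SeedParams(Protocol.KMER, k=k),
        "spaced_dense": SeedParams(
            Protocol.SPACED, mask=make_spaced_mask(k, "dense", dense_seed)
        ),
        "spaced_sparse": SeedParams(
            Protocol.SPACED, mask=make_spaced_mask(k, "sparse", sparse_seed)
        ),
        "minstrobe2": SeedParams(Protocol.MINSTROBE, n=2, ell=ell2, w_min=ell2 + 1, w_max=50),
        "minstrobe3": SeedParams(Protocol.MINSTROBE, n=3, ell=ell3, w_min=ell3 + 1, w_max=25),
        "randstrobe2": SeedParams(Protocol.RANDSTROBE, n=2, ell=ell2, w_min=ell2 + 1, w_max=50),
        "randstrobe3": SeedParams(Protocol.RANDSTROBE, n=3, ell=ell3, w_min=ell3 + 1, w_max=25),
        "hybridstrobe2": SeedParams(
            Protocol.HYBRIDSTROBE, n=2, ell=ell2, w_min=ell2 + 1, w_max=50, x=3
        ),
        "hybridstrobe3": SeedParams(
            Protocol.HYBRIDSTROBE, n=3, ell=ell3, w_min=ell3 + 1, w_max=25, x=3
        ),
    }


@dataclass
class SimRResult:
    """Output of :func:`run_sim_r`.

    ``table`` holds one row per (protocol, mu) with replicate-mean
    statistics; ``islands`` maps (protocol, mu) to the pooled island
    lengths across replicates; ``sequences`` optionally keeps the
    simulated pairs for export.
    """

    table: pd.DataFrame
    islands: dict[tuple[str, float], np.ndarray]
    sequences: list[tuple[str, str]] = field(default_factory=list)

    def to_tsv(self, path) -> None:
        """Write the metric table as TSV with percent-scaled columns."""
        out = self.table.copy()
        for col, pct in [
            ("fraction_matches", "pct_matches"),
            ("sequence_coverage", "pct_seq_cov"),
            ("match_coverage", "pct_match_cov"),
        ]:
            out[pct] = 100.0 * out.pop(col)
        cols = [
            "protocol", "parameters", "mu",
            "pct_matches", "pct_seq_cov", "pct_match_cov", "e_size",
        ]
        out[cols + [c for c in out.columns if c not in cols]].to_csv(
            path, sep="\t", index=False
        )


def _describe_params(p: SeedParams) -> str:
    if p.protocol is Protocol.KMER:
        return f"k={p.k}"
    if p.protocol is Protocol.SPACED:
        return f"k={p.k},L={p.mask.L}"
    desc = f"({p.n},{p.ell},{p.w_min},{p.w_max})"
    if p.protocol is Protocol.HYBRIDSTROBE:
        desc += f",x={p.x}"
    return desc


def _resolve_protocols(protocols, mask_seed) -> dict[str, SeedParams]:
    defaults = simr_protocols(mask_seed=mask_seed)
    if protocols is None:
        return defaults
    if isinstance(protocols, Mapping):
        return dict(protocols)
    resolved: dict[str, SeedParams] = {}
    for name in protocols:
        if isinstance(name, SeedParams):
            resolved[f"{name.protocol.value}_{len(resolved)}"] = name
            continue
        if name not in defaults:
            raise ValueError(
                f"unknown protocol {name!r}; known presets: {sorted(defaults)}"
            )
        resolved[name] = defaults[name]
    return resolved


def run_sim_r(
    L: int = 10_000,
    mu_list: Sequence[float] = (0.01, 0.05, 0.1),
    protocols: Union[Mapping[str, SeedParams], Iterable, None] = None,
    replicates: int = 1000,
    rng_seed=0,
    thin_w: int = 0,
    islands_basis: str = "match",
    keep_sequences: bool = False,
) -> SimRResult:
    """Replicated random-mutation experiment.

    For each replicate a random string ``s`` of length ``L`` is drawn
    and mutated at every rate in ``mu_list``; each protocol seeds both
    strings (optionally thinned with a minimizer window ``thin_w``) and
    the match statistics are computed on ``s``.  The table reports
    replicate means; island lengths are pooled.  Fully reproducible from
    ``rng_seed``.
    """
    if replicates < 1:
        raise ValueError("need at least one replicate")
    master = (
        rng_seed
        if isinstance(rng_seed, np.random.SeedSequence)
        else np.random.SeedSequence(rng_seed)
    )
    mask_ss, sim_ss = master.spawn(2)
    protos = _resolve_protocols(protocols, mask_ss)
    rep_seeds = sim_ss.spawn(replicates)

    acc: dict[tuple[str, float], list[list[float]]] = {
        (name, mu): [[], [], [], []] for name in protos for mu in mu_list
    }
    pooled: dict[tuple[str, float], list[np.ndarray]] = {
        key: [] for key in acc
    }
    sequences: list[tuple[str, str]] = []

    def seeds_of(seq: str, params: SeedParams):
        if thin_w and thin_w > 1:
            return minimizer_subsample(seq, params, thin_w)
        return generate_seeds(seq, params)

    for rep, rep_ss in enumerate(rep_seeds):
        children = rep_ss.spawn(1 + len(mu_list))
        s = random_sequence(L, children[0])
        if keep_sequences:
            sequences.append((f"rep{rep}_s", s))
        q_cache = {name: seeds_of(s, p) for name, p in protos.items()}
        for mi, mu in enumerate(mu_list):
            t, _ = mutate_random(s, mu, children[1 + mi])
            if keep_sequences:
                sequences.append((f"rep{rep}_mu{mu}_t", t))
            for name, p in protos.items():
                r_seeds = seeds_of(t, p)
                mm = _metrics.evaluate_pair(
                    q_cache[name], r_seeds, seq_len=L, islands_basis=islands_basis
                )
                cells = acc[(name, mu)]
                cells[0].append(mm.fraction_matches)
                cells[1].append(mm.sequence_coverage)
                cells[2].append(mm.match_coverage)
                cells[3].append(mm.e_size)
                pooled[(name, mu)].append(mm.island_lengths)

    rows = []
    for name in protos:
        for mu in mu_list:
            cells = acc[(name, mu)]
            rows.append(
                {
                    "protocol": name,
                    "parameters": _describe_params(protos[name]),
                    "mu": mu,
                    "fraction_matches": float(np.mean(cells[0])),
                    "sequence_coverage": float(np.mean(cells[1])),
                    "match_coverage": float(np.mean(cells[2])),
                    "e_size": float(np.mean(cells[3])),
                    "replicates": replicates,
                }
            )
    island_arrays = {
        key: (
            np.concatenate(parts) if parts else np.empty(0, dtype=np.int64)
        )
        for key, parts in pooled.items()
    }
    return SimRResult(pd.DataFrame(rows), island_arrays, sequences)
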