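"""Proof-of-concept sequence mapper built on the seeding protocols.

References are seeded and indexed in a flat array sorted by hash with a
hash -> (offset, count) lookup table.  Query seeds are matched against
the index; matches that overlap both on the query and on the reference
are greedily merged into *NAMs* (nonoverlapping approximately matching
regions).  Optionally the longest collinear chain of NAMs — the chain
maximizing covered query length under strictly increasing query and
reference starts — is computed per (query, reference) pair.  Mappings
are written as a seven-column TSV with 1-based inclusive coordinates.

The module also provides FASTA/FASTQ input (plain or gzip) and the
``strobeseed`` command line interface.
"""

from __future__ import annotations

import gzip
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence, TextIO, Union

import click
import numpy as np

from . import __version__
from .metrics import unique_fraction
from .seeding import (
    Protocol,
    SeedParams,
    SeedSet,
    SpacedMask,
    generate_seeds,
    make_spaced_mask,
)
from .simulate import run_sim_r
from .subsample import minimizer_subsample

__all__ = [
    "NAM",
    "Chain",
    "SeedIndex",
    "read_sequences",
    "write_fasta",
    "build_index",
    "compute_nams",
    "collinear_chain",
    "write_tsv",
    "read_tsv",
    "cli",
    "main",
]


# ---------------------------------------------------------------------------
# Sequence I/O
# ---------------------------------------------------------------------------

_FASTA_EXT = {".fa", ".fasta", ".fna", ".ffn"}
_FASTQ_EXT = {".fq", ".fastq"}


def _open_text(path) -> TextIO:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def _guess_format(path) -> str:
    path = Path(path)
    suffixes = [s.lower() for s in path.suffixes]
    if suffixes and suffixes[-1] == ".gz":
        suffixes = suffixes[:-1]
    if suffixes and suffixes[-1] in _FASTA_EXT:
        return "fasta"
    if suffixes and suffixes[-1] in _FASTQ_EXT:
        return "fastq"
    raise ValueError(f"cannot infer sequence format from {path.name!r}")


def read_sequences(path, format: str | None = None) -> list[tuple[str, str]]:
    """Read FASTA or FASTQ (optionally gzip-compressed) records.

    Returns ``(id, sequence)`` pairs in file order; sequences are
    uppercased, qualities (FASTQ) are ignored.  A malformed record
    raises :class:`ValueError` naming the record index.
    """
    from Bio import SeqIO

    fmt = format or _guess_format(path)
    records: list[tuple[str, str]] = []
    with _open_text(path) as handle:
        parser = SeqIO.parse(handle, fmt)
        index = 0
        while True:
            try:
                record = next(parser)
            except StopIteration:
                break
            except Exception as exc:
                raise ValueError(
                    f"malformed {fmt} record {index + 1} in {path}: {exc}"
                ) from exc
            records.append((record.id, str(record.seq).upper()))
            index += 1
    return records


def write_fasta(records: Iterable[tuple[str, str]], path) -> None:
    """Write ``(id, sequence)`` pairs as FASTA (gzip if path ends .gz)."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "wt") as fh:
        for name, seq in records:
            fh.write(f">{name}\n{seq}\n")


# ---------------------------------------------------------------------------
# Index, NAMs, chains
# ---------------------------------------------------------------------------


class SeedIndex:
    """Reference seeds in a flat array sorted by hash.

    Stores, per seed, the hash, the reference id and the start of the
    first and last sampled component (enough to recover the span).  A
    lookup table maps each hash to its (offset, count) in the sorted
    array.
    """

    def __init__(self, references: Sequence[tuple[str, str]], params: SeedParams,
                 thin_w: int = 0) -> None:
        if not references:
            raise ValueError("cannot index an empty reference set")
        self.params = params
        self.ref_names = [name for name, _ in references]
        self.ref_lengths = [len(seq) for _, seq in references]
        hash_parts, pos_parts, rid_parts = [], [], []
        strobe_len = None
        for rid, (name, seq) in enumerate(references):
            if thin_w and thin_w > 1:
                seeds = minimizer_subsample(seq, params, thin_w, seq_id=name)
            else:
                seeds = generate_seeds(seq, params, seq_id=name)
            strobe_len = seeds.strobe_len
            hash_parts.append(seeds.hashes)
            pos_parts.append(seeds.positions[:, [0, -1]])
            rid_parts.append(np.full(len(seeds), rid, dtype=np.int32))
        self.strobe_len = int(strobe_len)
        hashes = np.concatenate(hash_parts)
        order = np.argsort(hashes, kind="stable")
        self.hashes = hashes[order]
        self.positions = np.concatenate(pos_parts)[order]
        self.ref_ids = np.concatenate(rid_parts)[order]
        uniq, offsets, counts = np.unique(
            self.hashes, return_index=True, return_counts=True
        )
        self.lookup = {
            int(h): (int(o), int(c)) for h, o, c in zip(uniq, offsets, counts)
        }

    def __len__(self) -> int:
        return len(self.hashes)

    def query(self, h: int) -> tuple[np.ndarray, np.ndarray]:
        """(ref_ids, positions) of every indexed seed with hash ``h``."""
        entry = self.lookup.get(int(h))
        if entry is None:
            return (
                np.empty(0, dtype=np.int32),
                np.empty((0, 2), dtype=np.int64),
            )
        off, cnt = entry
        return self.ref_ids[off : off + cnt], self.positions[off : off + cnt]


def build_index(
    references: Sequence[tuple[str, str]], params: SeedParams, thin_w: int = 0
) -> SeedIndex:
    """Seed every reference and build the sorted hash index."""
    return SeedIndex(references, params, thin_w=thin_w)


@dataclass
class NAM:
    """Nonoverlapping approximately matching region.

    Coordinates are 0-based half-open on both sequences; ``n_hits``
    counts the merged seed matches supporting the region.
    """

    query_id: str
    ref_id: str
    q_start: int
    q_end: int
    r_start: int
    r_end: int
    n_hits: int = 1

    @property
    def q_length(self) -> int:
        return self.q_end - self.q_start


@dataclass
class Chain:
    """Collinear chain of NAMs with its covered query length."""

    nams: list[NAM] = field(default_factory=list)
    coverage: int = 0


def compute_nams(
    query: tuple[str, str],
    index: SeedIndex,
    params: SeedParams | None = None,
    max_occ: int | None = None,
    thin_w: int = 0,
) -> list[NAM]:
    """Merge the query's seed matches into NAMs, per reference.

    Matches are sorted by query position and greedily merged: a match
    joins an open NAM when its query span and reference span both
    overlap the NAM's current spans and both start coordinates are at or
    beyond the NAM's starts; otherwise it opens a new NAM.  NAM spans
    are the union of their member-match spans.  ``max_occ`` (off by
    default) skips seeds whose hash occurs more often in the index.
    """
    qid, qseq = query
    params = params if params is not None else index.params
    if thin_w and thin_w > 1:
        qseeds = minimizer_subsample(qseq, params, thin_w, seq_id=qid)
    else:
        qseeds = generate_seeds(qseq, params, seq_id=qid)
    sl = index.strobe_len
    rows = []  # (ref_id, q_start, q_end, r_start, r_end)
    for i in range(len(qseeds)):
        h = int(qseeds.hashes[i])
        entry = index.lookup.get(h)
        if entry is None:
            continue
        off, cnt = entry
        if max_occ is not None and cnt > max_occ:
            continue
        qs = int(qseeds.positions[i, 0])
        qe = int(qseeds.positions[i, -1]) + sl
        for j in range(off, off + cnt):
            rs = int(index.positions[j, 0])
            re_ = int(index.positions[j, 1]) + sl
            rows.append((int(index.ref_ids[j]), qs, qe, rs, re_))
    rows.sort()
    nams: list[NAM] = []
    open_nams: list[NAM] = []
    current_ref = None
    for rid, qs, qe, rs, re_ in rows:
        if rid != current_ref:
            nams.extend(open_nams)
            open_nams = []
            current_ref = rid
        still_open = []
        for nam in open_nams:
            if nam.q_end <= qs:
                nams.append(nam)  # no later match can reach it
            else:
                still_open.append(nam)
        open_nams = still_open
        joined = False
        for nam in open_nams:
            if qs < nam.q_end and nam.r_start <= rs < nam.r_end:
                nam.q_end = max(nam.q_end, qe)
                nam.r_end = max(nam.r_end, re_)
                nam.n_hits += 1
                joined = True
                break
        if not joined:
            open_nams.append(
                NAM(qid, index.ref_names[rid], qs, qe, rs, re_, n_hits=1)
            )
    nams.extend(open_nams)
    nams.sort(key=lambda n: (n.ref_id, n.q_start, n.r_start))
    return nams


def collinear_chain(nams: Sequence[NAM]) -> Chain:
    """Longest collinear chain of NAMs by covered query length.

    Selected NAMs must strictly increase in both query start and
    reference start; the objective is the length of the union of their
    query spans.  Solved exactly by dynamic programming over
    (score, chain-end) Pareto states.
    """
    if not nams:
        return Chain([], 0)
    if len({n.query_id for n in nams}) > 1:
        raise ValueError("all NAMs in a chain must share one query")
    order = sorted(
        range(len(nams)),
        key=lambda i: (nams[i].q_start, nams[i].r_start, nams[i].q_end, i),
    )
    # states[i]: list of (score, chain_max_q_end, predecessor state or None)
    states: list[list[tuple[int, int, tuple[int, int] | None]]] = [
        [] for _ in order
    ]
    for a, i in enumerate(order):
        ni = nams[i]
        cands: list[tuple[int, int, tuple[int, int] | None]] = [
            (ni.q_length, ni.q_end, None)
        ]
        for b in range(a):
            j = order[b]
            nj = nams[j]
            if nj.q_start < ni.q_start and nj.r_start < ni.r_start:
                for si, (score, end, _) in enumerate(states[b]):
                    gain = max(0, ni.q_end - max(ni.q_start, end))
                    cands.append((score + gain, max(end, ni.q_end), (b, si)))
        cands.sort(key=lambda t: (-t[0], t[1]))
        pareto: list[tuple[int, int, tuple[int, int] | None]] = []
        best_end = None
        for score, end, prev in cands:
            if best_end is None or end < best_end:
                pareto.append((score, end, prev))
                best_end = end
        states[a] = pareto
    best = None  # (score, a, state index)
    for a, state_list in enumerate(states):
        for si, (score, _, _) in enumerate(state_list):
            if best is None or score > best[0]:
                best = (score, a, si)
    chain_idx: list[int] = []
    a, si = best[1], best[2]
    while True:
        chain_idx.append(order[a])
        prev = states[a][si][2]
        if prev is None:
            break
        a, si = prev
    chain_idx.reverse()
    return Chain([nams[i] for i in chain_idx], int(best[0]))


# ---------------------------------------------------------------------------
# TSV output (MUMmer-like coordinate conventions: 1-based inclusive)
# ---------------------------------------------------------------------------

_TSV_HEADER = "query_id\tref_id\tq_start\tq_end\tr_start\tr_end\tn_hits"


def write_tsv(items: Iterable[Union[NAM, Chain]], path) -> None:
    """Write NAMs (or the NAMs of chains, in chain order) as TSV.

    Columns: query_id, ref_id, q_start, q_end, r_start, r_end, n_hits
    with 1-based inclusive coordinates; rows ordered by query (input
    order), then query start, then reference start.
    """
    flat: list[NAM] = []
    for item in items:
        if isinstance(item, Chain):
            flat.extend(item.nams)
        else:
            flat.append(item)
    query_rank: dict[str, int] = {}
    for nam in flat:
        query_rank.setdefault(nam.query_id, len(query_rank))
    flat.sort(key=lambda n: (query_rank[n.query_id], n.q_start, n.r_start))
    with open(path, "w") as fh:
        fh.write(_TSV_HEADER + "\n")
        for n in flat:
            fh.write(
                f"{n.query_id}\t{n.ref_id}\t{n.q_start + 1}\t{n.q_end}\t"
                f"{n.r_start + 1}\t{n.r_end}\t{n.n_hits}\n"
            )


def read_tsv(path) -> list[NAM]:
    """Read a mapping TSV written by :func:`write_tsv` back into NAMs."""
    nams = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        if header != _TSV_HEADER:
            raise ValueError(f"unexpected header in {path}: {header!r}")
        for line in fh:
            qid, rid, qs, qe, rs, re_, hits = line.rstrip("\n").split("\t")
            nams.append(
                NAM(qid, rid, int(qs) - 1, int(qe), int(rs) - 1, int(re_), int(hits))
            )
    return nams


# ---------------------------------------------------------------------------
# Command line interface
# ---------------------------------------------------------------------------


def _params_from_options(
    protocol: str,
    k: int | None,
    n: int | None,
    ell: int | None,
    w_min: int | None,
    w_max: int | None,
    x: int,
    mask_pattern: str | None,
    mask_density: str | None,
    mask_seed: int,
    no_narrow: bool,
) -> SeedParams:
    try:
        proto = Protocol(protocol)
        mask = None
        if proto is Protocol.SPACED:
            if mask_pattern:
                mask = SpacedMask.from_string(mask_pattern)
            else:
                if k is None:
                    raise ValueError("spaced protocol needs -k (with --mask-density)")
                mask = make_spaced_mask(k, mask_density or "dense", mask_seed)
        return SeedParams(
            proto,
            k=k if proto in (Protocol.KMER,) else None,
            n=n,
            ell=ell,
            w_min=w_min,
            w_max=w_max,
            x=x,
            mask=mask,
            narrow_tail=not no_narrow,
        )
    except ValueError as exc:
        raise click.BadParameter(str(exc)) from exc


def _protocol_options(f):
    opts = [
        click.option("--protocol", "-p", default="kmer", show_default=True,
                     type=click.Choice([p.value for p in Protocol])),
        click.option("-k", type=int, default=None, help="total sampled length (kmer/spaced)"),
        click.option("-n", "--order", "n", type=int, default=None, help="strobes per seed"),
        click.option("-l", "--ell", type=int, default=None, help="strobe length"),
        click.option("--w-min", type=int, default=None, help="window lower offset"),
        click.option("--w-max", type=int, default=None, help="window upper offset"),
        click.option("-x", type=int, default=3, show_default=True,
                     help="hybridstrobe subwindow count"),
        click.option("--mask", "mask_pattern", default=None,
                     help="explicit spaced mask, e.g. 101011"),
        click.option("--mask-density", type=click.Choice(["dense", "sparse"]),
                     default=None, help="random spaced mask density"),
        click.option("--mask-seed", type=int, default=0, show_default=True),
        click.option("--no-narrow", is_flag=True,
                     help="disable window narrowing at sequence ends"),
        click.option("--thin-w", type=int, default=0, show_default=True,
                     help="minimizer thinning window (0 = off)"),
    ]
    for opt in reversed(opts):
        f = opt(f)
    return f


@click.group()
@click.version_option(version=__version__, prog_name="strobeseed")
def main() -> None:
    """Strobemer/k-mer seeding, simulation and mapping toolkit."""


@main.command("seed")
@click.argument("input_path", type=click.Path(exists=True, dir_okay=False))
@click.option("-o", "--output", type=click.Path(dir_okay=False), required=True)
@_protocol_options
def seed_cmd(input_path, output, protocol, k, n, ell, w_min, w_max, x,
             mask_pattern, mask_density, mask_seed, no_narrow, thin_w):
    """Dump all seeds of the input sequences as TSV."""
    params = _params_from_options(protocol, k, n, ell, w_min, w_max, x,
                                  mask_pattern, mask_density, mask_seed, no_narrow)
    records = read_sequences(input_path)
    total = 0
    with open(output, "w") as fh:
        fh.write("seq_id\tpositions\tspan_start\tspan_end\thash\n")
        for name, seq in records:
            if thin_w and thin_w > 1:
                seeds = minimizer_subsample(seq, params, thin_w, seq_id=name)
            else:
                seeds = generate_seeds(seq, params, seq_id=name)
            total += len(seeds)
            for s in seeds:
                fh.write(
                    f"{s.seq_id}\t{','.join(map(str, s.positions))}\t"
                    f"{s.span_start}\t{s.span_end}\t{s.hash:016x}\n"
                )
    click.echo(f"wrote {total} seeds from {len(records)} sequences", err=True)


@main.command("map")
@click.option("-r", "--references", "ref_path", required=True,
              type=click.Path(exists=True, dir_okay=False))
@click.option("-q", "--queries", "query_path", required=True,
              type=click.Path(exists=True, dir_okay=False))
@click.option("-o", "--output", type=click.Path(dir_okay=False), required=True)
@click.option("--chain/--no-chain", default=False, show_default=True,
              help="report only the optimal collinear chain per query/reference")
@click.option("--max-occ", type=int, default=None,
              help="skip seeds occurring more often in the index")
@_protocol_options
def map_cmd(ref_path, query_path, output, chain, max_occ, protocol, k, n, ell,
            w_min, w_max, x, mask_pattern, mask_density, mask_seed, no_narrow,
            thin_w):
    """Map queries to references and write NAMs as TSV."""
    params = _params_from_options(protocol, k, n, ell, w_min, w_max, x,
                                  mask_pattern, mask_density, mask_seed, no_narrow)
    references = read_sequences(ref_path)
    queries = read_sequences(query_path)
    index = build_index(references, params, thin_w=thin_w)
    click.echo(
        f"indexed {len(index)} seeds from {len(references)} references "
        f"({len(index.lookup)} distinct hashes)",
        err=True,
    )
    results: list[Union[NAM, Chain]] = []
    n_nams = 0
    for query in queries:
        nams = compute_nams(query, index, max_occ=max_occ, thin_w=thin_w)
        n_nams += len(nams)
        if chain:
            by_ref: dict[str, list[NAM]] = {}
            for nam in nams:
                by_ref.setdefault(nam.ref_id, []).append(nam)
            for ref_nams in by_ref.values():
                results.append(collinear_chain(ref_nams))
        else:
            results.extend(nams)
    write_tsv(results, output)
    click.echo(f"{n_nams} NAMs from {len(queries)} queries", err=True)


@main.command("sim")
@click.option("--length", "-L", type=int, default=10_000, show_default=True)
@click.option("--mu", "mus", type=float, multiple=True,
              default=(0.01, 0.05, 0.1), show_default=True)
@click.option("--replicates", type=int, default=1000, show_default=True)
@click.option("--seed", "rng_seed", type=int, default=0, show_default=True)
@click.option("--protocols", default=None,
              help="comma-separated preset names (default: full battery)")
@click.option("--thin-w", type=int, default=0, show_default=True)
@click.option("-o", "--output", type=click.Path(dir_okay=False), required=True)
@click.option("--islands-out", type=click.Path(dir_okay=False), default=None,
              help="also write the pooled island lengths as TSV")
@click.option("--fasta-out", type=click.Path(dir_okay=False), default=None,
              help="also write the simulated sequence pairs as FASTA")
def sim_cmd(length, mus, replicates, rng_seed, protocols, thin_w, output,
            islands_out, fasta_out):
    """Run the replicated random-mutation experiment and write the table."""
    names = [p.strip() for p in protocols.split(",")] if protocols else None
    try:
        result = run_sim_r(
            L=length,
            mu_list=list(mus),
            protocols=names,
            replicates=replicates,
            rng_seed=rng_seed,
            thin_w=thin_w,
            keep_sequences=fasta_out is not None,
        )
    except ValueError as exc:
        raise click.BadParameter(str(exc)) from exc
    result.to_tsv(output)
    if islands_out:
        with open(islands_out, "w") as fh:
            fh.write("protocol\tmu\tisland_length\n")
            for (name, mu), lengths in result.islands.items():
                for x_ in lengths:
                    fh.write(f"{name}\t{mu}\t{int(x_)}\n")
    if fasta_out:
        write_fasta(result.sequences, fasta_out)
    click.echo(
        f"simulated {replicates} replicates at L={length}, mu={list(mus)}",
        err=True,
    )


@main.command("uniqueness")
@click.argument("input_path", type=click.Path(exists=True, dir_okay=False))
@_protocol_options
def uniqueness_cmd(input_path, protocol, k, n, ell, w_min, w_max, x,
                   mask_pattern, mask_density, mask_seed, no_narrow, thin_w):
    """Percentage of unique seeds per input sequence."""
    params = _params_from_options(protocol, k, n, ell, w_min, w_max, x,
                                  mask_pattern, mask_density, mask_seed, no_narrow)
    click.echo("seq_id\tn_seeds\tpct_unique")
    for name, seq in read_sequences(input_path):
        if thin_w and thin_w > 1:
            seeds = minimizer_subsample(seq, params, thin_w, seq_id=name)
        else:
            seeds = generate_seeds(seq, params, seq_id=name)
        click.echo(f"{name}\t{len(seeds)}\t{unique_fraction(seeds):.3f}")


def cli(argv: Sequence[str] | None = None) -> int:
    """Run the command line interface; returns the exit status."""
    try:
        main.main(args=list(argv) if argv is not None else None,
                  standalone_mode=False)
    except SystemExit as exc:  # --help / --version
        return int(exc.code or 0)
    except click.ClickException as exc:
        exc.show(file=sys.stderr)
        return exc.exit_code
    except (OSError, ValueError) as exc:
        print(f"error: {exc}", file=sys.stderr)
        return 1
    return 0
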