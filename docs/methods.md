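# Methods

## Seeds

All protocols sample one seed per admissible start position `i` of a
string `s`, `i ∈ [0, |s| − k]`, where `k` is the total sampled length.

**k-mers.** The contiguous substring `s[i : i+k)`.

**Spaced k-mers.** A 0/1 mask of span `L` with `k` ones; the seed is the
concatenation of the letters at the fixed positions. The first and last
mask positions are always fixed, pinning the span. Presets: *dense*
(`L = round(1.5k)`, ≈2/3 of positions fixed) and *sparse* (`L = 3k`,
≈1/3 fixed); the interior fixed positions are drawn uniformly without
replacement from a caller-supplied RNG seed, once per experiment. At
starts where the mask window would overrun the sequence the seed
degenerates to the contiguous k-mer at that start, so the protocol emits
the same number of seeds as every other protocol (mirroring strobemer
window narrowing below).

**Strobemers** `(n, ℓ, w_min, w_max)` link `n` strobes of length `ℓ`
(`k = nℓ`). Strobe 1 sits at `i`; strobe `j ≥ 2` is chosen from the
inclusive window `[i + w_min + (j−2)·w_max, i + (j−1)·w_max]` of start
positions. Three selection rules:

* *minstrobes* — strobe `j` is the window minimizer of the strobe hash,
  independently per window;
* *randstrobes* — strobe `j` minimizes
  `(h(m₁) + … + h(m_{j−1}) + h(candidate)) & q` with `q` a mask of ones
  at the 16 low-order bits, making each choice conditional on all
  previous strobes (sums are taken modulo 2⁶⁴; since 2¹⁶ divides 2⁶⁴
  the wrap never changes the masked score);
* *hybridstrobes* — the window is split into `x` disjoint subwindows of
  width `⌊(w_max − w_min)/x⌋` (the last absorbs the remainder; default
  `x = 3`), each with an independent minimizer; the previous strobe's
  hash modulo `x` selects which subwindow supplies the strobe.

All argmin selections break ties by the leftmost position, uniformly
across protocols and in thinning. `w_min < ℓ` (overlapping strobes) is
permitted; the per-seed span can then dip below `k` (to
`(n−1)·w_min + ℓ`). Parameters with `x > 1` but
`⌊(w_max − w_min)/x⌋ = 0` are rejected at validation time — silently
clamping the subwindow count would change the selection semantics.

**Window narrowing.** The full span of a strobemer is
`W = (n−1)·w_max + ℓ`. When `W > |s| − i` each window is shrunk to
length `v = ⌊(|s| − i)/n⌋` (lower offset `min(w_min, v)`); once `v ≤ ℓ`
the strobes snap adjacent and the terminal seeds equal the contiguous
k-mer at `i`. Narrowing is on by default; with `narrow_tail=False`
(useful in read mapping, where narrowed tail seeds differ between read
and reference) tail positions emit no seed at all — we deliberately do
not clip windows, because clipped windows can collapse onto each other
and break the strictly-increasing-positions invariant. In degenerate
narrowed hybridstrobe windows with fewer than `x` usable subwindows, a
single subwindow (plain window minimizer) is used.

**Hashing.** Strobe and k-mer hashes come from a fixed 64-bit
polynomial rolling hash: letters map to coefficients (A,C,G,T → 1–4;
any other byte `b` → `b+5`), the polynomial with a fixed odd base is
evaluated modulo 2⁶⁴ via prefix sums (using the base's modular
inverse, so every window hash is two table lookups and one multiply),
and the raw value is finalized with the splitmix64 mixer under a
constant salt. The hash is deterministic across runs and platforms,
vectorizes over whole sequences, and imposes no seed-length cap. It is
not cryptographic; on random strings the collision probability at the
scales used here is negligible.

The stored hash of an order-`n` strobemer is
`Σ_j h(m_j) // (n + j)` with `j = 0..n−1` — integer division by 2 and 3
for order 2, by 3, 4, 5 for order 3. The division makes the combination
asymmetric under strobe permutation and keeps the sum below 2⁶⁴.
Integer (floor) division is used; real division followed by truncation
would differ only in ties and the integer form is what the overflow
argument requires.

**Ambiguous letters.** A seed whose sampled positions overlap a
non-ACGT letter is skipped (invalid candidates lose every minimization,
so a valid candidate wins where one exists). The one-seed-per-position
count therefore holds exactly on clean ACGT strings.

**Implementation note.** Window minima are computed with vectorized
sliding-window argmin over the precomputed hash array rather than
per-position queues; the unit tests verify equivalence against naive
per-window recomputation for all three protocols, including the
narrowed tail.

## Mutation models

Two regimes, both drawing the mutation type uniformly from insertion,
deletion and substitution (1/3 each): *fixed spacing* mutates positions
`d, 2d, …` (0-based indices `d−1, 2d−1, …`) of the original string;
*random* mutates each position independently with probability `mu`.
Coordinates always refer to the original string: positions are decided
first and edits applied right-to-left. An insertion adds one uniform
base before the mutated position; a substitution always changes the
letter (drawn from the three alternatives). Insertions and deletions
are equiprobable, so the expected mutated length equals the original
length at every rate.

The generator emulates the idealized mutation process only: no
sequencing-error profiles, homopolymer bias, quality values or
read-length distributions. Conclusions from these simulations speak to
seeding statistics under uniform random mutations, not to any
platform's error structure. One property of the fixed-spacing regime is
worth noting: a deletion followed by a compensating insertion across a
short local repeat occasionally reproduces an identical k-length
substring (about 2% of 100-nt replicates at `d = 15`, `k = 18`), so
"no k-mer can match" holds only up to such chance identities; they are
true string equalities, not hash artifacts.

## Match statistics

A *match* is a hash-equal seed pair. On the query string (by default;
a flag switches to the reference):

* *fraction of matches* — matched query seed positions / query seeds
  (positions, not pairs, so repeats cannot push it above 1);
* *sequence coverage* — union of the matched strobes' own positions,
  as half-open length-`ℓ` (or length-`k`, or per-fixed-position)
  intervals, divided by `|s|`;
* *match coverage* — union of full seed spans (first to last sampled
  nucleotide); always ≥ sequence coverage;
* *islands* — maximal uncovered runs; computed against match coverage
  by default (configurable to sequence coverage; which of the two
  underlies the original tables is not stated, so both are available);
  covered length plus island lengths always equals `|s|`;
* *island E-size* — `E = (1/|s|) Σ x²` over island lengths `x`: the
  expected island length at a uniformly random position.

Simulation parameters are chosen so false matches (repeats, hash
collisions) are negligible; `find_matches` nevertheless returns all
hash-equal pairs, including duplicates.

## The replicated random-mutation experiment

Defaults: string length 10,000 nt, `mu ∈ {0.01, 0.05, 0.1}`, 1000
replicates, and nine protocols at total length `k = 30`: k-mers, spaced
dense/sparse, and min-/rand-/hybridstrobes of orders 2 and 3 with
windows `(2, 15, 16, 50)` and `(3, 10, 11, 25)`. The window convention
`(2, k/2, k/2+1, 50)` / `(3, k/3, k/3+1, 25)` gives equal sampled
length and comparable spans between orders; it is the package's choice,
as the original table's window parameters are not available. Spaced
masks are drawn once per run from the run seed. All randomness flows
from a single `numpy` `SeedSequence`, so tables are bit-reproducible.

The acceptance suite runs this experiment at 100 replicates (and the
thinned variant at 25, the mapper contiguity experiment at 20), sizes
at which every ordering asserted is stable; the full 1000-replicate
default reproduces the same orderings with tighter means.

Two ordering claims are operationalized with care, since at these
scales some protocol pairs are near-ties:

* "hybridstrobes fall between minstrobes and randstrobes" is asserted
  as: hybridstrobes improve on minstrobes (higher match coverage, lower
  E-size) *and* are closer to randstrobes than minstrobes are, per
  order, metric and rate — at `mu = 0.01` hybrid and randstrobe E-sizes
  differ by hundredths of a nucleotide and strict betweenness is not
  well-posed;
* under minimizer thinning (`w = 10`), randstrobes are asserted to beat
  every *non-hybrid* protocol on sequence coverage, match coverage and
  E-size; randstrobes and hybridstrobes are statistically
  indistinguishable after thinning in this implementation and trade
  places across seeds.

## Minimizer thinning

A window of `w` consecutive seed *start positions* slides over the
stream; each window retains its leftmost-minimum selection hash (the
seed hash for fixed-position protocols, the first-strobe hash for
strobemers), retained starts are deduplicated, and full strobemers are
built from retained starts under the normal protocol. A stream shorter
than `w` forms a single window. Window indexing over seed starts
coincides with nucleotide indexing here because every position emits a
seed. Expected density on random strings is ≈ `2/(w+1)`.

## Mapper

References are seeded and stored in a flat array sorted by hash (per
seed: hash, reference id, first and last component start) with a
hash → (offset, count) lookup. Matches of a query are sorted by
(reference, query start, reference start) and greedily merged into
NAMs: a match joins an open NAM when its query and reference spans both
overlap the NAM's current spans and both starts are at or beyond the
NAM's starts; several NAMs may be open at once (a NAM closes when no
later match can overlap it), so distinct reference loci are never
merged. The exact merge rule is this package's own definition; it makes
k-mer NAMs approximate maximal exact matches while letting linked-seed
NAMs bridge small differences.

The optimal collinear chain maximizes covered query length (the union
of chained NAM query spans) under strictly increasing query and
reference starts. Because chains are processed in start order, the
running maximum chain end is a sufficient statistic for the union, and
a dynamic program over (score, chain-end) Pareto states solves the
problem exactly; ties prefer smaller chain end, then earlier NAMs.
Mapping is forward-strand only; a repetitive-seed guard (`--max-occ`)
is available but off by default. Output is a seven-column TSV
(query_id, ref_id, q_start, q_end, r_start, r_end, n_hits) with 1-based
inclusive coordinates; internal coordinates are 0-based half-open
everywhere.

## Known limitations

* Forward strand only; no canonical (strand-collapsed) seeds.
* No base-level alignment or extension; NAMs are seed-merge regions.
* The polynomial hash is not adversarially collision-resistant.
* Chaining is exact but quadratic (cubic in pathological Pareto
  frontiers); it targets per-read NAM counts, not whole-genome anchor
  sets.
* The simulators do not model real sequencing error profiles (see
  above), so simulated orderings need not transfer quantitatively to
  platform-specific data.
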