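# Methods

This note documents the models and procedures implemented in `dupdiverge`,
the defaults and why they were chosen, what the synthetic data do and do not
emulate, and the numerical conventions that matter for reproducing results.

## Tandem-duplication clustering (`tandem`)

Two family members are tandem-linked when they lie on the same chromosome
with at most `max_gap` (default 20) other genes between them in the full gene
order — i.e. rank difference ≤ 21. Clusters are the connected components of
this relation: transitive chaining is on by default (it is what allows
clusters larger than two, such as a 42-member run), with `chain=False`
restricting clusters to rank-window cliques for sensitivity analysis.
Intergenic distance is measured in genes, not base pairs, so the full gene
catalog — every annotated gene of any biotype, ordered by start coordinate —
is the substrate, not just family members. Fragmented assemblies (contigs
treated as chromosomes) can only remove linkage, never add it, so tandem
counts on fragmented input are conservative; a property test asserts this.
Percentages are reported to the nearest integer. Gene-density tracks count
each family gene once, by start coordinate, in fixed windows (default 1 Mb,
last partial window included).

## Duplication–loss reconciliation (`reconcile`)

Gene trees are reconciled against the species tree by the LCA mapping: every
gene node maps to the species-tree LCA of its leaves' species, a node is a
DUPLICATION iff it maps to the same species node as one of its children, and
for each gene edge (u → v) the copy passes through the species nodes between
map(u) and map(v), losing a copy to the off-path branch at each — `dist − 1`
losses for a speciation, `dist` for a duplication that maps strictly above
its child. Under unit costs this is the minimum-cost reconciliation; the
suite checks cost-minimality by brute-force search over all valid mappings
for every gene-tree shape with ≤ 6 leaves on a 3-species tree (2 052 shapes
up to isomorphism — exhaustive, since child order is immaterial).

Aggregation sums per-branch duplications (as gains on the branch entering the
mapped node) and losses over a forest and adds one "origin" gain per family
on the branch entering the species LCA of its observed members, so families
absent from a clade create no phantom losses above their root. Ancestral copy
numbers are then defined by the bookkeeping identity
`count(child) = count(parent) + gains − losses`, evaluated top-down from zero
above every origin; consistency with the observed extant counts is asserted,
not assumed.

Parsimony is conservative: a duplication whose extra copy leaves no surviving
descendants is invisible, and complementary losses can make a duplication
node look like a speciation. At duplication rate 0.3 and loss rate 0.1 per
branch this under-counts planted gains by roughly 15–20%; with no losses the
recovery is exact (both are asserted — the inferred total never exceeds the
planted total beyond a 10% margin, and never falls below 70% of it).
Unit event costs; input trees are taken as given (no rearrangement); unrooted
input would be midpoint-rooted by the reader.

## Structural-divergence classification (`structdiv`)

Each exon of one sibling is aligned against the entire genomic span of the
other by local Smith–Waterman with affine gaps (match +2, mismatch −3, gap
open −5, extend −2; ties broken toward the lowest start). A hit is accepted
only at ≥ 30 aligned bp and ≥ 60% identity — deliberately the same stringency
as the dot-plot — and then assigned to a sibling exon (reciprocal overlap
≥ 50% of the shorter interval) or to a sibling intron (containment within
± 10 bp). At this scoring, unrelated 300 bp × 3 kb sequence pairs still
produce a spurious accepted local hit a few percent of the time, so "no
counterpart" for the gain/loss rule means *no feature-localised counterpart*:
a weak alignment that overlaps no exon and sits inside no intron is treated
as noise.

Mechanisms are called from the two directional correspondence maps, in fixed
priority order so that a single primary label is deterministic while all
events remain reported:

1. **exon split** — two adjacent exons of one gene both map inside a single
   exon of the other (the intervening intron is novel);
2. **exonization/pseudoexonization** — an exon's counterpart lies inside an
   intron of the sibling (the sequence survives, exon status differs);
3. **exon/intron gain/loss** — an exon with no feature-localised counterpart;
4. **boundary alteration** — a matched exon pair with length offset ≥ 3 bp
   while the flanking intron length ratio stays ≤ 2 (so it is not an
   elongation signal);
5. **intron elongation** — a homologous intron pair (both flanking exon pairs
   matched) with length ratio > 2, reported as max/min.

Without an outgroup, polarity (gain vs loss, elongation vs shortening) is
undecidable and reported as UNKNOWN; ratios are direction-symmetric. On 250
simulated sibling pairs (50 per mechanism; 4-exon genes, 5% point mutations)
the primary label matches the planted mechanism for ≥ 90% (measured ≈ 99%),
and ≥ 95/100 mutation-only pairs produce no event at all.

## Dot-matrix repeat detection (`dotplot`)

The self-comparison matrix records every forward-strand window-start pair
(stride 1, window 30) agreeing at ≥ ⌈0.6 × 30⌉ = 18 positions. At this
stringency the per-pair chance of a random hit is P(Bin(30, 1/4) ≥ 18) ≈
5 × 10⁻⁵ — about 18 spurious matches per random kilobase, arriving in short
correlated diagonal clumps because adjacent windows share 29 positions. The
repeat *caller* therefore demands the physical signature of a tandem array
rather than mere matches: collinear matches are chained into runs (offset
tolerance 2, ≥ 2 windows), and only *periodic* runs — whose matched segments
overlap their own offset, i.e. the diagonal re-enters the array — are
considered. Overlapping periodic runs are pooled, and a pool is called when a
common unit ≥ 10 bp explains at least two runs including both the
adjacent-copy offset (k = 1) and the two-copy offset (k = 2), with the k = 1
run the strongest (a unit whose base diagonal is weaker than its multiples is
a harmonic). The unit estimate is the offset that explains the most runs,
ties to the larger value. Measured behaviour: 0/200 random 1-kb sequences
produce any call, and planted units of 30/50/80 bp (6 copies, 5% per-copy
mutation) are recovered within ±2 bp with ≥ 90% span overlap in 60/60
replicates. Inverted repeats are out of scope. The per-intron annotation
reports overlap between repeat regions and intron intervals in the gene-local
frame.

## NG86 dN/dS with Jukes–Cantor correction (`selection`)

Synonymous sites per codon are counted position-wise as the synonymous
fraction of the three alternative bases, excluding alternatives that create
stop codons from the denominator, so s + n = 3 exactly for every sense codon.
Differences between codons are averaged over all orderings of the differing
positions; orderings that pass through a stop are excluded and the remainder
renormalised, with a flagged all-orderings fallback when every path hits a
stop. S and N for a pair are the averages of the two sequences' totals;
codons containing gaps, Ns or stops in either sequence are dropped pairwise.
The Jukes–Cantor correction d = −(3/4)ln(1 − 4p/3) is applied to p_S and p_N;
p ≥ 3/4 is reported as saturated and the window classed UNDEFINED, as is any
window with d_S = 0 (ω is neither 0 nor ∞ there, it is undefined).

Sliding windows are 45 **codons** with a 9-codon step (window counts follow
⌊(L − 45)/9⌋ + 1; shorter alignments fall back to one whole-sequence window,
flagged), and windows are classed POSITIVE above ω = 1.5, PURIFYING below
0.67, INTERMEDIATE between. The N-/C-terminal summary groups windows starting
before codon 50 as N-terminal; a boundary window can belong to both groups.
Correctness is anchored to an independent brute-force oracle (mutant
enumeration, pathway permutation, exact rational arithmetic, JC closed form):
200 random pairs up to 60 codons agree to 1 × 10⁻⁹ on S, N, S_d, N_d, d_S
and d_N.

## Expression divergence (`expression`)

Matrices are genes × developmental stages in FPKM-like units (7-stage set
EE/LE/L1/L2/L3/L4/YA or 4-stage EE/L2/L4/YA). Profiles are log2(x + 1)
transformed (dynamic-range compression appropriate to FPKM; a flag disables
it) and standardised per gene (population sd), giving mean-0/sd-1 z-scores;
exactly constant genes get all-zero z and a flag. Clustering is k-means on
z-profiles, k = 8, Euclidean, best of 20 restarts under a fixed seed. A gene
is stage-specific when exactly one stage reaches z ≥ 1.5 — with 7 stages a
clean one-stage peak scores z ≈ 2.45 and every other stage ≈ −0.41, so the
threshold separates one-peak profiles from diffuse ones; this z-rule is our
concrete rendering of a "mean deviation" specificity call, with the threshold
exposed. A sibling pair is expression-divergent when Pearson r between
z-profiles falls below 0.5 **or** both genes are stage-specific with
different peaks; both sub-criteria and r are always reported so either can
be examined alone, and constant-vs-anything comparisons (undefined r) fall
back to the peak criterion, flagged.

## Synthetic data (`synthetic_data`)

Every generator is a pure function of its parameters and a seed and ships a
ground-truth record sufficient to score the corresponding stage.

- **Catalogs** place family members at planted ranks (clusters with internal
  gaps ≤ the linkage threshold; singletons > 21 ranks from any member) among
  background genes with realistic spacing; infeasible plans raise before any
  output exists.
- **Paralog pairs** derive sibling B from a 4-exon gene A (exons 90–300 bp,
  introns 50–200 bp) by 5% point mutations plus exactly one planted event;
  intron elongation inserts tandem copies of a ~50 bp unit, tying the
  elongation mechanism to the repeat-detection stage.
- **Codon pairs** evolve by acceptance–rejection over single-base proposals:
  stops rejected, nonsynonymous changes accepted with min(1, ω), synonymous
  with min(1, 1/ω). The reciprocal synonymous rule (inactive for ω ≤ 1)
  makes diversifying regimes realizable — with synonymous acceptance fixed at
  1 the realized ratio can never exceed neutrality. The recovery target is
  the *realized* ω computed from the recorded substitution counts and the
  start sequence's site totals, not the nominal parameter, because the
  proposal process itself is not exactly site-proportional. Mean estimated ω
  at 500 codons tracks the realized value within ±0.15 (measured ≈ ±0.05).
- **Gene families** evolve top-down along the species tree: per branch each
  entering lineage gains k ~ Poisson(dup_rate) copies (caterpillar-joined,
  recorded) and each copy dies with probability 1 − e^(−loss_rate)
  (recorded). Families with < 2 surviving genes are discarded and excluded
  from the recoverable truth.
- **Expression matrices** use one-hot stage-peak archetypes (log2 FPKM 2
  baseline, peak +6) plus a flat-low archetype placed *below the detection
  floor*, so its FPKM values clip to exactly zero — silent genes in real
  FPKM tables have no reads, not Gaussian jitter about a tiny positive mean,
  and this is also what keeps the flat class identifiable after per-gene
  standardisation. Planted pairs draw from peaked archetypes (same peak =
  concordant, different = divergent).
- **Repeat sequences** are flank + n mutated copies of a random unit + flank.

What the generators do **not** emulate: realistic base composition or codon
usage bias, indels inside exons, rate variation among sites or lineages,
expression replicates or count noise, annotation errors. Passing tests
therefore demonstrate correctness of the algorithms under their stated
models, not robustness to every artefact of real genome annotation.

## Problem sizes and numerics

Test and acceptance runs use 200 random catalogs (≤ 500 genes), 200 codon
pairs (≤ 60 codons) for oracle equivalence, 100 pairs × 500 codons per ω for
recovery, 200 simulated families per forest, 250 sibling pairs for mechanism
recovery, and 100 random kilobases for false-positive measurement — sizes at
which every oracle comparison is exhaustive or exact and the whole suite runs
in a few minutes on one CPU. Floating point in TSV outputs is printed at
fixed precision (%.6g) so reruns are byte-comparable; all randomness flows
from explicit `numpy.random.default_rng` seeds; k-means determinism comes
from a fixed `random_state` plus `n_init=20`.

## Known limitations

- Reconciliation assumes correct, rooted, binary gene trees; no bootstrap
  rearrangement or transfer events.
- The structural classifier compares annotation-level gene models; it cannot
  distinguish annotation error from genuine structural change, and polarity
  needs an outgroup.
- The repeat caller targets direct tandem repeats with units ≥ 10 bp; short
  microsatellites and inverted repeats are out of scope.
- NG86 is a counting method: no transition/transversion or codon-frequency
  modelling, and sliding-window threshold calls are a heuristic, not a test
  with controlled error rates.
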