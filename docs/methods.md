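# Methods

This note documents the models, rules and numerical choices behind each
stage, what the synthetic-data generators do and do not emulate, and the
design decisions taken where the underlying procedures are underspecified
in the literature the package operationalizes.

## Sequence handling

FASTA records carry `sample_id|site_id|marker` headers. Five markers are
registered (plastid coding rbcL, matK, ycf; plastid spacer trnH-psbA;
nuclear spacer ITS2) plus fixed combination labels (core = matK+rbcL,
coding, non-coding, cpDNA, total). Concatenation order within a
combination is alphabetical by marker name (case-insensitive) — no
convention is standard, so one is fixed and documented. Sequences are
treated as pre-aligned per marker; alignment itself is out of scope and
the simulators emit gap-free alignments.

GC screening flags sequences whose (G+C)/(A+C+G+T) fraction is strictly
above 0.65 — "above 65%" is read as a strict inequality, so the boundary
value is not flagged. Ambiguity codes and gaps are excluded from both the
numerator and denominator. High-GC amplicons are only flagged (the wet-lab
response, cloning before sequencing, is outside the package).

The packaged site table transcribes the 26 collection sites with their
degree–minute–second coordinates verbatim, including one malformed seconds
token in row 25; the reader converts DMS defensively and reports NaN with a
warning for tokens it cannot interpret rather than rejecting the table.

## Distances and trees

Three models on aligned pairs under pairwise deletion (a site is dropped
for a pair when either sequence has a gap, N or ambiguity code):
uncorrected p; JC69 d = −¾ ln(1−4p/3); K2P d = −½ ln(1−2P−Q) − ¼ ln(1−2Q).
Saturated pairs (log argument ≤ 0) abort matrix construction with an error
listing the offending pairs — downstream partitions are never built on
partial matrices. Pairwise deletion rather than complete deletion matches
common barcode practice; "simple distance" is interpreted as uncorrected
p-distance.

Trees use canonical neighbor joining. Negative branch lengths are clamped
to zero with the deficit moved to the sister edge, so the joined pair's
summed length is preserved. NJ is a deliberate stand-in: the tree method
used by the original study's software is not stated, and tree inference is
not load-bearing for any downstream stage. Newick output carries branch
lengths at 6 decimals.

## Barcode-gap delimitation

Given a distance matrix, a prior maximal intraspecific divergence P and a
relative gap width X (default 1.5):

1. Sort the pairwise distances and collapse ties to unique values.
   Distances from aligned sequences live on a near-lattice (multiples of
   1/L distorted by the model correction), and tied or nearly tied values
   would otherwise make ordinary lattice steps look like gaps.
2. Scan consecutive intervals between unique values. An interval is a
   barcode gap when its midpoint exceeds P and its width exceeds X times
   both (a) the maximum width among the up-to-W preceding intervals
   (W = 10, at least 3 required) and (b) P itself. The local-maximum
   reference absorbs lattice granularity; the X·P floor encodes that a gap
   must be wide relative to the assumed intraspecific divergence — without
   it, a single long-branch individual splits off whenever its distances
   sit two lattice steps beyond its conspecifics.
3. Partition specimens by single linkage: groups are connected components
   of the graph joining pairs with d < threshold (the gap midpoint).
   Group ids are the lexicographically smallest member, making output
   stable under specimen reordering.
4. Recurse within every group of ≥4 members using that group's submatrix;
   stop on no gap, a trivial split, group size <4, or depth 10. The
   minimum group size of 4 prevents spurious splits of pairs.
5. The prior sweep runs the recursion at 10 log-spaced priors spanning
   [0.001, 0.100] inclusive and reports group counts per prior alongside
   histogram and ranked-distance curves.

The detection rule is this package's deterministic operationalization of
automatic barcode-gap discovery; the original tool's internals (slope
heuristics, coalescent-derived windows) are not published in
reimplementable detail. Only its stated knobs — X, the prior range, the
distance models — are carried over as defaults. Under the generators'
default study conditions (4 species, 8 specimens each, 600 bp,
intra = 0.005, inter = 0.08) the recursion recovers the true species in
50/50 seeded replicates at prior 0.01, and single species remain unsplit at
every prior in the sweep.

## Taxonomic assignment

Candidate sets: simple = top 10 hits by bit score; optimized = top 100 by
bit score re-ranked by `max_score * (query_cover / identity)`. Ties break
by identity (descending) then subject name, so output is deterministic.
Subjects are not deduplicated before rescoring. The "species within 1%
deviation" set contains the distinct species whose ranking score (of the
active method) is at least 0.99 of the best.

Identity tiers overlap at their boundaries in the source description
(Medium is stated as 90–95% inclusive on both ends); the package resolves
upper-bound-wins: High ≥95, Medium ≥90, Low otherwise.

The assignment ladder, isolated in one function for amendment:

1. High tier and exactly one species in the deviation set → **species**;
2. all deviation species inside one configured synonym group, tier
   High/Medium → **species group** (the packaged configuration seeds the
   six-name *S. europaea* complex);
3. all in one genus, tier High/Medium → **genus**;
4. all in one family (any tier — at Low only unanimity of family rescues
   the call) → **family**;
5. otherwise **unassigned**.

Combination-level calls are built by consensus across member markers: at
each rank from species downward, member calls project upward (a species
call votes for its genus at genus rank) and the most specific rank where a
strict majority agrees on one taxon wins; failed ranks degrade to the next
coarser one. Concatenating sequences before assignment is the alternative
route (via the concatenation utilities); consensus is the default because
it keeps per-marker provenance.

## AMOVA, F<sub>ST</sub> and Nei distance

For N specimens in P populations with squared distances d²ᵢⱼ:
SSD_total = Σᵢ<ⱼ d²ᵢⱼ/N, SSD_within = Σₚ Σᵢ<ⱼ∈ₚ d²ᵢⱼ/nₚ,
SSD_among = SSD_total − SSD_within; df = P−1 and N−P;
σ²𝓌 = SSD_within/df_within; n̄ = (N − Σnₚ²/N)/(P−1);
σ²ₐ = (SSD_among/df_among − σ²𝓌)/n̄; F_ST = σ²ₐ/(σ²ₐ+σ²𝓌). One level only
(populations within total), matching the within/among reporting the
package reproduces. Negative variance components are clamped to zero for
the reported F_ST and percentages, with raw values preserved on the result
object; the all-zero degenerate case reports 0 by convention.

The permutation test shuffles individuals among populations preserving
sample sizes, with p = (1 + #{F ≥ F_obs})/(n_perm + 1) and 1023
permutations by default. The *raw* (unclamped) F_ST is the test statistic:
clamping creates an atom of ties at zero under the null and destroys the
uniformity of null p-values, which the suite verifies by a KS test over
500 scaled-down replicates (n_perm = 199).

Haplotypes collapse by exact sequence match after dropping columns that
are gaps in every sequence; ambiguity codes mismatch unless identical.
Nei's standard distance is D = −ln I with
I = Σxᵢyᵢ/√(Σxᵢ²·Σyᵢ²) on the union haplotype index; disjoint pools give
I = 0 and D = ∞, reported as infinity. The standard (1972) form is used;
which Nei variant the original analysis used is unstated.

## Niche modeling

**Grids.** ESRI ASCII (.asc), 6-line header, north row first. Values are
written with full float repr so round trips are exact. Cell lookup is
half-open from the lower-left corner; a point on a shared edge belongs to
the higher-index cell.

**Occurrence cleaning.** Per environmental variable, values are sorted and
the Chapman-style critical gap t = (0.95√n + 0.2)·(range/50) computed.
Walking inward from each extreme, a value stays flagged while its gap to
the remaining body exceeds both t and twice the mean spacing
range/(n−1). The relative condition is this package's addition: the
absolute rule alone flags evenly spread small samples wholesale, while the
published standardized-gap variant can never flag anything at small n
because its statistic is bounded near 2.3 while its threshold scales with
the range. A record is removed when flagged in ≥3 variables (of the 19
bioclimatic layers in the default configuration).

**Model.** Over valid background cells x with features f(x) — each
variable standardized on background mean/sd, plus its square — the model
is p(x) = exp(λ·f(x))/Z. Fitting maximizes the mean presence
log-likelihood minus Σβⱼ|λⱼ| by FISTA with backtracking; the soft-threshold
step produces exact zeros, convergence is declared when the objective
improves by <1e-6, and non-convergence at 500 iterations warns but still
returns the model. The penalty is applied on the per-presence (mean)
scale with β = 1 per feature: a feature then enters only when its presence
mean shifts from the background mean by roughly one standard deviation,
so structureless data yield the exactly-uniform model (all λ = 0, AUC
exactly ½ by the tie convention) while strong signals are retained.
Features are restricted to linear + quadratic (no hinge/product/threshold
classes) for convexity and testability; the output transforms are raw
(normalized over the background reference, summing to 1, asserted after
every fit) and cumulative (100 × summed raw value of cells scoring at or
below the cell); the logistic transform is omitted because its prevalence
parameter has no stated value. Background is a uniform seeded sample of
valid cells (default 10,000, or all cells when fewer).

**Evaluation.** AUC is the rank-based probability that a random presence
outscores a random background cell, ties counting ½ (computed via
`roc_auc_score`). Bands: <0.5 random, [0.5,0.7) poor, [0.7,0.9) moderate,
≥0.9 good. The test split holds out round(N·0.25) records, seeded. The
jackknife report fits each variable alone and excluded on the training
presences and scores both on the held-out presences, ranking by the
with-only AUC.

## Synthetic data

Sequences evolve on a star phylogeny under exact K80 transition
probabilities with transition:transversion odds κ:1 (default 2). Branch
lengths are expected substitutions per site: species ancestors sit at
(inter − intra)/2 from the root and individuals at intra/2 below their
ancestor, so expected pairwise distance is intra within and inter between
species, and the K2P estimator is unbiased for both (verified within 3
standard errors over 50 replicates). inter > 2·intra is enforced so a
barcode gap exists by construction. This is deliberately not a coalescent:
no shared polymorphism, no recombination, no rate variation — sufficient
for exercising distance corrections and gap detection, and nothing here
speaks to how the pipeline behaves under incomplete lineage sorting.

Population structure draws each individual from its population's private
haplotype or, with probability `migration_mix`, from the shared pool:
mix = 0 fixes populations for distinct haplotypes (F_ST = 1 downstream),
mix = 1 is panmixia, and mean F_ST decreases monotonically in between.

Hit tables give every query a top-scoring true-species hit (identity
consistent with the intraspecific divergence), congeneric decoys at scores
consistent with the interspecific divergence, and confamilial decoys lower
still; decoy query coverage tracks decoy identity so the weighted score
stays proportional to the bit score for genuinely distant hits. With
probability `decoy_rate` one congeneric decoy lands inside the 1% band
under both ranking scores, exercising the species-group/genus branches.
With zero noise and zero close-decoy rate, both methods recover the true
species for every query.

Landscapes are Gaussian white noise smoothed with a kernel of width 1/10
of the grid extent (configurable), standardized over valid cells; true
suitability is the Gibbs density exp(coeffs·z) and presences are cell
centers sampled without replacement proportional to it. A one-cell nodata
ring exercises masking. 19 variables is the default, mirroring the
standard bioclimatic set. Smooth fields are spatially autocorrelated, so a
60×60 grid carries far fewer independent values than cells; the
parameter-recovery check therefore uses finer-scale fields
(smooth_frac = 0.05) and a light penalty (β = 0.1), where the fitted
linear weights rank an 8-coefficient ladder with mean Spearman ≥0.9 over
20 seeds.

## Pipeline and reproducibility

Six stages (simulate → distance → delimit → assign → popgen → sdm) run
from one YAML configuration whose defaults mirror the study shape: 26
sites from the packaged table, 2–5 specimens per site, 4 species, 5
markers, X = 1.5, prior range 0.001–0.100, 1023 permutations, 25% test
fraction, 3-of-19 outlier threshold, GC threshold 0.65. Stage k derives
its generator from `SeedSequence(seed, spawn_key=(k,))`, so stages re-run
independently with identical results. The manifest records the resolved
configuration, seed, per-stage parameters and SHA-256 of every output;
two runs with one seed are byte-identical, which the suite asserts
file by file.

Problem sizes in tests and in `scripts/acceptance.py` (e.g. 60×60 grids,
200 presences, 50-seed replicate loops, 199-permutation null replicates,
a 40×40 landscape in the default pipeline configuration) are chosen as
the smallest sizes at which the statistical claims are comfortably
resolvable; all thresholds were fixed by the generator's study conditions,
not by the grids' convenience.

## Known limitations

- Alignment, chromatogram processing and live database queries are out of
  scope; hit tables are the integration contract for real BLAST output.
- The gap detector and the reverse-jackknife rule are documented
  operationalizations, not reimplementations, of the original tools; both
  are isolated in single functions with their constants exposed.
- The MaxEnt variant is convex and small: no hinge features, no logistic
  output, background limited to the training extent.
- Synthetic landscapes are stationary Gaussian fields; real bioclimatic
  layers are cross-correlated and anisotropic, so passing tests bound
  behavior under the generator's assumptions only.
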