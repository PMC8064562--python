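# halobarcode

Barcode-based conservation genetics for halophytes, end to end and at desk
scale: species identification from BLAST-style hit tables, distance-based
species delimitation by automatic barcode-gap discovery, population
structure (AMOVA, F<sub>ST</sub>, Nei's genetic distance), and presence-only
ecological niche modeling with jackknife validation. The target system is
the taxonomically tangled genus *Salicornia* (glasswort), sampled across 26
saline sites and sequenced at five barcode loci (rbcL, matK, trnH-psbA,
ITS2, ycf), but every component is generic.

No sequence data were deposited for the original field study, so the
package ships seeded synthetic-data generators with known truth for every
stage — multi-species sequence sets with controlled intra/inter-specific
divergence and transition bias, hit tables with configurable confusability,
and environmental rasters with occurrences sampled from a known suitability
surface. The generators are first-class, tested code: they define the
conditions under which every downstream claim is verified.

## What the package computes

**Distances & trees.** Pairwise p, Jukes–Cantor and Kimura two-parameter
distances under pairwise deletion; K2P is
d = −½ ln(1−2P−Q) − ¼ ln(1−2Q) with P and Q the transition and transversion
proportions. Neighbor-joining trees with newick export.

**Species delimitation.** The barcode gap is the separation between
intra- and inter-specific distance distributions. Given a prior maximal
intraspecific divergence P, the detector scans ranked unique distances for
an interval wider than X times both the local spacing and the prior
(X = 1.5 by default), partitions specimens by single linkage below the gap,
recurses within groups, and sweeps P log-spaced over [0.001, 0.100].

**Taxonomic assignment.** Hits are ranked either by bit score (simple, top
10) or by the weighted score `max_score * (query_cover / identity)`
(optimized, top 100). A five-rule ladder combines the best hit's identity
tier (High ≥95%, Medium ≥90%, Low) with the set of species within 1% of the
best score to call species, species group (e.g. the six-name *S. europaea*
complex), genus, family, or unassigned; per-marker and per-combination
discrimination efficiencies are summarized as percent of queries per rank.

**Population structure.** One-level AMOVA from squared distances,
F<sub>ST</sub> = σ²ₐ/(σ²ₐ+σ²𝓌), permutation significance (1023
randomizations by default), and Nei's standard genetic distance
D = −ln I between haplotype frequency vectors.

**Niche modeling.** Reverse-jackknife outlier screening of occurrence
records (flagged in ≥3 of 19 bioclimatic variables ⇒ removed), a 25% random
test split, an L1-regularized maximum-entropy model over background cells
with linear + quadratic features, raw and cumulative suitability rasters
(ESRI ASCII), rank-based AUC with the usual bands (≥0.9 good), and
per-variable jackknife importance.

## Worked example

```python
import halobarcode as hb

recs, truth = hb.simulate_species_sequences(
    k=4, n_per=8, L=600, intra=0.005, inter=0.08, seed=7)
dm = hb.distance_matrix(recs, model="K2P")

part = hb.recursive_delimit(dm, prior_P=0.01)
print("groups:", part.n_groups, "threshold:", round(part.threshold, 4))

pops = {r.sample_id: truth.assignment[r.sample_id] for r in recs}
res = hb.amova_one_level(dm, pops)
print(res.summary().to_string(index=False))
print("Fst =", round(res.fst, 4),
      " p =", round(hb.fst_permutation_test(dm, pops, n_perm=1023, seed=7), 6))
```

prints

```
groups: 4 threshold: 0.0283
            source  df      SSD  variance        pct
 Among populations   3 0.034607  0.001439  98.510129
Within populations  28 0.000609  0.000022   1.489871
             Total  31 0.035216  0.001461 100.000000
Fst = 0.9851  p = 0.000977
```

Four species simulated with intraspecific divergence 0.005 and
interspecific divergence 0.08 are recovered as four groups: the detected
barcode-gap threshold (0.0283) falls inside the empty stretch between the
two distance modes. Treating the true species as populations, almost all
molecular variance lies among groups (F<sub>ST</sub> ≈ 0.99), and no
permutation of specimen labels reaches the observed value
(p = 1/1024).

The same stages run from the shell against a single YAML configuration:

```
halobarcode run-all --seed 1 --outdir run1
```

writes FASTA, distance matrices, NJ trees, delimitation sweeps, assignment
and efficiency tables, AMOVA/F<sub>ST</sub>/Nei reports, suitability
rasters and an SDM evaluation under `run1/`, with a manifest recording the
configuration, seed and SHA-256 of every output. Reruns with the same seed
are byte-identical.

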