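# Methods

## The analysis chain

`speleodiv` analyses a stratified survey of subterranean invertebrates in a
karst massif. The sampling frame divides the massif into three zones — warm
low-altitude **slope** caves, cold **shallow upper** caves on the plateau,
and the **deep core** reached through two deep vertical caves — and six depth
strata below the cave entrance (0–50, 50–100, 100–200, 200–330, 330–500,
and >500 m; half-open intervals `[lower, upper)`, so the strata partition
`[0, ∞)`). A *sampling unit* is an entire small cave or one depth stratum of
a deep cave; the default design has 5 slope + 5 shallow-upper + 10 deep-core
units.

The chain is: pool the two trapping seasons; normalize counts by sampling
effort; drop non-obligate species; reduce to presence/absence; then compare
communities (Jaccard, ANOSIM, UPGMA, Mantel) and partition beta diversity
against fill-preserving null models.

### Effort normalization

Trap density could not be constant across cave passages, so each pooled
count is divided by `n_traps × passage_length_m`, giving individuals per
sampled trap per meter. The phrase "per trap per meter" admits a second
reading (dividing by traps-per-meter, i.e. multiplying by length); we divide
by the product, which matches the stated unit bracket, and isolate the
choice in a single function. Because normalization rescales columns by
positive constants it never changes which cells are zero — every
incidence-based statistic downstream is provably invariant to it, so the
ambiguity has no effect on any test or partition in the pipeline.

### ANOSIM

Clarke's R contrasts mean between-group and within-group ranks of the
n(n−1)/2 dissimilarities, scaled by n(n−1)/4 so that R ∈ [−1, 1] (the
brute-force maximum on balanced groups of two is exactly 1). Ties take
midranks. The test is run pairwise between zone pairs (three runs), not as
an omnibus test. p-values are one-sided (permuted R ≥ observed) with the
add-one convention p = (count + 1)/(n_perm + 1); the permutation count
defaults to 999 and is configurable.

### Mantel test

Spearman correlation over the upper-triangle entries of the Jaccard matrix
and the 3D Euclidean distance matrix (coordinates in an arbitrary but
consistent Cartesian frame of the massif, meters). Ranking commutes with a
joint row/column permutation, so the permutation loop reindexes a
precomputed rank matrix; 999 permutations, one-sided greater, add-one p.

### UPGMA

Average linkage on Jaccard dissimilarities; merge height is half the
merge-time mean dissimilarity, so cophenetic distances reproduce those
means and the tree is ultrametric. When two candidate pairs tie for the
minimum, the pair whose smallest leaf labels sort first lexicographically is
merged — a platform-independent determinism rule (ties are real with
incidence data, where many pairs share small-integer overlap counts).
Newick branch lengths are parent height minus child height.

### Beta-diversity partition

The Jaccard-family additive partition: pairwise total (b+c)/(a+b+c) splits
into turnover 2·min(b,c)/(a+2·min(b,c)) and a nestedness-resultant
remainder; the multiple-site version replaces min/max of (b, c) with sums
over all site pairs and a with `ΣS_i − S_T`. This is the only partition
additive under Jaccard, and it reduces exactly to the pairwise formulas at
two sites (tested). The degenerate all-identical single-species set has zero
denominator and is defined as zero beta diversity.

Comparison sets mirror the design. *Vertical central*: each shallow-upper
unit combined with the five deep strata of each deep cave (5 × 2 = 10 sets
of six units) and the ten multisite values averaged componentwise
(additivity survives the mean, so averaging components independently or
recomputing nestedness as mean total − mean turnover is the same thing).
*Vertical slope*: one multisite value over the five slope units.
*Horizontal*: one set per depth stratum containing every unit labelled with
that stratum regardless of lateral position; slope caves carry explicit
massif-level stratum labels (there is no principled way to derive them from
within-cave depth, so they are metadata, produced by the generator from
entrance depth below the massif top), which is how slope communities join
the deeper strata. Strata with fewer than two units are skipped with a
warning.

### Null models

The null hypothesis of unrestricted connectivity says nothing constrains
where occurrences fall, so the default randomization preserves only the
*fill* — the total number of presences — and scatters it uniformly over all
species × unit cells. A stricter `per_species` variant preserving each
species' occupancy count is available but not the default. One whole-massif
matrix is randomized per replicate and every comparison set is evaluated on
the same replicate, preserving cross-setting correlation. 9,999 replicates
by default. Significance is two-sided,
p = min(1, 2·min(#\{null ≥ obs\}+1, #\{null ≤ obs\}+1)/(n_null+1)),
because both significantly high and significantly low beta diversity are
scientifically meaningful; stars follow \*\* p < 0.01, \* p < 0.05, with no
multiple-testing correction across the battery. Null replicates in which a
comparison set loses a unit to emptiness are evaluated on the non-empty
subset; replicates with fewer than two non-empty units are resampled (in
the battery, recorded as missing for that setting only, to keep the shared
stream intact) — both paths are logged.

## The synthetic-data generator

The generator emulates the study conditions: 34 obligate species (plus 26
non-obligate surface associates that exercise the obligate filter), 20
units in the design above, trap counts 6–75, passage lengths 20–500 m,
depths at stratum midpoints, and 3D coordinates with the two deep caves as
vertical shafts on the plateau and slope caves laterally offset with
entrances 250–950 m below the massif top. Background occupancy defaults to
0.3 per cell, calibrated once so per-unit richness spans roughly 4–18
species, the observed range in this kind of survey.

Scenarios (effect size e ∈ [0, 1] scales each structure; at e = 0 all
collapse to the unstructured background):

- **bfn_random** — exactly `fill` presences placed uniformly: the null
  generator itself, used for calibration.
- **deep_turnover** — round(e·S) species are endemic to the deep core,
  split between the two deep caves and occupying each stratum of their cave
  with probability 0.95. Same-stratum units of different caves then differ
  by species replacement, which is what elevated horizontal turnover means.
- **nested_central** — each deep cave gets a species pool (≈ 1.8× background
  occupancy) that thins upward as nested subsets (retention 0.85 per
  stratum step), and every shallow-upper community is a subsample of its
  cave's pooled deep fauna; cells follow this coherent pattern with
  probability e. Only modelling the shallow units as subsets is not enough:
  with independently random deep strata a single nested unit barely moves a
  six-unit multisite statistic, whereas vertically coherent species ranges
  — the actual mechanism implied by downward funnelling — produce the
  below-null vertical beta diversity with an elevated nestedness share.
- **slope_distinct** — slope caves draw from a reserved third of the
  species pool and the rest of the massif avoids it (probabilities rescaled
  to keep richness comparable); at e = 1 the pools are disjoint and ANOSIM
  of slope vs the rest returns R = 1.

Abundances put 1 + Poisson(3) individuals in each occupied cell;
`generate_trap_samples` splits each count Binomial(n, ½) over the two
seasons so pooling recovers the matrix exactly. All randomness descends
from one seed through spawned child generators.

What the generator does *not* emulate: detection failure (presences are
observed perfectly), within-zone environmental gradients, abundance
structure beyond the occupancy pattern, and spatial autocorrelation of
community composition (coordinates and communities are generated
independently except through zone membership). Passing scenario-recovery
tests therefore show that the statistics detect these compositional
structures at realistic matrix sizes — not that field data are free of
observation effects.

## Scenario recovery and calibration

The recovery checks run the full null-model machinery on 100 generated
datasets per scenario at effect size 0.6 with 999 nulls (a reduced replicate
count that keeps the whole suite in the minutes range at these matrix
sizes; the observed statistics do not depend on it, only the granularity of
p). *Nested-central recovery* requires the averaged vertical-central total
BD to be significantly below its null (two-sided p < 0.05) with the observed
nestedness component above its null mean. *Deep-turnover recovery* averages
the horizontal sets of the strata deeper than 100 m — the strata that
contain deep-core and slope units — and requires total BD significantly
above its null with observed turnover exceeding nestedness. Both recover in
well over 80% of replicates; at effect 0 the scenarios are the null process
and rejections fall back to the nominal rate.

Calibration runs `null_test` on 200 datasets generated by the null process
itself (20-unit multisite total BD, 999 nulls each); the two-sided rejection
rate at α = 0.05 sits at the nominal level, slightly conservative because
ties between observed and null values of a discrete-numerator statistic
inflate both tail counts.

## Numerical conventions and edge cases

- Shared-species percentages round half-up (57.14 → 57, 14.71 → 15).
- Jaccard of two empty communities is undefined and raises; empty units are
  either dropped explicitly (`drop_empty_units`) or rejected by name.
- Permutation p-values always lie in [1/(n_perm+1), 1]; identical seeds give
  bit-identical null streams and byte-identical JSON reports (no timestamps
  are written).
- Dissimilarity matrices are validated symmetric, zero-diagonal, finite;
  dense storage is fine at n ≈ 20 units.
- Stratum labels are stored explicitly when provided and derived from depth
  otherwise; explicit labels win, which is what lets slope caves sit in
  deep massif strata while their own entrance-relative depth is small.

## Known limitations

- The multiple-site partition is exact but its null distribution is obtained
  by simulation only; no analytic approximation is attempted.
- The fill-only null is deliberately liberal (unit richness and species
  prevalence are both free); with very sparse matrices many replicates can
  degenerate, which is logged and, in the extreme, aborts.
- ANOSIM requires at least two units per group, so it cannot compare
  single-cave zones.
- The pipeline assumes one massif; nothing supports multi-massif designs.
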