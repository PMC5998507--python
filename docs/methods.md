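# Methods

`teboot` tests whether carrying a transposable-element (TE) insertion of a
given class and age is associated with a shift in gene expression, using a
covariate-matched weighted bootstrap. This note documents the model, the
defaults and why they are what they are, what the synthetic data does and
does not emulate, and the numerical choices.

## The comparison being made

For one species, one gene universe (single-copy orthologs or the remaining
genes) and one focal *element* — a TE class (DNA transposon, ERV/LTR, LINE
or SINE) at one age group — genes are split into a **test pool** (genes
whose extent ±1 kb contains at least one insertion of that element) and a
**reference pool** (all genes lacking it, i.e. genes carrying the same
class at the other age, other classes, or no TE at all). Age is defined by
percent identity of the insertion to its consensus: **ss**
(species-specific, recently active) when identity ≥ 94 (boundary
inclusive), **ns** otherwise. Intersection uses 0-based half-open
semantics with a ≥ 1 bp overlap rule and symmetric, strand-agnostic 1 kb
flanks clipped at coordinate 0.

Most genes carry several TE classes at once, so a raw carrier/non-carrier
contrast confounds the focal element with its co-travellers. Each bootstrap
iteration therefore draws

* a test set of *n* genes uniformly with replacement from the test pool,
* a reference set of *n* genes with replacement from the reference pool,
  with per-gene weights chosen so the reference draw reproduces the test
  pool's distribution of matching covariates,

with *n* = min(1000, pool sizes); pools under 600 genes skip the test
(`skipped_small_pool`). Two statistics per iteration, both test minus
reference:

* **median_diff** — difference in median log2(TPM), computed after
  omitting genes with TPM = 0 from each set independently;
* **prop_diff** — difference in the fraction of genes detected as
  expressed (TPM > 0 by default; threshold configurable), zeros retained.

## Sampling weights

A covariate stratum is *(combination of co-occurring TE types, length
decile)*. For a focal (class, age), a gene's stratum records: presence of
each of the other three TE classes (either age), presence of the focal
class at the *other* age group (exactly the recent-vs-old confound the
comparison must not absorb), and the gene-length bin (equal-frequency
deciles of gene length, flanks excluded, computed within the analysis
universe, ties broken by gene ID).

A reference gene in stratum *s* gets weight ∝ f_test(s) / f_ref(s), the
ratio of the stratum's frequency in the two pools, normalized to sum to 1.
In expectation the weighted reference draw then has exactly the test
pool's stratum distribution (verified directly: total-variation distance
< 0.001 over 5000 draws on a 20-stratum instance). Test strata with no
reference representative are unmatchable: they are dropped from the target
(renormalized) and logged; reference genes in strata absent from the test
pool get weight zero.

Why stratum = TE *types* and not the full age-resolved multiset: matching
on the full multiset of (class × age) elements fragments a realistic
3000-gene universe into ~600 strata, leaves hundreds of test strata
unmatchable, and concentrates the weights until the weighted draw's
effective sample size (1/Σw²) falls well below the 1000-gene set size — at
which point the bootstrap spread understates the replicate-to-replicate
variability of the statistic and the type-I error inflates several-fold
(measured ~1.25% per test against a nominal 0.21%). The type-level
stratum keeps ≤ 2⁴ compositions × 10 length bins, has essentially full
coverage, and restores nominal error control. The fully age-resolved
composition is still computed and exported per gene for inspection.

## Interval estimation, p-values, multiplicity

With B iterations (default 5000) the point estimate is the mean of the
iteration statistics (the median across iterations is also reported).
Confidence intervals are percentile intervals at the family-wise level
1 − α/m: empirical quantiles at α/(2m) and 1 − α/(2m), linear
interpolation between order statistics, α = 0.05, and m = n_tissues ×
n_elements tests per family (a family is one species × universe ×
age-group sweep; m is computed automatically and can be overridden). When
B < 2m/α the tail quantile falls outside the sample; the CI then
degenerates to the sample range and a width warning is emitted. Two-sided
p-values are the smallest percentile level at which the interval touches
zero, p = 2·min(#{≤0}+1, #{≥0}+1)/(B+1) capped at 1 — the add-one keeps
p > 0, and ties at exactly zero count on both sides. Benjamini–Hochberg
FDR is computed across each family's p-values, per statistic. Iterations
whose median is undefined (an entirely unexpressed set) are excluded from
that statistic's CI and counted in `n_iter_used`.

## Clustering

Samples are clustered on log2(TPM + 1) vectors over the ortholog-group ×
sample matrix (the pseudocount is needed because clustering requires
complete vectors; the bootstrap statistic deliberately does not use it).
UPGMA is average linkage on a configurable dissimilarity — Euclidean by
default, 1 − Spearman correlation as an option, since the source protocol
specifies the linkage but not the metric. Ward.D2 is Ward's
minimum-variance criterion on Euclidean distances (heights on the distance
scale). Default tree cuts: k = 5 (UPGMA) and k = 7 (Ward.D2). PCA is the
SVD of per-gene-centered log2(TPM + 1), with variance fractions from the
squared singular values.

## Synthetic data

The generator emulates the *structure* the analysis depends on, not any
real genome:

* Gene lengths are log-normal (mean-log 9.2, sd-log 0.9 → median ≈ 10 kb);
  genes are laid out without overlap, with intergenic gaps wide enough
  that neighbouring 1 kb flanks never touch, on 5 chromosomes.
* TE counts per gene and class are Poisson with a shared per-gene gamma
  frailty (mean 1, variance = cooccurrence_dispersion − 1, default 1.5),
  which makes counts of different classes positively correlated and
  reproduces the "most genes carry several TEs, few carry none" regime.
  Default class rates: DNA 0.6, ERV/LTR 1.0, LINE 1.8, SINE 1.6 insertions
  per gene. Insertions are placed uniformly within gene ± flank with
  class-typical lengths (SINE 0.1–0.4 kb … LINE 0.5–6 kb); additional
  background insertions land strictly between flanked genes.
* Identity is uniform on [94, 100) with probability ss_fraction (default
  0.3) and uniform on [50, 94) otherwise, so the ss boundary is exercised
  from both sides.
* log2(TPM) = gene baseline N(3, 2) + per-(gene, tissue) effect N(0, 1)
  shared across species + per-(gene, species) effect N(0, 0.5) + noise
  N(0, 0.5); exact zeros (dropout) replace values at zero_rate = 0.1.
  Tissue effects dominating species effects is what makes samples cluster
  by tissue. Planted effects add delta to log2(TPM) for carrier genes of
  one (species, tissue, class, age); every affected gene is recorded in a
  truth table.
* Orthology is by construction: the same gene index across species forms a
  group; a configurable fraction (default 0.7) of indices is orthologous.

Deliberately not emulated: sequence content, intragenic insertion-position
effects (the analysis only uses presence/absence), TE family phylogenies,
read-level noise, batch structure across studies, and realistic
between-class rate differences per species. Passing tests therefore show
the *procedure* is correct and calibrated under a plausible generative
model — not that any biological conclusion transfers to real data.

## Validation studies and the sizes used

`teboot.validation` packages three end-to-end studies, run by the test
suite and `scripts/acceptance.py`. They use a single-species design — six
tissues, four ss elements, m = 24, 3000 genes, ortholog_fraction 1.0 —
with class rates DNA/ERV 1.0, LINE 1.8, SINE 1.6 and ss_fraction 0.5 so
that every ss carrier pool clears the 600-gene minimum:

* **FWER** — 200 null replicates, B = 1000: the fraction of replicates in
  which any of a statistic family's m CIs excludes zero must stay ≤ α =
  0.05 (+3 binomial SE). The guarantee is per variable of interest: the m
  median-difference tests form one family and the m proportion-expressed
  tests another, each with its CIs at level 1 − α/m. (Pooling all 2m CIs
  into one count would double the budget: even perfectly calibrated tests
  would give 1 − (1 − α/m)^{2m} ≈ 2α.) The study reports the
  median-difference family as the headline rate and the
  proportion-expressed family alongside.
* **Recovery** — 100 replicates per delta ∈ {−0.5, +1.0}, planted on
  (SINE, ss) in brain: CI coverage of delta and point-estimate bias.
* **Matching** — TV distance between sampled-reference and test-pool
  stratum distributions on a 20-stratum instance at B = 5000.

B = 1000 (rather than 5000) in the replicated studies keeps a full study
at roughly eight minutes on one core; at m = 24 the extreme tail quantile
(α/2m ≈ 0.001) is still inside a 1000-draw sample.

## Numerical choices and degenerate inputs

* Weighted draws use the Walker alias method; row medians use a single
  sort with +inf padding — both exact, chosen for speed at B × n = 10⁶.
* Determinism: every stage takes a seed; the full sweep derives one child
  RNG stream per family from (seed, species, universe, age) spawn keys, so
  results are independent of family execution order.
* All gene lengths equal → a single length bin, with a warning.
* Empty test pool → pair flagged unusable; pool below 600 → skipped, shown
  grey in the report heatmap.
* A TE on a chromosome absent from the gene annotation is a warning, not
  an error.
* Known limitation: with-replacement weighted resampling understates the
  bootstrap spread if the weights are extremely concentrated (effective
  sample size ≪ set size). The type-level strata keep this margin
  comfortable at the validated sizes; `n_dropped_strata` and the pool
  sizes in the results table are the things to watch on unusual inputs.
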