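# Methods

This note records the statistical models, parameter choices and numerical
conventions behind `hypoxsig`, and what the synthetic-data generators do
and do not emulate.

## Differential abundance on intensity matrices

The unit of analysis is a log2 protein-intensity matrix with explicit
missing values (`NaN`), distinct from zero. Three stages mirror the
conventional label-free workflow:

**Valid-value filter.** A protein is kept if its fraction of quantified
values is at least `min_valid_fraction` (default 0.5) in at least one
group of the contrast (`any_group`, the default). The natural-language
rule "remove proteins quantified in fewer than half the samples in at
least one group" can also be read as requiring the threshold in *every*
group; that stricter reading is available as `filter_mode="all_groups"`.
Both modes are first-class and tested; the default follows the retention
convention of the widely used desktop proteomics software. The filter
never alters an observed value.

**Downshifted-normal imputation.** Missing values are replaced column-wise
(per sample) by draws from `N(μ̂ − downshift·σ̂, (width·σ̂)²)`, where `μ̂`
and `σ̂` (ddof = 1) are computed from the observed values of that column;
defaults `width = 0.3`, `downshift = 1.8`. The rationale is
missing-not-at-random dropout: unquantified proteins are predominantly
low-abundance, so the imputation distribution sits in the lower tail of
the observed distribution. Imputation is deterministic under a seed, never
changes an observed cell, and refuses columns with fewer than two observed
values. A matrix-wide mode is deliberately not provided.

**Two-sample t test.** Equal-variance two-sided Student's *t* per protein
(Welch available behind a flag, never default). The statistic is signed
`(mean₁ − mean₂)/se` while `log2fc = mean₂ − mean₁`, so a protein higher
in group 2 has positive fold change. Degenerate cases: zero pooled
variance with equal means gives `t = 0, p = 1`; with unequal means, `p`
is reported as the smallest positive float with a warning. No
multiple-testing correction is applied on the derivation path — the
procedure thresholds raw p at α = 0.05 — but a Benjamini–Hochberg q-value
column can be requested as an annotation.

**Microdissection purity.** Epithelial contamination of microdissected
stroma is estimated from an epithelium-specific marker (cytokeratin-8 in
the motivating application): per patient, the linear-scale stroma/
epithelium intensity ratio of the marker, times 100. Ratios are computed
per patient and then summarized by mean and median, rather than as a
ratio of means; a 62-fold epithelial excess thus reads as 100/62 ≈ 1.6%
contamination.

## Signature derivation and scoring

"Increased by hypoxia" is operationalized as `p < α` **and** `log2fc > 0`
within a subtype; no fold-change magnitude threshold is imposed because
none is part of the procedure. The hypoxome is the union of the
per-subtype sets. The stroma-exclusive set subtracts every
epithelium-significant protein regardless of effect direction — the
subtraction is about *where* a difference exists, not which subtype is
higher. All derived sets are sorted lexicographically so GMT output is
reproducible; empty results are legal for the set operations (with a
logged warning) but cannot be written as GMT lines.

Scoring centers each signature gene on its cohort-wide mean and sums
centered values per patient, so scores sum to zero over the cohort (an
algebraic identity, used as a test invariant) and are invariant to
per-gene constant shifts. Signature genes absent from a cohort are
dropped with a warning by default (`missing_gene_policy="drop_warn"`);
an `error` policy is available. Multiple probes per gene are collapsed by
per-sample maximum ("max probe") before scoring.

Quartile stratification uses linear-interpolation quantiles at the
25th/50th/75th percentiles; a score exactly on a boundary goes to the
lower group, making the signature-high group (Q4) conservative. Fewer
than four patients, or all-identical scores, are errors.

## Survival analysis

Kaplan–Meier estimation and Cox proportional-hazards fitting are
delegated to lifelines: Efron tie correction, Newton–Raphson
maximization, 95% Wald confidence intervals, all covariates entered
simultaneously. A constant covariate is rejected before fitting (named in
the error), as is a model with fewer events than covariates plus one;
non-convergence surfaces as an error with the fitter's diagnostic. The
log-rank statistic is computed in-package — the Mantel–Haenszel sum of
observed-minus-expected events over the risk sets at each distinct event
time, with the hypergeometric variance — because the per-group O/E
decomposition is part of the result contract; it agrees with lifelines
and R `survival::survdiff` to numerical precision in tests. Subjects
censored at an event time remain in that event's risk set (events precede
censorings). Deaths from other causes are censored.

The treatment-interaction test fits
`score_high + treatment + score_high × treatment (+ adjusters)` and
reports the interaction hazard ratio with its Wald p. Collinearity of the
product with a main effect and constant inputs are rejected up front.

## Permutation uniqueness and greedy reduction

The strength of a gene set is the log-rank χ² of Q4 vs Q1–Q3 of its
score; χ² and p are monotone in each other at 1 df so either ranks sets
identically. The permutation null draws same-size sets uniformly without
replacement from a pool — conventionally the union of the two source sets
the candidate was intersected from, supplied as an input rather than
recomputed. The empirical p uses the add-one rule,
`(1 + #{null ≥ observed})/(B + 1)`, so it is never zero; the default
`B = 10,000` resolves p down to ~10⁻⁴. Pool members absent from the
cohort are dropped with a warning before drawing.

The greedy reduction records the full signature as step 0, then at each
step evaluates all leave-one-out subsets and keeps the one with the
lowest p, to a single member; the best step is the trajectory-wide
argmin of p (ties keep the larger set). Ties between subsets at machine
precision prefer the larger χ², then removal of the lexicographically
smallest gene — an explicit convention so the procedure is bit-for-bit
reproducible. Internally both procedures share a precomputed
mean-centered expression matrix, verified in tests to agree exactly with
the public scoring path.

## Synthetic-data generators

The generators are first-class, tested code; their defaults define the
conditions under which the pipeline's recovery and calibration properties
are demonstrated.

**Secretome** (`SecretomeSimConfig`): 800 proteins; 6 replicate columns
per (subtype, oxygen) group; per-protein baseline log2 intensity
`N(25, 2²)`; a +1 log2 global basal-vs-luminal baseline shift; planted
hypoxia effects of +2 log2 on 60 luminal-responsive and 20
basal-responsive proteins, 5 shared — mostly subtype-private responses,
scaled down from the hundreds-of-proteins scale of real discovery
panels; residual noise sd 0.5 (a strong but realistic log2 effect against
replicate-level variation). Dropout is
`P(missing) = logistic((midpoint − intensity)·slope)` with midpoint 20
and slope 0.8, putting ~4% of cells missing overall, concentrated at low
abundance — the MNAR pattern downshifted imputation targets.

**Tissue** (`TissueSimConfig`): 12 patients per subtype (matching a
two-dozen-sample microdissection study), paired epithelium/stroma
columns per patient; 40 planted stroma-exclusive and 20 shared-compartment
subtype effects of +2 log2; same baseline, noise and dropout model.
Protein identifiers are shared with the secretome generator so the two
planted designs intersect, emulating the discovery design.

**Cohort** (`CohortSimConfig`): gene expression `N(μ_g, 1)` with
`μ_g ~ N(8, 1)` (log2 microarray scale); the signature score is
standardized internally so `beta` is a log hazard ratio per score sd
regardless of signature size; event times are exponential with rate
`0.003·exp(βz + γ·treat + δ·z·treat)` per month and administrative
censoring at 240 months, giving roughly half the patients an event —
event-rich enough for stable Cox fits at a few hundred patients.
Treatment is Bernoulli(0.5); clinical covariates (tumor size class,
grade, node status, basal subtype at 14%) are drawn independently of the
hazard, so adjusted analyses are exercised without confounding.

What the generators do **not** emulate: peptide/spectrum-level structure,
between-run normalization artifacts, batch effects, cell-line identity
within subtype (replicates are pooled, as the downstream t-tests pool
them), correlated gene expression, non-proportional hazards, informative
censoring, and covariates correlated with outcome. Passing recovery tests
therefore demonstrate the correctness and calibration of the pipeline's
statistics under its own assumptions, not robustness to these real-data
complications.

## Problem sizes and determinism

Tests and the acceptance script run simulations at deliberately modest
sizes — 200–1500 proteins, 120–1000 patients, 200 replicate cohorts for
calibration loops, B = 199–999 permutations — chosen so the full suite
completes in about a minute while leaving Monte-Carlo bands (binomial
3σ, 3 standard errors) tight enough to be informative. Every stochastic
operation takes an explicit seed; identical seed and inputs give
byte-identical output. The greedy reduction consumes no randomness at
all.

## Known limitations

* The end-to-end derivation subtracts every epithelium-significant
  protein, so ~α of true stroma-exclusive proteins are lost to chance
  epithelium significance; recall of the planted signature fluctuates
  around 0.94 and its exact value is seed-dependent.
* The log-rank p for Q4 vs Q1–Q3 treats the quartile cut as fixed; no
  correction is made for having chosen the upper quartile as the cut
  point.
* Cox fitting inherits lifelines' convergence behavior; near-monotone
  partial likelihoods (e.g. tiny datasets with complete separation) are
  reported as errors rather than fitted.
* The permutation test's pool is an input; the test says nothing about
  selection steps upstream of the pool's construction.
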