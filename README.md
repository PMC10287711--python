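# hypoxsig

Tumors outgrowing their vascular supply become hypoxic, and tumor cells
respond by secreting proteins that remodel the surrounding stroma. This
package implements a pipeline for discovering and evaluating a **stromal
hypoxia protein signature** in breast cancer: it derives the signature
from cell-line secretome and microdissected tumor-compartment proteomics,
scores it in gene-expression cohorts, and evaluates its prognostic value
by survival stratification, a random-selection permutation test and a
greedy leave-one-out reduction. It is aimed at computational biologists
working with label-free proteomics and clinically annotated expression
cohorts.

## The method

**Differential abundance.** Log2 intensity matrices are filtered to
proteins with valid quantification in at least 50% of the samples of at
least one group; remaining missing values — which arise preferentially at
low abundance (missing not at random) — are imputed per sample column from
a downshifted normal, `N(μ̂ − 1.8·σ̂, (0.3·σ̂)²)` with `μ̂, σ̂` the observed
column mean and sd. Groups are compared with an equal-variance two-sided
Student's *t* test at α = 0.05 on raw p values.

**Signature derivation.** With luminal-like and basal-like cell lines
conditioned at normoxia or hypoxia, the *hypoxome* is the union over
subtypes of proteins with p < α and positive log2 fold change under
hypoxia. From paired microdissected tumor compartments, the
*stroma-exclusive* set is the proteins separating the subtypes in stroma
minus those also separating them in epithelium. The signature is their
intersection.

**Scoring and survival.** In a cohort, each signature gene *g* is
centered on its cohort mean and patient *j* receives the score
`S_j = Σ_g (x_gj − x̄_g)`. Patients are cut at score quartiles; Q4 is the
signature-high group. Q4 vs Q1–Q3 is tested by Kaplan–Meier / log-rank,
and Cox proportional-hazards models (Efron ties, all covariates entered
simultaneously) give adjusted hazard ratios and a score × treatment
interaction test.

**Uniqueness and reduction.** The permutation test compares the
signature's Q4-vs-rest log-rank χ² against same-size random draws from a
protein pool, with `p = (1 + #{null ≥ obs}) / (B + 1)`. The greedy
reduction repeatedly removes the member whose absence gives the lowest
log-rank p, down to one member, and reports the strongest subset.

Synthetic-data generators (`simulate_secretome`, `simulate_tissue`,
`simulate_cohort`) reproduce the statistical structure each stage assumes
— planted hypoxia effects, stroma-exclusive subtype differences,
intensity-dependent dropout, and an exponential proportional-hazards
cohort — and return the planted ground truth for recovery checks.

## Worked example

`examples/derive_signature.py` simulates a secretome (800 proteins, 6
replicates per subtype × oxygen group, 2-log2 planted hypoxia effects)
and a tissue experiment (12 patients per subtype, paired compartments),
then runs the derivation:

```
hypoxia-increased: 82 luminal, 40 basal, union 114
stroma-exclusive subtype differences: 77
derived signature: 38 proteins
planted intersection recovered: 37/40 (precision 0.97, recall 0.93)
```

The 114-protein hypoxome and 77 stroma-exclusive proteins intersect in 38
proteins, 37 of which belong to the generator's planted intersection —
the derivation recovers the planted signature almost exactly, with the
few losses coming from chance epithelium significance subtracting true
stroma-exclusive proteins.

`examples/score_and_survival.py` scores a planted prognostic signature in
an 852-patient synthetic cohort (hazard doubles per score sd, plus a
planted radiotherapy interaction):

```
log-rank Q4 vs Q1-3: chi2=218.5, p=1.92e-49
univariate HR (Q4 vs Q1-3): 3.80 [3.14-4.59]
adjusted HR (Q4 vs Q1-3):   3.77 [3.12-4.56]
score x radiotherapy interaction HR: 2.68 [1.84-3.91], p=0.000
```

`examples/permutation_and_reduction.py` shows the permutation test
(empirical p = 0.0030 for a hazard-carrying candidate against random
16-gene draws) and the greedy reduction, which strips the eight
non-prognostic dilution genes first and keeps 100% of the planted
hazard-carrying genes in its best subset.

A thin CLI mirrors the library (`hypoxsig simulate | diff |
derive-signature | score | survival | permute | reduce`), exchanging TSV
matrices, TSV clinical tables and GMT gene sets.

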