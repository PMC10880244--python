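# Methods

## The evaluation framework

A two-arm randomized trial (ICI vs chemotherapy) supports separating
*predictive* from *prognostic* models. Each model produces one real score
per patient; within each arm a basal metric (BM) measures how well the
scores rank the observed endpoint — Harrell's C-index for PFS/OS, ROC-AUC
for the progressive-disease (PD) label. The primary metric is

    DSS = [2(BM_ici − ½)]² − [2(BM_chemo − ½)]².

Squaring credits models that rank "backwards" equally with models that rank
forwards (the information content is the same); the difference nulls out
whatever a model knows about outcome *independently of treatment*. A purely
prognostic score earns similar BMs in both arms, hence DSS ≈ 0; a score
that tracks ICI benefit is informative only where patients received the
ICI, hence DSS > 0; DSS < 0 indicates a chemotherapy-specific signal.

### Conventions and numerical choices

* **C-index comparability.** A pair (i, j) with t_i < t_j is comparable
  when i had the event; pairs with tied times are comparable when exactly
  one of the two had the event (the censored one counts as surviving
  longer). Tied scores count ½. Tied event times with both events are
  incomparable. These are the standard Harrell conventions; they are
  asserted against exhaustive pair enumeration (all instances with n ≤ 8)
  and against `lifelines` on tie-free inputs.
* **ROC-AUC** is the Mann–Whitney U statistic with mid-rank ties,
  U/(n₁·n₀).
* **Direction handling.** Every model declares whether larger scores mean
  better predicted ICI outcome (`benefit_high`) or worse (`benefit_low`).
  Survival metrics orient scores accordingly; for the PD endpoint a
  `benefit_high` model is credited for predicting PD = 0. Because DSS
  squares the scaled BM, evaluation is ultimately direction-agnostic; the
  declaration only fixes signs in per-arm BM reporting and Kaplan–Meier
  stratification.
* **OS is evaluated on as-recorded outcomes.** Crossover of control-arm
  patients onto ICI therapy biases OS contrasts in real trials; a corrected
  OS time can be supplied by substituting the `os_time`/`os_event` columns,
  but no correction is implemented here.
* **Quantiles** (tertiles, medians, 67th percentiles) use the linear
  interpolation (type-7) definition throughout, computed on the pooled
  cohort across both arms. Pooling is a choice — the source descriptions do
  not stratify cut points by arm.
* **Kaplan–Meier medians** are the smallest time at which the product-limit
  estimate drops to ≤ 0.5 (reported as "not reached" when the curve never
  gets there). The curve comes from `lifelines`; the crossing rule is
  applied to the curve directly so that an estimate of exactly 0.5 counts
  as reached.

## Bootstrap, Bayes factors and ranking

Uncertainty in (BM_ici, BM_chemo, DSS) is estimated by resampling patients
with replacement *within each arm*, keeping arm sizes fixed (B = 1000 by
default; seeded, reproducible). DSS compares arms, so letting arm sizes
fluctuate across resamples would add variance unrelated to the model.
Resamples on which a metric is undefined (no comparable pairs, single
class) are redrawn and counted.

Model A's Bayes factor against model B is estimated from paired resamples
as continuity-corrected win odds: with w = #{i : DSS_A[i] > DSS_B[i]}
(ties ½), K = (w + ½)/(B − w + ½), capped at 2B. K(x, x) = 1 exactly and
K(a, b)·K(b, a) ≈ 1 (within ≤ 5% for B ≥ 500). This estimator is this
package's operationalization of the challenge's paired-bootstrap
comparison; numerical agreement with any specific challenge's K values is
not claimed.

Ranking applies three rules in order: *eligibility* (K > 3 against the TMB
baseline evaluated on the same draws), the *tie set* (eligible models with
K < 3 against the highest-DSS eligible model), and *tie-breaking* by the
ICI-arm BM, declaring top performers all tie-set models within `tie_tol` of
the best tie-break score. `tie_tol` defaults to one bootstrap standard
error of the winner's ICI-arm BM — "close" is not otherwise quantified in
the source material. An empty eligible set yields an empty top-performer
list, a valid outcome.

## Reference models

All cohort-level thresholds are recomputed on the cohort being scored
(fit = threshold computation, predict = rule application).

* **Netphar** — Y = 10·1[TMB ≥ 243] + 1[TMB ≥ 243]·PD-L1. Missing TMB
  falls on the conservative low branch (score 0). The scalar rule requires
  PD-L1; the estimator imputes missing PD-L1 with the cohort median so a
  full-cohort submission is always complete (`impute_missing=False`
  restores the strict rule).
* **I-MIRACLE** — TMB-high = TMB ≥ cohort upper tertile, falling back to a
  proliferation-signature upper-tertile rule when TMB is missing (the
  proliferation score correlates with TMB in NSCLC); PD-L1-high =
  PD-L1 ≥ 50%, falling back to an ICR (immunologic constant of rejection)
  signature rule. Score 3 = both high, 1 = both low, 2 otherwise. Both
  signature proxies are scored with the mean-rank enrichment statistic.
* **Aginome-Amoy** — groups: 1 = PD-L1 < median; 2 = PD-L1 ≥ median and
  TMB < median; 3 = both ≥ median; within-group scores on min–max
  normalized values (group 3: T + 2P; group 1: T + P; group 2: T − P);
  group offsets (+20/+10/0) enforce the stated ordering group 3 > group 1 >
  group 2. The offsets are arbitrary rank-preserving constants — all basal
  metrics are rank-based, so only the induced ordering matters. The "TMB
  and PD-L1 expression scores" are taken to be the measured TMB count and
  PD-L1 percentage; min–max normalization over the scored cohort is this
  package's choice (the normalization was not specified), with constant
  variables mapping to 0.5. Missing values are cohort-median imputed by
  default.
* **FICAN-OSCAR** — Y = −0.693·panel − 0.357·isTMBhigh − 0.105·isMale −
  0.198·isSquamous − 0.05·isSquamous&PD-L1>5 − 0.223·isEversmoker −
  0.105·isECOG0, with the printed coefficients used as-is (no refitting).
  The panel signature is scored with the random-walk enrichment statistic.
  isTMBhigh uses the cohort upper tertile (the cut point was not stated;
  this matches the other models' TMB-high rules); missing TMB gives 0. All
  coefficients are negative, so the model declares `benefit_low` — an
  explicit assumption, harmless to DSS (squared metrics) but visible in
  per-arm BM signs and KM stratification.
* **DukeLKB1** — six features: 1[TMB > p67], 1[PD-L1 > p67], and the means
  of per-gene z-scores for a 4-gene inflammatory signature and LKB1-loss,
  NRF2-activation and neuroendocrine signatures, with z-scoring performed
  separately within squamous and non-squamous subsets (expression
  distributions differ by histology). How the six features combine into a
  single prediction was unspecified; the default is a signed equal-weight
  sum — immune features positive, the three resistance phenotypes negative,
  matching their known associations — exposed as a `weights` parameter.
* **Baselines** — the raw TMB or PD-L1 value, cohort-median imputed.

Gene membership of the published signatures (20-gene ICR, proliferation,
4-gene inflammatory, LKB1/STK11-loss, NRF2, neuroendocrine, the custom
panel) is user-supplied configuration via GMT files; the package ships no
gene lists. The synthetic generator writes its own true signature blocks as
a GMT so the full pipeline runs without external data.

## Signature scoring

* `zscore_genes` — per-gene mean 0 / unit sample sd (ddof 1), optionally
  within patient strata (≥ 2 patients each); zero-variance genes map to 0.
* `rank_enrichment_score` — per patient, all G genes are mid-ranked
  ascending; with m set genes the score is the standardized Mann–Whitney
  mean rank (mean set rank − (G+1)/2) / √((G+1)(G−m)/(12m)). Symmetric
  around 0 under exchangeability, antisymmetric under expression negation,
  invariant to monotone transforms. This competitive statistic stands in
  for the external enrichment package used by the original I-MIRACLE
  implementation; exact numerical equivalence with that package is not
  claimed — the contract is the formula above.
* `walk_enrichment_score` — per patient, genes are ordered by decreasing
  expression; the walk steps up by rank^exponent (normalized over set
  genes; exponent 1 by default) at set genes and down by 1/(G−m)
  elsewhere; the score is (max positive deviation) − (max negative
  deviation magnitude), the "difference" convention of single-sample GSEA
  variants. Plain ranks deliberately replace the kernel-density weighting
  of the original method; the bracketing properties (top-m set → positive,
  bottom-m → negative, full set → constant) are tested against a
  step-by-step brute-force walk.
* Gene identifiers match by exact string comparison after upper-casing;
  set genes absent from the matrix are ignored with a warning, and an
  entirely absent set is an error.

## The synthetic trial generator

The generator targets *structural* realism — the dependence structure the
evaluation framework is sensitive to — not calibration to any real trial's
summary statistics.

Per patient: covariates (male 0.60, squamous 0.30, ever-smoker 0.85,
ECOG 0 0.35 — typical first-line NSCLC trial frequencies); latent immune
and proliferation factors ~ N(0,1); expression for 200 genes =
loading·factor + N(0,1) noise for the signature blocks (20-gene immune,
10-gene proliferation, 5-gene panel, loading 0.8; the panel loads on the
immune factor), pure noise elsewhere. TMB =
round(exp(5.0 + 0.8·z)) — median ≈ 150 missense mutations — with z coupled
to the proliferation factor by a Gaussian copula (ρ = 0.5, mirroring the
TMB–proliferation association the I-MIRACLE proxy rule relies on). PD-L1 =
100·expit(1.5·z) with z coupled to the immune factor (ρ = 0.6).

Outcomes follow an exponential proportional-hazards model with linear
predictor η = θ·1[ICI] + β_prog·b + β_pred·b·1[ICI], hazard
λ₀·e^(−η), λ₀ = ln2/5 per month (5-month control-arm median PFS); b is the
designated biomarker standardized by its population parameters
(log TMB by default). OS = PFS + an independent exponential residual
(median 8 months), guaranteeing OS ≥ PFS and positive endpoint
correlation. The PD label is Bernoulli with
logit P(PD) = α − γ_prog·b − γ_pred·b·1[ICI], α = −0.4 (≈ 40% PD).
Censoring is administrative at 24 months plus random exponential censoring
at 0.02/month. TMB is missing completely at random in 20% of patients and
PD-L1 in 5% (TMB ascertainment is the leakier assay in practice);
informative missingness is not modelled. Exponential rather than Weibull
baseline hazards are deliberate: all metrics are rank-based, so the shape
of the time scale is irrelevant, and the exponential admits closed-form
inverse sampling.

All randomness derives from one seed through named substreams (covariates,
expression, outcomes, censoring, missingness), so changing, say, an outcome
coefficient leaves the covariate and expression draws untouched.

Scenario presets: `null` (θ = β_prog = β_pred = 0), `prognostic_only`
(β_prog = 0.8), `predictive_only` (β_pred = 1 on TMB), `mixed` (θ = 0.3,
β_prog = 0.5, β_pred = 0.8), with the BOR coefficients moved in step.

**What passing tests show, and what they do not.** The generator draws
expression as Gaussian noise around a low-rank factor structure, uses
proportional hazards with a single biomarker, and masks values completely
at random. Real trial data have heavier-tailed expression, batch effects,
non-proportional hazards, informative censoring and assay-dependent
missingness. Tests against this generator therefore validate the
*framework* — that the metrics, bootstrap, ranking rules and models compute
what they claim, and that DSS separates interaction signal from main-effect
signal — not that any model here would reproduce its published performance
on restricted trial data, which is out of scope by design.

## Problem sizes

The predictive-vs-prognostic separation check uses 200 simulated trials of
n = 500 with β_pred = 1 (median TMB-model DSS > 0.1 under
`predictive_only`, |median| < 0.05 under `prognostic_only`). Null-model
symmetry and copula-correlation checks use single trials of n = 2000–5000.
Pipeline determinism is checked at n = 80–120 with B = 150–200; the
bootstrap default remains B = 1000 for analyses.

## Known limitations

* Enrichment scores are this package's standardized statistics, not
  re-implementations of the exact external tools the original models
  called; rank-level agreement is expected, numerical identity is not.
* The Bayes-factor estimator is one defensible operationalization of
  paired-bootstrap model comparison; the cap at 2B truncates extreme odds.
* No multi-endpoint composite ranking: each endpoint is ranked
  independently.
* OS crossover correction, external databases and pre-trained
  expression-based models are out of scope.
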