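# Methods

This note documents the models, parameter choices and numerical decisions
behind `polyrisk`, and what the synthetic-data tests do and do not establish
about real data.

## Phenotype classification

Cases are classified from clinical fields. Aggressive disease: Gleason
score > 7, non-localized stage (regional or metastatic), PSA > 50 ng/mL, or
death from the disease. Nonaggressive: Gleason ≤ 7 with localized stage for
US studies, or Gleason ≤ 7 with PSA ≤ 50 for the Ugandan study, where staging
is unavailable. The metastatic subset is stage = metastatic (US) or
PSA > 100 ng/mL (Uganda) and always counts as aggressive. Cases matching
neither rule because of missing fields are `unclassified`: they are excluded
from the aggressive/nonaggressive/metastatic contrasts but retained in the
overall case-control analysis. That inclusion rule is our choice — clinical
datasets rarely state how incompletely staged cases were handled — and it
only affects the overall contrast.

## Variant classification

A variant is P/LP/D when rare (MAF < 1%) and (a) truncating (frameshift
indel, stop gain, essential splice donor/acceptor loss), or (b) missense-like
(missense or exon-boundary codon change) with a ClinVar
pathogenic/likely-pathogenic assertion by ≥ 1 clinical laboratory, or (c)
missense-like with an in-silico consensus. Excluded consequence classes
(intronic, UTR, in-frame indel, synonymous, near-splice outside the 2 bp
consensus site) dominate every other field. Decisions left open by the rule
set, and how we fixed them:

* **In-silico consensus.** The five predictors do not always agree or return
  calls. Default policy: every non-missing predictor calls damaging, with at
  least 3 informative predictors — the most conservative plausible reading.
  `majority` (> half of informative) and `any` are available as
  `insilico_rule`.
* **ClinVar conflicts.** One laboratory's pathogenic/likely-pathogenic
  assertion qualifies the variant even if another asserts benign; the audit
  label carries a `clinvar_conflict` flag so conflicted calls are traceable.
* **MAF source.** The MAF in the annotation record is taken at face value
  (study controls or a reference panel — the caller's choice).
* **Gene panels.** Default {BRCA2, ATM, NBN, PALB2}; a secondary panel
  {BRCA1, RAD50, MLH1, MSH6} is supported via configuration. Variants in
  other genes are skipped with an `outside_panel` audit label, not an error.

## PRS

The score is the raw weighted sum of effect-allele dosages (not
standardized; a flag exists). Scoring variants are first filtered to those
polymorphic in controls (folded MAF > 1%) and present in the dosage table.
Tertile cut points are the 1/3 and 2/3 quantiles of the control score
distribution, type-7 linear interpolation, with left-closed upper bands
(low < q₁ ≤ intermediate < q₂ ≤ high); any consistent quantile rule would
do, this one is fixed and documented. A missing single dosage is imputed as
2 × the control effect-allele frequency (its Hardy–Weinberg expectation);
individuals missing > 10% of model variants get a missing score and are
dropped at cohort assembly with a count in the join report.

## Association models

Maximum-likelihood logistic regression (Newton iterations, log-likelihood
tolerance 1e-8, max 100 iterations) of case status on five joint-category
indicators (reference: intermediate-PRS non-carrier), age in years
(continuous), study indicators (first level dropped) and 10 principal
components. Wald 95% CIs are exp(β ± 1.96·se); the full category coefficient
vector and covariance are retained for absolute-risk propagation.

Sparse cells are a real feature of this design — carriers are ~0.6% of
controls — so the default is a plain ML fit with a warning when any category
has < 5 cases or controls (wide CIs are then honest); a Firth-type penalized
fit (Jeffreys-prior score correction) is available via `firth=True`.
Categories with zero cases or zero controls have no finite MLE: they are
flagged, reported with an undefined OR, and their rows are excluded from the
fit so the remaining contrasts stay estimable.

The interaction test compares main effects (2 tertile indicators + carrier)
against the same model plus the 2 tertile × carrier products: LRT statistic
2·(ll_full − ll_reduced) on df = number of estimable products, and a joint
Wald chi-square on the product coefficients. A product term whose nonzero
rows contain only cases or only controls (an empty or separated cell) is
dropped with a warning and the df reduced. Because the categorical scale of
the test is a design choice, a continuous-PRS × carrier variant (df = 1) is
available via `continuous_prs=True`; the tertile parameterization is the
default, matching the categorical analysis.

## Absolute risk

ORs are used as relative risks r_g — adequate for a rare-ish disease on the
ages considered, and a documented approximation rather than an identity.
Population category frequencies are the prevalence-weighted mixture
p_g = π f_case,g + (1 − π) f_ctrl,g with π = 0.167 by default. The baseline
hazard λ₀(t) = λ_pop(t) / Σ_g p_g r_g keeps the calibration identity
Σ_g p_g r_g λ₀(t) = λ_pop(t) exact at every age. Frequencies are static
(no depletion of high-risk categories with age); the population-average of
category curves therefore tracks the single-category population curve to
within ~2% relative error up to age 85 with realistic rates, which the test
suite verifies by simulation. Cumulative risk uses the discrete-time
recursion with the yearly survival factor 1 − h_g − μ floored at zero and
the risk clamped to [0, 1].

Overall-disease ORs are a case-mix mixture w·OR_agg + (1−w)·OR_nonagg with
w = 0.37 (the expected aggressive share among cases in the general
population), arithmetic on the OR scale; `log_scale=True` gives the
geometric alternative since the weighting scale is a genuine ambiguity.

Monte Carlo CIs: the category log-OR vector is drawn jointly from
N(β, Σ) — joint sampling is the default because the fitted covariance is
available; independent per-category sampling would discard it. Per draw the
baseline is recalibrated and every curve recomputed; the reported estimate is
the iteration mean (the deterministic plug-in curve is also available via
`plugin_curves`) and the bands are empirical 2.5/97.5 percentiles over 1,000
iterations by default. Σ is checked for positive semi-definiteness
(eigenvalue tolerance −1e-10) before sampling; sampling uses the SVD method
of `numpy.random.Generator.multivariate_normal`, and a fixed seed gives
bit-identical curves. For case-mix-weighted curves the aggressive and
nonaggressive coefficient vectors are sampled independently (their
cross-covariance is not estimated) and mixed on the OR scale per iteration.

Rates are supplied per 100,000 person-years and converted to annual hazards
by division — the registry convention; no exponential conversion, since the
rates involved are small. The default age grid is 40–85 in 1-year steps.

## Synthetic-data generator

The generator emulates a case-enriched case-control study: per-variant
dosages are binomial(2, f_j) with f_j ~ U(0.05, 0.5); weights are drawn once
per scoring file; carrier status is Bernoulli; disease status follows
logit P(case) = α + β_c·carrier + β_low·1[low] + β_high·1[high]
+ β_sd·z(PRS) + γ·carrier·(1[high] − 1[low]) + small age/study/PC effects
(each |log-OR| ≤ 0.1). Defaults echo the study being emulated: n = 3,220,
254 PRS variants, case fraction 0.558, carrier frequency 0.6% among
controls, carrier OR 4.51, high- and low-tertile ORs 3.02 and 0.57,
interaction 0, aggressive share of cases 37% with a 25% metastatic subset,
population prevalence 0.167 recorded separately for absolute-risk weighting.

Two quantities are solved numerically rather than set directly:

* the intercept α (bisection/Brent) so the realized case fraction matches the
  case-enriched design, and the carrier base frequency so the expected
  carrier frequency *among controls* matches its target (carriers are
  enriched among cases, so the population frequency must sit slightly
  higher);
* the true tertile cut points. The analysis anchors tertiles to the control
  score distribution, which is case-depleted relative to the generated
  population. Defining the generator's "true" categories on population
  quantiles would make the analysis estimate a different (attenuated)
  contrast than the nominal truth. The generator therefore solves a fixed
  point: cut points that are tertiles of the expected control score
  distribution, jointly with α and the carrier frequency (≤ 12 iterations,
  convergence within 1e-4 control-score SDs).

What the generator does **not** model: LD between PRS variants, haplotypes,
imputation dosage uncertainty, relatedness, ancestry confounding (PCs are
pure noise covariates with small effects, so adjustment is exercised but
confounding correction is not), or age-dependent carrier effects. Passing
tests therefore demonstrate the statistical machinery is correct under the
stated model, not that the pipeline is robust to population structure or LD
artifacts in real data.

Annotation records are generated by cycling through record kinds that cover
every decision branch of the classifier (three truncating classes, ClinVar
missense with and without conflicts, unanimous in-silico missense,
exon-boundary ClinVar, each excluded class with deliberately misleading
other fields, common truncating, majority-but-not-unanimous and
too-few-informative in-silico patterns, and an off-panel truncating
variant), so truth recovery is exact by construction when the rules are
implemented correctly.

## Problem sizes in the test suite

The statistical acceptance tests use: 100 random 2×2 tables for oracle
equivalence; 200 cohorts of n = 5,000 (seeds 1–200, 40 PRS variants) for
parameter recovery and CI coverage; 500 cohorts of n = 20,000 (40 PRS
variants) for interaction-test type-I calibration; 1,000 randomized records
for the exclusion-dominance property. The PRS panel is slimmed in the
replicate-heavy tests because the variant count does not enter the
quantities under test; effect sizes, carrier frequency and case fraction
stay at the package defaults.

## Known limitations

* OR→RR substitution overstates relative risks for genuinely common
  outcomes; with lifetime risks above ~30% in the top categories the
  absolute-risk curves for those categories should be read as approximate.
* Static category frequencies ignore differential depletion of high-risk
  categories at old ages (the ~2% bound above); a dynamic-frequency mode is
  a possible extension but would break the exact calibration identity.
* The ML fits deliberately reproduce plain maximum likelihood behavior on
  sparse carrier cells (very wide CIs); use the Firth option when cells are
  tiny and a usable point estimate matters more than comparability.
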