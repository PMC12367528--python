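# Methods

This note documents the statistical procedures implemented in `painpipe`, the
assumptions behind the synthetic cohort generator, the defaults and why they
were chosen, and the package's numerical conventions and known limitations.
It states no empirical result beyond what the test suite and
`scripts/acceptance.py` compute.

## Synthetic cohort generator

The generator emulates the statistical structure a multimodal biomarker
analysis assumes, not the marginal distributions of real assays.

**Features.** Each modality holds `n_features` exchangeable continuous
columns built as `sqrt(rho) * z_latent + sqrt(1-rho) * noise`, with features
assigned round-robin to `n_latent` latent factors; features sharing a latent
have pairwise correlation `rho = feature_block_correlation`. Confounder
leakage adds `leakage_strength * c` to every feature. Default `rho = 0.1`:
heterogeneous clinical assay panels show weak-to-moderate positive coupling,
and the real correlation structure of such panels is unknown here — the block
model is a stand-in, not an estimate. The default was chosen once; tightening
it raises, and loosening it lowers, how faithfully encoding maps (which
estimate `Sigma @ beta`, not `beta`) can rank the planted coefficients.

**Planted effects.** Per (modality, diagnosis), `ceil(effect_sparsity *
n_features)` coefficients are nonzero, with heterogeneous signed magnitudes
(`|N(0,1)| + 0.2`, so no entry is vanishingly small and the magnitude ranking
is well defined) normalized to `||beta|| = effect_scale`. `effect_scale` is
therefore approximately the log-odds SD contributed by the modality. With
`shared_beta = True` every diagnosis reuses one vector per modality — the
regime in which a composite signature is meaningful. Defaults:
`effect_sparsity = 0.25`, `effect_scale = 1.0`, `base_rate = 0.10`.

**Diagnoses.** Labels are Bernoulli(sigmoid(c + eta)) with
`eta = sum_m w_m (X_m beta_m) + gamma * z_bio * z_psy + w_C * sum_k c_k`,
where `z_bio`/`z_psy` are the first latents of the first biological modality
and of the modality named `psychosocial`. The intercept `c` is found by
bisection on the cohort's realized linear predictor so the expected
prevalence equals `base_rate`; using the realized draw rather than a separate
simulation keeps the generator single-pass and exactly seed-deterministic.
The `confounder_weight` term plants labels that depend on the features *only*
through a leaked confounder — the deconfounding test condition.

**Pain sites.** The number of chronic sites follows a cumulative-logit model
with equally spaced cutpoints `0.2 + k` on
`1.0 * z_psy + 0.3 * z_bio` (psychosocial weight dominating by design, since
self-reported pain is predominantly psychosocially determined in this class
of analysis); the specific sites are drawn uniformly. A rare pain-all-over
state (`sigmoid(eta_pain - 4)`) clears the individual site flags — the two
are mutually exclusive by construction. Acute flags are independent
Bernoulli(0.05) on non-chronic sites.

**Onsets and medications.** Onset times are exponential with hazard
`hazard_scale * exp(eta - mean(eta))` and administrative censoring at the
last follow-up offset (defaults `[4, 9]` years, matching a biobank-style
two-follow-up cadence; `hazard_scale = 0.02`/year). Medication families
(default 11) are Bernoulli flags with diagnosis-conditional rates
(0.05 / 0.25) — only the marginal association matters for the exclusion
analysis. Missingness is off by default; an MCAR rate is available.

**What passing tests do and do not show.** The generator produces Gaussian,
exchangeable features with linear effects and a single multiplicative latent
interaction. Recovery and calibration results on it validate the *estimators*
(no leakage, correct formulas, correct null behaviour); they do not establish
performance on real data with skewed assay distributions, nonlinear effects,
informative missingness or site batch structure.

## Classification

Repeated nested CV, stratified in both layers (several diagnoses are rare;
stratification keeps every fold two-class). Per repeat `r`, folds are
reshuffled with seed `base_seed + r`. Within each outer fold:

* the residualizer (per-feature OLS on the confounders, intercept included)
  is fit on the outer-training rows only and applied to both partitions;
  features are standardized by the training residual mean/SD *after*
  residualization, keeping encoding maps on a common scale. Zero-variance
  features map to zero and are flagged, never dropped, so signature
  dimensionality is stable across folds;
* the L2 strength lambda is selected by mean inner-CV AUC over
  `n_hyperparameter_draws` log-uniform samples from `penalty_range`
  (defaults: 25 draws over [1e-4, 1e4] — the method prescribes a randomized
  search without fixing the distribution, so both are configuration);
* the final model is refit on the full outer-training partition with
  balanced class weights `w_c = n/(2 n_c)`; out-of-fold decision scores,
  probabilities and AUCs are recorded.

The lbfgs solver runs at tolerance 1e-8; failure to converge is an error,
not a warning. AUC is the probability a random case outscores a random
control with ties counted one half. Metric lists are summarized by the mean
and a seeded percentile bootstrap 95% CI (default 1,000 resamples). AUC
matrices are z-scored per diagnosis across subcategories (sample SD), and
entries with z <= 0 are flagged for display suppression.

## Encoding maps and signatures

The structure coefficient of feature `j` in one fold model is the Pearson
correlation between the residualized standardized feature and the model's
linear decision score over that fold's training rows; fold maps are averaged
across folds and repeats. This is the standard encoding/activation-pattern
construction for interpreting a linear classifier in feature space; the
correlation (rather than covariance) scaling is pinned here because features
are standardized anyway and correlations share the [-1, 1] scale, which also
justifies averaging raw coefficients across disease models into the
composite signature (per-feature SD across models is retained).

Simplification keeps the `k` largest-|coefficient| features; density
thresholding keeps `ceil(density * n_features)` — ties break deterministically
toward the earlier feature, and retained sets are nested along any density
ladder. Subjects are scored by the dot product with their residualized
standardized profile. Map similarity is Pearson `r` with a two-sided
feature-index permutation p-value, `(count+1)/(n_perm+1)`; signature
discrimination is validated against a label-permutation null (default 1,000
permutations, configurable upward).

## Deviance partitioning

Predicted probabilities enter the refit on the logit scale after clipping to
`[1e-6, 1 - 1e-6]`: near-0/1 probabilities destabilize an identity-scale
refit, and the link scale makes D² invariant to logit-affine recalibration of
a source. Constant predictors contribute nothing (D² = 0 exactly); a
duplicate predictor is dropped with a warning, which forces both unique terms
of the partition toward zero. Negative shared deviance (suppression) is
reported as computed. The identity
`unique_bio + unique_psy + shared = D2_combined` holds algebraically.
A saturated refit (clipped separable predictor) is a legitimate D² → 1
outcome, not an error; only non-finite fits fail.

## Synergy

Pooled risk scores are means of natural-log predicted probabilities
(clipped at 1e-6 so one extreme model cannot dominate; the log base only
rescales scores and cannot change ranks or quintiles). Quintiles split at the
empirical 20/40/60/80 percentiles; ties at a cut go to the *lower* bin, a
deterministic convention stated openly. Odds ratios are unconditional MLEs
with Haldane–Anscombe +0.5 on zero cells and Wald 95% CIs; the 5×5 grid
compares each quintile combination against all other participants, flags
sparse cells, and returns the marginal per-source quintile ORs alongside.
Cohen's d uses the (n-1)-weighted pooled SD with a within-group percentile
bootstrap; spread associations use Spearman rho (average ranks) and R² =
rho².

## Survival

Kaplan–Meier, log-rank and Cox estimation delegate to lifelines. Event times
in the synthetic cohorts are continuous, so ties occur with probability
zero and lifelines' Efron handling coincides with any other tie convention;
the Cox grid-search oracle in the test suite uses distinct event times for
the same reason. Hazard ratios default to the each-group-versus-rest
parameterization (matching the four-risk-group framing); a reference-group
parameterization is available. Prognostic contrasts delegate to Cohen's d
and AUC on baseline scores.

## Path model

An observed-variable path analysis, not a covariance-fitting SEM: the model
has no latent variables and inference is bootstrap-based, so equation-wise
regression with a subject-level bootstrap is sufficient and exact on the
point estimates (refitting the un-resampled data reproduces them). The
binary mediator keeps a logistic link — a linear probability model would
misstate the interaction — and its coefficients are log-odds per SD of the
standardized risk scores; the interaction is the product of the centred
(standardized) scores. Outcome equations are linear with all variables
z-scored, so their coefficients are standardized. Two-sided bootstrap
p-values are `2 * (min(#{b <= 0}, #{b >= 0}) + 1) / (B + 1)`; degenerate
resamples (single-class mediator) are skipped and an error is raised if more
than half are lost. The mediator equation uses an internal Newton/IRLS
solver because the bootstrap refits it thousands of times; it is verified
against a generic GLM fit in the tests.

## Pipeline and I/O

Every artifact is plain delimited text with a header and a `subject_id` key;
floats print with 12 significant digits, which bounds write→read round-trip
error at ~5e-12 relative and makes repeated runs byte-identical. The demo
pipeline chains simulate → train (every modality × diagnosis) → encoding
maps → composite signature → deviance partition → synergy grid → survival
contrasts → path model and writes a manifest with a configuration hash
(output directory excluded), the seeds in play and the sorted file list.
AUCs are flagged "null-consistent" when the mean is within 3 SE of 1/2,
with a Hanley–McNeil-style SE floor so the flag is meaningful even when few
fold values are available.

## Problem sizes used in validation

The validation suite and acceptance script run at sizes chosen to make each
property measurable with sharp margins: signature recovery uses 13 diagnoses
sharing one planted 52-assay vector at n = 20,000 (cosine similarity of the
composite with truth, and top-10 retention across 20 seeds, under a compact
CV configuration — 3 outer folds, 2 inner folds, 1 repeat, 5 penalty draws);
synergy recovery uses 50 cohorts of n = 20,000 with a 0.5 log-odds planted
interaction; Cox recovery uses a planted hazard ratio of 2 at n = 5,000;
log-rank type-I calibration uses 1,000 equal-hazard replicates; path-model
bootstrap coverage uses 100 replicates at n = 5,000 with 200 resamples each.

## Limitations

* Encoding maps estimate the covariance-projected coefficients
  (`Sigma @ beta` up to scale), so correlated feature blocks blur the
  ranking of small planted coefficients; this is a property of the
  construction, visible in the recovery margins, not an implementation bug.
* The generator's product interaction `z_bio * z_psy` is symmetric: both-low
  subjects receive the same positive interaction term as both-high subjects,
  so the low-low stratum is *not* protective under strong interactions —
  unlike typical observational cohorts. Synergy conclusions therefore rest on
  the high-high versus mixed-group contrasts.
* Only two prediction sources are supported in the deviance partition; only
  administrative censoring and time-constant covariates in survival; no
  latent-variable SEM, fit indices or model search in the path model.
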