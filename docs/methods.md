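# Methods

This note documents the statistical model, the numerical choices, and the
synthetic-data conditions behind `sembiome`. The package reconstructs a
complete latent-variable biomarker workflow for gut-microbiome data: cohort
definition, compositional transformation, marker selection, structural
equation modeling (SEM), factor scoring, and logistic risk estimation, with
atopic dermatitis (AD) in adult women as the worked case.

## Cohort groups

Samples are partitioned per sex into four mutually exclusive analysis groups
from questionnaire metadata: normal controls (NC), AD only (AS), AD plus
other disease (AM), and other disease without AD (OD); everything else is
`excluded`. NC requires thirteen conditions (no disease, no medication,
18.5 ≤ BMI < 25, CES-D < 16, no hospitalization/surgery history, no
*Helicobacter* treatment, no insomnia consultations, regular defecation,
at most moderate alcohol use, never smoked, and — for women — a regular or
post-menopausal cycle at age ≥ 40, not menstruating at collection, not
pregnant or breastfeeding). For the patient groups, "other disease" is an
extended marker: any reported non-AD disease, BMI outside [18.5, 25),
CES-D ≥ 16, or a history of colorectal cancer/polyp surgery. Criteria are
evaluated in the order NC, AS, AM, OD and the first fully satisfied group
wins. Two resolutions the criteria text leaves open:

* the colorectal-surgery marker also disqualifies NC (otherwise a
  surgery-only sample would satisfy both NC and OD, and published group
  tables show no such controls);
* a per-sample missing value makes a criterion fail only if the decision
  cannot be short-circuited (e.g. a missing BMI is irrelevant when a disease
  flag already settles "other disease"); an undecidable criterion raises an
  error naming the criterion rather than guessing.

Free-text disease/medication answers are assumed to be reduced upstream to
boolean flags; alcohol and defecation frequency are closed category sets
mirroring the questionnaire's phrasing.

## Compositional transform

Counts are compositional, so analyses run on centered log-ratios computed on
Dirichlet Monte-Carlo instances: for each sample, 128 composition vectors
are drawn from Dirichlet(counts + 0.5) and transformed as
`clr(p)_j = log2 p_j − mean_j log2 p_j`, centering over all genera. The
uniform 0.5 prior keeps zeros finite; log base 2 follows common practice in
compositional differential-abundance tooling. A deterministic
"expected-proportion" mode substitutes the posterior mean for the draws and
is used by exact tests. Gamma draws are made in a canonical (sorted-label)
genus order so the ensemble — and everything downstream — is invariant to
the row order of the input table. The default seed is 1234. A single
sample × genus matrix for the SEM is the element-wise median over instances,
re-centered per sample.

## Effect sizes and stability selection

The two-group effect size per genus is a robust standardized difference on
the CLR ensemble: between-group differences from random cross-group sample
pairings in every instance, within-group dispersions from random
within-group pairings, and

    effect = median(between) / max(median |within A|, median |within B|).

The number of pairings per instance equals the larger group size (the
smaller group is sampled with replacement). Positive effects mean higher
abundance in the second-listed group (AS, in the pipeline's NC-vs-AS
comparison). Pairing randomness is drawn from per-group streams keyed by
group membership, so exchanging the listed order of the two groups negates
every effect exactly.

Because the Monte-Carlo layer injects randomness, the calculation is
repeated (500 times by default) with fresh seeds — both the Dirichlet
instances and the pairings are re-randomized — and only genera appearing in
the top-20 by |effect| of *every* repetition are kept as stable markers,
reported with their mean effect across repetitions. Note what this does and
does not randomize: the cohort itself is fixed, so the repetition filter
removes genera whose ranking is sensitive to the Monte-Carlo layer, not
genera whose effect is driven by sampling noise of the cohort. On a
no-signal cohort the procedure therefore still returns a non-empty stable
set (the top of the noise ranking is stable across repetitions); emptiness
under the null would require re-drawing the cohort per repetition, which is
not what the procedure does.

## Structural equation model

Two latent variables explain the marker genera: positive-effect genera load
on lv1 (hypothesized to raise AD risk), negative-effect genera on lv2
(hypothesized to lower it); the binary AD indicator is regressed on both
latents, whose correlation is free. The binary outcome is handled by a
latent-response formulation: an underlying standard-normal response crosses
a threshold (probit link). With standardized latents and observed variables
the free parameters are the loadings `a_ij`, paths `b1, b2` and the latent
correlation `c`; residual variances follow from `v_ij = 1 − a_ij²` and
`ψ_y = 1 − (b1² + b2² + 2·b1·b2·c)`, so the standardized identities hold by
construction.

Estimation is diagonally weighted least squares (DWLS) on a correlation
structure: Pearson correlations among indicators, two-step maximum-likelihood
polyserial correlations between each indicator and the binary outcome
(threshold from the sample prevalence), each weighted by its inverse
asymptotic variance — `(1 − r²)²/N` for Pearson, the observed-information
variance of the profile likelihood for polyserial. The weighted residual
problem is solved by bounded trust-region least squares (loadings in
±1.8 so inadmissible Heywood solutions are representable and detectable,
`|c| < 0.99`). Standard errors use the diagonal-weight approximation
`(ΔᵀWΔ)⁻¹`; the off-diagonal sampling covariance between correlations is
ignored, which is the usual simplification when only the diagonal weight
matrix is estimated. Derived parameters (`v_ij`, `ψ_y`) get delta-method
standard errors.

Fit indices: `χ² = (N−1)·F` with `F` the weighted sum of squared
off-diagonal correlation residuals; `RMSEA = sqrt(max(χ²−df, 0)/(df·(N−1)))`;
`GFI = 1 − F/F₀` with `F₀` the weighted total for the sample correlations;
`AGFI = 1 − (q(q+1)/2df)(1−GFI)` (undefined at df = 0). No mean/variance
correction is applied to the chi-square; index values are therefore
comparable across this package's fits but may differ by convention from
other software on the same data.

Model modification is backward elimination in two phases, then selection:
(1) while any variance component is negative (Heywood case), delete the
indicator with the most negative residual variance and refit; (2) while any
loading has p ≥ α (default 0.05), delete the worst offender and refit;
(3) among all admissible fitted models visited — converged, no Heywood case,
all loadings *and both structural paths* significant, at least two
indicators per latent, RMSEA < 0.08 — return the one maximizing the summed
absolute structural paths. The latent correlation is exempt from the
significance requirement (it is a freely estimated nuisance correlation).
If no admissible model exists the procedure raises "model could not be
constructed", the documented terminal outcome for cohorts without usable
latent structure. Deletions are one-at-a-time and logged.

## Factor scores

The accepted model's measurement part (loadings, residual variances, latent
covariance) is frozen and applied to any sample via Bartlett scores,
`f̂ = (ΛᵀΘ⁻¹Λ)⁻¹ΛᵀΘ⁻¹x`, computed in closed form; refitting the measurement
model with all parameters fixed is mathematically equivalent for scoring.
Indicators are standardized with moments frozen from the NC+AS fitting
population, so held-out samples (AM, OD, new data) are scored on the same
scale without consulting disease status. Bartlett scores are conditionally
unbiased for the true factor values and independent of the latent
covariance (the loading matrix is block-diagonal). Scores are compared
between groups with the two-sided Wilcoxon–Mann–Whitney test: exact by
enumeration (tie-safe) when n₁+n₂ ≤ 10, otherwise the normal approximation
with continuity and tie corrections.

## Risk model

The scored cohort (all four groups) is split 80/20, stratified by group,
with round-half-even per-stratum training counts. The training fold is
balanced by SMOTE: each synthetic minority point interpolates between a
minority point and one of its k = 5 nearest minority neighbors with a
Uniform(0,1) weight; 200% over-sampling (two synthetic points per minority
point) and 200% under-sampling (majority subsampled to twice the synthetic
count) follow the defaults of the classical formulation. Balancing happens
strictly after the split and never touches verification rows. An
unpenalized maximum-likelihood logistic regression on the latent scores is
evaluated on the verification fold by ROC AUC (ties count one half) with a
DeLong 95% confidence interval.

## Synthetic cohorts

The generator inverts the analysis model. Per sample: latent factors
`(F1, F2)` are bivariate standard normal with correlation `c`; marker genus
log2 signals are `a_ij·F_i + e_ij` with unit total variance; background
genera are independent normals around genus-specific baseline offsets drawn
from `N(0, 3²)` (log2 units), giving the several-orders-of-magnitude
abundance spectrum of real genus tables; the log2 vector maps to a
composition by base-2 softmax and to counts by a multinomial draw at depth
20,000 reads (Dirichlet-multinomial if overdispersion > 0). The AD label is
a probit threshold on `b1·F1 + b2·F2 + ε` with the threshold set from a
target prevalence. Defaults: 150 background genera (genus-level richness of
adult cohorts is typically 100–300; with far fewer genera the CLR closure
term visibly biases correlations by ~1/G), depth 20,000 (typical amplicon
scale), no overdispersion.

The preset female scenario echoes the published standardized solution —
loadings (0.54, 0.53, 0.44) and (0.58, 0.42, 0.20), c = 0.07, paths
(0.32, −0.41) — and the published group sizes (321, 45, 75, 1669). Its
threshold reproduces the AD rate of the NC+AS population (45/366): the
printed solution is the estimand of the SEM *fitted to NC+AS*, so that is
the population the generative model must describe; a whole-cohort threshold
would make the fitting subset case-enriched and shift the estimand away
from the configured parameters. Cohorts with exact group sizes are
assembled retrospectively: prospective draws from the threshold model fill
the AS/AM quotas with label-positive samples and the NC/OD quotas with
label-negative ones, and questionnaire metadata is written so that group
assignment recovers the requested sizes exactly. Within groups the
factor–count relationship is untouched by this conditioning.

What the generator does *not* emulate: genus–genus ecological correlation
beyond the two factors, compositional interactions among markers,
overdispersed or zero-inflated counts (unless enabled), covariate effects
(age, BMI) on the microbiome, and the real-data phenomenon that lv1 tracks
other-disease variation. Passing tests therefore demonstrate correctness of
the estimators under the model's own assumptions, not robustness to real
microbiome data.

## Replication experiments and problem sizes

`sembiome.experiments` packages four studies, all driven by one root seed:

* **Identities** — the published standardized solution satisfies
  `a² + v = 1` per indicator (max deviation 0.0064 at printed precision)
  and implies an outcome residual of 0.748 (~25% explained variance).
* **Recovery** — 20 cohorts at full study scale (N = 366 for the fit); the
  across-seed mean of the fitted solution recovers the generating
  parameters (bias MAE ≈ 0.03). Individual estimates scatter with the
  sampling error expected at N = 366 (per-estimate MAE ≈ 0.10, in line
  with the printed standard errors of ~0.10), and a small systematic
  loading attenuation (~0.04) remains from counting noise and CLR closure.
* **Null** — a zero-signal cohort: the risk model sits at chance
  (AUC ≈ 0.5); the stable marker set is *not* empty, for the structural
  reason given above.
* **Ordering** — 20 half-scale cohorts, both single-score models judged on
  the same stratified verification fold: the lv2-only model's verification
  AUC exceeds the lv1-only model's on average (≈0.60 vs ≈0.58). The
  asymptotic margin implied by paths of 0.32/−0.41 and the measurement
  reliabilities is only ~0.03 AUC, which is comparable to AUC sampling
  error at ~210 verification samples, so individual replicates flip sign
  roughly half the time; a sharper per-replicate ordering would require
  real-data features (lv1 tracking other-disease variation) that the
  generative model does not encode. At this scale the significance-pruning
  phase of model modification is skipped (a loading of 0.20 cannot reach
  p < 0.05 at N = 183) and only Heywood clearing is applied; replicates
  where even the cleared model is inadmissible count against the ordering.

Problem sizes were chosen to keep each experiment in the seconds-to-minutes
range: 20 seeds for the simulation studies, 50 repetitions for the null
selection, 128 Monte-Carlo instances throughout.

## Known limitations

* DWLS standard errors use the diagonal-weight approximation; they are
  adequate for ranking parameters during backward elimination but mildly
  understate uncertainty relative to a full sandwich estimator.
* The chi-square (hence GFI/AGFI/RMSEA) is uncorrected; absolute index
  values are convention-dependent.
* Polyserial correlations use two-step rather than joint ML.
* With three indicators per latent and a weak loading, Heywood cases occur
  in a few percent of cohorts at N ≈ 366 — a property of the model class,
  handled by the modification procedure rather than hidden.
* SMOTE subsamples the majority without replacement when possible (with
  replacement only when the requested count exceeds the majority size).
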