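# Methods

`telodyn` implements the inference chain used in multi-year field studies of
relative telomere length (rTL) in wild ectotherms: qPCR quantification, gamma
mixed modelling with multimodel averaging, hierarchical partitioning of
goodness of fit, and permutation-tested cross-correlation with extreme-weather
indices. This note records the models, the numerical choices, and what the
synthetic-data generator does and does not emulate.

## 1. qPCR quantification

**Cq calling.** Each well's fluorescence trace is baseline-corrected by
subtracting the median of its first five cycles (robust, deterministic; real
instruments vary in their baseline handling, and a fixed rule keeps results
reproducible). The quantification cycle is the fractional cycle of the first
upward crossing of a constant per-target threshold, located by linear
interpolation between the bracketing cycles. Default thresholds are 0.171
(telomere plates) and 0.144 (single-copy-gene, SCG, plates), held constant
across plates; both are configurable.

**Efficiency.** Per-well amplification efficiency comes from a
window-of-linearity fit: log10 fluorescence is regressed on cycle over every
contiguous window of 4–6 strictly increasing readings lying between 5% and
80% of the plateau signal; the window with the highest R² wins, and
efficiency = 10^slope, clipped to (1, 2.2]. The plate-level efficiency used in
the ratio is the mean over wells (per-well efficiencies in the exponent would
amplify well-level noise). Wells with no valid window are flagged and
excluded from the mean.

**Replicates.** Samples run in triplicate; replicates whose Cq deviates from
the replicate median by more than 1.0 cycle are excluded (a standard qPCR QC
rule), and the mean of survivors is used. The per-plate calibrator Cq is the
mean over calibrator ("gold standard") wells after the same rule. Samples
with no surviving replicate for either target are dropped.

**Ratio.** Relative telomere length is the efficiency-corrected ratio

    rTL = E_tel^dCq_tel / E_scg^dCq_scg,  dCq = Cq(calibrator) − Cq(sample),

so a sample whose telomere target amplifies one cycle before the calibrator
at efficiency 2 has twice the calibrator's relative telomere content. The
orientation (calibrator minus sample) makes rTL increase with telomere
abundance.

**Standardisation.** Raw ratios are z-scored across the data set (sample SD,
n−1), and the modelling response is the positively shifted z-score, z + 1.
A +1 shift cannot make values with z ≤ −1 positive; in that case the shift
|min z| + 0.001 is applied instead and a warning is logged. A gamma response
must be strictly positive, so the fallback is unavoidable whenever any
observation lies more than one SD below the mean — with realistic spread this
is the common case, and the choice of shift only translates the response.

## 2. Environmental features

Monthly microclimate values are aggregated to annual mean/max/min per
locality; the PCA uses the annual means of the four climatic variables
(radiant sky temperature, wind speed, relative humidity, solar radiation)
plus elevation, all centred and scaled (correlation-matrix PCA via SVD).
Which annual statistic feeds the PCA is configurable; means are the default
because max/min columns of the same variable are strongly collinear with the
mean and add little beyond seasonal amplitude.

Component signs are arbitrary; we fix each loading column so its
largest-magnitude entry is positive. Orientation has no effect on model fit,
only on the sign of reported loadings and scores. Components are retained as
model predictors up to a cumulative explained-variance threshold (default
0.85, which with the generator's covariance structure selects the first two).
Scores are computed on the locality-year table and joined to samples by
(locality, year).

## 3. Gamma models

The response y (shifted rTL z-score) is modelled as Gamma with mean
μ = exp(Xβ) and shape α (Var = μ²/α), i.e. a log-link gamma GLM.
Categorical predictors use treatment contrasts with reference levels female
(sex), blood (tissue) and eisentrauti (morphotype), so reported contrasts are
the male, unknown, tail and galloti rows. Continuous predictors (SVL, the
environmental PCs) are centred and scaled inside the design builder (can be
disabled), making coefficients per-SD effects. Rows with missing required
fields are dropped and counted.

**GLM.** Coefficients by IRLS (statsmodels); these do not depend on α under
the log link. The shape is then estimated by maximum likelihood from the
digamma score equation log α + 1 − ψ(α) + mean(log(y/μ) − y/μ) = 0 (solved by
bracketed root finding on log α), and the reported log-likelihood is the full
gamma likelihood at the joint optimum. The Wald covariance is the inverse
Fisher information (XᵀX)⁻¹/α; p-values use the normal reference.

**GLMM.** A year-level random intercept u_g ~ N(0, σ²) enters the linear
predictor. The marginal likelihood integrates u_g out per group by adaptive
Gauss–Hermite quadrature: the integrand's mode is found by Newton's method
(the conditional log-density is strictly concave in u), nodes are centred at
the mode and scaled by the curvature, and 15 nodes are used by default
(1 node = the Laplace approximation; configurable). (β, log α, log σ) are
optimised jointly by L-BFGS-B from GLM starting values, with a
derivative-free polish if the line search stalls on a flat likelihood.
σ̂ collapsing to the lower bound is a valid boundary fit (flagged); in that
limit the marginal likelihood equals the GLM likelihood exactly. The fixed-
effect covariance is the β block of the inverse numerical Hessian of the
negative marginal log-likelihood. The parameter count for AICc is fixed
coefficients + shape (+ the variance parameter for the GLMM), the standard
mixed-model accounting.

Note a subtlety of the σ = 0 boundary: when data are generated with no year
effect, the *fitted* GLMM log-likelihood exceeds the GLM's by a
half-χ²(1)/2-distributed amount that does not vanish with n, so equality of
fitted log-likelihoods holds only for draws where σ̂ hits the boundary. The
exact statement — verified in the tests — is that the marginal likelihood
evaluated at σ → 0 equals the GLM likelihood.

**Fit statistics.** AICc = −2ℓ + 2k + 2k(k+1)/(n−k−1); Nagelkerke's
R² = (1 − exp(2(ℓ₀−ℓ₁)/n)) / (1 − exp(2ℓ₀/n)); gamma deviance
D = 2Σ[−log(y/μ) + (y−μ)/μ], with deviance explained 1 − D_model/D_null.

## 4. Model selection and averaging

All subsets of the global fixed-effect terms respecting marginality (the
sex:svl interaction only with both parents) are fitted — 80 models for the
full term set (2⁶ main-effect subsets + 2⁴ with the interaction) — ranked by
AICc, and weighted w_i ∝ exp(−Δ_i/2). Averaging is over the full enumerated
set by default (Δ ≤ x and cumulative-weight subsets are options, since
reported inference sometimes restricts to the Δ < 2 set); weights are
renormalised within any subset.

Two averages are reported per term: the *full* average (β = 0 in models
omitting the term — shrinks weakly supported effects toward zero) and the
*conditional* average (only models containing the term). The unconditional
SE is the revised estimator se = Σ w_i √(var_i + (β_i − β̄)²); the exact
small-sample variant used by any particular software stack is rarely
documented, so both full- and conditional-referenced versions are exposed and
labelled. Term importance is the summed weight of models containing the term.

**Marginal means and trends.** EMMs for a factor are link-scale predictions
at each level, averaged with equal weights over the other factors' levels,
continuous covariates at their means; SEs by the delta method; CIs
estimate ± 1.96·SE, back-transformed by exp. Pairwise contrasts are Tukey-
adjusted through the studentized-range distribution with infinite error df —
GLMM residual df are ill-defined, and the normal-theory version matches the
large-sample behaviour of the usual tooling; for k = 2 it reduces exactly to
the unadjusted normal p. Marginal trends are link-scale slopes per factor
level (adding the interaction coefficient where present).

## 5. Hierarchical partitioning

The goodness-of-fit gain of the full model over the null is decomposed per
predictor into an independent contribution I (the Shapley value of the gof
game over the 2^k subset lattice, computed by the level-averaging form) and a
joint contribution J_i = gof({i}) − gof(∅) − I_i. The default gof is the
gamma-GLM log-likelihood (an R² option exists for linear cross-checks);
factor contrast columns enter as one block. Year is not partitioned — it is
the grouping/nuisance term — and the partition covers the five substantive
predictors (tissue, SVL, sex, PC1, PC2). GLM rather than GLMM subset fits
keep the 2^k lattice affordable; the year intercept mainly absorbs temporal
noise and barely moves the relative shares.

Significance is assessed by randomisation: each predictor block's rows are
permuted independently, the partition recomputed (default 999 permutations),
and Z = (I_obs − mean I*)/SD(I*) compared against 1.65 (upper one-sided
0.95), the established convention for this method.

## 6. Climate extremes and cross-correlation

A month is a *heatwave month* if its maximum OR mean temperature lies at or
above the 90th percentile of that calendar month's distribution across years
(per station), and a *drought month* if its total precipitation lies at or
below the 10th percentile. Stratifying by calendar month deseasonalises the
thresholds (a pooled-months mode exists); the OR rule is the more sensitive
reading of a max-or-mean definition (AND available). Ties at a constant
stratum never flag: an extreme must differ from the opposite end of the
stratum's range, so a constant series produces no events. Quantiles use
linear interpolation.

Annual flagged-month counts (averaged across stations) and the annual mean
rTL z-score are min-max normalised and cross-correlated at lags up to ±6
years, r(k) with overall means and denominator-n SDs (so r(0) is exactly
Pearson's r), with the white-noise band ±1.96/√n. Significance of the
zero-lag correlation — the same-year association is the hypothesis of
interest — comes from permuting the year assignment of the biological series
(5000 permutations by default), two-sided p = (1 + #{|r*| ≥ |r_obs|})/(B+1),
which is exactly valid under exchangeability.

## 7. The synthetic-data generator

The generator draws a full study: a cohort (default n = 236 individuals over
10 years and 19 localities spanning a 25–2450 m elevation gradient), qPCR
plates, an annual microclimate table and a monthly station weather series.

* **Response.** rTL (on the shifted-z scale) is Gamma(α = 10) with mean
  exp(Xβ + u_year), u_year ~ N(0, 0.1²). Default slope coefficients are the
  study-scale magnitudes on the log-link scale: sex male −0.131, sex unknown
  −0.163, SVL −0.046 per SD, tissue tail +0.140, PC1 +0.007, morphotype
  galloti −0.009; the intercept is 0 so the response mean sits near 1, the
  scale of a positively shifted z-score. Drought years (2016–2019 by
  default) subtract 0.4 on the link scale — a decrement producing the
  clearly significant negative zero-lag drought correlation the method is
  designed to detect.
* **qPCR plates.** The telomere-target Cq encodes the latent raw rTL against
  the per-plate calibrator anchor, Cq_tel = anchor − log(rTL)/log(E_tel),
  with the SCG Cq held at calibrator level, so the efficiency-corrected
  ratio inverts the generator exactly at zero replicate noise (replicate Cq
  noise SD defaults to 0.05 cycles). Synthetic amplification curves are
  exactly exponential through the measured phase — threshold·E^(c−Cq) — with
  a C1-continuous exponential rollover to the plateau above 80% of plateau,
  so the threshold crossing and the per-cycle ratio are exactly invertible;
  a pure logistic cannot have both properties at once.
* **Microclimate.** Variables share a linear elevation lapse (sky
  temperature −6.5 °C/km, humidity +12 %/km, wind +1.5 m s⁻¹/km) with
  independent noise; solar radiation is elevation-independent. This induces
  the dominant elevation–humidity–temperature correlation axis through
  shared dependence rather than an explicit covariance matrix, mirroring how
  an elevational gradient structures real microclimate.
* **Weather.** Monthly temperature follows a seasonal cycle (peak August);
  precipitation is gamma-distributed around a wet-winter climatology.
  Drought years scale the precipitation climatology by 0.25; heat years
  shift temperatures up 2.5 °C. The station record extends 18 years before
  the first study year: decile thresholds need a climatological baseline
  longer than the sampling window (with 4 drought years inside a 10-year
  record, the bottom-decile threshold falls inside the drought cluster and
  the counts lose contrast).
* **Sex/size.** Sexes are drawn 45/50/5% female/male/unknown (the unknown
  fraction mirrors field studies where some individuals cannot be sexed);
  SVL is normal per sex with males larger (118 ± 14 mm vs 105 ± 12 mm),
  reflecting the species' male-biased size dimorphism. Neither the sex ratio
  nor the SVL distribution of any particular data set is asserted; both are
  configurable.
* **Determinism.** All randomness flows through one seeded generator per
  call (independent child streams for cohort, microclimate, plates,
  weather); identical (config, seed) reproduces identical output, and the
  pipeline's output files are byte-identical across runs.

**What the generator does not emulate:** spatially explicit terrain,
within-year sampling dates, tail autotomy/regeneration, plate batch effects
beyond the calibrator anchor, age structure (SVL is the only size/age
proxy), and real station data gaps. Passing tests therefore demonstrate the
*statistical machinery* — unbiased recovery, calibrated tests, exact
inversions — under the assumed generative structure, not robustness to every
artefact of field data.

## 8. Problem sizes and tolerances

Tests and the acceptance script run at the study's own scale: n = 236
individuals, 10 years, 19 localities; parameter-recovery uses 200 replicate
draws; permutation calibration uses 500 null repetitions at 199 permutations;
drought-detection power uses 20 replicate studies at 999 permutations; the
headline drought/heatwave tests use 5000 permutations. The dredge fits all 80
mixed models; hierarchical partitioning fits the full 2⁵ lattice. Optimiser
tolerances: IRLS 1e-10; GLMM L-BFGS-B ftol 1e-12 with 15-node quadrature;
quadrature agreement with dense numeric integration is at the 1e-12 level on
toy problems. Fits are deterministic; only the generator and the permutation
procedures consume seeds.

## 9. Known limitations

* The GLMM supports a single grouping factor (year or locality), no crossed
  or multiple random effects, and ML only (no REML).
* Full-average coefficients shrink toward zero by construction when a term's
  importance is below 1; single-draw averaged estimates are therefore not
  unbiased estimates of the generative coefficients (the conditional average
  is closer; the recovery analyses use the global-model fit).
* Hierarchical partitioning is exact and exponential in the number of
  predictor blocks (capped at 12).
* The window-of-linearity efficiency estimator assumes a clean exponential
  phase; heavily baseline-drifted or low-plateau curves are flagged rather
  than rescued.
* Decile-based event counts are sensitive to the length of the station
  record; with short records the thresholds are noisy and the counts
  undersample true extremes.
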