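# telodyn

Relative telomere length (rTL) quantification and inference for multi-year
field studies of wild ectotherms.

Telomere length is widely used as an integrative marker of physiological
condition, but in lizards and other ectotherms it responds to a tangle of
intrinsic drivers (sex, body size, tissue sampled) and extrinsic ones
(elevation-driven microclimate, drought and heatwave years). `telodyn`
implements the full analysis chain needed to separate those drivers in a
spatio-temporal cohort, together with a seeded synthetic-study generator so
every stage can be verified end to end against a known truth.

The chain:

1. **qPCR → rTL.** Cq calling at constant fluorescence thresholds with
   window-of-linearity efficiency estimation, triplicate QC, and the
   efficiency-corrected ratio against a per-plate calibrator,
   `rTL = E_tel^ΔCq_tel / E_scg^ΔCq_scg` with `ΔCq = Cq_cal − Cq_sample`;
   ratios are z-scored and positively shifted for gamma modelling.
2. **Microclimate → principal components.** Annual aggregation per locality
   and correlation-matrix PCA; the leading components (default: cumulative
   variance ≥ 85%) join the sample table as environmental predictors.
3. **Gamma mixed models.** Log-link gamma GLM (IRLS + ML shape) and a
   year-random-intercept gamma GLMM fitted by marginal maximum likelihood
   with adaptive Gauss–Hermite quadrature (15 nodes; 1 node = Laplace).
4. **Dredge → model averaging.** All marginality-respecting subsets of the
   global model (80 models for the full term set), AICc ranking, Akaike
   weights, full and conditional model-averaged coefficients with revised
   unconditional SEs, estimated marginal means with Tukey contrasts, and
   marginal trends.
5. **Hierarchical partitioning.** Shapley decomposition of the
   goodness-of-fit gain into independent/joint contributions per predictor,
   with a block-permutation randomisation test.
6. **Climate extremes.** Decile-threshold heatwave/drought month counts per
   station climatology, annual series, lagged cross-correlation with annual
   mean rTL, and an exact permutation test of the zero-lag correlation.

See `docs/methods.md` for the models, assumptions and numerical choices.

## Worked example

Generate a study at the default configuration (236 lizards, 10 years, 19
localities on an elevation gradient, drought years 2016–2019), quantify the
plates, dredge the mixed model, and test the drought association:

```python
from telodyn.synthetic import StudyConfig, generate_study
from telodyn.qpcr import quantify_plates, standardise
from telodyn.gamma_models import ModelSpec
from telodyn.selection import dredge, average_coefficients
from telodyn.climate import climate_rtl_analysis

study = generate_study(StudyConfig(seed=1))
rtl = quantify_plates(study.plates, efficiencies={"telomere": 1.9, "scg": 1.85})
print(rtl[["sample_id", "rtl_raw", "rtl_z", "rtl_shifted"]].head(3))

spec = ModelSpec(
    response="rtl_true",
    fixed_terms=("env_pc1", "env_pc2", "sex", "svl", "tissue", "morphotype", "sex:svl"),
    random_intercept="year",
)
ms = dredge(study.samples, spec)
print(ms.table().head(3))
avg = average_coefficients(ms)
print(avg.table()[avg.table().term.isin(["sex_male", "svl", "tissue_tail"])])

z, _ = standardise(study.samples["rtl_true"].to_numpy())
res = climate_rtl_analysis(study.weather, study.samples.assign(rtl_z=z),
                           n_perm=5000, seed=1)
ccf = res["drought_ccf"]
print(f"drought r(0) = {ccf.r[6]:.3f}, permutation p = {ccf.perm_p:.4f}")
```

Output (abridged):

```
sample_id  rtl_raw  rtl_z  rtl_shifted
    S0000    0.262 -1.012        0.610
    S0001    0.607  0.799        2.421
    S0002    0.669  1.120        2.742

                                  model  k  loglik   aicc  delta  weight
 env_pc2 + sex + svl + tissue + sex:svl 10 -36.963 94.904  0.000   0.327
           env_pc2 + sex + svl + tissue  8 -39.940 96.515  1.611   0.146
...
       term  estimate  conditional_estimate  adjusted_se      z     p  importance
   sex_male    -0.103                -0.116        0.056 -1.826 0.068       0.887
        svl    -0.056                -0.057        0.038 -1.493 0.135       0.990
tissue_tail     0.139                 0.142        0.046  3.010 0.003       0.981

drought r(0) = -0.914, permutation p = 0.0014
```

The averaged coefficients recover the generative truth (sex male −0.131,
SVL −0.046 per SD, tissue tail +0.140 on the log-link scale) to within
sampling error; sex and tissue carry most of the support, the environmental
components little. The drought-year decrement in the generator shows up as a
strongly negative zero-lag correlation between annual drought-month counts
and annual mean rTL z-score, significant under the 5000-permutation test —
the same-year "dry years, short telomeres" signature the pipeline is built
to detect.

A command-line interface wraps the same stages
(`telodyn simulate | qpcr | envpca | fit | average | partition | climate |
run-all`), driven by a YAML config with `--seed` and `--outdir` overrides;
`run-all` writes every stage's tables plus a manifest that makes runs
reproducible byte for byte.

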