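# thermoflex

Analysis pipeline for studying **thermogenic flexibility** — the capacity of
small endotherms to reversibly adjust their summit metabolism (M_sum, the
maximum cold-induced oxygen consumption) — and its relationship to the
thermal heterogeneity of the environments populations occupy.

The package re-implements, as tested reusable components, the full analysis
chain such a study needs:

1. **Respirometry** (`thermoflex.respirometry`) — open-flow heliox trace
   processing: linear baseline-drift correction between bracketing
   animal-absent segments, per-sample oxygen consumption
   `VO2 = flow * (FiO2(t) - FeO2) / (1 - FiO2)` for a dry, CO2-scrubbed
   excurrent stream, and M_sum as the highest 5-minute sliding-window mean,
   with drift/flow QC.
2. **Acclimatization windows** (`thermoflex.envwindows`) — per-individual
   means of daily weather variables (including the daily temperature range
   `T_d_range = Tmax - Tmin`) over 7–14-day windows strictly preceding
   capture, and the 2-SD standardization used for all continuous predictors.
3. **Field reaction norms** (`thermoflex.field_models`) — the model family
   `M_sum = M_b + taxon x env`, ranked by AIC across environmental variables
   and window lengths against a null model; raw-scale taxon-specific slopes
   (ml O2 min^-1 °C^-1) back-transformed from the standardized fit; and the
   regression of those slopes on each taxon's mean annual temperature range.
4. **Genotype–environment association** (`thermoflex.popgen`) — the SNP
   filter cascade (mean depth, minor-allele count, missingness, per-species
   Hardy–Weinberg exact test), modal imputation, PCA, partial redundancy
   analysis conditioned on ancestry axes with ANOVA-like permutation tests,
   per-variable variance partitioning on the adjusted-R² scale, VIF and
   correlation pruning, and pairwise weighted Weir–Cockerham θ (F_ST).
5. **Distance tests** (`thermoflex.distances`) — linearized genetic distance
   F_ST/(1 − F_ST), haversine geographic distance, Euclidean environmental
   distance, and the partial Mantel permutation test.
6. **Acclimation experiment** (`thermoflex.acclimation`) — a Gibbs-sampled
   Bayesian linear mixed model for ΔM_sum (post- minus pre-acclimation) with
   fixed effects `mass + treatment * T_range` and a population random effect
   whose covariance derives from pairwise F_ST (similarity 1 − θ, PSD
   projected); posterior means, 95% credible intervals, pMCMC; the
   coefficient-of-variation analysis of flexibility; and the control-group
   paired t-test.
7. **Synthetic data** (`thermoflex.synthetic`) — generators for every input
   with known planted ground truth (trace peaks, weather cycles,
   Balding–Nichols island-model genotypes with an optional environmental
   cline, taxon reaction norms, treatment × T_range interactions), so the
   whole pipeline is testable end to end without any external data.

## Worked example

```python
import numpy as np
from thermoflex import SimConfig
from thermoflex.synthetic import gen_field_dataset
from thermoflex.envwindows import build_env_features
from thermoflex.field_models import select_model, reaction_norm_slopes

cfg = SimConfig(seed=2)
pheno, weather, bioclim, truth = gen_field_dataset(cfg)
feats = build_env_features(pheno, weather, bioclim)
table, best, diag = select_model(pheno, feats)
print(table.head(3)[["variable", "window", "aic", "r2"]])
norms = reaction_norm_slopes(best, feats.merge(pheno[["id", "taxon"]], on="id"))
print(norms.slopes.round(3))
```

prints

```
    variable  window         aic        r2
0  t_d_range     8.0  705.563488  0.940513
1  t_d_range     9.0  733.378449  0.937110
2  t_d_range     7.0  741.272797  0.936109

caniceps     0.158
hyemalis     0.318
mearnsi     -0.001
oreganus     0.172
palliatus    0.117
```

The AIC ranking identifies the daily temperature range averaged over the
8 days before capture — the window the generator planted — as the best
predictor of field M_sum, and the back-transformed per-taxon slopes recover
the planted reaction norms (0.15, 0.30, 0.03, 0.20, 0.10 ml O2 min^-1 °C^-1)
within their standard errors.

A full end-to-end run, from synthetic inputs to mixed-model posteriors, is
one command:

```sh
thermoflex all --seed 1 --out run_dir
```

Other subcommands (`simulate`, `msum`, `field-select`, `gea`, `mantel`,
`acclim`) run single stages on files you supply; see `thermoflex --help`.

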