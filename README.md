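# phenostate

Alternative stable states in forest leaf phenology — a tested pipeline for
asking whether evergreen and deciduous forests are self-maintaining states
rather than a smooth environmental continuum.

Temperate forest inventories show a strikingly bimodal distribution of the
plot-level **relative evergreen abundance**

```
relEV_area    = BA_EV / (BA_EV + BA_DE)        (basal-area share)
relEV_density =  n_EV / (n_EV  + n_DE)         (stem-count share)
```

Most plots are nearly pure evergreen or nearly pure deciduous. Bimodality
alone is weak evidence for alternative stable states — environmental
filtering can produce it too — so the package implements the four
complementary lines of evidence used to test the hypothesis on
remeasured inventory data, exercised end-to-end on synthetic inventories:

1. **Environmental null model** (`phenostate.nullmodel`): zero-adjusted
   Poisson (hurdle) abundance models per leaf type over spline functions of
   ten environmental principal components; 1000 simulated composition
   ensembles give pointwise 2.5–97.5 % envelopes for the relEV histogram
   (bin width 0.05) and a null distribution for the Spearman correlation of
   evergreen vs deciduous abundance. Observed outer-bin excess and
   excess negative coupling indicate that environment alone is not enough.
2. **Con-phenological demographic feedbacks** (`phenostate.demography`):
   per-phenology GAMs (penalized B-splines, basis dimension 5) for tree
   survival (binomial), diameter growth (Gaussian) and plot-level
   recruitment (Poisson), each with the feedback predictor relEV alongside
   tree size, stand structure and the environmental PCs. Headline
   contrasts are predicted at relEV ∈ {0, 1} (survival, growth, relative %
   difference con vs hetero) and relEV ∈ {0.1, 0.9} (recruitment-rate
   ratio), holding all other predictors at training means, with 95 %
   intervals from 100 coefficient draws.
3. **Succession simulation** (`phenostate.simulate`): a stochastic
   individual-based simulator (5-yr steps, stand-replacing disturbance at
   0.0036 yr⁻¹, Poisson recruitment entering at 12.7 cm) driven by the
   fitted or true vital-rate functions, with and without the feedback
   term; the feedback variant generates and maintains a bimodal final
   relEV distribution, the null variant collapses to a unimodal one.
4. **Hysteresis** (`phenostate.simulate.hysteresis_experiment`): along a
   mean-annual-temperature gradient (−2 to 23 °C, 12 sections), plots
   initialized 80 % evergreen vs 80 % deciduous end in different states
   under the feedback model (initialization dependence = hysteresis) and
   in the same state under the null model.

Where the states sit on a map is quantified by the **bimodality index**
(`phenostate.dip`, `phenostate.clustering`): Hartigan's dip statistic `D`
of a cluster's relEV values, scaled to `D' = √n·D`, combined with the
sample skewness `S` as

```
BI = −exp(−a·D'^b) · sign(S),    a = 6, b = 2
```

so that `BI ≈ ±1` labels unimodal evergreen-/deciduous-dominated clusters
and `|BI| ≤ 0.22` (the image of the dip threshold `D' = 0.5`) labels
bistable ones. Clusters come from a 10-arc-minute lon/lat "fishing net"
or K-means on the leading three environmental PCs; a bootstrap
permutation-importance analysis ranks seven key climate/soil determinants.

The dip statistic is implemented from first principles (greatest convex
minorant / least concave majorant modal-interval iteration) and is
cross-checked in the test-suite against an independent linear-programming
oracle; p-values are Monte-Carlo against the uniform null, n-exact.

Because the real inventories (FIA, GFBi, FunDivEUROPE) are not
redistributable, `phenostate.generator` builds synthetic two-census
inventories with exactly controllable feedback effect sizes (calibrated in
closed form), environmental gradients and zero-inflated abundance — every
stage is testable offline, and planted-effect recovery is the acceptance
standard.

## Worked example

```python
import numpy as np
from phenostate import GeneratorParams, generate_environment, \
    generate_two_census_inventory
from phenostate.demography import (VitalRateModelSet,
                                   predict_survival_growth_contrast,
                                   predict_recruitment_ratio)
from phenostate.inventory import Phenology
from phenostate.simulate import SimConfig, TrueRateAdapter, run_simulation
from phenostate.dip import bimodality_result

params = GeneratorParams(n_plots=3000, seed=1)   # 14/17 % survival, 43/4 %
plots = generate_two_census_inventory(            # growth, 5x recruitment
    generate_environment(params), params)         # advantages planted
models = VitalRateModelSet.fit(plots)

rng = np.random.default_rng(1)
for c in predict_survival_growth_contrast(
        models.survival[Phenology.EV], models.survival[Phenology.DE], rng=rng):
    print(f"survival  relEV={c.relev_point:.0f}: {c.con_phenology.value} "
          f"advantage {c.contrast:+5.1f}%  [{c.ci_low:.1f}, {c.ci_high:.1f}]")
for c in predict_recruitment_ratio(
        models.recruitment[Phenology.EV], models.recruitment[Phenology.DE],
        rng=rng):
    print(f"recruits  relEV={c.relev_point}: con:hetero ratio "
          f"{c.contrast:.2f}x [{c.ci_low:.2f}, {c.ci_high:.2f}]")

cfg = SimConfig(n_plots=200, horizon_years=500, seed=1, variant="feedback")
res = run_simulation(cfg, TrueRateAdapter(params))
r = bimodality_result(res.final_relev, compute_pvalue=True, n_null=500,
                      rng=np.random.default_rng(1))
print(f"succession (feedback, 500 yr): dip={r.dip:.3f} (p={r.dip_pvalue:.3f}), "
      f"BI={r.bi:+.2f} -> {r.label.value}")
```

prints

```
survival  relEV=0: DE advantage +15.4%  [12.5, 17.5]
survival  relEV=1: EV advantage +16.9%  [14.8, 19.4]
recruits  relEV=0.1: con:hetero ratio 4.49x [3.95, 5.09]
recruits  relEV=0.9: con:hetero ratio 4.68x [4.10, 5.39]
succession (feedback, 500 yr): dip=0.189 (p=0.000), BI=+0.00 -> bistable_evergreen
```

The fitted contrasts recover the planted advantages (14 % / 17 % survival,
5× recruitment) within their intervals: trees survive and recruit better
among their own leaf type. Five hundred years of simulated succession
under those feedbacks turn a uniform composition mixture into a strongly
bimodal one — the dip is far beyond the unimodal null (p < 0.002) and the
near-zero BI classifies the landscape as bistable.

A `phenostate` console script exposes the same stages
(`generate-data`, `test-bimodality`, `fit-demography`, `simulate-forest`,
`hysteresis`, `bimodality-map`, `drivers`, `run-all`) over a YAML config;
outputs are CSV/JSON plus a manifest with seeds and a config hash, so
identical configs reproduce identical results byte for byte.

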