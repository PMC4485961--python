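# samaradisp

Trait-based wind-dispersal kernels for auto-gyrating tree fruit.

Many tropical trees — dipterocarps above all — disperse single-seeded,
winged fruit that gyrate as they fall. How far a fruit travels depends on
how much lift its wings provide per unit weight, summarized by the
**inverse wing loading** IWL = long-wing area (cm²) / mass (g), and on the
wind during its fall. `samaradisp` packages a complete analysis chain for
release experiments of such fruit, aimed at dispersal ecologists and forest
modellers who need species-level dispersal kernels from simple morphological
traits:

* **morphometrics** — genus-specific wing-area rules, IWL, and conversion to
  classical wing loading (weight in millidynes per cm² of wing) and its
  square root, which governs descent rate;
* **dispersal_lmm** — a random-intercept linear mixed model

  ln *d* = β₀ + β₁ ln(IWL+1) + β₂ ln(*U*+1) + β₃ ln(IWL+1)·ln(*U*+1)
  + *a*<sub>species</sub> + ε,

  with *a*<sub>species</sub> ~ N(0, σ²<sub>species</sub>),
  ε ~ N(0, σ²<sub>resid</sub>) and *U* the maximum wind speed during the
  release, fitted by profiled REML (ML for AIC comparison of the max- vs
  mean-wind covariate);
* **parametric_bootstrap** — simulate-then-refit replicates giving percentile
  confidence intervals and approximate two-sided tail-count p-values;
* **kernel_simulation** — log-normal dispersal kernels (analytic and Monte
  Carlo) with pointwise 95% bootstrap confidence bands, over any IWL × wind
  grid;
* **ballistic_model** — the classical comparison model *d* = *U·H*/*V*ₜ with
  terminal velocity *V*ₜ linear in √(wing loading), calibrated from anchor
  rows of a published comparison table;
* **synthetic_data** — a generator that emulates a 13-species, 728-fruit
  canopy-tower release experiment (release height 30 m, maximum winds
  averaging 1.72 m/s with a right tail capped at 10.5 m/s), so the whole
  chain is testable without the original field data.

## Worked example

```python
import samaradisp as sd
from samaradisp import fixtures as fx

cfg = fx.default_generator_config(rng_seed=1)     # 13-species study design
df, truth = sd.generate_releases(cfg)
y, X, g, _ = sd.design_from_frame(df, wind_choice="max")
fit = sd.fit_lmm(y, X, g, method="REML")
boot = sd.bootstrap(fit, X, g, B=200, base_seed=2)
ci = sd.percentile_interval(boot, "beta1", 0.95, point=fit.params.beta1)
k = sd.kernel_closed_form(fit.params, sd.KernelRequest(iwl=44.6, wind=1.72))
```

which prints (via the calls in the snippet above):

```
n = 728 fruit, 13 species
beta (intercept, log IWL+1, log wind+1, interaction) = (0.313, 0.273, 0.110, 0.139)
sigma_species = 0.215, sigma_resid = 0.543
IWL effect 95% CI = (0.178, 0.376), p = 0.005
S. argentifolia-like kernel at 1.72 m/s: median 7.36 m, 90th pct 14.76 m
pooled: median 4.40 m, 90th pct 10.87 m
```

Read: on this synthetic replicate of the study design the IWL effect is
positive and clearly non-zero (its bootstrap interval excludes 0), a
high-IWL species (44.6 cm²/g) has a median dispersal of ~7 m at the mean
maximum wind speed, and half of all released fruit land within ~4.4 m —
dispersal is predominantly local.

The same stages are available from the shell:

```sh
samaradisp simulate --seed 1 --out run/
samaradisp fit --in run/releases.csv --wind max --out run/fit.json
samaradisp bootstrap --fit run/fit.json --data run/releases.csv -B 1000 --seed 2 --out run/boot.json
samaradisp kernels --fit run/fit.json --boot run/boot.json --iwl 1:50 --wind 1:10 --out run/kernels/
samaradisp ballistic --fit run/fit.json --out run/comparison.csv
samaradisp run --out run/          # full pipeline with a manifest
```

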