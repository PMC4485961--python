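# Methods

## The dispersal model

For fruit *j* of species *i* released into maximum wind speed U the model is

    ln d_ij = β0 + β1 ln(IWL_ij + 1) + β2 ln(U_ij + 1)
              + β3 ln(IWL_ij + 1) ln(U_ij + 1) + a_i + e_ij,

with a_i ~ N(0, σ²_species) a per-species random intercept and
e_ij ~ N(0, σ²_resid) homoscedastic residual noise. The +1 offsets keep
the transforms finite for wingless fruit (IWL = 0) and calm releases
(U = 0). Natural logarithms are used everywhere; the base cancels out of
all predictions and only rescales coefficients, but is fixed for
reproducibility. The interaction regressor is the product of the two
logged terms, the default expansion of a crossed linear-model formula.

Assumptions worth keeping in mind: homoscedastic log-scale residuals (a
power-of-the-mean variance function is deliberately out of scope — see
Limitations), one wind summary per release treated as exogenous, and no
direction: kernels are one-dimensional in horizontal distance.

### Fitting

Fitting is REML with the covariance structure profiled down to one free
parameter. For a fixed variance ratio λ = σ²_species/σ²_resid the
covariance is V(λ) = I + λZZ', block diagonal over species, and both the
GLS fixed effects and σ²_resid have closed forms; a bounded Brent search
over ln λ ∈ [−12, 12] (absolute tolerance 1e−10) completes the fit, with
the λ = 0 boundary checked explicitly. Because the random effect is a
per-group intercept, all λ-dependent quantities reduce to per-group sums
cached once per dataset, so one criterion evaluation is O(#species) and a
full refit costs ~1–2 ms at n ≈ 700 — which is what makes the parametric
bootstrap and the simulation-based tests cheap.

Degenerate inputs: a dataset with a single species pins λ at 0, because
with one group the random intercept is unidentifiable next to the fixed
intercept (the unconstrained criterion is flat in λ along a ridge and an
optimizer would return an arbitrary large ratio with no change in fit).
Rank-deficient fixed designs raise an error rather than returning a
pseudo-inverse fit.

Two independent routes guard the profiled shortcut: a dense-likelihood
maximizer (`fit_lmm_direct`, Nelder–Mead over log-variances with
multistart, supporting any number of random-intercept terms) and, in the
test suite only, statsmodels' MixedLM. The dense route is also how
multi-term structures (mother tree nested in species, nested in genus) are
fitted; `variance_decomposition` then flags any random term contributing
< 0.1% of total variance as droppable, the screening rule used to justify
the species-only final model.

Model selection between the max-wind and mean-wind covariate uses ML (not
REML) AICs with k = 6, since REML criteria are not comparable across
different fixed-effect designs.

### Inference

Parametric bootstrap: each replicate simulates a fresh response from the
fitted model (new species intercepts, new residuals, fixed-effect surface
kept) and refits; per-replicate seeds are spawned from one base seed, so a
draw table is fully reproducible. B defaults to 1000. Failed or
non-converged refits are dropped and counted rather than retried —
transparent and unbiased within the replicate budget. Intervals are
equal-tailed percentile intervals with type-7 quantile interpolation (the
convention fixed throughout the package). Approximate p-values are
two-sided tail counts,

    p = max(2 · min(#{θ* ≤ 0}, #{θ* ≥ 0}) / B_retained, 1/B_retained),

capped at 1. Ties at exactly 0 count in both tails (the conservative
reading); the floor means p can never be 0, and at B = 1000 the smallest
reportable p is 0.001.

### Kernels

Conditional on (IWL, U), distance is log-normal with location μ given by
the fixed effects and log-scale s, where s² = σ²_resid for a conditional
kernel (species effect known, set to its median 0) or
σ²_resid + σ²_species for the marginal kernel of a new, unobserved
species. Both are exposed; the conditional kernel is the default because
per-species comparisons condition on species identity. Analytic kernels
use scipy's log-normal; Monte Carlo kernels (histogram density on the
grid, empirical cdf and type-7 quantiles) converge to them and exist so
that bootstrap-band machinery has a simulation route to validate against.
Confidence bands evaluate the analytic kernel at every bootstrap parameter
draw and take pointwise 2.5/97.5 percentiles of density and of each
quantile. The default evaluation grid is 512 geometric points from 0.05 m
to 1.5× the 99.9th percentile.

One consequence of the log-normal form worth stating: q90/q50 =
exp(1.2816·s) is constant in IWL, so "longer tails" for high-IWL species
are an absolute-scale effect (both quantiles stretch together), not a
change of kernel shape.

## The ballistic comparison model

d = U·H/V_t: a fruit released at height H into a constant lateral wind U
falls for H/V_t seconds at its terminal velocity, assumed reached
instantaneously (no acceleration phase is modelled). V_t = a + b·√WL with
WL the wing loading in millidynes (weight) per cm²; the conversion from
IWL uses standard gravity, WL = 980665/IWL, which makes IWL·WL = 980665 an
exact identity. For wingless fruit WL diverges and √WL is reported as
undefined (NaN), never 0 — the comparison table carries NA in the
ballistic column for such species.

The (a, b) line for helicopter-type fruit comes from published drop
experiments whose coefficients are not restated in the comparison table we
package; they are recovered by anchor calibration: each table row implies
V_t = U·H/d, two rows determine the line exactly, more give least squares,
and the largest distance residual over the anchors is kept as a
diagnostic. The default anchors are the two extremes of the √WL range,
which reproduce the other finely-printed rows to ±0.01 m; rows printed
with coarser rounding are reproduced to ±0.03 m. Anchor choice matters at
the rounding level only: any pair of finely printed rows recovers the
column to ≲0.05 m, but pairs with nearly coincident √WL amplify rounding
in the printed distances and should not be used as anchors.

Default H = 30 m and U = 1.72 m/s (the experiment's release height and
mean maximum wind); both are parameters. The comparison uses the table's
printed per-species √WL values by default, because they embed per-fruit
averaging (√ of a mean IWL is not the mean of per-fruit √WL); the
closed-form transform of mean IWL is accepted as an alternative input.

## The synthetic release experiment

The generator emulates the study design the analysis assumes: 13 species
(10 with the five-winged rule, 2 two-winged, 1 wingless) with the panel's
mean IWLs, fruit counts (728 total) and masses; per-fruit IWL from a
normal truncated at zero by redraw (published standard errors of species
means convert to per-fruit SDs via SE·√n — the only reconstruction
consistent with both numbers); mass log-normal with median equal to the
panel mean and CV from the mass SE; wing dimensions back-solved (aspect
ratio 3, the long-wing pair split 55/45 for the five-winged rule) so the
genus area rules reproduce the drawn IWL to machine precision; maximum
winds Gamma(shape 1) scaled to mean 1.72 m/s and truncated at 10.5 m/s by
redraw — shape 1 makes roughly 1 in 450 draws approach the cap, matching a
record maximum of 10.5 m/s in ~700 releases under otherwise calm
conditions; mean wind a Uniform(0.3, 1) fraction of the maximum (generated
although the default model uses maximum wind, so covariate selection has a
real competitor); and distances from the mixed model at the published
estimates. All randomness flows from one integer seed through SeedSequence
spawning: identical configurations give byte-identical datasets.

Under these defaults the synthetic experiments land where the study did:
pooled median distance ≈ 4.4 m (published: half under 4 m) and pooled 90th
percentile ≈ 10.9 m (published: 90% within 10.5 m).

What the generator does *not* emulate: within-species mother-tree
structure (species intercepts only), unrecovered or entangled fruit (only
recovered fruit are emitted), temporal autocorrelation of wind across
releases, turbulence and updrafts. Passing tests therefore validate the
statistical machinery under the model's own assumptions — they do not
validate the model against field reality.

## Validation results and two honest discrepancies

The acceptance suite verifies: exact reproduction of the ballistic column
from two anchors; agreement of the profiled REML fit with dense
two-parameter maximization (criterion to 1e−6, parameters to 1e−4, 20
datasets); recovery of all four β and σ_resid within 3 Monte-Carlo SEs
over 500 replicates at the study design; 95% interval coverage for the IWL
effect within [0.85, 1.0] (50 replicates at B = 200) and type-I error for
its p-value within [0.02, 0.09] under a null truth (200 replicates);
Monte-Carlo/analytic kernel agreement (cdf sup-norm < 0.01 at 1e5 draws)
and median monotonicity across the full IWL 1–50 × wind 1–10 grid.

Two checks fail for documented structural reasons and are left failing:

1. **σ_species recovery.** The mean of σ̂_species over 500 replicates is
   ≈ 0.148 against a generating 0.154, about 3.1 MC SEs low. The REML
   *variance* estimate is unbiased within MC error; the deficit is the
   concavity (Jensen) bias of the square root with only 13 species, and
   the delta-method prediction E[σ̂] ≈ 0.149 matches what is observed.
   An independent implementation (statsmodels) shows the same mean on the
   same replicates.

2. **Per-species median predictions.** The closed-form medians
   exp(μ̂) at the packaged point estimates track the packaged per-species
   predictions within ±20% for 12 of 13 species, but one (mean IWL 11.53,
   predicted 4.20 m vs printed 3.08 m, +36%) falls outside. That species'
   empirical median (2.62 m) is far below what its IWL predicts, so the
   printed prediction almost certainly includes a strongly negative
   species-level intercept (a BLUP or bootstrap-median conditional
   prediction) that cannot be reconstructed from the printed fixed effects
   alone. Both conventions (fixed-effects median, bootstrap quantiles) are
   implemented; the discrepancy is documented rather than resolved.

## Parameters that matter

| parameter | default | units | why |
|---|---|---|---|
| wind_mean_max | 1.72 | m/s | mean maximum wind over releases |
| wind_max_cap | 10.5 | m/s | highest recorded wind; truncation point |
| wind_shape | 1.0 | — | right-skew of maximum winds (see above) |
| B | 1000 | — | bootstrap replicates; p floor = 1/B |
| level | 0.95 | — | interval/band coverage |
| release_height H | 30 | m | tower height |
| ballistic wind U | 1.72 | m/s | comparison-table condition |
| kernel grid | 1–50 × 1–10 | cm²/g × m/s | IWL range covering ~75% of regional species |
| droppable threshold | 0.001 | — | variance-share screen for random terms |

## Known limitations

Beyond the generator gaps above: no heteroscedastic residual variance (a
power-of-the-mean structure was considered and rejected in the source
analysis; only the homoscedastic model is implemented); no random slopes,
crossed random effects or non-Gaussian responses; percentile intervals
only (no BCa or studentized bootstrap); no mechanistic wind-field,
turbulence or updraft modelling, so the far tail relevant to long-distance
dispersal is extrapolation; the ballistic model assumes constant wind over
the whole fall and is known to overestimate distances under a forest
canopy, which is precisely why it is kept as a comparison rather than a
predictor.
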