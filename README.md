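# tricause

Triangulated causal-effect estimation for two-period observational cohorts
with binary outcomes.

Comparative-effectiveness questions — "does drug A cause more adverse events
than drug B?" — are routinely asked of electronic health records, where
treatment is not randomized and unmeasured confounding can bias any single
analysis.  `tricause` implements a *triangulation* workflow: it fits several
estimators that rest on different, partially non-overlapping assumptions,
reports each on the same collapsible scale (the risk difference), and then
tests formally whether the resulting estimates are statistically dissimilar
— taking into account that estimates computed from the same patients are
correlated.

## What it computes

The estimand is the average causal risk difference

    β = E[Y₁(X=1)] − E[Y₁(X=0)]

for a binary treatment X and binary study-period outcome Y₁, with a prior
period outcome Y₀ observed before treatment started, measured confounders
W₀/W₁ per period, and a binary provider-level preference instrument Z.

Estimators (all reported as a risk difference via average marginal effects,
with delta-method standard errors):

| label | strategy | key assumption |
|---|---|---|
| `cat` | logistic outcome regression on X and W₁ ("corrected as treated") | no unmeasured confounding |
| `psm` | the same on a 1–1 nearest-neighbour propensity-matched subset | no unmeasured confounding |
| `iv`  | two-stage IV: logistic X ~ Z + W₁, then Y₁ ~ X̂ + W₁ | exclusion restriction (Z affects Y₁ only through X) |
| `cf`  | control function: first-stage residual Δ̂ and Δ̂·Z enter the outcome model | exclusion restriction |
| `did` | difference-in-difference over the stacked prior/study periods | prior outcome does not drive treatment; time-constant confounding |
| `poa_iv` / `poa_cf` | prior-outcome-augmented IV/CF: the interaction Y₀·Z is the instrument, with Z and Y₀ controlled in the outcome model | Y₀·Z predicts X; Y₀ and Z unconfounded |

Dissimilarity of a set *e* of estimates is tested with a generalized
Cochran's Q,

    Q_e = (β̂_e − β̂_IVW)ᵀ Σ̂⁻¹ (β̂_e − β̂_IVW) ~ χ²(|e|−1),

where β̂_IVW is the inverse-variance-weighted pool and Σ̂ is the estimates'
covariance estimated by refitting every method on non-parametric bootstrap
resamples of the patients.

A calibrated simulator generates two-period cohorts (5000 patients in 50
provider clusters by default, true risk difference 0.1) under eleven named
scenarios that switch individual assumption violations on and off, storing
both potential outcomes so the ground truth is known exactly.

## Worked example

```python
import tricause as tc

config = tc.make_scenario_config("base5", {})   # unmeasured confounding active
data = tc.simulate_dataset(config, seed=7)

print(tc.fit_cat(data).summary(percent=True))
print(tc.fit_did(data).summary(percent=True))

result = tc.Triangulation(data, ["cat", "cf", "did"], B=500, seed=7).fit()
print(result.summary())
```

Output:

```
CaT risk-difference estimate
----------------------------------------
estimate :  12.1390%
std err  :  1.0401%
95% CI   : [ 10.1004,  14.1776]%
p-value  :  1.8e-31
n used   : 5000
converged: True
DiD risk-difference estimate
----------------------------------------
estimate :  9.4765%
std err  :  1.3864%
95% CI   : [ 6.7591,  12.1938]%
p-value  :  8.19e-12
n used   : 5000
converged: True
dissimilarity test over {CaT, CF, DiD}
------------------------------------------------
estimates : 0.1214, 0.1023, 0.0948
IVW pool  : 0.1118
Q statistic: 9.291 on 2 df
p-value   : 0.009603  (reject at alpha=0.05)
bootstrap : B=500, 0 failed resamples
```

The confounder-adjusted estimate (12.1%) overshoots the true 10% risk
difference because an unmeasured confounder drives both treatment and
outcome in this scenario; DiD, which differences that confounding out using
the prior period, stays close to the truth.  The Q test (p ≈ 0.02) flags
that the three estimates are statistically dissimilar despite their
correlation — exactly the signal a triangulation analysis looks for.

The same functionality is available from the shell:

```bash
tricause simulate --scenario base5 --seed 7 --out cohort.csv
tricause fit --data cohort.csv --methods cat,cf,did --percent
tricause qtest --data cohort.csv --methods cat,cf,did --B 500 --seed 7
```

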