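# dopaproxy

Can cheap, "off-the-shelf" trait measures stand in for an [18F]-FDOPA PET
scan? Working-memory span tests, the BIS-11 impulsivity questionnaire,
spontaneous eye-blink rate (sEBR) and the Behavioural Activation Scale have
all been proposed as proxies of striatal dopamine synthesis capacity. Testing
that claim properly requires the full chain: quantifying dopamine synthesis
capacity as the Patlak influx rate k_i^cer per striatal region, extracting
sEBR from EOG, and then asking — with calibrated frequentist, Bayesian and
predictive machinery — whether the traits track k_i^cer at all.

`dopaproxy` implements that chain for biostatisticians and cognitive
neuroscientists, with a synthetic-data module so every stage runs end-to-end
with known ground truth:

* **`kinetics`** — reference-region Gjedde–Patlak analysis: for an
  irreversibly trapped tracer, y(t) = C_T(t)/C_ref(t) against
  x(t) = ∫₀ᵗC_ref ds / C_ref(t) is linear after equilibration (t* = 24 min
  on the 24-frame/89-min schedule), with slope k_i^cer (min⁻¹);
  `PatlakModel(...).fit()` returns a results object with the slope,
  intercept and fit diagnostics.
* **`blinks`** — sEBR from vertical EOG: zero-phase 0.5–20 Hz band-pass,
  rectification, and threshold detection (100 µV rise within 400 ms,
  nearby events merged).
* **`association`** — one-sided Pearson tests with Holm–Bonferroni control
  across ROIs, and exact correlation Bayes factors
  BF01 = f(r | ρ=0, n) / ∫ f(r | ρ, n) π(ρ) dρ, with f the exact sampling
  density of r under bivariate normality and π a stretched beta
  (ρ = 2u−1, u ~ Beta(1/w, 1/w)) on (0,1) or (−1,1); prior-robustness
  sweeps over widths w ∈ (0, 2].
* **`prediction`** — out-of-sample R² and RMSE of ki ~ 1 + trait under
  10-fold cross-validation × 100 repeats, with a 5000-permutation null.
* **`powercalc`** — power of the one-sided correlation test (noncentral-t
  and exact bivariate-normal formulations), detectable effect sizes,
  required sample sizes, Cohen's d conversions, and subsample-variability
  curves.
* **`synthdata`** — Gaussian-copula cohorts with configurable latent
  trait–k_i^cer correlations (study design defaults: N = 94, per-measure Ns
  92/66, inter-ROI structure 0.751/0.649/0.787, k_i^cer IQR ≈ 0.003 min⁻¹),
  compartmental-model TACs with an analytic Patlak asymptote, and vEOG
  traces with known blink counts.

See `docs/methods.md` for the models, defaults and numerical choices.

## Worked example

```python
import numpy as np
import dopaproxy as dp
from dopaproxy.synthdata import (KineticGroundTruth, simulate_tissue_tac,
                                 frame_average, patlak_asymptote)

truth = KineticGroundTruth()          # K1=0.10, k2=0.15, k3=0.03, K1r=0.10, k2r=0.12
t = np.linspace(0.0, 89.0, 200)
sched = dp.study_frame_schedule()     # 24 frames: 4x1, 3x2, 3x3, 14x5 min
target = frame_average(simulate_tissue_tac(truth, t, "target"), sched)
reference = frame_average(simulate_tissue_tac(truth, t, "reference"), sched)
print(dp.PatlakModel(target, reference, t_star=24.0).fit().summary())
```

```
Reference-region Patlak fit
---------------------------
influx rate k_i^cer :  0.019590 min^-1
intercept           :  0.7266
t*                  :  24.0 min
frames used         : 13
R^2 (linear segment):  0.99981
```

The fitted slope sits within 3% of the analytic asymptote
K1·k3·k2r/((k2+k3)·K1r) = 0.02 min⁻¹ — the residual gap is the late-time
transient, which shrinks as t* grows.

Correlation inference on a synthetic null cohort (all true trait–k_i^cer
correlations zero, study-sized):

```python
cohort = dp.simulate_cohort(dp.study_cohort_spec(seed=1))
print(dp.TraitAssociation(cohort, traits=("bas",)).fit().summary(published_rounding=True))
```

```
Pearson correlations between k_i^cer and trait measures
(one-sided p, Holm-adjusted across ROIs; BF01 at flat prior)
trait       roi  n      r  p_one_sided  p_adjusted  bf01_0_1  bf01_m1_1
  bas   caudate 94 -0.175        0.955       0.955     20.13       1.90
  bas   putamen 94  0.030        0.386       0.771      6.07       7.44
  bas accumbens 94  0.073        0.241       0.724      4.02       6.09
```

Under the null, directional BF01 > 1 quantifies evidence *for* absence of a
positive correlation — note how a chance negative r (caudate) yields strong
directional evidence (20.1) while its non-directional counterpart stays
modest (1.9).

Summary statistics suffice for the Bayesian re-analysis — no raw data
needed:

```python
dp.bf01_correlation(-0.035, 94, dp.PriorSpec((0.0, 1.0), 1.0))  # -> 9.91
dp.detectable_rho(94, power=0.9)                                 # -> 0.2909
dp.required_n(0.1, power=0.8)                                    # -> 614
```

A command-line interface mirrors the library:

```bash
dopaproxy patlak --tac target.csv --ref reference.csv --tstar 24
dopaproxy sebr --eog trace.csv --threshold 100
dopaproxy bf --r -0.035 --n 94 --interval 0,1 --width 1
dopaproxy power --mode detectable-rho --n 94 --power 0.9
dopaproxy run --config study.yaml
```

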