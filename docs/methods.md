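# Methods

This note records the models implemented in `dopaproxy`, the defaults and why
they were chosen, the numerical decisions, and what the synthetic-data tests
do and do not demonstrate.

## Scientific setting

The package implements the analysis chain used to ask whether cheap,
"off-the-shelf" trait measures — Digit Span and Listening Span (working
memory), BIS-11 total (trait impulsivity), spontaneous eye-blink rate (sEBR),
and BAS total (subjective reward sensitivity) — track striatal dopamine
synthesis capacity measured with [18F]-FDOPA PET in a cohort of 94 healthy
adults. Dopamine synthesis capacity is quantified per striatal region of
interest (caudate nucleus, putamen, nucleus accumbens) as the Patlak influx
rate k_i^cer (min⁻¹) relative to cerebellar grey matter. The statistical
machinery is built to quantify evidence *for absence*: one-sided Pearson
tests with Holm–Bonferroni control, Bayes factors BF01 under stretched-beta
priors, out-of-sample prediction with a permutation null, and power analysis.

## Patlak quantification (`kinetics`)

For an irreversibly trapped tracer, plotting y(t) = C_T(t)/C_ref(t) against
the "normalised time" x(t) = ∫₀ᵗ C_ref ds / C_ref(t) becomes linear once the
reversible compartments equilibrate; the slope is k_i^cer.

Decisions:

* **Frame time** entering x, y and the t* cut is the frame **mid-time**
  (standard Patlak practice; symmetric within the frame).
* **Integration** of the reference curve is piecewise-constant over frames,
  matching how frame-averaged data arise; at a frame's mid-time the running
  integral includes half of that frame's area.
* **t\* = 24 min, inclusive**, mirroring the 24–89-min fit window of the
  acquisition protocol (24 frames: 4×1, 3×2, 3×3, 14×5 min, 89 min total).
  Thirteen frames have mid-times ≥ 24 min.
* **Unweighted OLS** on the late-frame (x, y) points; no frame weighting is
  applied because none is specified for the analysis being reproduced.
* Frames with reference activity ≤ 1e-12 are dropped (logged); fewer than
  three usable or late frames is an error, as is a zero-variance abscissa.
* Voxel maps are plain 3-D arrays with binary masks (threshold 0.5);
  `load_ki_map_nifti` is a thin NIfTI-1 adapter (voxel-wise correspondence
  required, no resampling). Both analysis orders are possible: fit-per-voxel
  then `roi_mean_ki` (the default when maps are given), or ROI-mean TAC then
  fit.

## Kinetic ground truth (`synthdata`)

The simulator exists to give the Patlak stage a known answer.

* Target tissue: irreversible two-tissue compartment model,
  dC1/dt = K1·Cp − (k2+k3)·C1, dC2/dt = k3·C1, C_T = C1 + C2.
  Reference: one-tissue, dCr/dt = K1r·Cp − k2r·Cr. Blood-volume fraction is
  zero so the asymptotic slope stays analytic:
  **k = K1·k3·k2r / ((k2+k3)·K1r)**.
* Defaults K1 = 0.10, k2 = 0.15, k3 = 0.03, K1r = 0.10, k2r = 0.12 min⁻¹
  give k = 0.02 min⁻¹, the right order for striatal FDOPA, and equilibration
  time constants (5.6 and 8.3 min) comfortably inside the 24-min t*.
* Plasma input is a gamma-variate A·t·exp(−t/τ) with τ = 20 min. This is
  deliberately slower than a real arterial peak: a single gamma-variate has
  only one time constant, and it must keep the cerebellar curve measurable at
  89 min so that late Patlak frames are usable. A multi-exponential input is
  out of scope; consequences for realism are confined to the early frames,
  which the fit never uses.
* Frame noise is zero-mean Gaussian with SD = noise_scale·√(mean/duration),
  the usual count-statistics scaling (short, hot frames noisiest). ODEs are
  solved with LSODA at rtol 1e-9 with dense output; frame averages use
  65-point trapezoidal quadrature per frame.

## Synthetic cohorts (`synthdata`)

Cohorts come from a Gaussian copula: latent MVN with unit variances and a
correlation matrix assembled from (i) trait–k_i^cer correlations under test,
(ii) inter-ROI correlations (defaults 0.751 / 0.649 / 0.787, the observed
striatal structure), (iii) optional trait–trait correlations (default 0).
Latent normals are pushed through monotone marginal transforms, so Spearman
structure is preserved exactly and Pearson structure is preserved exactly for
Gaussian marginals.

Default marginals are plausibility choices, not fitted values: Digit Span
N(16, 4) on a half-point grid; Listening Span N(4.5, 1) on the half-point
grid [2, 7]; BIS-11 N(62, 8) in [30, 120]; sEBR log-normal with median 17
blinks/min and log-SD 0.5; BAS N(40, 5) in [17, 68]. k_i^cer is N(0.015,
0.00222) min⁻¹ truncated at 0 — the SD chosen so the normal IQR (1.349·SD)
matches the observed dispersion of ≈ 0.003 min⁻¹; the mean is a plausible
scale, not a reported value, and all marginals are configurable.

`study_cohort_spec()` encodes the study design: N = 94 with per-measure
missingness (2 sEBR rows, 28 BIS-11 rows) reproducing the analysis Ns of
94/92/66, and all trait–k_i correlations zero — the study's conclusion is the
generator's null default. A non-positive-definite latent matrix raises an
error naming the trait–ROI pair(s) whose removal would restore feasibility.

## Blink extraction (`blinks`)

Zero-phase 4th-order Butterworth band-pass 0.5–20 Hz (no filter family is
prescribed for the procedure being emulated; Butterworth's flat passband is
the standard EOG choice), then rectification. A blink is a max–min voltage
rise exceeding the threshold (default 100 µV) within a sliding 400 ms
window; supra-threshold runs closer than the window are merged, replacing
manual curation. The window plus merge rule imply a dead time of roughly
0.8–1 s — far below typical resting inter-blink intervals (3–4 s at ~17
blinks/min), so it does not bias sEBR in practice, but bursts faster than
~1 s would be counted once. Horizontal-EOG saccade flagging is a hook
(`flag_saccade_windows`); full manual artefact review is out of scope. The
threshold is a per-participant parameter with default 100 µV.

## Correlation inference (`association`)

* One-sided p-values use the exact null distribution via
  t = r√(n−2)/√(1−r²), df = n−2, alternative "greater" throughout (the prior
  literature predicts positive associations). Pairwise deletion per trait
  reproduces per-measure Ns.
* Holm–Bonferroni is applied across the three-ROI family per trait.
* The Bayes factor is BF01 = f(r | 0, n) / ∫ f(r | ρ, n) π(ρ) dρ with f the
  **exact sampling density of r under bivariate normality** (Hotelling's
  hypergeometric form, evaluated in log space; stable to n ≥ 1000) and π a
  stretched beta: ρ = 2u − 1, u ~ Beta(1/w, 1/w), truncated/renormalised to
  the hypothesis interval. Width w = 1 is the flat prior used for headline
  numbers; `bf_robustness_curve` sweeps w over (0, 2]. As w → 0 the prior
  collapses on ρ = 0 and BF01 → 1 analytically (w = 0 itself is excluded
  with a warning).
* The marginal likelihood is integrated after substituting the prior CDF
  (u = Beta-quantile of a uniform v), which keeps the integrand smooth both
  for very concentrated priors (small w) and for the endpoint-singular
  priors with w > 1; adaptive quadrature at relative tolerance 1e-10 with a
  convergence check.
* This exact-density formulation reproduces the published correlation table
  to within the rounding of its printed coefficients for 14 of 15 rows on
  the p-values and non-directional Bayes factors, and for 13 of 15
  directional Bayes factors. The two gaps are informative rather than
  numerical: two listening-span cells differ by ~2%, consistent with the
  reference R implementation's slightly different internal likelihood, and
  the printed directional BF of the impulsivity/accumbens row (4.97) equals,
  to three decimals, the Bayes factor for the *opposite* direction at its
  r = −0.04 — i.e. a sign slip in the published cell. The test suite checks
  both facts explicitly.
* A summary mode builds the full results table from printed (trait, ROI, r,
  n) rows so published tables can be re-analysed without raw data.

## Out-of-sample prediction (`prediction`)

Simple linear regression ki ~ 1 + trait, evaluated by 10-fold
cross-validation with 100 repeats and a 5000-permutation null (defaults).

* Folds are a seeded Fisher–Yates shuffle chunked contiguously; sizes differ
  by at most one (n = 94, k = 10 gives four folds of 10 and six of 9).
* R² and RMSE are computed on the **pooled out-of-fold predictions within a
  repeat**, then summarised across repeats; std_err = SD across repeats /
  √repeats. Pooling yields one value per repeat, matching per-repeat,
  per-participant error displays; per-fold metrics would be systematically
  more negative under the null (small-denominator effect) and are available
  from the per-repeat error matrix if wanted.
* Each permutation shuffles the outcome and runs **one** CV replicate — the
  null needs one draw per permutation, and 5000 × 100 repeats would add
  nothing but runtime. The permutation p is the literal proportion of
  permutations at least as accurate as the observed summary (ties count);
  the (b+1)/(B+1) smoothed estimator is behind a flag. Note the observed
  statistic averages `repeats` CV replicates while each permutation draws
  one, so exact exchangeability — hence exact uniformity of p under the
  null — holds at repeats = 1; calibration tests use that setting.
* A constant predictor inside a training fold falls back to the
  intercept-only fit (logged).

Under a true-null cohort the pooled out-of-sample R² is negative (mean
≈ −0.03 at n = 94; a superfluous predictor must lose to the grand mean), and
with 100-repeat averaging it is negative in ≥ 95% of null cohorts — the
qualitative signature the real analysis showed for every trait × ROI pair.

## Power analysis (`powercalc`)

Two power models for the one-sided test, differing in the alternative's
sampling model:

* `method="nct"` (default): noncentral-t / point-biserial formulation,
  δ = √n·ρ/√(1−ρ²), df = n−2. This is what the common desk calculators
  compute and it reproduces the published sensitivity numbers exactly:
  detectable ρ = 0.29 (power 0.9) and 0.25 (power 0.8) at n = 94, α = 0.05;
  required N = 614 / 850 for ρ = 0.1 at power 0.8 / 0.9 — together with the
  matching Cohen's d values (d = 2r/√(1−r²): 0.61 and 0.52).
* `method="exact"`: distributionally exact bivariate-normal power — critical
  r from the null t distribution, power as the upper-tail integral of the
  exact r density (integrated on the side away from the density mode so
  near-unity ρ does not defeat the quadrature). It is validated against
  Monte-Carlo rejection rates (2×10⁵ simulated datasets per grid cell,
  agreement within 3 binomial SEs) and gives slightly different third
  decimals (detectable ρ 0.296, required N 616/853). The exact method is
  never *less* sensitive than the Fisher-z approximation (0.297 / 617).

The published values correspond to the noncentral-t formulation, which is
why it is the default; the exact method is the ground truth against
simulation. `detectable_rho` solves by bracketed root-finding (xtol 1e-6);
`required_n` by doubling bracket plus bisection on the integer n.

Subsample-variability curves resample (with replacement, as in the original
analysis, even near the full n) and report percentile intervals of r per
subsample size; BCa corrections are not used because plain interval
summaries are being emulated. Degenerate resamples are redrawn (capped).
At size 15 under a true null the 95% interval spans roughly ±0.51 (the exact
null quantile of r at n = 15), illustrating how strongly small-sample
correlations scatter.

## Orchestration (`report`, `cli`)

`run_all` writes table1.csv (correlations), table2.csv (cross-validated
prediction), robustness_curves.csv and subsample_curves.csv plus a YAML run
log with seed and library versions. Every stochastic stage draws from a
named offset of the master seed, so identical configs give byte-identical
outputs. CSVs are written at full precision; `--published-rounding` reproduces
the 2–3-decimal presentation. Per-trait failures are collected and re-raised
together. The `dopaproxy` CLI exposes patlak / sebr / assoc / bf / predict /
power / subsample / run.

## What the synthetic tests do and do not show

The generator reproduces the study's *design* (Ns, missingness, inter-ROI
structure, dispersion anchor, frame schedule) and gives every stage known
ground truth. It does not emulate scanner physics (attenuation, scatter,
reconstruction), real plasma input shapes, item-level questionnaire
behaviour, EOG artefacts beyond Gaussian noise, or non-Gaussian trait–ki
dependence. Passing tests therefore demonstrate that the *estimators* are
correct and calibrated under the stated models — not that the acquisition
pipeline upstream of them is free of bias.

## Problem sizes used in the test suite

Calibration and oracle checks run at: 200 null cohorts (n = 94) for the CV
sign pattern (100 repeats each); 200 replicates × 200 permutations for
permutation-p uniformity; 100 replicates × 500 permutations for signal
detection at ρ = 0.6; 2×10⁵ simulated datasets per Monte-Carlo density/power
cell; 500 noisy replicates for Patlak bias; 100 seeded vEOG fixtures. These
sizes give Monte-Carlo errors well below the margins asserted.
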