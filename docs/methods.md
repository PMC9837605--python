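# Methods

This note documents the models, estimators, and numerical choices behind
`erroraware`, and what the synthetic-data tests do and do not establish
about real data.

## The task and its simulation

The Error Awareness Task (EAT) is a motor Go/No-Go paradigm: a serial
stream of color words appears in a congruent (No-Go) or incongruent (Go)
ink color. Subjects press left on Go trials, withhold on No-Go trials,
and signal awareness of a commission error with a right press on the
trial that follows it. The default design is 6 blocks of 175 trials (900
Go + 150 No-Go), 900 ms stimuli with a 600 ms inter-stimulus interval
(1.5 s stimulus-onset asynchrony), 30 s rest between blocks, and 1–12 Go
trials between consecutive No-Go trials.

`task.generate_sequence` places the No-Go trials block by block: the Go
run lengths around them are drawn uniformly on `[min_gap, max_gap]` and
then stochastically repaired (unit increments/decrements of randomly
chosen runs, within bounds) until they sum to the block's Go budget.
Any constraint-satisfying pseudorandom placement is admissible for this
design; the uniform-gap sampler is used because its distribution is easy
to state. Two conventions are fixed: a No-Go trial is never the first
trial of a block (so the pre-event Go reaction time needed by the
slowing statistic always exists), and runs truncated by a block boundary
are exempt from the gap bounds (`exempt_edge_runs`, configurable). The
emitted sequences have a mean inter-No-Go gap of ≈5.8 Go trials (range
1–12); the exact gap distribution of any particular published sequence
is not reproducible without its generating script, and only the range
and counts are treated as design constants.

## Behavioral generator

Go reaction times are lognormal (right-skewed, positive support) with
target mean 518 ms and SD 81 ms. Each No-Go trial is withheld with
probability `p_inhibit` (default 0.536); otherwise a left press occurs
with an additive latency shift (−29 ms for to-be-aware errors, −10 ms
for unaware ones, reproducing the faster erroneous responses seen
empirically). With probability `p_aware` (default 0.865) the error is
signaled by a right press on the next trial. Go omissions occur with
probability 0.02, except on the first trial after a commission error —
the subject demonstrably just responded, and suppressing that omission
keeps the classified awareness rate equal to `p_aware` in expectation.
Post-error slowing is planted as +19 ms added to the reaction time of
the third trial after an unaware error when that trial is a Go trial.

Classification follows the deterministic rule: a No-Go with no press is
a correct inhibition; a left press followed by a left press on the next
trial is an unaware error; any other commission pattern is an aware
error. An error on the final trial of the run (no following trial) is
aware only if the erroneous press itself was the right button. A No-Go
error followed by an omission is classified aware, per the literal "any
deviation" reading of the rule. Right presses on Go trials not preceded
by an error are recorded as anomalous and excluded from RT summaries.

The post-No-Go adjustment statistic is RT(third following Go) −
RT(immediately preceding Go). The first two post-error trials are
contaminated by the awareness press and are never used. Events are
dropped when the window crosses a block boundary, contains another
No-Go trial, or lacks a left-press RT at either end; a subject's value
is the mean of the retained events, and missing (not zero) when none
remain.

## BOLD forward model

Each voxel's time series is

    baseline + Σ_condition c_k · (event train ⊛ h) + drift + noise

with baseline 100 arbitrary units (so percent signal reads directly),
`h` the gamma variate `t^r e^(−t/b)` (r = 8.6, b = 0.547 s, peak at
4.7 s) normalised to unit area and sampled at the TR (2.46 s), and event
trains binned to the nearest TR. The scale `c_k = a/100 · baseline ·
window_s` is chosen so that a planted region amplitude `a` is exactly
the percent-area activation the analysis estimates. Drift is a sum of
Legendre polynomials (orders 1–3) with per-voxel Gaussian coefficients.
Noise is temporally AR(1) (ρ = 0.3), spatially smoothed to 6 mm FWHM
with periodic boundaries (which keeps the field stationary so residual
smoothness estimation is well posed), and rescaled to a marginal SD of
1% of baseline — a typical temporal SNR for 3 mm voxels at 3 T. The
planted signal itself is confined to its region and not spatially
smoothed, so recovered region amplitudes are unbiased; real data spread
signal into neighbouring voxels, which the simulation deliberately does
not emulate.

What the generator does **not** model: anatomy, motion, physiological
noise, slice timing, spatial normalisation (all subjects share one
grid), or any mechanistic difference in autonomic response between
aware and unaware errors — the per-condition amplitudes are free
parameters, not claims.

## Subject-level estimation

The impulse response of each event class (aware error, unaware error,
correct inhibition) is estimated without shape assumptions by FIR
deconvolution: 8 lagged indicator columns per class spanning 0–17.22 s
(8 × TR). Omission events enter as one regressor of no interest
(indicator convolved with a fixed canonical gamma variate), rest epochs
as boxcars, and drifts as mean-centred Legendre polynomials of order
1–3. Ordinary least squares is solved voxel-wise; AR(1) autocorrelation
is tolerated rather than prewhitened (OLS stays unbiased; standard
errors at the subject level are never used downstream). The design is
rejected with a named-column error if rank deficient; in cohort runs a
subject whose design cannot separate the regressors (too few events) is
excluded, mirroring the exclusion of participants who never signal
awareness.

A gamma variate `A·t^r·e^(−t/b)` is then fitted to each estimated IRF
by least squares. For fixed (r, b) the amplitude is linear, so a
48 × 48 log-spaced grid over r ∈ (0.5, 20], b ∈ (0.05, 5] s (restricted
to peak times r·b ∈ [2, 10] s) gives closed-form amplitudes and
residuals; the grid minimiser seeds a damped Gauss–Newton polish
(vectorised over voxels, steps rejected unless they reduce the residual
and stay in bounds). This recovers noiseless inputs exactly and serves
as the multi-start strategy. All-zero IRFs return a flagged A = 0 fit.

Activation is summarised as the percent of baseline area:

    pct_area = 100 · AUC / (β0 · window_s),

with AUC = A·Γ(r+1)·b^(r+1) in closed form and β0 the GLM intercept —
the residual Go-trial processing level. The window is 17.22 s, matching
the FIR span.

**ROI estimates.** Averaging per-voxel percent-area values over a
region inflates sparse conditions: the nonlinear AUC estimator has an
O(σ²) positive bias, and with ~10 unaware events per subject the
per-voxel IRF noise makes that bias material (≈ +1 SE of a 30-subject
cohort mean, measured on 400 simulated subjects). Region-of-interest
activity is therefore estimated by averaging the FIR coefficients over
the region's voxels first and gamma-fitting the mean IRF — the averaged
IRF is ~3× cleaner and the residual bias ≈ −0.6 SE. The generic
voxel-map averaging (`roi.cluster_means`) remains available for map
summaries.

## Group inference

The group map is a voxel-wise paired t (one-sample t of aware−unaware
differences, df = n−1). Residual spatial smoothness is estimated per
axis from first differences of the GLM residual maps, ρ = 1 −
var(diff)/(2·var), FWHM = Δ·√(2 ln 2/−ln ρ), averaged over volumes and
combined as a geometric mean.

Cluster-extent calibration: each Monte Carlo iteration draws Gaussian
white noise on the analysis grid, smooths it to the estimated FWHM
(periodic boundaries), standardises, thresholds at the two-tailed
voxel-wise p, and records the maximum suprathreshold cluster size under
face (6-neighbour) connectivity. The extent threshold is the smallest
size whose null exceedance frequency is at most the corrected alpha
(0.010) — family-wise control via the max-cluster distribution. A
cluster-count variant (expected number of clusters ≥ s per map ≤ alpha)
is available behind `statistic="count"` and is never looser. A hard
extent override (e.g. the conventional 250 µL) can replace the
simulated threshold; on the default 24×24×18 grid of 3 mm voxels at
6 mm smoothness the simulated threshold lands near 270 µL. Cluster
tables report volume (voxels × voxel volume; 1 mm³ = 1 µL), hemisphere
by the sign of world x (RAS+, grid centred on the origin), |t|-weighted
centre of mass, and peak t. The published voxel threshold for a
402-subject sample (t = 6.60) is far too strict for desk-scale cohorts;
synthetic runs use voxel p = 0.001 at the matching t quantile for their
df.

## Trait stability selection

Questionnaire batteries are simulated as 22 standardised subscales
(three impulsivity, five autism-spectrum, four behavioral
inhibition/activation, two hospital anxiety/depression, eight adult
ADHD) with a block latent correlation structure (0.5 within instrument,
0.15 between). A subscale with planted effect β is built as β·z(outcome)
+ √(1−β²)·latent, so its population correlation with the outcome is β.
Missingness is MCAR at the subject level (whole battery absent) at rate
20/402.

The lasso objective is `(1/2n)‖y − Xβ‖² + λ‖β‖₁` on z-scored variables
(n−1 denominator), solved by coordinate descent (scikit-learn); every
returned fit is KKT-verified at tolerance 1e-6. The penalty grid is 100
log-spaced points from λ_max down by 1e-3; λ is chosen by seeded
10-fold cross-validation at the minimum mean held-out squared error
(not the 1-SE rule; configurable via the grid argument). Stability is
the percentage of 500 bootstrap resamples (with replacement, original
size) in which a predictor's coefficient is nonzero; by default the
entire CV-lasso is re-run inside each resample (`refit_lambda=False`
freezes the full-sample penalty instead — the two conventions differ
and both are exposed). Rows with missing values are dropped first and
the count reported. Only the Gaussian family is implemented; all
outcomes handled here are continuous. No p-values are attached to lasso
coefficients.

## Problem sizes used in the test suite

- FWE calibration: 24×24×18 grid, 3 mm voxels, 6 mm smoothness,
  10,000 selection iterations, 1,000 fresh validation maps.
- End-to-end recovery: 20 cohorts of n = 30 subjects on a 12×12×10 grid
  with the full 6-block task, planted aware/unaware/correct amplitudes
  1.0/0.5/0.3 percent-area in a 27-voxel region, 2,000 Monte Carlo
  iterations per cohort for the extent threshold.
- Behavioral recovery: one 500-subject cohort on the full design.
- Stability selection: n = 400, 500 bootstrap resamples.

A seed governs every random draw, routed through named substreams
(`io.substream`) so each stage is independently reproducible.

## Known limitations

- Percent-area estimates from per-voxel gamma fits are biased upward
  for conditions with few events; use ROI-level IRF averaging for
  quantitative comparisons (the group t-map is unaffected in its null
  behaviour, which the calibration test checks).
- OLS without prewhitening inflates subject-level variance under AR(1)
  noise; group inference absorbs this in the between-subject variance.
- The Monte Carlo null assumes Gaussian, stationary, isotropically
  smooth noise; heavy-tailed or non-stationary real noise would make
  the extent threshold anti-conservative.
- Holm-adjusted paired contrasts replace Tukey's method for the
  three-condition post hoc comparisons; Holm is the adjustment used
  everywhere else here and is conservative for k = 3.
- Correlation analyses always report Spearman coefficients rather than
  switching on a normality test, since the switching criterion is
  inherently arbitrary; the correlation-family grouping for Holm is
  user-declared.
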