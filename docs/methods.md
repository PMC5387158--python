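# Methods

This package reimplements, with simulated observers and synthetic brain maps,
an analysis chain that relates perceptual metacognitive ability to voxelwise
quantitative grey-matter measures. This note documents the models, the
defaults and the numerical choices, and what the synthetic data can and
cannot establish.

## The behavioural task and the simulated observer

The task is a two-alternative global-motion discrimination: on each trial
1100 dot directions are drawn as `sign(side) * mean_angle + N(0, sd_angle)`
(angles from vertical; LEFT carries negative sign), shown for 250 ms, and the
observer reports left/right followed by a 0–100 confidence rating. Two
randomly interleaved conditions hold accuracy near 71% with 2-up-1-down
staircases (two consecutive correct responses → one step harder, one error →
one step easier; accuracy fixed point `sqrt(1/2) ≈ 0.707`):

* **μ-staircase** — the mean angle adapts (start 15°, step 1°, bounds
  0.5–45°), direction SD fixed at 30°;
* **σ-staircase** — the direction SD adapts (start 30°, step 2°, bounds
  5–90°), mean angle fixed at 15°.

Step sizes, starting levels and bounds are package choices (the start of each
track is the fixed value of the opposite condition); they are configurable
on `Staircase`.

A session is 320 main trials in 8 blocks of 40, each block containing 20
trials of each condition in random order, preceded by a 56-trial practice
(no confidence ratings; the session records whether practice accuracy
exceeded the 70% entry criterion). Simulated observers never time out;
imported trial tables may contain `response == NONE`, which the filter stage
drops.

**Observer model.** The decision variable is the mean of a random subsample
of `n_effective_dots` dots (default 8) plus internal noise
`N(0, sensory_noise)` (default 15°); the response is the sign of this
estimate. The subsample is the one deliberate departure from an ideal
averager: an observer that pools all 1100 dots reduces the stimulus
direction SD by `1/sqrt(1100)`, leaving the σ-staircase with almost no
leverage on accuracy; a limited-capacity integrator is both psychophysically
standard for global motion and necessary for the variance staircase to
converge. With the defaults the analytic accuracy is
`Phi(mean_angle / sqrt(sensory_noise^2 + sd_angle^2 / n_effective_dots))`,
strictly monotone in either adapted quantity.

**Confidence channel.** Confidence evidence is the uncertainty-normalized
magnitude `|estimate| / sigma_eff` with
`sigma_eff = sqrt(sensory_noise^2 + sd_angle^2 / n_effective_dots)` — the
observer knows its own noise level, so confidence tracks the probability of
being correct rather than the raw evidence magnitude (an un-normalized
channel would make confidence rise with stimulus SD purely because wider
evidence distributions have larger `|e|`, masking any planted bias). The
evidence is corrupted by `N(0, metacognitive_noise)` (unitless; the
normalized evidence has spread of order 1), shifted by
`variance_bias_weight * sd_angle` (default −0.25 per degree: noisier stimuli
feel less certain, the generative analogue of the variance-induced
confidence bias), then mapped affinely (`offset 25, gain 25`) and clamped to
[0, 100]. The defaults were set so cohort summary statistics land in the
range typical of this task (mean AROC ≈ 0.64, mean confidence ≈ 40/100,
lower confidence in the variance condition). `metacognitive_noise = 0` makes
confidence a deterministic monotone function of evidence (type-II AROC at
its ceiling for that observer); large values drive AROC to 0.5. RT is
`rt_base_ms + Gamma(2, rt_noise_ms / 2)`.

**Cohorts.** `simulate_cohort` draws per-subject parameters (heterogeneous
`metacognitive_noise ~ N(0.7, 0.45)` truncated at 0.02, chosen so the
between-subject spread of estimated AROC approaches the ~0.05–0.06 typical
of this task; the 4-bin AROC ceiling of the observer caps how much higher
the cohort mean can sit)
plus demographics: age `N(24, 5)` clipped to 20–40 years, gender Bernoulli
(60% female), TIV `N(1400, 100) ml + 100 ml` for males. A table of the
generating parameters is returned for recovery tests.

## Behavioural statistics

* **Filtering** (single pass, in order): drop the first block (staircase
  stabilization), drop non-responses, drop RT < 100 ms, then drop
  |RT − mean| > 3 SD with mean/SD computed once on the surviving pooled
  trials (not per condition; iterative trimming is deliberately not done, so
  the filter is not idempotent — documented and tested).
* **Confidence binning**: rank-based quartiles (4 bins, sizes differing by at
  most 1), ties broken by trial index. Rank binning makes AROC invariant to
  any strictly monotone transform of the raw ratings.
* **Type-I SDT**: RIGHT is the signal class; `d' = z(H) − z(F)`,
  `c = −(z(H) + z(F))/2`; rates of exactly 0 or 1 are replaced by `1/(2N)`
  and `1 − 1/(2N)` to keep the quantiles finite.
* **Type-II AROC**: cumulative hit/false-alarm rates
  `P(conf ≥ k | correct)` and `P(conf ≥ k | incorrect)` at the three interior
  criteria, anchored at (0,0) and (1,1); area by the trapezoid rule. This is
  the standard cumulative type-II ROC construction; it is verified against an
  independent brute-force oracle in the tests. AROC is computed per condition
  and then averaged, never pooled across conditions.
* **Variance-induced confidence bias**: within-subject OLS of raw confidence
  on z-standardized trial mean angle, direction SD, accuracy and RT; the SD
  weight is the bias. Constant predictors are dropped and flagged.
* **Staircase stability**: per condition, retained trials are re-binned into
  8 equal-count bins of consecutive trials; per-cell accuracy enters a
  two-way repeated-measures ANOVA (bin × condition, subject as random
  factor) via pingouin, reporting uncorrected and Greenhouse–Geisser
  adjusted p-values side by side (sphericity over 8 bins is not assumed).
  The all-cells-equal degenerate case returns F = 0, p = 1 by convention.

## Synthetic quantitative maps

Maps of MT saturation (percent units, grey-matter baseline 0.9), R1
(1/s, baseline 0.6) and R2* (1/s, baseline 16) are generated on an MNI-like
grid: a diagonal affine over an ellipsoidal grey-matter envelope (semi-axes
60/92/55 mm centred at (0, −16, 6)) sized so every analysis coordinate is
inside the mask; default voxel size 2 mm, configurable down to 0.8 mm (tests
and the demo pipeline use 4–8 mm for desk-scale runtime). A subject's map is

    baseline + Σ_sites slope · (predictor − cohort mean) · Gaussian kernel
             + nuisance fields + smoothed noise

with a Gaussian spatial profile of σ = `spatial_extent_mm / 2` (default 8 mm
extent, truncated at 3σ), spatially uniform nuisance slopes for age, gender
and TIV (e.g. R2* rises 0.05 s⁻¹ per year, emulating age-related iron
accrual), and white noise smoothed with a 4 mm-FWHM Gaussian kernel, then
rescaled so the post-smoothing SD equals the stated noise SD
(MT 0.045, R1 0.03, R2* 1.0). Default planted sites put AROC effects at the
canonical coordinates (right aPFC MT+/R1+, left hippocampus MT−, precuneus
R2*+, V1 R2*−, left MTG R2*+) with slopes scaled so one between-subject SD
of AROC (≈0.06) moves the map one noise SD at the peak — matching peak
t-values around 4–6 in a ~48-subject cohort. Values are floored at
0.1% of baseline so maps stay positive in-mask.

Field smoothness is checked with a gradient-variance estimator: for a
Gaussian-smoothed white field the lag-d autocorrelation is
`exp(−d²/(4σ²))`, giving FWHM = `sqrt(8 ln 2) σ`; the empirical FWHM of pure
noise volumes must sit within 20% of the requested kernel.

**What the generator does not emulate:** MRI physics (FLASH/ESTATICS, B1
correction), segmentation and registration error, tissue-specific smoothing,
non-stationary noise, spatially structured confounds. Passing tests show the
statistical machinery is correct under the generative model, not that the
original biological effects would be re-detected in new human data.

## Voxelwise regression and permutation inference

The group design has 10 columns: intercept, AROC (the predictor of
interest), d′, mean confidence, criterion c, the variance-induced confidence
bias, the μ–σ staircase mean-signal difference, age, gender and TIV.
Continuous nuisance covariates are z-scored and gender mean-centred for
conditioning (t-statistics are scale-invariant); AROC stays on its native
scale so the slope is interpretable per AROC unit. Constant columns drop
with a warning; residual rank deficiency raises and names the collinear
columns.

Per in-mask voxel an OLS fit yields the AROC t-statistic with n − p degrees
of freedom, computed by partialling the nuisance columns out of both map and
predictor (algebraically identical to the full-model t; verified against
statsmodels per-voxel OLS to 1e-10). The negative contrast is the
sign-flipped map.

Inference is by permutation rather than random-field theory: exact under
exchangeability, assumption-light, and testable by calibration. Nuisance
covariates are handled Freedman–Lane style — the reduced (nuisance-only)
model residuals are row-permuted and the statistic recomputed, which for the
partialled t reduces to `t(R_Z P R_Z Y)`. Two modes:

* **peak** — maxT over the analysis mask (optionally restricted to the VOI
  mask: the union of 5 mm-radius spheres at the eight published prefrontal /
  precuneus coordinates, intersected with grey matter; each sphere always
  contains the voxel nearest its center so a zero radius degenerates to the
  center voxels);
* **cluster** — supra-threshold clusters (26-connectivity) at the
  cluster-forming threshold `t_{1−p}` (p = 0.001, exploratory 0.005),
  against the maximum-cluster-extent null. Because extents are small
  integers at desk scale, the raw extent null is heavily tied and the
  rank-based p becomes conservative (measured familywise level ~0.03
  instead of 0.05); exact extent ties are therefore broken continuously by
  cluster mass (`statistic = extent + mass/(1+mass)`, which never reorders
  clusters of different extent). Reported `k` is always the plain voxel
  extent.

Tests are one-tailed per signed contrast, mirroring separate
positive/negative analyses. P-values use the tie-safe estimator
`p = (1 + #{perm ≥ obs}) / (1 + n_perm)`, so the smallest attainable p is
`1/(1 + n_perm)`; a warning fires when `n_perm` cannot resolve the requested
α. An empty cluster list is a valid result, not an error.

## Pipeline and determinism

`run_pipeline` chains simulate-behaviour → analyse-behaviour →
simulate-maps → run-vbq and writes a manifest with SHA-256 checksums of
every output. Each stage (and each permutation run) receives a child seed
derived from the master seed and the stage name by SHA-256, so stages are
reproducible independently of execution order and two runs with one master
seed are checksum-identical. NIfTI outputs are written uncompressed so the
bytes are deterministic.

## Problem sizes used in the validation suite

The test suite scales simulations to desk size as its own design choice:
staircase convergence uses single 2500-trial tracks; null calibration of the
familywise error rate uses 200 replicate 24-subject cohorts on a 6 mm grid
with 300 permutations, with the noise kernel scaled to preserve the default
kernel-to-voxel ratio of 2. The reduced grid cannot be made arbitrarily
coarse for the cluster mode: with ~2 expected suprathreshold voxels (8 mm
grid at p = .001) even the tie-broken extent statistic has little to work
with; the 6 mm grid (~6 expected suprathreshold voxels) realizes the
nominal level; planted-effect recovery uses 20 replicate 48-subject
cohorts on a 4 mm grid with 99 permutations; the determinism check runs the
full pipeline twice at 8 mm with 20 permutations. Default runs of the
installed pipeline use the 2 mm grid and 500 permutations.

## Known limitations

* The observer is stationary: no lapses, fatigue, learning or RT–accuracy
  coupling, so the staircase-stability ANOVA is calibrated under a true
  null rather than stress-tested against drift.
* Nuisance fields are spatially uniform; real demographic confounds have
  spatial structure.
* AROC, though standard, is not bias-free under unequal type-I performance;
  the design controls for d′, confidence and c as covariates instead of
  using a model-based efficiency measure (meta-d′ is out of scope).
* The permutation null assumes exchangeable subjects; heteroscedastic
  cohorts would need a studentised variant.
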