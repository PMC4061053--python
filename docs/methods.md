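# Methods

This note documents the models, parameter choices and numerical decisions
behind the package, and what the synthetic data do and do not emulate.

## Stimulus model

A dSFM cylinder is a dot field on the surface of a transparent vertical
cylinder. Each dot carries a phase θ and a height y; the screen projection
is `x = R sin θ` (R = half the field width, 2.5° by default), the screen
speed `R ω cos θ`, and the binocular disparity `s · d_max · cos θ` with
`d_max = 0.09°` center-to-front. Speed and disparity therefore peak at the
cylinder midline and vanish at the edges.

A deliberate design choice: clockwise and counter-clockwise cylinders share
*identical* dot kinematics — θ always advances at +ω — and differ only in
the disparity sign `s` (+1 for counter-clockwise, −1 for clockwise, 0 for a
perceptually ambiguous cylinder). This reflects the physics (the projected
motion of a rotating cylinder is two opposite-moving sheets regardless of
rotation direction; disparity alone assigns which sheet is near) and makes
direction reversal exactly equivalent to negating every disparity, a
property the test suite checks per dot and per frame. Positive disparity is
near (crossed) and attaches to the rightward-moving sheet for
counter-clockwise rotation. The per-eye split is `x_left = x + δ/2`,
`x_right = x − δ/2`; the rendering code is the single place this convention
is defined.

Dot phases are initialized uniformly on [0, 2π); heights are stratified
(one dot per row of spacing height/n) with ±0.5-row uniform jitter — the
jitter magnitude is a free choice, set to the largest value that cannot
produce visible row collisions. Each frame, 2% of dots are deleted and
replotted uniformly in (θ, y) with age reset; phase wrap-around at 2π is a
distinct mechanism that preserves dot age. At 100 Hz this yields a
geometric dot lifetime with stationary mean age (1−p)/p ≈ 49 frames.
Angular speed is rotation about the cylinder axis (so the rotation period
is 360/ω seconds, exactly); the default 138.5 °/s is the midpoint of the
100–177 °/s stimulus range. Dot polarity (half white, half black) and dot
size are carried as metadata; the engine emits coordinates, not rasters.

## Design and observer

One scan: six conditions × 10 blocks × 4 trials × 4 s = 960 s = 240 volumes
at TR = 4 s. "Pseudo-randomized and counterbalanced" is implemented as
rejection-sampled permutation with at most 2 identical consecutive blocks
(no scheme is canonical; this is the simplest constraint that prevents long
runs). The unattended cylinder's rotation direction is fixed within a scan
and alternates across scans; the attended direction follows from the
similarity condition. Attended and unattended rotation speeds are drawn
independently and uniformly from 100–177 °/s, and the unattended cylinder
never changes speed within a trial, so cross-cylinder comparison cannot
solve the task. The within-trial split (interval 1, interval 2, response)
defaults to 1.5/1.5/1 s and is configurable; nothing downstream depends on
it at TR = 4 s resolution.

The observer compares noisy internal estimates of log speed between the two
intervals: `P(correct|r) = λ/2 + (1−λ)Φ(|log r|/(σ√2))`. A cumulative
Gaussian on log ratio is the standard 2IFC link; the √2 reflects the
difference of two single-interval estimates. Defaults σ = 0.35, λ = 0.02
place the true 75%-correct point at a speed factor of ≈1.41, the mean
training threshold the experimental literature reports for this task; the
invalid-cue σ multiplier of 9 puts invalid-cue performance at that factor
near 0.53, matching the reported cost of misdirected attention. These are
calibrations to published behavioral anchors, not fits to data generated
here.

Threshold estimation defaults to a 2-down-1-up staircase (which converges
near the 70.7% point) followed by a maximum-likelihood cumulative-Gaussian
fit to all staircase trials, evaluated at the 75% criterion. The staircase
concentrates trials near threshold, making the ML fit robust at the
~1300-trial training scale; an analytic inversion and a constant-stimuli
fit are provided as alternatives and as oracles for each other. Binomial
confidence intervals are Clopper-Pearson by default (Wald optional), and
the factorial behavioral breakdown is assessed with a permutation test on
the variance of group means rather than a nested ANOVA — the non-parametric
analogue adequate for a type-I control check.

## BOLD generator

Per voxel, the neural drive in percent of baseline is

    s(t) = g_stim·S + g_att·S·A + g_feat·S·U·Same + w_dir·D·S

with indicators defined relative to the cylinder contralateral to the
voxel's hemisphere, and passive (static-dots) volumes exactly zero.
Defaults: g_stim = 1%, g_att = 0.5%, g_feat = 0.05% (the published scale of
global-feature-attention modulation), baseline 100. The drive is convolved
at TR resolution with a gamma HRF whose shape/scale are moment-matched to a
6-s delay and 3-s SD (shape 4, scale 1.5); the kernel integrates the gamma
density over TR bins and is normalized to unit sum so a sustained unit
drive produces a unit plateau. Intensity is
`baseline·(1 + (hrf⊛s)/100 + drift/100) + AR(1) noise` with noise SD 0.5%
of baseline, AR(1) coefficient 0.3, and per-voxel linear drift with SD
0.5% per scan.

Three independent lognormal sensitivity factors (SD of log = 0.3,
normalized to population mean 1) scale g_stim, g_att and g_feat per voxel,
and a zero-mean Gaussian direction preference `w_dir` (SD 0.2%) creates
voxels preferring clockwise or counter-clockwise rotation. The independence
matters: if one factor scaled all gains, every voxel would have the same
temporal *shape* and per-voxel z-scoring would normalize the heterogeneity
away, leaving nothing for pattern classification after ROI-mean removal.
Independent factors give voxels different modulation ratios — the kind of
fine-scale heterogeneity attributed to within-voxel neural subpopulations —
so decoding accuracy grows with the population gain while ROI-average
expectations still equal the population parameters exactly.

ROIs are disjoint slabs on a 20×20×10 grid (x split into hemispheres, y
into one strip per area), 7 areas × 2 hemispheres × 200 voxels, with the
contralateral visual-field mapping. Eye traces are an Ornstein-Uhlenbeck
fixation-jitter process (stationary SD 0.2°, correlation time 0.5 s,
500 Hz) with an optional condition-dependent horizontal offset for
fixation-failure scenarios.

What the generator does **not** emulate: retinotopic eccentricity
structure, spatially correlated physiological noise, motion artifacts, and
non-linear hemodynamics. The absence of spatial noise correlation makes
ROI averages unrealistically precise — with 200 independent voxels the
default 0.05% feature gain is reliably detectable univariately at 15
replicates, whereas in real data comparable effects sit at or below the
noise floor. Passing tests therefore validate the *analysis machinery*,
not claims about detectability in real recordings.

## Univariate analysis

The four active conditions are modeled as HRF-convolved boxcars in a
per-scan OLS GLM; the passive condition is the implicit baseline, so
condition betas are directly contrasts against static dots. Temporal
derivatives are orthogonalized against all non-derivative columns before
inclusion, which makes them latency absorbers that provably leave the other
betas unchanged; rank-deficient designs are rejected with the offending
columns named. %BOLD is `100·beta/intercept` per voxel: the intercept is
the GLM's own baseline-intensity estimate, uncontaminated by task
response, so noiseless amplitude recovery is exact to machine precision
(dividing by the raw temporal mean, the common shortcut, biases amplitudes
by the mean task response, ≈0.7% here). High-pass filtering defaults to a
Gaussian-weighted running-line with a 100-s cutoff — its gentle roll-off
passes the ~96-s block alternation essentially unattenuated — with a
sharp DCT projection available; both preserve the temporal mean, and the
filter is applied identically to data and condition regressors. A global
AR(1) prewhitening option stands in for full autocorrelation modeling.

Replicates are scans (or session averages of two scans, configurable,
matching the ambiguity of replicate pooling in such designs). Per area,
Wilcoxon signed-rank tests assess activation against baseline and
matched-pairs contrasts (attended vs unattended; unattended same vs
different rotation), Bonferroni-corrected over the 7 areas, with a
Kolmogorov-Smirnov normality screen reported alongside. Note the discrete
floor of the signed-rank test: with n replicates the smallest two-sided p
is 2^(1−n), so at least 9 replicates are needed for any corrected rejection
at α = 0.05/7 — the reason replicate-hungry designs pool sessions and
hemispheres to ~15 data points.

## Multivariate analysis

Per ROI: the 100 most activated voxels (stimulus-vs-passive t statistic;
in this synthetic setting the localizer statistic is computed from the
simulated main data rather than a separate localizer scan), per-scan linear
detrending, z-scoring to mean 0/SD 1, regression of the ROI-mean time
course out of each voxel (residuals exactly orthogonal to the mean course),
a one-volume label shift for hemodynamic lag (the final trial of a scan is
clamped to the last acquired volume), and trial-pair averaging into
patterns. Three comparisons are defined from the contralateral cylinder's
viewpoint: spatial attention (all active trials), attended rotation
direction (contralateral-attended trials), and unattended same-vs-different
rotation (contralateral-unattended trials) — which yields exactly twice as
many patterns for the spatial comparison as for the feature comparisons.

Two decisions deserve emphasis:

- **Pairs and folds respect blocks.** Trials are paired within their block
  and cross-validation folds are built over whole blocks (stratified by
  class, re-drawn if a training split would lack a class). Temporally
  adjacent trials share autocorrelated noise and the same condition label;
  letting them straddle the train/test boundary inflates null-signal
  accuracy to ≈0.6 in this generator. Block-level folds restore chance on
  null data while keeping 5-fold cross-validation and the 2:1 pattern
  ratio.
- **Empirical mean removal is imperfect.** When the only signal is a
  uniform additive gain, the estimated ROI-mean course and per-voxel
  normalizers are noise-contaminated, leaving scan-specific magnitude-only
  class structure that a linear SVM *anti-learns* (accuracy systematically
  below chance, never reliably above the permutation null). Univariate
  leakage into patterns is thus abolished in the one-sided sense that
  matters for inference; genuinely distributed signals (heterogeneous
  gains, direction preferences) decode above chance.

Classification is a linear SVM with C = 1.0 (no feature scaling beyond the
z-scoring, no hyperparameter search), 5-fold cross-validation, and 10,000
default iterations that re-randomize trial pairing and fold assignment
(what varies across iterations is not canonical; pairing and folds are the
two randomized ingredients here). Significance uses an empirical null from
label-shuffled re-runs with identical parameters: the observed mean is
significant when strictly outside the null's Bonferroni-corrected 95%
percentile interval. Fewer than 100 permutations triggers an instability
warning. Fixed seeds make the entire pipeline bit-reproducible.

## Eye-movement controls

Per-trial mean positions are compared across conditions with two-sample
t-tests after removing linear baseline drift across the trial sequence
(optionally z-normalizing for uncalibrated recordings; detrending precedes
normalization). Because a pro-saccade and its return cancel in the mean,
trial-wise classification of horizontal traces (down-sampled to 50 bins,
the same SVM/permutation machinery, trials not pair-averaged) complements
the mean test: side decoding pools the similarity conditions, similarity
decoding runs within each side and averages the two observed means and
nulls. A constructed zero-mean biphasic excursion verifies the designed
dissociation: invisible to the mean test, detected by the classifier.

## Problem sizes and tolerances

The test suite validates statistical guarantees at sizes chosen for a
single CPU: familywise type-I control uses 500 simulated null datasets
(14 small ROIs, 15 replicate scans each) with a two-binomial-SE Monte-Carlo
allowance on the α = 0.05 bound; gain recovery averages 50 datasets at
noise SD 0.2% (tolerance 10%); decoding monotonicity uses a three-point
gain grid averaged over seeds; permutation-null centering uses 1000
shuffles (tolerance [0.48, 0.52]); threshold recovery uses the 1295-trial
training length (tolerance 5%). Degenerate inputs are defined errors:
empty ROIs, non-positive speeds or ratios, rank-deficient designs,
single-trial conditions, zero-variance voxels (excluded with a log entry),
and identical samples in location tests (p = 1 by convention).
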