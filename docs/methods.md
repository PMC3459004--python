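# Methods

This note documents the models implemented in `dyadscan`, the choices
made where the design was genuinely open, and what the synthetic data do
and do not establish about real recordings.

## The paradigm being emulated

Two participants lie in separate scanners, see each other's eyes in real
time, and perform a gaze-cued joint-attention task. Trials last 5 s: 2 s
of plain eye contact, a 2.5 s cue period in which one ball target changes
colour (or the partner's gaze moves), and a 0.5 s blank. The same
condition repeats three times per 15 s block. Runs come in two flavours:
*concordant* (look at the cued target; conditions ES, BS, control SBNc)
and *discordant* (look away from it; EN, BN, control SBNd). Labels are
complementary across partners: a ball cue on P's screen is an eye cue
from Q's point of view. Acquisition bookkeeping: TR = 3 s, 85 volumes per
run, the first five discarded (80 retained = 240 s = 16 blocks), six runs
per subject, 480 retained volumes in total.

## Synthetic dyadic BOLD

Per voxel the generator emits

    y(t) = sum_c beta_c(v) (boxcar_c * HRF)(t) + drift(t) + noise(t)

* **Task effects.** Cue-period boxcars convolved with the canonical
  double-gamma HRF at 16x oversampling. Default amplitudes place a common
  visual response (0.5) in the "OP" box ROI for every cued condition and
  an extra eye-cue response (to 1.0, plus 0.5 in "STS") for ES/EN —
  eye-cue processing engages gaze-specific regions. Eye-contact-only
  trials evoke nothing: eye contact is the baseline state.
* **Drift.** A cosine of period 256 s and unit default amplitude with
  random phase, safely inside the 128 s high-pass stop band.
* **Noise.** Stationary AR(1), lag-1 coefficient 0.3, marginal SD 1
  (all amplitudes are expressed in noise-SD units).
* **Inter-brain coupling.** For true pairs only, voxels inside the
  "IFG_seed" ROI mix their noise with a pair-specific latent
  `sqrt(1-c)*own + sqrt(c)*shared`. Both components have equal marginal
  variance, so the expected inter-brain voxel correlation inside the ROI
  is exactly `c`; `c = 0` reproduces the uncoupled draws bit for bit
  because the latent is drawn from a separate generator stream. The
  latent is band-limited to 0.01-0.06 Hz so that it survives the
  connectivity band-pass.
* **Block-transition transient.** A 0.5 s response (amplitude 0.5) at
  every 15 s block boundary, confined to "OP" and deliberately absent
  from the condition regressors. This reproduces the empirical
  observation that the task effect is never completely removed from
  residuals: the block lattice has its fundamental at exactly
  1/15 ~ 0.067 Hz, which the HRF attenuates only mildly. Pure
  HRF-parameter mismatch on the cue boxcars cannot produce this peak —
  with three 5 s trials per block the cue train's 1/15 and 2/15
  components cancel exactly, and its leakage lands instead at the aliased
  trial harmonics (0.2 Hz folds to 2/15 at TR = 3 s). A switch-locked
  transient is the parsimonious mechanism that puts the residual peak
  where it is observed.
* **ROIs.** Three disjoint boxes scaled to any grid ("OP", "IFG_seed",
  "STS"); spatial realism is out of scope. Default grid 16 x 16 x 12 at
  4 mm; tests use smaller grids.

Two residual-level shortcuts mirror the voxel model for Monte-Carlo work:
`simulate_coupled_residuals` (pairs sharing a variance fraction `c`) and
`simulate_connected_residuals` (a per-subject latent driving "IFG_seed"
and, scaled by a per-subject weight, "STS" — the generative picture
behind seed-to-voxel connectivity).

**Behaviour.** Accuracy = cell mean + N(0, 0.06), clipped to [0, 1].
Baselines 0.93/0.91/0.96/0.95 for ES/EN/BS/BN; deficits of 0.15 (ASD) and
0.04 (their typically-developed partners) in the eye-cued conditions
only; group sizes 21/21/19/19. These values produce the qualitative
pattern the analysis is designed to detect — group differences confined
to eye cues — at realistic effect-to-noise ratios.

## First-level model

Design matrix per run: one HRF-convolved regressor per condition present,
`floor(2 * duration / 128)` orthonormal DCT drift columns (every
frequency at or below 1/128 Hz; 3 columns for a 240 s run), and an
intercept. Runs concatenate with shared condition columns and
run-specific nuisance columns; rank is checked and deficiency raised.

Serial correlation: a single AR(1) coefficient pooled over voxels and run
segments (ratio of summed lag-1 cross-products to summed squares of the
OLS residuals), then exact whitening per run (`x_0 * sqrt(1-rho^2)`,
`x_t - rho x_{t-1}`) and whitened least squares. Per-voxel rho is out of
scope. Two numerical facts worth knowing:

* The direct estimator recovers rho to +-0.01 at T = 1e5 and +-0.05 at
  the study length T = 468 on raw AR(1) series. The *pooled estimate from
  fitted residuals* is attenuation-biased (about 0.22 for a generating
  0.3): the design projection absorbs low-frequency autocorrelated power.
  This mirrors the behaviour of any residual-based AR estimate and does
  not affect the coherence analyses, which only need approximately
  whitened residuals.
* Whitened residuals are orthogonal to the whitened design at machine
  precision; the residual *series* handed to downstream analyses drops
  the first two volumes of each run **before** concatenation (the per-run
  reading of the discard rule) — 6 x (80 - 2) = 468 samples.

Contrasts: primed maps (ES' = ES - SBNc etc.), and the 2 x 2 effects on
them; the controls cancel, so eye-cued = (ES + EN) - (BS + BN) on the raw
coefficients. Smoothing is Gaussian with sigma = fwhm / sqrt(8 ln 2),
reflective boundaries (preserves image sums, hence ROI means, on small
grids).

High-pass behaviour, measured on the 240 s run basis: a 256 s-period
sinusoid loses >= 99% of its power (quadrature average over phase; the
worst single phase is 98.5%) and a 32 s-period sinusoid keeps >= 95%.

## Inter-brain analysis

All nA x nB combinations are enumerated with a deterministic ordering;
the true-pair map is a bijection. Correlations are clipped to
|r| <= 1 - 1e-6 before `artanh` so identical series give a finite z. The
Experiment x Pairing ANOVA treats all 802 combinations as independent
observations — deliberately reproducing the original analysis although
pseudo-pairs reuse subjects; `pairing_permutation_test` is provided as a
dependence-aware companion (it permutes which partner belongs to whom,
preserving the shared-subject structure) and is *not* part of the
emulated analysis. Under the null the combination z values are
uncorrelated, and the ANOVA's type-I rate measures at 0.05 +- 0.02 over
500 replicates; with c = 0.2 at n = 21 true pairs, power exceeds 90%.

One magnitude caveat: the generator's latent is perfectly coherent across
ROI voxels, so ROI-mean series correlate far more strongly than single
voxels (averaging k voxels shrinks only the idiosyncratic noise). The
ROI-level pairing F on paper-shaped synthetic data is therefore orders of
magnitude larger than anything a real study reports; the calibrated
quantities are the rejection rates, not the F magnitude.

## Connectivity

Band-pass 0.01-0.06 Hz, Butterworth applied forward-backward (zero
phase). The default prototype order is 8: at TR = 3 s this yields
measured attenuation of 25 dB at the 0.067 Hz task fundamental and < 1 dB
ripple across 0.02-0.05 Hz; a 4th-order prototype would only reach about
13 dB after the two passes and would let the task leakage through.
"Connectivity strength" for the behaviour correlation is the mean z
inside the significant cluster of the group comparison — the analysis
leaves this implicit, so the operationalisation is documented here.
Filtering shrinks the effective sample size of correlation noise well
below T (the null z SD corresponds to roughly 100-200 effective samples
at T = 468), which the tests estimate empirically rather than assume.

## Group level

Cluster-level familywise error is controlled by group-label permutation
of the maximum cluster size (18-neighbour connectivity), replacing
random-field theory: assumption-light and exactly testable at desk
scale. p_FWE = (1 + #{null max >= observed}) / (n_perm + 1). The test is
valid (never anticonservative) but discrete: with high cluster-forming
thresholds on small grids the achievable p values are coarse and the
empirical FWE drops below nominal; calibration lands at 0.05 +- 0.02 with
a two-sided forming threshold of p = 0.05 on a 6 x 6 x 4 grid with 8
subjects per group. The factorial module tests a 2 (group, between) x 2
(cue) x 2 (attention) layout by carrying each within-subject contrast to
the subject level and applying one- or two-sample t maps.

## Behavioural ANOVA

The mixed-design decomposition is authored here rather than delegated:
the Greenhouse-Geisser epsilon must correct the Group x Task interaction
as well as the Task main effect, which off-the-shelf mixed-ANOVA routines
do not do. Epsilon is the standard doubly-centred-covariance estimator
computed on the *pooled within-group* covariance (group means removed so
group separation cannot masquerade as non-sphericity); it is bounded in
[1/(k-1), 1] and equals 1 exactly at k = 2. The sums of squares match
`pingouin.mixed_anova` to machine precision (cross-checked in the tests),
and epsilon matches `pingouin.epsilon` on group-centred data. Corrected
p values can only increase for effects with F >= 1; for F < 1 the df
shrinkage can move p either way, which is immaterial since nothing there
is significant. Accuracy is analysed untransformed.

## Problem sizes

Tests and the acceptance script run the full generative pipeline at
reduced spatial resolution (grids from 6 x 6 x 4 to 10 x 10 8) with the
study's temporal structure intact (6 runs x 85 volumes, TR 3 s), 500
replicates for the power/type-I calibrations and 200 permutations x 500
outer replicates for the FWE calibration. These sizes make every
stochastic claim checkable in seconds while leaving the temporal
statistics — the quantities the method actually rests on — at full scale.

## Known limitations

* No spatial realism: box ROIs, no anatomy, no smoothing-induced spatial
  autocorrelation in the generator (smoothing exists as an operation but
  the calibration suites run unsmoothed).
* No physiological noise (cardiac/respiratory), motion, or
  scanner-specific field effects beyond a noise-SD knob.
* The pooled AR(1) residual estimate is attenuation-biased (above).
* The pairing ANOVA inherits the original analysis's independence
  assumption across combinations; use the permutation companion when
  that matters.
* Passing calibrations on synthetic data show the *machinery* is
  correct and calibrated under the stated generative model; they cannot
  certify real-data effect sizes or anatomical claims.
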