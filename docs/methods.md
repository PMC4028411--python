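# Methods

## Problem and scope

The package implements a source-space MEG analysis of oscillatory coupling
during cued memory retrieval: a 1-s pre-cue fixation window is contrasted
with the 0.5–1.5 s post-cue window, per trial, in three bands (theta
4–8 Hz, low gamma 30–45 Hz, high gamma 65–85 Hz). Sensor epochs are
projected to a 10-mm voxel grid with an LCMV scalar beamformer; a
frontal-midline theta seed is chosen per subject; theta phase coupling
(PLV, PLI) and theta-phase → gamma-amplitude coupling (envelope-phase PLV)
are mapped from the seed to every voxel; per-trial confounds are removed
by linear regression; and condition differences are tested across subjects
with one-sample t maps, cluster-extent thresholding and sign-flip
permutation FWE correction.

Because no recordings are available, validation is by parameter recovery:
a synthetic generator plants every effect at known voxels with known
magnitudes, and the pipeline must find them — and must stay silent when
they are absent.

## Signal model and estimators

**Windows.** Baseline = [−1, 0) s and cue = [0.5, 1.5) s relative to cue
onset; half-open sample ranges, times rounded to the nearest sample (480
samples each at 480 Hz). Both windows are equally long so finite-sample
bias of the coupling metrics cancels in the contrast.

**Filtering.** Zero-phase forward–backward Butterworth (order 4 per pass).
The full epoch (0.5 s of context on each side of the analysis windows) is
filtered and Hilbert-transformed before cropping: a 4-Hz component in an
isolated 1-s window would be badly distorted. Phases are wrapped to
(−π, π].

**Band power.** Mean squared band-passed signal over the window (a unit
in-band sinusoid gives 0.5).

**Beamformer.** For voxel *n* with lead field `l_n` and regularised sensor
covariance `C_r = C + γ·mean(diag C)·I` (γ = 0.05 by default):

    w_n = (l_nᵀ C_r⁻¹ l_n)⁻¹ C_r⁻¹ l_n,

the unit-gain (`w_nᵀ l_n = 1`) minimum-variance linear estimate. The
covariance pools the baseline and cue windows of all trials (a common
filter), so condition differences cannot be artifacts of differing
weights. Power maps are normalised by the projected sensor white-noise
power `σ²·w_nᵀw_n`, with σ² defaulting to the smallest covariance
eigenvalue. Sources are scalar (fixed orientation); free-orientation
optimisation is out of scope.

Filtering, the Hilbert transform and the beamformer projection are all
linear and time-invariant, so the pipeline filters at sensor level and
projects the complex analytic signal — identical to filtering virtual
electrodes (checked in tests to 1e-7) and roughly twice as fast when
voxels outnumber sensors.

**Coupling metrics.** Within each trial window with seed phase φ_s(t) and
target phase φ_v(t):

    PLV = |⟨exp(i(φ_s − φ_v))⟩_t|
    PLI = |⟨sign(wrap(φ_s − φ_v))⟩_t|,  sign(0) = 0

PAC uses the double-Hilbert construction: gamma-band filter the target,
take the analytic amplitude, theta-band filter that envelope, take its
analytic phase, and compute the PLV of that phase against the seed theta
phase. The envelope's theta-band filtering removes its DC; no further
detrending. Per-trial values are averaged per condition before
second-level testing. The PLV's positive bias at 480-sample windows is not
corrected — it is identical in the two equally long windows and cancels in
the contrast.

**Seed selection.** The subject seed is the voxel with the largest theta
cue-minus-baseline contrast within 20 mm of the group peak, ties broken by
distance then index. The group peak is the argmax of the group-average
contrast map — not of the t map, whose argmax can land on distant voxels
with minute but hyper-consistent leakage (tiny variance inflates t without
any source nearby). Inference still runs on the t map.

**Confound regression.** Per-trial covariates over all 72 trial-windows
(36 baseline + 36 cue): eye-movement variance for power maps; eye variance
plus seed power plus per-voxel source power for coupling maps. Covariates
are z-scored (sample sd); the response is regressed on them plus an
intercept, pooled over conditions, and residuals carry the condition
labels forward. Condition itself is deliberately *not* a regressor — it
would remove the effect under test. Each voxel's regression gets its own
source-power column; at the seed voxel that column duplicates the seed
power covariate and is dropped.

**Group statistics.** Per-voxel one-sample t over subjects (df = n−1),
z-values by matching upper-tail probability (clipped at |z| = 8),
one-sided threshold p < 0.001, 6-connected clusters (faces only) with
minimum extent 10 voxels. Cluster FWE p-values come from sign-flip
permutation: under the null of symmetric subject effects, flipping whole
subject maps is exchangeability-preserving; the null distribution of the
maximal supra-threshold cluster extent gives
p = (1 + #{null max ≥ observed})/(n_perm + 1). This replaces
random-field-theory correction: it is distribution-free and exactly
implementable for a one-sample design.

## The synthetic generator

Each subject contributes 36 trials of 3.5 s (t ∈ [−1.5, 2.0] s) at 480 Hz,
each trial containing both analysis windows; cue-condition parameters act
only inside the cue window (50-ms cosine ramps). Three scalar sources on
the grid are mixed into 32 sensors through Gaussian-profile lead fields
(spatial scale 25 mm, 5% fixed random perturbation): neighbouring voxels
project to overlapping sensor patterns, which is exactly the zero-lag
leakage ("volume conduction") the PLI is meant to discount.

* **Seed source** (frontal-midline analogue): theta oscillator with
  smoothly jittered instantaneous frequency (6 ± 0.8 Hz, OU-smoothed);
  amplitude 3.0, multiplied by √power_ratio (default 2.0) in the cue
  window. Its grid location is drawn per subject from the voxels within
  20 mm of the reference voxel, emulating between-subject variability in
  frontal-midline source location.
* **Coupled source** (MTL analogue, amplitude 1.5): phase
  φ_seed + lag + ε(t) with lag = π/4 and ε a slowly varying (τ = 0.25 s,
  twice-smoothed AR(1)) Gaussian phase jitter whose sd is matched to the
  requested von Mises concentration via σ = √(−2 ln(I₁(κ)/I₀(κ))), so the
  long-run PLV of the pair equals the Bessel ratio of κ. κ defaults to 0.8
  (baseline) → 1.6 (cue). *Why not iid von Mises jitter?* White phase
  noise spreads the source's power out of the theta band as κ falls, so a
  coupling change would masquerade as a band-power change and the power
  regressors would absorb the genuine effect; with the smooth jitter, band
  power moves < 25% over a 5× range of κ while the PLV doubles. The
  low-level `simulate_coupled_phases` keeps the iid von Mises contract for
  metric validation against the Bessel-ratio oracle.
* **PAC source** (parietal analogue, amplitude 1.5): gamma carrier
  (75 ± 2 Hz) with envelope (1 + m·cos φ_seed)/√(1 + m²/2) — the
  normalisation keeps gamma power independent of the modulation depth m
  (default 0.15 → 0.6).
* **Artifact**: a slow (τ = 0.3 s) unit-variance process scaled per trial
  by a variance drawn uniformly from [0.5, 1.5], injected through its own
  random sensor topography; an optional condition gain correlates it with
  condition for confound tests. The realised artifact variance per
  trial-window is recorded as the eye-movement covariate (ICA extraction
  from sensor data is out of scope; the generator supplies the covariate).
* **Sensor noise**: iid Gaussian, sd 1.0.

All source amplitudes carry per-trial log-normal jitter (log-sd 0.35).
Without it, per-trial power covariates would be nearly collinear with the
condition label and the confound regression would strip the effect of
interest; with it, power varies across trials within condition, as real
rhythms do.

Randomness: one top-level seed; per-subject streams from
`(seed, subject_id)`; lead fields and artifact topographies from dedicated
sub-streams. Same seed ⇒ bit-identical output.

### What the generator does not emulate

No head geometry or Maxwell physics (lead fields are abstract smooth
profiles), no 1/f background spectrum, no non-stationary artifacts, no
heartbeat/line noise, no source orientation dynamics, and sensor noise is
white. Passing recovery tests therefore demonstrates the *estimators and
inference machinery* are correct under a controlled forward model — not
that the pipeline is robust to every property of real MEG noise.

## Parameter defaults and why

| parameter | default | rationale |
|---|---|---|
| n_subjects / n_trials | 17 / 36 | the study geometry |
| fs / windows | 480 Hz / 1-s each | the study geometry |
| grid | 4×4×4 at 10 mm | smallest grid on which the 10-voxel cluster-extent rule is meaningful |
| n_sensors | 32 | enough spatial rank to resolve 64 voxels with regularisation |
| seed amplitude / noise sd | 3.0 / 1.0 | clean seed: power-ratio recovery bias < 5% |
| coupled amplitude | 1.5 | moderate SNR: PLV at the coupled voxel sits mid-range (~0.6), sensitive to both κ and SNR confounds |
| κ baseline→cue | 0.8 → 1.6 | Bessel ratios 0.37 → 0.58; yields paper-like per-subject consistency (≥14/17) without being trivially strong |
| pac depth | 0.15 → 0.6 | detectable against the envelope-phase null (~0.35 at 1-s windows) |
| reg_fraction | 0.05 | standard few-percent Tikhonov loading |
| p_voxel / min_extent / α | 0.001 / 10 / 0.05 | the study's thresholds |

## Numerical choices

* Phase wrap via `angle(exp(iφ))`, giving (−π, π] exactly.
* The coupling stage caches the source-space analytic signal in single
  precision (complex64); metric values agree with the double-precision
  path to ~1e-7, far below any scientific resolution here.
* Coupling values are clipped to [0, 1] after a 1e-6 tolerance check
  (float roundoff can produce 1 + 1e-8 on perfectly locked pairs).
* Zero-variance voxels in the group t map are masked to NaN with a
  warning; NaNs never enter cluster formation.
* `select_seed` tie-breaks: contrast, then distance to the group peak,
  then voxel index — fully deterministic.
* Degenerate confounds: constant covariates raise; rank-deficient designs
  raise and name the collinear columns (except the documented seed-voxel
  source-power duplication, which drops the column).

## Problem sizes used in validation

The validation suite runs cohort simulations at the full study geometry
(17 subjects × 36 trials × 480 Hz × 1-s windows) for the recovery and
confound experiments — 50 repetitions for the coupling-recovery rate with
199 permutations — and a compact geometry (8 subjects, 18 trials, 16
sensors, 3×3×3 grid) for the 100-run zero-lag specificity experiment and
other calibration loops. The statistical-calibration checks use direct
Gaussian null maps (no MEG simulation), 200 runs on a reduced grid. These
sizes are the package's chosen validation design; rates quoted in test
assertions (e.g. ≥ 80% recovery, ≥ 95% specificity) refer to them.

## Known limitations

* The beamformer's leakage at 32 sensors / 64 voxels is substantial, so
  significant coupling clusters are spatially extended rather than focal;
  detection is assessed as "a significant cluster covering the planted
  voxel or a 10-mm neighbour".
* Residualisation removes only *linear* power dependence of the coupling
  metrics; near the seed, leakage-driven effects can survive it. Voxels
  within the seed search radius are flagged `seed_adjacent` in reports and
  should not be interpreted.
* The PLV/PLI values at 1-s windows carry the usual positive
  finite-sample bias; only contrasts between equally long windows are
  interpretable.
* Window edges sit 0.5 s from the epoch edges; at 4 Hz a ~2–3% power bias
  from residual filter transients is possible, common to both conditions
  to first order.
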