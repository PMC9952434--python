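# Methods

## Scope and model

The package computes, per ECG epoch, the biomarker panel
{mean RR, HR, LF, HF, LF/HF, DC, PRD} from a 4-electrode
Wilson-tetrahedron recording, and compares paired conditions with
Shapiro–Wilk + paired t statistics. The signal model underlying every
stage is the single-dipole approximation: the body-surface potentials are
linear in a rotating heart vector, so four well-placed electrodes
determine its direction (exactly) and magnitude (up to the lead-field
model embodied in the gain K).

## Preprocessing

* Band-pass: 4th-order Butterworth, 2–26 Hz, applied forward–backward
  (`sosfiltfilt`), i.e. an 8-pole zero-phase magnitude response. The
  family/order is our choice (maximally flat passband; standard for ECG
  morphology). Edges are reflect-padded over three low-cut time constants
  (3·fs/low_cut samples) so the transient stays out of the analysis span;
  signals must exceed that span.
* Isoline: the per-channel median over the recording is subtracted after
  filtering — robust to QRS outliers; manual visual quality control is
  replaced by logged per-channel quality flags (non-finite fraction, RMS).
* Common-average re-reference: subtracts the per-sample mean of the four
  channels. Lead *differences* are invariant under it, hence so are the
  direction cosines; only the V_B² term of the gain K sees the reference.
  Recordings are analysed at unit gain ("scale = 1"); a config `gain`
  field exists.

## Tetrahedron → VCG

Coefficients (the 1/22 matrix, and K = (1/33)·√(8E² + V_B²) with
E² = (V_L−V_R)² + ⅓(V_F−V_R + V_F−V_L)², the Einthoven frontal-plane
magnitude) are stored in `data/vcg_coefficients.txt` with a provenance
comment; a corrected transcription is a data change. Every property the
tests rely on — unit-norm direction cosines, invariance under positive
lead rescaling, sample locality, |V| = 3K, forward/inverse round trip —
holds for any fixed, invertible coefficient set.

Samples where all three differences vanish have no defined direction;
they are bridged by linear interpolation and counted (warning above 5 %,
refusal above 50 %) rather than silently propagating NaNs.

## Delineation

R-peaks: squared vector magnitude, 15 ms moving average, adaptive
threshold at 0.4× the rolling 2 s maximum, 250 ms refractory, peak
refinement to the local |V| maximum — a Pan–Tompkins-class detector with
no training and deterministic output. The "QRS mark" anchoring the
T window is the R-peak (config `qrs_mark`); "RR of beat i" is the
*preceding* interval (config `rr_mode`) — the alternative readings shift
windows by a constant and were judged immaterial, but both switches are
exposed and logged.

Ectopic rule: sequential, strict 20 % comparison against the last
*unflagged* RR; the first interval is accepted by definition; flagged
beats do not update the reference. This makes the rule idempotent and
flags both halves of an early-beat/compensatory-pause pair.

T windows: Ton = R + 90 ms; Tend = R + min(360 ms, ⅔·RR), so the 360 ms
cap binds for all RR ≥ 540 ms (and a fortiori for the conventional
RR ≥ 720 ms statement of the rule). ms→samples rounding is
nearest-integer, ties up, so windows are stable across platforms. Windows
that leave the recording or reach the next R-peak are invalid.

## HRV spectra

The RR series is unevenly sampled, so the PSD uses cubic-spline
resampling at 4 Hz over unflagged beats (ectopic beats removed *before*
interpolation, the spline bridging the gap), linear detrend, Hann window,
single-segment FFT periodogram. Welch averaging is deliberately not used:
a 2-minute epoch cannot afford segment averaging at 0.04 Hz resolution.
The periodogram scaling preserves total power, so a sinusoidal modulation
of amplitude a contributes a²/2 inside its band, and the PSD integral
matches the detrended series variance (Parseval, tested at 5 %). Band
integrals place the band edges exactly on the integration grid
(interpolating the PSD there), making adjacent bands tile additively.
LF/HF with zero HF power is reported as NaN (undefined), not infinity.
All method metadata is recorded in the result.

## PRSA, DC, PRD

Window convention k = −L…L−1 with the anchor at k = 0 (X₁ exists for all
L ≥ 2). Edge exclusion is applied at *both* ends — windows are two-sided,
so anchors in the first L beats are as undefined as in the last L. Ties
are never anchors (strict inequalities). Windows containing an
ectopic-flagged beat are dropped, not interpolated. The optional guard
excluding RR prolongations > 5 % (common in DC practice) is implemented
but OFF by default. L is a free parameter with defaults 12 (DC) and 20
(PRD); M = 9 for the PRD averaged-comparison anchors. Acceleration
capacity is computed internally only, for symmetry testing
(DC(c−x) = −AC(x) exactly).

dT° is unsigned (arccos of the normalized dot product) — the dot-product
construction carries no sign. Pairs straddling dropped beats are excluded
and retained pairs keep true timestamps, preserving the oscillation's
frequency content. The "10th-order median filter" is read as an 11-tap
centered window (odd windows have a unique center; config
`prd.median_window`), reflect-padded. T vectors with norm < 5 µV (config)
are invalid — angles between near-zero vectors are meaningless.

## Synthetic data: what it emulates, and what it does not

The generator produces the study conditions the pipeline targets:

* RR: mean 800 ms; LF sinusoid 38 ms at 0.10 Hz and HF sinusoid 38 ms at
  0.25 Hz (band powers a²/2 ≈ 722 ms², the scale of a resting cohort);
  white beat-to-beat jitter 10 ms; 2-minute epochs; optional isolated
  ectopics (30–50 % early beat + compensatory pause preserving cumulative
  time), the exact discontinuity the 20 % rule targets.
* Morphology: Gaussian P/QRS/T lobes per axis at 250 Hz (a config field —
  no device rate is assumed); QRS triphasic along a fixed direction at a
  12° spatial angle to the T axis (healthy hearts: < 30°); T amplitude
  500 µV, σ 50 ms, peak at R + 220 ms; P 40 µV. The T direction of beat i
  is rigidly rotated by A·sin(2π·0.05·tᵢ + φ) about a fixed axis
  orthogonal to the base direction — a rigid rotation isolates the angle
  signal PRD measures from amplitude effects. Defaults: A = 6° at rest,
  12° under simulated cold pressor (the manipulated quantity), giving a
  consecutive-beat angle signal of ≈ 1.5–3° peak, the scale seen in dT°
  series, and PRD ≈ 0.15 vs 0.24°.
* Leads: the tetrahedron transform is inverted per sample — K is
  homogeneous of degree 1 in the lead differences, so the difference
  scale can be chosen to make the reconstructed VCG equal the source
  exactly — then per-channel offset, 50 µV / 0.3 Hz baseline wander, and
  2 µV white noise are added. Everything is deterministic per seed, and
  every recording carries machine-readable truth (fiducials, RR, ectopic
  flags, per-beat T directions and rotation angles).

Not emulated: conduction-system physiology, respiration–ECG coupling
beyond the stated HF modulation, pathological morphologies, electrode
motion artifacts. Passing tests therefore demonstrate correctness of the
measurement chain under the stated signal model, not robustness to every
real-world artifact.

### The band-pass angle floor

A characterized interaction worth knowing: the 2–26 Hz zero-phase filter
spreads each wave's low-frequency counterweight over hundreds of ms, so
neighbouring-beat tails reach into the T window, and RR variability
modulates that leakage beat-to-beat. With the defaults above this sets an
intrinsic dT° fluctuation of ~1° raw (PRD floor ~0.13°) that is
*independent of channel noise* and masks sub-degree rotation sweeps
end-to-end. Consequently (a) the angle-measurement chain itself is
validated on the unfiltered vectorcardiogram, where injected rotations of
0.1–0.4° are recovered to < 0.05° and channel noise is the only error
source, and (b) the end-to-end contrast uses oscillation amplitudes (6°
vs 12°) sized — mirroring the detectability of the effect the marker is
known for — so the paired design separates conditions well above that
floor (p < 0.001 at n = 17 in the worked example). The floor itself is a
property of the filter choice, not of the implementation.

## Statistics

Shapiro–Wilk on paired differences, paired t-test per biomarker, means ±
SE (SD/√n); zero-variance differences are reported as degenerate (p NaN,
or 1.0 for all-zero) rather than p = 0. Standard library implementations
(scipy.stats) are used — the tests are textbook procedures, not a
contribution. No multiplicity correction is applied to the headline
p-values across the seven biomarkers; a Holm-adjusted column is emitted
alongside, labelled as an extension. An unpaired (Mann–Whitney) mode is
not part of the headline path.

One unit note: PRD is reported in degrees (max − min of the averaged
curve). Parts of the PRSA-repolarization literature report deg²; the
discrepancy is noted here and not resolved — values are comparable only
within one convention.

## Problem sizes

Default epochs are 120 s (~150 beats) at 250 Hz; the cohort is 17
subjects × 2 conditions; the acceptance script analyses one such cohort
(34 recordings) plus two closed-form checks, and the test suite's
end-to-end test runs 20 replicate cohorts. A full cohort simulates and
analyses in a few seconds on one core.
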