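# Methods

This note records the models implemented in csdflow, the parameter choices
that matter, and the numerical decisions taken where the underlying
measurement conventions are genuinely open.

## Conventions

Time is in seconds on the experiment clock with t = 0 at KCl application;
frame k of a movie maps to t₀ + k/rate; every analysis window is half-open
[start, end). Pixel coordinates are 0-based row-major; ROIs are axis-aligned
rectangles (widefield) or explicit pixel sets (two-photon). Missing
acquisition metadata (frame rate, pixel pitch, trace unit) is always an
error, never a default — a silently guessed frame rate corrupts every
downstream speed and interval estimate.

## Widefield analysis

**ΔF/F.** Baseline F is the mean intensity over the 40 s window ending 20 s
before KCl application, computed once per ROI; the output is (x − F)/F. F is
not recomputed after the post-CSD baseline decrement, so late-recording
relative amplitudes are measured against the original pre-KCl state.

**Wave detection.** Threshold = baseline mean + 5 SD on the *unfiltered*
ΔF/F trace, with baseline statistics from the same 40 s pre-KCl window used
for F. An event starts at an upward threshold crossing (linearly
interpolated between samples) and ends when the signal falls below half its
running peak; a new event requires a fresh crossing at least 10 s after the
previous event ends — far below the shortest physiological inter-CSD
interval (~280 s), so the guard can only merge noise, never split waves.
Candidates that stay above threshold for less than `min_duration_s` (default
1 s) are rejected: a genuine CSD wave remains supra-threshold for tens of
seconds, while a bare single-sample rule would fire on the rare Gaussian
excursions expected beyond 5 SD in multi-minute recordings. One second at
10 Hz is two orders of magnitude below real wave durations and therefore
physiologically inert.

**Peak, arrival, passage.** The peak is refined with a cubic interpolating
spline on a ±2 s window around the discrete maximum (wide enough at 10 Hz to
span the peak without flanking dynamics); the continuous maximum is never
below the discrete one, and a window truncated by a trace edge falls back to
the discrete maximum with a warning. Arrival and passage are the half-peak
up- and down-crossings, linearly interpolated; their difference is the wave
duration. Speed uses arrival (half-max) times, not onsets, matched across
ROIs by rank order; non-positive transit times are returned as NaN with a
warning rather than dropped.

**Band-limited amplitude.** Slow-wave (0.5–2 Hz UP/DOWN-state) activity is
quantified as the RMS of the 0.1–3 Hz band in consecutive non-overlapping
5-min windows. The filter is a second-order Butterworth band-pass applied
forward-backward (zero-phase), so filtering cannot shift the event timings
used elsewhere; its gain at 1 Hz after the two passes is 0.9996, which is
why amplitude-recovery tolerances of 2% are achievable. Recovery curves
divide each windowed RMS by the mean over the 10-min pre-KCl reference.

## Two-photon analysis

Per-pixel ΔF/F uses that pixel's pre-CSD temporal mean as F; pixels with
non-positive F are masked (NaN) and reported. The high-Ca²⁺ rule marks a
pixel-frame when ΔF/F exceeds that pixel's reference-window mean + 4 SD —
per-pixel statistics, consistent with the per-pixel ΔF/F normalization. The
reference window defaults to the pre-CSD period and is configurable;
zero-variance pixels are excluded and counted. P(High Ca²⁺) is the high
pixel-frame count divided by (valid pixels × evaluation frames), computed
per soma and pooled over the entire non-soma region for gliopil. Soma ROIs
come from connected components of the astrocyte-marker mask within an area
band; touching somata merge (splitting them is out of scope), and the
non-soma region excludes a 2-px dilation ring around each soma. Gliopil ROI
selection reuses the same 4 SD rule: non-soma pixels supra-threshold at
least once in any reference period. Because the threshold statistics come
from the same period being scanned, pixels whose events occupy a large
fraction of the reference period inflate their own threshold; the rule is
intended for sparse events, and an empty result falls back (with a warning)
to the whole non-soma region.

Soma traces for correlation are the per-frame mean ΔF/F over soma pixels;
correlation is Pearson, reported per pair or as the mean over the upper
triangle per recording. Post-CSD statistics default to the 15–300 s window
after wave passage.

## Electrophysiology

Calibration regresses voltage on **log₁₀(concentration)**: the valinomycin
ionophore response is Nernstian (≈58 mV per decade at body temperature), and
no single straight line in raw mM can fit standards spanning 3.5–100 mM. A
`mode="linear"` option exists for comparison with naive calibrations. The in
vivo chain is: subtract the reference-barrel LFP sample-for-sample, resample
to 10 Hz through a polyphase FIR anti-alias filter (with linear-trend edge
padding so a nonzero resting voltage does not ring at the record edges),
then invert the calibration. Samples outside the calibrated concentration
range are flagged per-sample, not clamped — clamping would silently bias
post-CSD peaks. [K⁺]e is summarized as medians over consecutive 10-min
intervals.

Evoked LFP amplitude is the baseline-to-extremum magnitude: baseline = mean
over the 50 ms before the stimulus, extremum searched in the 100 ms after
it. The response polarity is detected once from the mean stimulus-locked
waveform and held fixed for all stimuli. Amplitudes are binned (10 min) and
normalized to the pre-KCl mean; the LFP–[K⁺] relation pairs each amplitude
bin with the nearest [K⁺] interval and reports Spearman rank correlation.

## Synthetic scenarios

The generator's defaults are the study conditions the estimators are
validated under: 12.8 mm field on a 64×64 grid (512×512 binned by 8) at
10 Hz; KCl window [0, 600) s; first wave onset 38.3 s at 4.4 mm/min with
peak ΔF/F 2.0 and 50 s supra-half-max duration; 1 Hz slow wave of 3.0% ΔF/F
RMS; post-CSD suppression recovering with τ = 900 s; 10% baseline drop after
passage; two-photon events at 0.02 Hz per soma with 1 s exponential decay
and 0.5 ΔF/F amplitude (placing post-CSD soma P(High Ca²⁺) near 0.1, orders
of magnitude above the ~3×10⁻⁵ Gaussian-tail floor of quiet periods);
electrode baseline 3.5 mM ramping to 30 mM with τ = 800 s clearance, 58
mV/decade, evoked stimuli every 30 s attenuated by 50% at peak K⁺.

Design choices, and what they do and do not emulate:

- **Wavefront**: circular from the application site at constant speed (a
  planar option exists for clean speed tests); the per-pixel pulse is a
  trapezoid — 2 s linear rise, hold, 2 s fall — timed so the
  supra-half-maximum duration is exactly `wave_duration_s`. Real wavefronts
  are anisotropic and their pulse shape is not trapezoidal; only the timing
  observables (front, half-max crossings) are meant to be faithful, so
  passage-time tests depend on the chosen shape only through its symmetry.
- **Slow wave**: a single sinusoid with amplitude √2·RMS, multiplicatively
  gated to zero at each wave's local passage and recovering as
  1 − exp(−t/τ). Real UP/DOWN activity is broadband and aperiodic; the
  sinusoid suffices for amplitude and recovery estimators but not for
  spectral analyses.
- **Baseline decrement**: a persistent step drop after wave passage. The
  drop is DC and therefore invisible to the 0.1–3 Hz band-RMS recovery
  analysis; no separate relaxation constant is introduced.
- **Soma correlation**: xᵢ = √ρ·s + √(1−ρ)·nᵢ with s, nᵢ independent
  unit-variance filtered Poisson processes, so the expected pairwise Pearson
  correlation equals ρ exactly; ρ is recovered through the full movie
  pipeline to within Monte-Carlo error. Imaging noise averaged over soma
  pixels attenuates the measured correlation by σ²ₛᵢ𝓰/(σ²ₛᵢ𝓰 + σ²ₙₒᵢₛₑ/Nₚₓ),
  negligible at the default amplitudes.
- **Electrode**: [K⁺] ramps linearly over the KCl window, then decays
  exponentially; voltage = offset + slope·log₁₀[K⁺] + common-mode LFP. The
  slow-wave LFP amplitude is scaled by K_baseline/K(t) (activity low while
  K⁺ is high) and evoked deflections — alpha-functions of 10 ms rise — are
  attenuated in proportion to the K⁺ excess, so evoked recovery parallels
  clearance by construction. The native rate defaults to 1 kHz: the
  conversion path only needs to exercise anti-aliased decimation to 10 Hz,
  and nothing in the chain depends on acquisition-grade 20 kHz sampling.

All randomness flows through a single seeded generator per scenario:
identical seeds give bit-identical outputs.

Passing parameter-recovery tests on these scenarios shows that the
estimators are unbiased and correctly scaled under the stated signal models;
it does not establish robustness to motion, vascular artifacts,
photobleaching, electrode drift, or non-stationary noise, none of which are
simulated (motion and bleach correction are explicitly out of scope).

## Problem sizes

Test and acceptance scenarios are desk-scale by design: 32–64 pixel grids,
5–10 min movies, 1 kHz electrode traces, and 30-seed Monte-Carlo loops for
the correlation recovery — sizes at which every suite runs in a few minutes
on one CPU while leaving the estimators' accuracy limits (frame
quantization, filter ripple, Monte-Carlo error) the binding constraint.

## Known limitations

- Event detection assumes a stationary pre-KCl baseline; slow drift between
  the baseline window and the waves shifts the absolute threshold.
- The onset statistic is reported per ROI; whether a recording-level onset
  should be read at the application-site ROI or a distal ROI is left to the
  caller.
- Touching somata are analyzed as one ROI; the gliopil selection rule
  under-selects pixels whose events dominate the reference period (above).
- The half-max passage is undefined (NaN, flagged) when activity has not
  subsided by the end of the recording.
- Repeated-measures ANOVA / post-hoc group comparisons are deliberately
  delegated to standard statistics environments; `csdflow report` exports
  tidy long-format tables for that purpose.
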