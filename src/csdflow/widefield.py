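"""Transcranial widefield CSD analysis.

Implements the quantification chain for cortex-wide Ca2+ imaging of
KCl-induced spreading depolarization: dF/F against a pre-KCl baseline,
threshold-based wave detection, spline-refined peaks, half-maximum
arrival/passage timing, propagation speed over a known ROI separation,
inter-event intervals, band-limited (0.1-3 Hz) RMS amplitude in 5-min
windows, and amplitude recovery relative to the pre-KCl reference.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy import signal
from scipy.interpolate import CubicSpline

from csdflow.io import TimeWindow, Trace

__all__ = [
    "CSDEvent", "RecoveryCurve", "compute_dff", "detect_csd_events",
    "peak_by_spline", "half_max_times", "wave_speed", "inter_event_interval",
    "band_rms_amplitude", "recovery_curve", "speed_along_rows",
]


@dataclass
class CSDEvent:
    """One detected CSD wave at one ROI.

    ``onset_s`` is the first crossing of the +k SD detection threshold;
    ``arrival_s``/``passage_s`` are the half-maximum up- and down-crossings
    (linear interpolation between samples); ``duration_s`` their difference.
    ``passage_s`` and ``duration_s`` are NaN when the signal never subsides
    below half-maximum before the trace ends.
    """

    onset_s: float
    peak_s: float
    peak_dff: float
    arrival_s: float = np.nan
    passage_s: float = np.nan
    roi_id: str | None = None

    @property
    def duration_s(self) -> float:
        return self.passage_s - self.arrival_s


@dataclass
class RecoveryCurve:
    """Windowed amplitude relative to a pre-KCl reference (1.0 = reference)."""

    window_centers_s: np.ndarray
    relative_amplitude: np.ndarray
    reference_window: TimeWindow

    def at(self, t_s: float) -> float:
        """Relative amplitude of the window whose center is nearest ``t_s``."""
        i = int(np.argmin(np.abs(self.window_centers_s - t_s)))
        return float(self.relative_amplitude[i])


def compute_dff(t: Trace, kcl_time_s: float) -> Trace:
    """dF/F with baseline F = mean over the 40 s ending 20 s before KCl.

    The baseline window is [kcl - 60 s, kcl - 20 s); the trace must cover it.
    """
    w = TimeWindow(kcl_time_s - 60.0, kcl_time_s - 20.0)
    base = t.window_values(w, require_full=True)
    f0 = float(base.mean())
    if f0 <= 0:
        raise ValueError(f"baseline F = {f0} is not positive; cannot form dF/F")
    return Trace(values=(t.values - f0) / f0, rate_hz=t.rate_hz, t0_s=t.t0_s, unit="dff")


def _interp_crossing(times, values, i, level, rising):
    """Linear-interpolated time at which values crosses ``level`` between i and i+1."""
    v0, v1 = values[i], values[i + 1]
    if v1 == v0:
        return times[i + 1] if rising else times[i]
    frac = (level - v0) / (v1 - v0)
    frac = min(max(frac, 0.0), 1.0)
    return times[i] + frac * (times[i + 1] - times[i])


def detect_csd_events(t: Trace, baseline_window: TimeWindow, k_sd: float = 5.0,
                      min_duration_s: float = 1.0, refractory_s: float = 10.0,
                      roi_id: str | None = None) -> list[CSDEvent]:
    """Detect CSD waves as excursions above baseline mean + k_sd * SD.

    An event begins at an upward threshold crossing and ends when the signal
    falls below half of that event's peak; crossings inside an event do not
    start new events, and a new event requires a fresh crossing at least
    ``refractory_s`` after the previous event ends (far below the shortest
    physiological inter-CSD interval of ~280 s). Candidates that stay above
    threshold for less than ``min_duration_s`` are rejected as noise spikes:
    a genuine CSD wave remains supra-threshold for tens of seconds, whereas
    a single-sample threshold rule would fire on rare noise excursions.

    Detection operates on the unfiltered dF/F trace with baseline statistics
    taken from ``baseline_window`` (the same pre-KCl window used for F).
    Returned events carry spline-refined peaks and half-maximum timings.
    """
    base = t.window_values(baseline_window, require_full=True)
    sd = float(base.std())
    if sd == 0:
        raise ValueError("baseline window has zero variance; threshold undefined")
    threshold = float(base.mean()) + k_sd * sd

    v = t.values
    times = t.times_s
    n = len(v)
    events: list[CSDEvent] = []
    i = 0
    next_allowed_t = -np.inf
    while i < n - 1:
        if v[i] < threshold <= v[i + 1] and times[i + 1] >= next_allowed_t:
            onset_s = _interp_crossing(times, v, i, threshold, rising=True)
            # walk forward tracking the running peak until below half of it
            j = i + 1
            peak_val = v[j]
            peak_idx = j
            end_idx = None
            above_count = 1 if v[j] >= threshold else 0
            while j < n - 1:
                j += 1
                if v[j] > peak_val:
                    peak_val = v[j]
                    peak_idx = j
                if v[j] >= threshold:
                    above_count += 1
                if v[j] < peak_val / 2.0:
                    end_idx = j
                    break
            if above_count / t.rate_hz < min_duration_s:
                i = (end_idx if end_idx is not None else n - 1)
                continue
            ev = CSDEvent(onset_s=onset_s, peak_s=times[peak_idx],
                          peak_dff=float(peak_val), roi_id=roi_id)
            peak_s, peak_dff = peak_by_spline(t, ev)
            ev = replace(ev, peak_s=peak_s, peak_dff=peak_dff)
            arrival_s, passage_s = half_max_times(t, ev)
            ev = replace(ev, arrival_s=arrival_s, passage_s=passage_s)
            events.append(ev)
            if end_idx is None:
                break
            i = end_idx
            next_allowed_t = times[end_idx] + refractory_s
        else:
            i += 1
    return events


def peak_by_spline(t: Trace, event: CSDEvent, half_window_s: float = 2.0) -> tuple[float, float]:
    """Continuous peak of an event via a cubic interpolating spline.

    A cubic spline is fitted to the samples within ``half_window_s`` of the
    discrete maximum and its continuous maximum returned; the result is
    never below the discrete maximum. If the window is truncated by a trace
    edge the discrete maximum is returned with a warning.
    """
    times = t.times_s
    v = t.values
    pk = int(np.argmin(np.abs(times - event.peak_s)))
    # re-center on the discrete maximum near the recorded peak time
    lo0 = max(pk - int(half_window_s * t.rate_hz), 0)
    hi0 = min(pk + int(half_window_s * t.rate_hz) + 1, len(v))
    pk = lo0 + int(np.argmax(v[lo0:hi0]))
    half_n = int(round(half_window_s * t.rate_hz))
    lo, hi = pk - half_n, pk + half_n + 1
    if lo < 0 or hi > len(v):
        warnings.warn("spline window truncated by trace edge; using discrete maximum")
        return float(times[pk]), float(v[pk])
    if hi - lo < 5:
        warnings.warn("too few samples around peak for spline; using discrete maximum")
        return float(times[pk]), float(v[pk])
    cs = CubicSpline(times[lo:hi], v[lo:hi])
    crit = cs.derivative().roots(extrapolate=False)
    cand_t = np.concatenate([crit, times[[lo, hi - 1]]])
    cand_v = cs(cand_t)
    best = int(np.argmax(cand_v))
    peak_s, peak_dff = float(cand_t[best]), float(cand_v[best])
    if peak_dff < v[pk]:       # interpolating spline passes through samples
        peak_s, peak_dff = float(times[pk]), float(v[pk])
    return peak_s, peak_dff


def half_max_times(t: Trace, event: CSDEvent) -> tuple[float, float]:
    """Half-maximum arrival (up-crossing) and passage (down-crossing) times.

    Arrival is the last up-crossing of peak/2 before the peak; passage is the
    first down-crossing after it, both linearly interpolated between samples.
    Passage is NaN if the signal never subsides below half-maximum before
    the trace ends.
    """
    v = t.values
    times = t.times_s
    half = event.peak_dff / 2.0
    pk = int(np.argmin(np.abs(times - event.peak_s)))
    i = pk
    while i > 0 and v[i - 1] >= half:
        i -= 1
    if i == 0 and v[0] >= half:
        arrival = float(times[0])
    else:
        arrival = _interp_crossing(times, v, i - 1, half, rising=True)
    j = pk
    n = len(v)
    while j < n - 1 and v[j + 1] >= half:
        j += 1
    if j >= n - 1:
        warnings.warn("signal never subsides below half-maximum; passage undefined")
        passage = float("nan")
    else:
        passage = _interp_crossing(times, v, j, half, rising=False)
    return arrival, passage


def wave_speed(near: list[CSDEvent], far: list[CSDEvent],
               separation_mm: float = 2.0) -> list[float]:
    """Propagation speed (mm/min) per wave from half-max arrival-time lags.

    Waves are matched by rank order of occurrence in each ROI. A wave whose
    transit time is not positive is reported as NaN with a warning rather
    than silently dropped; unmatched trailing waves are likewise flagged.
    """
    n_match = min(len(near), len(far))
    if len(near) != len(far):
        warnings.warn(f"{abs(len(near) - len(far))} wave(s) unmatched between ROIs")
    speeds = []
    for a, b in zip(near[:n_match], far[:n_match]):
        dt = b.arrival_s - a.arrival_s
        if not dt > 0:
            warnings.warn(f"non-positive transit time {dt:.3f} s; wave unmatched")
            speeds.append(float("nan"))
        else:
            speeds.append(separation_mm / dt * 60.0)
    return speeds


def inter_event_interval(events: list[CSDEvent]) -> list[float]:
    """Successive onset-to-onset intervals in seconds (empty for < 2 events)."""
    onsets = sorted(e.onset_s for e in events)
    return list(np.diff(onsets)) if len(onsets) >= 2 else []


def band_rms_amplitude(t: Trace, band_hz: tuple[float, float] = (0.1, 3.0),
                       window_s: float = 300.0) -> Trace:
    """Band-limited RMS amplitude over consecutive non-overlapping windows.

    A second-order zero-phase (forward-backward) Butterworth band-pass is
    applied, then the RMS is computed per 5-min window; the output trace is
    timestamped at window centers. Zero-phase filtering preserves the event
    timings used elsewhere in the pipeline.
    """
    if t.rate_hz <= 2 * band_hz[1]:
        raise ValueError(f"trace rate {t.rate_hz} Hz too low for band up to {band_hz[1]} Hz")
    wlen = int(round(window_s * t.rate_hz))
    if len(t.values) < wlen:
        raise ValueError("trace shorter than one analysis window")
    sos = signal.butter(2, band_hz, btype="bandpass", fs=t.rate_hz, output="sos")
    filt = signal.sosfiltfilt(sos, t.values)
    n_win = len(filt) // wlen
    rms = np.sqrt(np.mean(filt[: n_win * wlen].reshape(n_win, wlen) ** 2, axis=1))
    centers_rate = 1.0 / window_s
    t0 = t.t0_s + window_s / 2.0
    return Trace(values=rms, rate_hz=centers_rate, t0_s=t0, unit=t.unit)


def speed_along_rows(movie, kcl_time_s: float, origin_row: int, center_col: int,
                     near_offset_mm: float = 0.5, separation_mm: float = 2.0,
                     roi_half_px: int = 2, k_sd: float = 5.0) -> list[float]:
    """End-to-end speed estimate from two ROIs along the row axis.

    Places a near ROI ``near_offset_mm`` from the wave origin and a far ROI
    ``separation_mm`` beyond it (each (2*roi_half_px+1)^2 pixels), computes
    dF/F at both, detects events and converts matched half-max arrival lags
    to mm/min. This is the standard two-ROI speed measurement for a wave
    initiated at a known site and travelling along the row axis.
    """
    from csdflow.io import extract_roi_trace

    pitch = movie.pixel_pitch_mm
    near_r = origin_row + int(round(near_offset_mm / pitch))
    far_r = near_r + int(round(separation_mm / pitch))
    sep_actual = (far_r - near_r) * pitch
    baseline = TimeWindow(kcl_time_s - 60.0, kcl_time_s - 20.0)
    events = []
    for r in (near_r, far_r):
        tr = extract_roi_trace(movie, (r - roi_half_px, r + roi_half_px + 1,
                                       center_col - roi_half_px, center_col + roi_half_px + 1))
        dff = compute_dff(tr, kcl_time_s)
        events.append(detect_csd_events(dff, baseline, k_sd=k_sd))
    return wave_speed(events[0], events[1], separation_mm=sep_actual)


def recovery_curve(amp: Trace, kcl_window: TimeWindow) -> RecoveryCurve:
    """Windowed amplitude normalized to the mean over the 10 min before KCl."""
    ref_w = TimeWindow(kcl_window.start_s - 600.0, kcl_window.start_s)
    centers = amp.times_s
    in_ref = (centers >= ref_w.start_s) & (centers < ref_w.end_s)
    if not in_ref.any():
        raise ValueError("amplitude trace has no windows in the 10-min pre-KCl reference")
    ref = float(amp.values[in_ref].mean())
    if ref <= 0:
        raise ValueError("pre-KCl reference amplitude is zero; cannot normalize")
    return RecoveryCurve(window_centers_s=centers.copy(),
                         relative_amplitude=amp.values / ref,
                         reference_window=ref_w)
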