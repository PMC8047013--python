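"""Ion-selective K+ electrode calibration and [K+]e reconstruction, plus
whisker-evoked LFP amplitude quantification.

The electrode obeys a Nernstian law: voltage linear in log10 of the K+
concentration, ~58 mV per decade at body temperature. Calibration fits that
line by ordinary least squares on the standard solutions (3.5-100 mM); the
in vivo signal is reference-subtracted, resampled to 10 Hz with anti-alias
filtering, and inverted through the calibration to millimolar. Evoked LFP
deflections are measured baseline-to-extremum in a short post-stimulus
window and normalized to the pre-KCl period.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from fractions import Fraction

import numpy as np
import pandas as pd
from scipy import signal, stats

from csdflow.io import TimeWindow, Trace
from csdflow.widefield import RecoveryCurve

__all__ = [
    "CalibrationCurve", "EvokedResponse", "fit_calibration",
    "subtract_reference", "to_concentration", "k_summary",
    "evoked_amplitudes", "normalize_evoked", "lfp_k_relation",
]


@dataclass
class CalibrationCurve:
    """Fitted voltage <-> concentration mapping for one K+ electrode.

    ``mode`` records the regressor: 'log10' (Nernstian, default) fits
    voltage against log10(conc); 'linear' fits against raw mM for
    comparison with naive calibrations.
    """

    slope_mV_per_decade: float
    offset_mV: float
    r_squared: float
    conc_range_mM: tuple[float, float]
    mode: str = "log10"

    def __post_init__(self):
        if self.slope_mV_per_decade == 0:
            raise ValueError("calibration slope must be non-zero")
        if not 0.0 <= self.r_squared <= 1.0 + 1e-12:
            raise ValueError("r_squared must lie in [0, 1]")


@dataclass
class EvokedResponse:
    """One whisker-evoked LFP deflection: magnitude and latency of the extremum."""

    stim_time_s: float
    amplitude_mV: float
    latency_s: float

    def __post_init__(self):
        if self.amplitude_mV < 0:
            raise ValueError("amplitude is a magnitude and must be >= 0")


def fit_calibration(table, mode: str = "log10") -> CalibrationCurve:
    """Least-squares calibration line from (conc_mM, voltage_mV) pairs.

    Accepts a DataFrame with ``conc_mM``/``voltage_mV`` columns or an
    iterable of pairs; requires at least 3 distinct positive concentrations.
    """
    if isinstance(table, pd.DataFrame):
        conc = table["conc_mM"].to_numpy(dtype=np.float64)
        volt = table["voltage_mV"].to_numpy(dtype=np.float64)
    else:
        arr = np.asarray(list(table), dtype=np.float64)
        conc, volt = arr[:, 0], arr[:, 1]
    if (conc <= 0).any():
        raise ValueError("calibration concentrations must be positive")
    if len(np.unique(conc)) < 3:
        raise ValueError("calibration needs >= 3 distinct concentrations")
    if mode not in ("log10", "linear"):
        raise ValueError("mode must be 'log10' or 'linear'")
    x = np.log10(conc) if mode == "log10" else conc
    res = stats.linregress(x, volt)
    return CalibrationCurve(slope_mV_per_decade=float(res.slope),
                            offset_mV=float(res.intercept),
                            r_squared=float(res.rvalue ** 2),
                            conc_range_mM=(float(conc.min()), float(conc.max())),
                            mode=mode)


def subtract_reference(k_electrode: Trace, ref_lfp: Trace) -> Trace:
    """Remove the common-mode field potential from the K+-electrode signal."""
    if k_electrode.rate_hz != ref_lfp.rate_hz:
        raise ValueError("K+ electrode and reference LFP must share a sampling rate")
    if len(k_electrode) != len(ref_lfp) or k_electrode.t0_s != ref_lfp.t0_s:
        raise ValueError("K+ electrode and reference LFP must be aligned sample-for-sample")
    return Trace(values=k_electrode.values - ref_lfp.values,
                 rate_hz=k_electrode.rate_hz, t0_s=k_electrode.t0_s, unit="mV")


def to_concentration(v: Trace, c: CalibrationCurve,
                     out_rate_hz: float = 10.0) -> tuple[Trace, np.ndarray]:
    """Resample a voltage trace to ``out_rate_hz`` and invert the calibration.

    Resampling uses a polyphase FIR anti-alias filter. Concentration is
    10**((v - offset)/slope) in log10 mode (or the linear inverse).
    Returns ``(concentration, extrapolated)`` where the second element flags
    samples outside the fitted concentration range — flagged, not clamped,
    because clamping would silently bias post-CSD peaks.
    """
    if v.rate_hz == out_rate_hz:
        res = v.values.copy()
    else:
        frac = Fraction(out_rate_hz / v.rate_hz).limit_denominator(10_000)
        res = signal.resample_poly(v.values, frac.numerator, frac.denominator,
                                   padtype="line")
    if len(res) < 1:
        raise ValueError("input shorter than one output sample")
    if c.mode == "log10":
        conc = 10.0 ** ((res - c.offset_mV) / c.slope_mV_per_decade)
    else:
        conc = (res - c.offset_mV) / c.slope_mV_per_decade
    lo, hi = c.conc_range_mM
    # tiny relative slack so values exactly at a calibration endpoint count as in range
    extrapolated = (conc < lo * (1 - 1e-9)) | (conc > hi * (1 + 1e-9))
    out = Trace(values=conc, rate_hz=out_rate_hz, t0_s=v.t0_s, unit="mM")
    return out, extrapolated


def k_summary(t: Trace, interval_s: float = 600.0, stat: str = "median") -> pd.DataFrame:
    """Summary statistic of [K+]e per consecutive interval (default 10-min medians).

    Returns a DataFrame with interval centers and values; a trailing partial
    interval is dropped.
    """
    if stat not in ("median", "mean"):
        raise ValueError("stat must be 'median' or 'mean'")
    wlen = int(round(interval_s * t.rate_hz))
    n_int = len(t.values) // wlen
    if n_int == 0:
        raise ValueError("trace shorter than one summary interval")
    blocks = t.values[: n_int * wlen].reshape(n_int, wlen)
    vals = np.median(blocks, axis=1) if stat == "median" else blocks.mean(axis=1)
    centers = t.t0_s + (np.arange(n_int) + 0.5) * interval_s
    return pd.DataFrame({"center_s": centers, f"k_{stat}_mM": vals})


def _detect_polarity(lfp: Trace, stim_times, pre_n: int, post_n: int) -> int:
    """Sign (+1/-1) of the mean stimulus-locked extremum, held fixed thereafter."""
    segs = []
    for st in stim_times:
        i = lfp.sample_index(st)
        if i - pre_n < 0 or i + post_n + 1 > len(lfp.values):
            continue
        seg = lfp.values[i - pre_n: i + post_n + 1].copy()
        seg -= seg[:pre_n].mean()
        segs.append(seg)
    if not segs:
        raise ValueError("no stimulus fully covered by the trace")
    mean_post = np.mean(segs, axis=0)[pre_n + 1:]
    return 1 if mean_post.max() >= -mean_post.min() else -1


def evoked_amplitudes(lfp: Trace, stim_times, pre_ms: float = 50.0,
                      post_ms: float = 100.0,
                      polarity: str | int = "auto") -> list[EvokedResponse]:
    """Baseline-to-extremum magnitude of each stimulus-evoked LFP deflection.

    Baseline is the mean over [-pre_ms, 0) before the stimulus; the extremum
    is searched in (0, post_ms]. Polarity ('auto', +1 or -1) selects which
    extremum counts as the response; 'auto' takes it from the mean
    stimulus-locked waveform and holds it fixed for all stimuli. Stimuli too
    close to a trace edge are skipped with a warning.
    """
    pre_n = int(round(pre_ms / 1000.0 * lfp.rate_hz))
    post_n = int(round(post_ms / 1000.0 * lfp.rate_hz))
    if pre_n < 1 or post_n < 1:
        raise ValueError("analysis windows must span at least one sample")
    pol = _detect_polarity(lfp, stim_times, pre_n, post_n) if polarity == "auto" else int(polarity)
    out = []
    for st in stim_times:
        i = lfp.sample_index(st)
        if i - pre_n < 0 or i + post_n + 1 > len(lfp.values):
            warnings.warn(f"stimulus at {st:.3f} s too close to trace edge; skipped")
            continue
        baseline = lfp.values[i - pre_n: i].mean()
        post = (lfp.values[i + 1: i + post_n + 1] - baseline) * pol
        j = int(np.argmax(post))
        out.append(EvokedResponse(stim_time_s=float(st),
                                  amplitude_mV=float(max(post[j], 0.0)),
                                  latency_s=float((j + 1) / lfp.rate_hz)))
    return out


def normalize_evoked(resp: list[EvokedResponse], pre_kcl: TimeWindow,
                     bin_s: float = 600.0) -> RecoveryCurve:
    """Binned mean evoked amplitude relative to the pre-KCl mean (1.0 = reference)."""
    ref = [r.amplitude_mV for r in resp if pre_kcl.contains(r.stim_time_s)]
    if not ref:
        raise ValueError("no evoked responses in the pre-KCl reference window")
    ref_mean = float(np.mean(ref))
    if ref_mean <= 0:
        raise ValueError("pre-KCl reference amplitude is zero; cannot normalize")
    times = np.array([r.stim_time_s for r in resp])
    amps = np.array([r.amplitude_mV for r in resp])
    t_lo = times.min()
    bins = np.floor((times - t_lo) / bin_s).astype(int)
    centers, rel = [], []
    for b in np.unique(bins):
        sel = bins == b
        centers.append(t_lo + (b + 0.5) * bin_s)
        rel.append(amps[sel].mean() / ref_mean)
    return RecoveryCurve(window_centers_s=np.array(centers),
                         relative_amplitude=np.array(rel),
                         reference_window=pre_kcl)


def lfp_k_relation(amp: RecoveryCurve, k: pd.DataFrame) -> tuple[pd.DataFrame, float, float]:
    """Pair LFP recovery with [K+]e summaries and rank-correlate them.

    Each amplitude bin is matched to the nearest [K+]e interval center.
    Returns (paired table, Spearman r, p). The physiological expectation is
    an inverse relationship: activity is low while [K+]e is high.
    """
    kcol = [c for c in k.columns if c.startswith("k_")][0]
    pairs = []
    for t_amp, a in zip(amp.window_centers_s, amp.relative_amplitude):
        j = int(np.argmin(np.abs(k["center_s"].to_numpy() - t_amp)))
        pairs.append({"center_s": float(t_amp), "relative_amplitude": float(a),
                      "k_mM": float(k[kcol].iloc[j])})
    table = pd.DataFrame(pairs)
    if len(table) < 3:
        raise ValueError("need at least 3 paired points for a rank correlation")
    r, p = stats.spearmanr(table["relative_amplitude"], table["k_mM"])
    return table, float(r), float(p)
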