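"""Synthetic widefield, two-photon and electrophysiology scenarios with ground truth.

Every generator takes a frozen scenario (all parameters explicit, including the
seed) and returns both the simulated data and the ground truth used to build
it, so each analysis stage can be validated by parameter recovery. Identical
seeds give bit-identical output; there is no hidden global randomness.

The widefield scenario emulates a KCl-induced cortical spreading
depolarization (CSD) experiment: a 0.5-2 Hz slow-wave baseline oscillation,
one or more radially (or planar, for clean speed tests) expanding Ca2+ waves
travelling at a few mm/min with peak dF/F around 200%, post-passage
suppression of the slow wave with exponential recovery, and a persistent
baseline decrement after the wave. The two-photon scenario plants correlated
astrocyte soma events using a shared-signal construction whose expected
pairwise Pearson correlation equals the requested rho exactly. The
electrophysiology scenario produces a Nernstian K+-electrode voltage on top
of a common-mode LFP, with exponential post-KCl clearance and whisker-evoked
deflections whose attenuation tracks the K+ excess.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from csdflow.io import Movie, TimeWindow, Trace

__all__ = [
    "WidefieldScenario", "TwoPhotonScenario", "EphysScenario",
    "WidefieldTruth", "simulate_widefield", "simulate_twophoton",
    "simulate_ephys", "simulate_calibration", "CALIBRATION_STANDARDS_MM",
]

#: canonical calibration standard concentrations (mM)
CALIBRATION_STANDARDS_MM = (3.5, 4.5, 10.0, 20.0, 50.0, 100.0)

_RISE_S = 2.0   # linear rise time of the wave pulse at one pixel
_FALL_S = 2.0   # linear fall time


@dataclass
class WidefieldScenario:
    """Parameters of a synthetic transcranial widefield CSD recording.

    Defaults follow the study conditions the generator emulates: a 12.8 mm
    field imaged at 10 Hz on a 64x64 grid (512x512 binned by 8), KCl applied
    at t = 0 for 10 min, first wave ~4.4 mm/min with peak dF/F 2.0 (200%),
    ~50 s supra-half-max duration, a 1 Hz slow wave of 3% dF/F RMS, and
    post-passage suppression recovering over ~15 min.
    """

    duration_s: float = 1200.0
    field_mm: float = 12.8
    grid: int = 64
    rate_hz: float = 10.0
    t0_s: float = -120.0
    kcl_window: TimeWindow = field(default_factory=lambda: TimeWindow(0.0, 600.0))
    origin_px: tuple[int, int] = (56, 32)
    wave_onsets_s: tuple[float, ...] = (38.3,)
    speed_mm_per_min: float = 4.4
    wave_peak_dff: float = 2.0
    wave_duration_s: float = 50.0
    slowwave_freq_hz: float = 1.0
    slowwave_rms_dff: float = 0.030
    suppression_recovery_s: float = 900.0
    post_csd_baseline_drop_frac: float = 0.10
    noise_sd_dff: float = 0.01
    geometry: str = "radial"        # 'radial' or 'planar' (front moves along +rows)
    allow_truncation: bool = False
    seed: int = 0

    def __post_init__(self):
        if list(self.wave_onsets_s) != sorted(self.wave_onsets_s):
            raise ValueError("wave_onsets_s must be sorted ascending")
        if not self.speed_mm_per_min > 0:
            raise ValueError("speed must be > 0")
        if self.grid <= 0:
            raise ValueError("grid must be > 0")
        if not 0 <= self.post_csd_baseline_drop_frac < 1:
            raise ValueError("post_csd_baseline_drop_frac must be in [0, 1)")
        if self.geometry not in ("radial", "planar"):
            raise ValueError("geometry must be 'radial' or 'planar'")
        if self.wave_duration_s <= _RISE_S:
            raise ValueError(f"wave_duration_s must exceed the {_RISE_S} s rise time")

    @property
    def pixel_pitch_mm(self) -> float:
        return self.field_mm / self.grid


@dataclass
class WidefieldTruth:
    """Ground truth of a widefield scenario.

    ``front_s[k]`` is the (grid, grid) array of times at which wave k's front
    reaches each pixel; ``arrival_s`` / ``passage_s`` are the half-maximum
    up- and down-crossing times of the pulse at each pixel.
    """

    scenario: WidefieldScenario
    front_s: list[np.ndarray]
    arrival_s: list[np.ndarray]
    passage_s: list[np.ndarray]

    @property
    def speed_mm_per_min(self) -> float:
        return self.scenario.speed_mm_per_min

    def table(self) -> pd.DataFrame:
        s = self.scenario
        return pd.DataFrame({
            "wave": np.arange(len(s.wave_onsets_s)),
            "onset_s": list(s.wave_onsets_s),
            "speed_mm_per_min": s.speed_mm_per_min,
            "peak_dff": s.wave_peak_dff,
            "duration_s": s.wave_duration_s,
        })


def _pixel_front_times(s: WidefieldScenario) -> np.ndarray:
    """Distance-derived front delay (s) from the origin to every pixel."""
    rr, cc = np.meshgrid(np.arange(s.grid), np.arange(s.grid), indexing="ij")
    if s.geometry == "radial":
        d_mm = np.hypot(rr - s.origin_px[0], cc - s.origin_px[1]) * s.pixel_pitch_mm
    else:
        d_mm = np.maximum(0.0, (rr - s.origin_px[0]) * s.pixel_pitch_mm).astype(float)
    speed_mm_per_s = s.speed_mm_per_min / 60.0
    return d_mm / speed_mm_per_s


def simulate_widefield(s: WidefieldScenario) -> tuple[Movie, WidefieldTruth]:
    """Render a widefield CSD movie and its ground truth.

    The movie is on an intensity scale with pre-KCl baseline 1.0, so that
    downstream dF/F (baseline F from the pre-KCl window) recovers the
    scenario's dF/F-scale amplitudes. Each wave is a trapezoidal pulse per
    pixel: linear rise over 2 s to ``wave_peak_dff``, a hold, then a linear
    2 s fall, timed so the supra-half-maximum duration equals
    ``wave_duration_s`` everywhere. The slow-wave amplitude is gated to zero
    at each wave's local passage and recovers as 1 - exp(-t/tau); the
    baseline drops by ``post_csd_baseline_drop_frac`` after the first
    passage.
    """
    rng = np.random.default_rng(s.seed)
    n = int(round(s.duration_s * s.rate_hz))
    t = s.t0_s + np.arange(n) / s.rate_hz
    delay = _pixel_front_times(s)                     # (grid, grid)
    hold_s = s.wave_duration_s - _RISE_S
    pulse_len = _RISE_S + hold_s + _FALL_S

    t_end = s.t0_s + s.duration_s
    for onset in s.wave_onsets_s:
        if onset + delay.max() + pulse_len > t_end and not s.allow_truncation:
            raise ValueError(
                f"wave at onset {onset} s overlaps the movie end "
                f"(needs {onset + delay.max() + pulse_len:.1f} s, movie ends {t_end:.1f} s); "
                "set allow_truncation=True to truncate")

    front, arrival, passage = [], [], []
    for onset in s.wave_onsets_s:
        f = onset + delay
        front.append(f)
        arrival.append(f + _RISE_S / 2.0)
        passage.append(f + _RISE_S + hold_s + _FALL_S / 2.0)

    amp_slow = np.sqrt(2.0) * s.slowwave_rms_dff
    phase = rng.uniform(0, 2 * np.pi)
    flat_delay = delay.ravel()
    npx = flat_delay.size

    data = np.empty((n, s.grid, s.grid), dtype=np.float32)
    chunk = max(1, int(2e6 // max(npx, 1)))
    for i0 in range(0, n, chunk):
        tt = t[i0:i0 + chunk]                          # (m,)
        m = tt.size
        sig = np.ones((m, npx))
        # wave pulses
        for f in front:
            u = tt[:, None] - f.ravel()[None, :]
            prof = np.minimum(u / _RISE_S, 1.0)
            prof = np.minimum(prof, (pulse_len - u) / _FALL_S)
            np.clip(prof, 0.0, 1.0, out=prof)
            sig += s.wave_peak_dff * prof
        # slow-wave gate and baseline drop, driven by each wave's passage
        gate = np.ones((m, npx))
        base = np.ones((m, npx))
        for p in passage:
            dt = tt[:, None] - p.ravel()[None, :]
            after = dt >= 0
            rec = 1.0 - np.exp(-np.maximum(dt, 0.0) / s.suppression_recovery_s)
            gate = np.where(after, rec, gate)
            base = np.where(after, 1.0 - s.post_csd_baseline_drop_frac, base)
        sig += base * gate * amp_slow * np.sin(2 * np.pi * s.slowwave_freq_hz * tt[:, None] + phase) \
            + (base - 1.0)
        if s.noise_sd_dff > 0:
            sig += rng.normal(0.0, s.noise_sd_dff, size=sig.shape)
        data[i0:i0 + chunk] = sig.reshape(m, s.grid, s.grid)

    movie = Movie(data=data, frame_rate_hz=s.rate_hz,
                  pixel_pitch_mm=s.pixel_pitch_mm, t0_s=s.t0_s)
    return movie, WidefieldTruth(scenario=s, front_s=front, arrival_s=arrival, passage_s=passage)


# ---------------------------------------------------------------------------
# two-photon


@dataclass
class TwoPhotonScenario:
    """Parameters of a synthetic two-photon astrocyte recording.

    The pre-CSD window is event-free (noise only); post-CSD soma events are
    a shared-signal mixture sqrt(rho)*s + sqrt(1-rho)*n_i of unit-variance
    filtered Poisson processes, so the expected pairwise Pearson correlation
    between somata equals ``pairwise_rho`` exactly.
    """

    duration_s: float = 390.0
    grid: int = 128
    rate_hz: float = 30.0
    t0_s: float = 0.0
    n_somata: int = 10
    soma_radius_px: int = 3
    pre_csd_window: TimeWindow = field(default_factory=lambda: TimeWindow(0.0, 90.0))
    post_csd_window: TimeWindow = field(default_factory=lambda: TimeWindow(105.0, 390.0))
    soma_event_rate_hz: float = 0.02
    event_amp_dff: float = 0.5
    event_decay_s: float = 1.0
    pairwise_rho: float = 0.10
    gliopil_event_rate_hz: float = 0.2
    gliopil_patch_radius_px: int = 2
    noise_sd_dff: float = 0.02
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.pairwise_rho <= 1.0:
            raise ValueError("pairwise_rho must be in [0, 1]")
        if self.n_somata < 0 or self.soma_radius_px < 1:
            raise ValueError("invalid soma geometry")


def _filtered_event_process(rng, n, rate_hz, fs, decay_s, window_idx):
    """Unit-variance (over window_idx) exponentially filtered Poisson train.

    Returns (signal, event_times_idx). Zero-rate processes come back as
    zeros rather than dividing by a zero standard deviation.
    """
    x = np.zeros(n)
    i0, i1 = window_idx
    n_win = i1 - i0
    lam = rate_hz * n_win / fs
    k = rng.poisson(lam)
    idx = np.sort(rng.integers(i0, i1, size=k))
    kern_len = int(decay_s * fs * 6) + 1
    kern = np.exp(-np.arange(kern_len) / (decay_s * fs))
    for i in idx:
        seg = kern[: n - i]
        x[i: i + seg.size] += seg
    win = x[i0:i1]
    sd = win.std()
    if sd > 0:
        mu = win.mean()
        x[i0:i1] = (win - mu) / sd
        x[:i0] = 0.0
        x[i1:] = 0.0
    return x, idx


def _place_disks(rng, grid, n, radius, margin, forbidden=None, max_tries=5000):
    """Centers of n non-overlapping disks; raises if they cannot be placed."""
    centers = []
    tries = 0
    while len(centers) < n:
        tries += 1
        if tries > max_tries:
            raise RuntimeError(f"could not place {n} non-overlapping disks of radius {radius} on a {grid} grid")
        r = rng.integers(margin, grid - margin)
        c = rng.integers(margin, grid - margin)
        if any((r - r2) ** 2 + (c - c2) ** 2 < (2 * radius + 1) ** 2 for r2, c2 in centers):
            continue
        if forbidden is not None and forbidden[r, c]:
            continue
        centers.append((int(r), int(c)))
    return centers


def _disk_mask(grid, center, radius):
    rr, cc = np.meshgrid(np.arange(grid), np.arange(grid), indexing="ij")
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius ** 2


def simulate_twophoton(s: TwoPhotonScenario) -> tuple[Movie, np.ndarray, pd.DataFrame]:
    """Render a two-photon movie, a soma label mask, and the ground truth table.

    Returns (movie, mask, truth): ``mask`` is a (grid, grid) uint16 label
    image (0 = background, i = soma i); ``truth`` lists planted event times
    per source ('shared', 'soma_i', 'gliopil') plus the target rho row.
    """
    rng = np.random.default_rng(s.seed)
    n = int(round(s.duration_s * s.rate_hz))
    margin = s.soma_radius_px + 1
    centers = _place_disks(rng, s.grid, s.n_somata, s.soma_radius_px, margin)

    post_idx = (int(np.ceil((s.post_csd_window.start_s - s.t0_s) * s.rate_hz)),
                min(int(np.ceil((s.post_csd_window.end_s - s.t0_s) * s.rate_hz)), n))

    shared, shared_ev = _filtered_event_process(
        rng, n, s.soma_event_rate_hz, s.rate_hz, s.event_decay_s, post_idx)
    a, b = np.sqrt(s.pairwise_rho), np.sqrt(1.0 - s.pairwise_rho)
    rows = [{"source": "shared", "event_idx": list(map(int, shared_ev)),
             "rho": s.pairwise_rho, "center": None}]
    soma_signals = []
    for i in range(s.n_somata):
        own, ev = _filtered_event_process(
            rng, n, s.soma_event_rate_hz, s.rate_hz, s.event_decay_s, post_idx)
        soma_signals.append(s.event_amp_dff * (a * shared + b * own))
        rows.append({"source": f"soma_{i + 1}", "event_idx": list(map(int, ev)),
                     "rho": s.pairwise_rho, "center": centers[i]})

    mask = np.zeros((s.grid, s.grid), dtype=np.uint16)
    for i, c in enumerate(centers):
        mask[_disk_mask(s.grid, c, s.soma_radius_px)] = i + 1

    data = np.ones((n, s.grid, s.grid), dtype=np.float32)
    for i, c in enumerate(centers):
        m = _disk_mask(s.grid, c, s.soma_radius_px)
        data[:, m] += soma_signals[i][:, None].astype(np.float32)

    # gliopil: transient patches at random non-soma locations in the post window
    post_dur = (post_idx[1] - post_idx[0]) / s.rate_hz
    n_gliopil = rng.poisson(s.gliopil_event_rate_hz * post_dur)
    kern_len = int(s.event_decay_s * s.rate_hz * 6) + 1
    kern = np.exp(-np.arange(kern_len) / (s.event_decay_s * s.rate_hz)).astype(np.float32)
    gl_margin = s.gliopil_patch_radius_px + 1
    soma_blocked = mask > 0
    gl_rows = []
    for _ in range(n_gliopil):
        i = int(rng.integers(post_idx[0], post_idx[1]))
        center = _place_disks(rng, s.grid, 1, s.gliopil_patch_radius_px, gl_margin,
                              forbidden=soma_blocked)[0]
        m = _disk_mask(s.grid, center, s.gliopil_patch_radius_px) & ~soma_blocked
        seg = kern[: n - i]
        data[i: i + seg.size, m] += s.event_amp_dff * seg[:, None]
        gl_rows.append({"source": "gliopil", "event_idx": [i],
                        "rho": np.nan, "center": center})
    rows.extend(gl_rows)

    if s.noise_sd_dff > 0:
        data += rng.normal(0.0, s.noise_sd_dff, size=data.shape).astype(np.float32)

    movie = Movie(data=data, frame_rate_hz=s.rate_hz, pixel_pitch_mm=0.001, t0_s=s.t0_s)
    return movie, mask, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# electrophysiology


@dataclass
class EphysScenario:
    """Parameters of a synthetic K+-electrode / reference-LFP recording.

    [K+]e ramps from ``k_baseline_mM`` to ``k_peak_mM`` over the KCl window,
    then clears exponentially with ``k_clearance_tau_s``. The electrode
    voltage is Nernstian (``nernst_slope_mV_per_decade`` per decade of
    concentration) plus a common-mode LFP shared with the reference
    electrode. Slow-wave LFP amplitude is suppressed in proportion to the
    K+ excess; whisker-evoked deflections every ``evoked_every_s`` are
    attenuated by ``evoked_attenuation_frac`` at peak K+ and recover as
    [K+]e clears (the recovery of evoked activity parallels K+
    normalization).
    """

    duration_s: float = 4200.0
    rate_hz: float = 1000.0
    t0_s: float = -600.0
    kcl_window: TimeWindow = field(default_factory=lambda: TimeWindow(0.0, 600.0))
    k_baseline_mM: float = 3.5
    k_peak_mM: float = 30.0
    k_clearance_tau_s: float = 800.0
    nernst_slope_mV_per_decade: float = 58.0
    nernst_offset_mV: float = 0.0
    lfp_slowwave_rms_mV: float = 0.2
    lfp_slowwave_freq_hz: float = 1.0
    evoked_every_s: float = 30.0
    evoked_amp_mV: float = 0.5
    evoked_attenuation_frac: float = 0.5
    noise_sd_mV: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if not self.k_baseline_mM > 0:
            raise ValueError("k_baseline_mM must be > 0")
        if not self.k_clearance_tau_s > 0:
            raise ValueError("k_clearance_tau_s must be > 0")
        if not self.nernst_slope_mV_per_decade > 0:
            raise ValueError("nernst slope must be > 0")


def true_k_concentration(s: EphysScenario, t: np.ndarray) -> np.ndarray:
    """Ground-truth [K+]e (mM) at times ``t`` for an ephys scenario."""
    t = np.asarray(t, dtype=np.float64)
    k = np.full(t.shape, s.k_baseline_mM)
    w = s.kcl_window
    rising = (t >= w.start_s) & (t < w.end_s)
    frac = (t[rising] - w.start_s) / w.duration_s
    k[rising] = s.k_baseline_mM + (s.k_peak_mM - s.k_baseline_mM) * frac
    after = t >= w.end_s
    if np.isfinite(s.k_clearance_tau_s):
        decay = np.exp(-(t[after] - w.end_s) / s.k_clearance_tau_s)
    else:
        decay = np.ones(after.sum())
    k[after] = s.k_baseline_mM + (s.k_peak_mM - s.k_baseline_mM) * decay
    return k


def _evoked_kernel(rate_hz: float, rise_s: float = 0.01) -> np.ndarray:
    """Alpha-function deflection of unit peak magnitude, ~5 rise constants long."""
    u = np.arange(int(rise_s * rate_hz * 5) + 1) / rate_hz
    return (u / rise_s) * np.exp(1.0 - u / rise_s)


def simulate_ephys(s: EphysScenario) -> tuple[Trace, Trace, list[float], dict]:
    """Simulate K+-electrode voltage, reference LFP, stimulus times and truth.

    Returns (k_voltage, ref_lfp, stim_times_s, truth) where truth holds the
    ground-truth [K+](t) sampled at 10 Hz, the clearance tau and the per-
    stimulus evoked amplitude scale factors.
    """
    rng = np.random.default_rng(s.seed)
    n = int(round(s.duration_s * s.rate_hz))
    t = s.t0_s + np.arange(n) / s.rate_hz
    k = true_k_concentration(s, t)

    # common-mode LFP: slow wave suppressed in proportion to K+ excess
    gate = s.k_baseline_mM / k
    phase = rng.uniform(0, 2 * np.pi)
    common = gate * np.sqrt(2.0) * s.lfp_slowwave_rms_mV * np.sin(
        2 * np.pi * s.lfp_slowwave_freq_hz * t + phase)

    kern = _evoked_kernel(s.rate_hz)
    stim_times, stim_scales = [], []
    t_stim = s.t0_s + s.evoked_every_s
    t_end = s.t0_s + s.duration_s
    while t_stim < t_end - 1.0:
        i = int(round((t_stim - s.t0_s) * s.rate_hz))
        excess = (k[i] - s.k_baseline_mM) / (s.k_peak_mM - s.k_baseline_mM)
        scale = 1.0 - s.evoked_attenuation_frac * excess
        seg = kern[: n - i]
        common[i: i + seg.size] -= s.evoked_amp_mV * scale * seg
        stim_times.append(float(t_stim))
        stim_scales.append(float(scale))
        t_stim += s.evoked_every_s

    nernst = s.nernst_offset_mV + s.nernst_slope_mV_per_decade * np.log10(k)
    kv = nernst + common
    ref = common.copy()
    if s.noise_sd_mV > 0:
        kv += rng.normal(0.0, s.noise_sd_mV, size=n)
        ref += rng.normal(0.0, s.noise_sd_mV, size=n)

    k_voltage = Trace(values=kv, rate_hz=s.rate_hz, t0_s=s.t0_s, unit="mV")
    ref_lfp = Trace(values=ref, rate_hz=s.rate_hz, t0_s=s.t0_s, unit="mV")

    t10 = s.t0_s + np.arange(int(round(s.duration_s * 10.0))) / 10.0
    truth = {
        "k_true_mM_10hz": Trace(values=true_k_concentration(s, t10), rate_hz=10.0,
                                t0_s=s.t0_s, unit="mM"),
        "k_clearance_tau_s": s.k_clearance_tau_s,
        "stim_times_s": stim_times,
        "stim_scales": stim_scales,
        "scenario": s,
    }
    return k_voltage, ref_lfp, stim_times, truth


def simulate_calibration(concs_mM=None, slope_mV_per_decade: float = 58.0,
                         offset_mV: float = 0.0, noise_sd_mV: float = 0.0,
                         seed: int = 0) -> pd.DataFrame:
    """Nernstian calibration table over the standard K+ concentrations.

    Voltage = offset + slope * log10(conc) + Gaussian noise.
    """
    if concs_mM is None:
        concs_mM = CALIBRATION_STANDARDS_MM
    concs = np.asarray(concs_mM, dtype=np.float64)
    if (concs <= 0).any():
        raise ValueError("calibration concentrations must be positive")
    rng = np.random.default_rng(seed)
    v = offset_mV + slope_mV_per_decade * np.log10(concs)
    if noise_sd_mV > 0:
        v = v + rng.normal(0.0, noise_sd_mV, size=concs.size)
    return pd.DataFrame({"conc_mM": concs, "voltage_mV": v})
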