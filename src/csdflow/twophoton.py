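"""Two-photon astrocyte Ca2+ analysis: soma/gliopil ROIs, the high-Ca2+ pixel
rule, event probability P(High Ca2+), and pairwise soma correlations.

The high-Ca2+ rule marks a pixel-frame as an event when its dF/F exceeds that
pixel's reference-window temporal mean + k SD (k = 4 by default). P(High
Ca2+) is the fraction of high pixel-frames over an ROI and evaluation window
— computed per soma, or pooled over the entire non-soma region for
gliopil/neurogliopil. Pixel sets are (n, 2) integer arrays of 0-based
(row, col) coordinates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from skimage import measure, morphology

from csdflow.io import Movie, TimeWindow, Trace

__all__ = [
    "RoiSet", "EventProbability", "pixel_dff", "soma_rois_from_mask",
    "high_ca_mask", "event_probability", "gliopil_roi_from_events",
    "pairwise_soma_correlation", "soma_traces",
]


@dataclass
class RoiSet:
    """Soma ROIs plus the non-soma (gliopil candidate) region.

    ``soma_rois`` maps an id to an (n, 2) array of (row, col) pixels; somata
    are pairwise disjoint, and ``nonsoma_roi`` is disjoint from all of them.
    """

    soma_rois: dict[int, np.ndarray]
    nonsoma_roi: np.ndarray
    provenance: str = "mask-derived"   # manual | mask-derived | event-derived

    def __post_init__(self):
        seen: set[tuple[int, int]] = set()
        for rid, px in self.soma_rois.items():
            pts = {tuple(p) for p in np.asarray(px)}
            if seen & pts:
                raise ValueError(f"soma ROI {rid} overlaps another soma ROI")
            seen |= pts
        if len(self.nonsoma_roi) and seen & {tuple(p) for p in np.asarray(self.nonsoma_roi)}:
            raise ValueError("non-soma ROI overlaps a soma ROI")


@dataclass
class EventProbability:
    """P(High Ca2+) for one ROI: high pixel-frame count / (pixels x frames)."""

    roi_id: str
    p_high: float
    n_pixels: int
    n_frames: int

    def __post_init__(self):
        if not 0.0 <= self.p_high <= 1.0:
            raise ValueError("p_high must lie in [0, 1]")


def _px_index(px: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    px = np.asarray(px)
    return px[:, 0], px[:, 1]


def pixel_dff(m: Movie, pre_period: TimeWindow) -> tuple[Movie, np.ndarray]:
    """Per-pixel dF/F with F the temporal mean over the pre-CSD period.

    Pixels whose baseline F is not positive cannot be normalized; they are
    set to NaN in the output, reported in the returned boolean bad-pixel
    mask, and excluded by downstream thresholding.
    """
    sl = m.window_slice(pre_period)
    f0 = m.data[sl].astype(np.float64).mean(axis=0)
    bad = f0 <= 0
    if bad.any():
        warnings.warn(f"{int(bad.sum())} pixel(s) with non-positive baseline F masked")
    f0_safe = np.where(bad, 1.0, f0)
    out = (m.data.astype(np.float64) - f0_safe) / f0_safe
    out[:, bad] = np.nan
    return Movie(data=out, frame_rate_hz=m.frame_rate_hz,
                 pixel_pitch_mm=m.pixel_pitch_mm, t0_s=m.t0_s), bad


def soma_rois_from_mask(mask: np.ndarray, min_px: int = 5, max_px: int = 500,
                        dilate_px: int = 2) -> RoiSet:
    """Soma ROIs from a binary astrocyte-marker mask (e.g. SR101 channel).

    Connected components with area in [min_px, max_px] become soma ROIs
    (touching somata merge into one component — segmenting them apart is out
    of scope). The non-soma region is the frame minus all somata dilated by
    ``dilate_px`` to keep a guard ring of mixed pixels out of both classes.
    """
    labels = measure.label(np.asarray(mask) > 0)
    somata: dict[int, np.ndarray] = {}
    keep = np.zeros_like(labels, dtype=bool)
    rid = 0
    for region in measure.regionprops(labels):
        if min_px <= region.area <= max_px:
            rid += 1
            somata[rid] = np.array(region.coords)
            keep[labels == region.label] = True
    if not somata:
        warnings.warn("no connected components within the soma size range")
    dilated = morphology.dilation(keep, morphology.disk(dilate_px))
    nonsoma = np.argwhere(~dilated)
    return RoiSet(soma_rois=somata, nonsoma_roi=nonsoma, provenance="mask-derived")


def high_ca_mask(dff: Movie, roi: np.ndarray, k_sd: float = 4.0,
                 ref: TimeWindow | None = None,
                 eval_window: TimeWindow | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Boolean high-Ca2+ exceedance matrix for one pixel set.

    Per-pixel threshold = temporal mean + k_sd * SD over the reference
    window. Returns ``(exceed, valid)``: ``exceed`` is (n_eval_frames,
    n_pixels) and ``valid`` marks pixels with finite, non-zero-variance
    reference statistics; invalid pixels are reported and always False.
    """
    if ref is None:
        raise ValueError("a reference window for the threshold statistics is required")
    rows, cols = _px_index(roi)
    ref_vals = dff.data[dff.window_slice(ref)][:, rows, cols].astype(np.float64)
    mu = ref_vals.mean(axis=0)
    sd = ref_vals.std(axis=0)
    valid = np.isfinite(mu) & np.isfinite(sd) & (sd > 0)
    if not valid.all():
        warnings.warn(f"{int((~valid).sum())} pixel(s) excluded (zero-variance or invalid reference)")
    thresh = mu + k_sd * sd
    ev_sl = dff.window_slice(eval_window) if eval_window is not None else slice(None)
    vals = dff.data[ev_sl][:, rows, cols]
    with np.errstate(invalid="ignore"):
        exceed = vals > thresh[None, :]
    exceed[:, ~valid] = False
    return exceed, valid


def event_probability(dff: Movie, rois: RoiSet, eval_window: TimeWindow,
                      ref_window: TimeWindow, mode: str = "per_soma",
                      k_sd: float = 4.0) -> list[EventProbability]:
    """P(High Ca2+) per soma, or pooled over the entire non-soma ROI.

    The probability is the total high pixel-frame count divided by the
    number of valid ROI pixels times the number of evaluation frames.
    """
    if mode not in ("per_soma", "pooled_nonsoma"):
        raise ValueError("mode must be 'per_soma' or 'pooled_nonsoma'")
    roi_items = (list(rois.soma_rois.items()) if mode == "per_soma"
                 else [("nonsoma", rois.nonsoma_roi)])
    out = []
    for rid, px in roi_items:
        px = np.asarray(px)
        if px.size == 0:
            raise ValueError(f"ROI {rid} is empty")
        exceed, valid = high_ca_mask(dff, px, k_sd=k_sd, ref=ref_window,
                                     eval_window=eval_window)
        n_pix = int(valid.sum())
        n_frames = exceed.shape[0]
        if n_pix == 0:
            warnings.warn(f"ROI {rid}: no valid pixels; P(High Ca2+) reported as 0")
            p = 0.0
        else:
            p = float(exceed[:, valid].sum()) / (n_pix * n_frames)
        out.append(EventProbability(roi_id=str(rid), p_high=p,
                                    n_pixels=n_pix, n_frames=n_frames))
    return out


def gliopil_roi_from_events(dff: Movie, rois: RoiSet,
                            ref_periods: list[TimeWindow],
                            k_sd: float = 4.0) -> np.ndarray:
    """Gliopil ROI: non-soma pixels showing a Ca2+ event in any reference period.

    A pixel qualifies if it is supra-threshold (mean + k SD over that
    period) in at least one frame of at least one reference period. An empty
    result falls back, with a warning, to the whole non-soma region.
    """
    px = np.asarray(rois.nonsoma_roi)
    hit = np.zeros(len(px), dtype=bool)
    for w in ref_periods:
        exceed, valid = high_ca_mask(dff, px, k_sd=k_sd, ref=w, eval_window=w)
        hit |= exceed.any(axis=0) & valid
    if not hit.any():
        warnings.warn("no non-soma pixels with events in the reference periods; "
                      "falling back to the whole non-soma region")
        return px.copy()
    return px[hit]


def soma_traces(dff: Movie, rois: RoiSet, window: TimeWindow | None = None) -> list[Trace]:
    """Mean dF/F over each soma's pixels per frame, in soma-id order."""
    sl = dff.window_slice(window) if window is not None else slice(None)
    t0 = dff.t0_s + (sl.start or 0) / dff.frame_rate_hz if sl != slice(None) else dff.t0_s
    out = []
    for rid in sorted(rois.soma_rois):
        rows, cols = _px_index(rois.soma_rois[rid])
        vals = np.nanmean(dff.data[sl][:, rows, cols], axis=1)
        out.append(Trace(values=vals, rate_hz=dff.frame_rate_hz, t0_s=t0, unit="dff"))
    return out


def pairwise_soma_correlation(traces: list[Trace] | list[np.ndarray],
                              aggregate: str = "per_pair"):
    """Pearson correlation of simultaneously recorded soma Ca2+ signals.

    ``per_pair`` returns the full symmetric correlation matrix (unit
    diagonal, NaN rows/cols for excluded zero-variance traces);
    ``mean_per_recording`` returns the mean over the upper triangle of
    valid pairs — the per-recording synchrony statistic.
    """
    if aggregate not in ("per_pair", "mean_per_recording"):
        raise ValueError("aggregate must be 'per_pair' or 'mean_per_recording'")
    arrs = [np.asarray(tr.values if isinstance(tr, Trace) else tr, dtype=np.float64)
            for tr in traces]
    if len(arrs) < 2:
        raise ValueError("need at least two traces")
    lengths = {len(a) for a in arrs}
    if len(lengths) != 1:
        raise ValueError(f"traces have unequal lengths: {sorted(lengths)}")
    x = np.vstack(arrs)
    sd = x.std(axis=1)
    bad = sd == 0
    if bad.any():
        warnings.warn(f"{int(bad.sum())} zero-variance trace(s) excluded from correlations")
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(x)
    corr[bad, :] = np.nan
    corr[:, bad] = np.nan
    np.fill_diagonal(corr, np.where(bad, np.nan, 1.0))
    if aggregate == "per_pair":
        return corr
    iu = np.triu_indices(len(arrs), k=1)
    vals = corr[iu]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValueError("no valid soma pairs")
    return float(vals.mean())
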