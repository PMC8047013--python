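"""Core containers and readers/writers shared by all analysis stages.

Conventions: time is in seconds on the experiment clock with t = 0 at KCl
application; frame ``k`` of a movie maps to ``t0_s + k / frame_rate_hz``;
all analysis windows are half-open ``[start, end)``; pixel coordinates are
0-based, row-major; ROIs are axis-aligned rectangles.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import h5py
import numpy as np
import tifffile
import yaml

__all__ = [
    "Movie", "Trace", "TimeWindow", "PixelRect",
    "read_movie", "write_movie", "bin_movie", "extract_roi_trace",
    "read_trace", "write_trace",
]

TRACE_UNITS = ("dff", "mV", "mM", "au")


@dataclass(frozen=True)
class TimeWindow:
    """Half-open interval [start_s, end_s) on the experiment clock."""

    start_s: float
    end_s: float

    def __post_init__(self):
        if not self.end_s > self.start_s:
            raise ValueError(f"TimeWindow requires end_s > start_s, got [{self.start_s}, {self.end_s})")

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s

    def contains(self, t: float) -> bool:
        return self.start_s <= t < self.end_s


@dataclass
class Movie:
    """A fluorescence movie: intensity[frame, row, col] plus acquisition geometry.

    ``data`` holds raw counts (16-bit native) or float values after
    processing; ``pixel_pitch_mm`` is the physical size of one pixel.
    """

    data: np.ndarray
    frame_rate_hz: float
    pixel_pitch_mm: float
    t0_s: float = 0.0

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3 or self.data.shape[0] < 1:
            raise ValueError("Movie data must be a (frame, row, col) array with >= 1 frame")
        if not self.frame_rate_hz > 0:
            raise ValueError("frame_rate_hz must be > 0")
        if not self.pixel_pitch_mm > 0:
            raise ValueError("pixel_pitch_mm must be > 0")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def shape(self):
        return self.data.shape

    @property
    def times_s(self) -> np.ndarray:
        return self.t0_s + np.arange(self.n_frames) / self.frame_rate_hz

    def frame_index(self, t_s: float) -> int:
        """Index of the first frame at or after clock time ``t_s``."""
        return int(np.ceil((t_s - self.t0_s) * self.frame_rate_hz - 1e-9))

    def window_slice(self, w: TimeWindow) -> slice:
        """Frame slice covering the half-open window [start, end)."""
        i0 = max(self.frame_index(w.start_s), 0)
        i1 = min(self.frame_index(w.end_s), self.n_frames)
        if i1 <= i0:
            raise ValueError(f"window {w} contains no frames of this movie")
        return slice(i0, i1)


@dataclass
class Trace:
    """A uniformly sampled 1-D signal with a physical unit tag.

    ``unit`` is one of 'dff' (relative fluorescence change), 'mV', 'mM'
    or 'au'. NaNs are rejected at construction: a NaN here would silently
    poison every downstream threshold, RMS and median.
    """

    values: np.ndarray
    rate_hz: float
    t0_s: float = 0.0
    unit: str = "au"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 1:
            raise ValueError("Trace values must be 1-D")
        if not self.rate_hz > 0:
            raise ValueError("rate_hz must be > 0")
        if self.unit not in TRACE_UNITS:
            raise ValueError(f"unit must be one of {TRACE_UNITS}, got {self.unit!r}")
        if np.isnan(self.values).any():
            raise ValueError("Trace values contain NaN")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def times_s(self) -> np.ndarray:
        return self.t0_s + np.arange(len(self.values)) / self.rate_hz

    @property
    def duration_s(self) -> float:
        return len(self.values) / self.rate_hz

    def sample_index(self, t_s: float) -> int:
        return int(np.ceil((t_s - self.t0_s) * self.rate_hz - 1e-9))

    def window_slice(self, w: TimeWindow, require_full: bool = False) -> slice:
        i0 = self.sample_index(w.start_s)
        i1 = self.sample_index(w.end_s)
        if require_full and (i0 < 0 or i1 > len(self.values)):
            raise ValueError(f"trace does not fully cover window {w}")
        i0 = max(i0, 0)
        i1 = min(i1, len(self.values))
        if i1 <= i0:
            raise ValueError(f"window {w} contains no samples of this trace")
        return slice(i0, i1)

    def window_values(self, w: TimeWindow, require_full: bool = False) -> np.ndarray:
        return self.values[self.window_slice(w, require_full=require_full)]


@dataclass(frozen=True)
class PixelRect:
    """Axis-aligned pixel rectangle, half-open: rows [r0, r1), cols [c0, c1)."""

    r0: int
    r1: int
    c0: int
    c1: int

    def __post_init__(self):
        if self.r1 <= self.r0 or self.c1 <= self.c0:
            raise ValueError("PixelRect must have positive extent")


# ---------------------------------------------------------------------------
# movies


def _load_sidecar(path: str) -> dict:
    base, _ = os.path.splitext(path)
    for cand in (base + ".yaml", base + ".yml", path + ".yaml"):
        if os.path.exists(cand):
            with open(cand) as fh:
                return yaml.safe_load(fh) or {}
    return {}


def read_movie(path: str, meta: dict | str | None = None) -> Movie:
    """Read a multi-page TIFF movie plus its acquisition metadata.

    Metadata (``frame_rate_hz``, ``pixel_pitch_mm``, optional ``t0_s``) comes
    from ``meta`` — a dict or path to a YAML file — or, if omitted, from a
    sidecar YAML next to the TIFF. Missing frame rate or pixel pitch is an
    error, never a default: a silently guessed frame rate corrupts every
    downstream speed and interval estimate.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    with tifffile.TiffFile(path) as tf:
        shapes = {p.shape for p in tf.pages}
        if len(shapes) != 1:
            raise ValueError(f"inconsistent geometry: TIFF pages have shapes {sorted(shapes)}")
        data = tf.asarray()
    if data.ndim == 2:
        data = data[None]

    if meta is None:
        md = _load_sidecar(path)
    elif isinstance(meta, str):
        with open(meta) as fh:
            md = yaml.safe_load(fh) or {}
    else:
        md = dict(meta)
    for key in ("frame_rate_hz", "pixel_pitch_mm"):
        if key not in md:
            raise ValueError(f"movie metadata missing required key {key!r} (no silent defaults)")
    return Movie(data=data, frame_rate_hz=float(md["frame_rate_hz"]),
                 pixel_pitch_mm=float(md["pixel_pitch_mm"]), t0_s=float(md.get("t0_s", 0.0)))


def write_movie(path: str, m: Movie) -> None:
    """Write a movie as multi-page TIFF with a YAML metadata sidecar."""
    tifffile.imwrite(path, m.data, photometric="minisblack")
    base, _ = os.path.splitext(path)
    with open(base + ".yaml", "w") as fh:
        yaml.safe_dump(
            {"frame_rate_hz": float(m.frame_rate_hz),
             "pixel_pitch_mm": float(m.pixel_pitch_mm),
             "t0_s": float(m.t0_s)}, fh)


def bin_movie(m: Movie, factor: int) -> Movie:
    """Spatially bin a movie by ``factor`` using block means.

    Block means (not sums) keep intensities comparable across binning factors
    and leave dF/F, which is scale-invariant, untouched. The pixel pitch
    scales by ``factor``.
    """
    if factor < 1 or int(factor) != factor:
        raise ValueError("binning factor must be a positive integer")
    n, r, c = m.data.shape
    if r % factor or c % factor:
        raise ValueError(f"movie geometry {r}x{c} is not divisible by binning factor {factor}")
    out = m.data.reshape(n, r // factor, factor, c // factor, factor).mean(axis=(2, 4))
    return Movie(data=out, frame_rate_hz=m.frame_rate_hz,
                 pixel_pitch_mm=m.pixel_pitch_mm * factor, t0_s=m.t0_s)


def extract_roi_trace(m: Movie, roi: PixelRect | tuple) -> Trace:
    """Per-frame mean intensity over a rectangular ROI, as an 'au' trace."""
    if not isinstance(roi, PixelRect):
        roi = PixelRect(*roi)
    n, r, c = m.data.shape
    if roi.r0 < 0 or roi.c0 < 0 or roi.r1 > r or roi.c1 > c:
        raise ValueError(f"ROI {roi} out of bounds for {r}x{c} frames")
    vals = m.data[:, roi.r0:roi.r1, roi.c0:roi.c1].mean(axis=(1, 2))
    return Trace(values=np.asarray(vals, dtype=np.float64), rate_hz=m.frame_rate_hz,
                 t0_s=m.t0_s, unit="au")


# ---------------------------------------------------------------------------
# traces


def write_trace(path: str, t: Trace) -> None:
    """Write a trace to CSV (``# key: value`` header, time,value rows) or HDF5.

    The format is chosen by extension (.h5/.hdf5 vs anything else). Both
    store float64 losslessly: CSV uses 17 significant digits, which
    round-trips IEEE doubles bit-exactly.
    """
    ext = os.path.splitext(path)[1].lower()
    if ext in (".h5", ".hdf5"):
        with h5py.File(path, "w") as fh:
            g = fh.create_group("trace")
            g.create_dataset("values", data=t.values, dtype="f8")
            g.attrs["rate_hz"] = float(t.rate_hz)
            g.attrs["t0_s"] = float(t.t0_s)
            g.attrs["unit"] = t.unit
        return
    with open(path, "w") as fh:
        fh.write(f"# unit: {t.unit}\n# rate_hz: {t.rate_hz!r}\n# t0_s: {t.t0_s!r}\n")
        fh.write("time_s,value\n")
        for k, v in enumerate(t.values):
            fh.write(f"{float(t.t0_s + k / t.rate_hz)!r},{float(v)!r}\n")


def read_trace(path: str) -> Trace:
    """Read a trace written by :func:`write_trace` (CSV or HDF5)."""
    ext = os.path.splitext(path)[1].lower()
    if ext in (".h5", ".hdf5"):
        with h5py.File(path, "r") as fh:
            g = fh["trace"]
            if "rate_hz" not in g.attrs or "unit" not in g.attrs:
                raise ValueError("trace HDF5 missing rate_hz/unit metadata")
            return Trace(values=g["values"][:], rate_hz=float(g.attrs["rate_hz"]),
                         t0_s=float(g.attrs.get("t0_s", 0.0)), unit=str(g.attrs["unit"]))
    meta: dict[str, str] = {}
    values = []
    with open(path) as fh:
        header_done = False
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                key, _, val = line[1:].partition(":")
                meta[key.strip()] = val.strip()
                continue
            if not header_done:
                if line.split(",") != ["time_s", "value"]:
                    raise ValueError(f"unexpected trace CSV column header: {line!r}")
                header_done = True
                continue
            parts = line.split(",")
            if len(parts) != 2:
                raise ValueError(f"expected 2 columns in trace CSV, got {len(parts)}: {line!r}")
            values.append(float(parts[1]))
    if "unit" not in meta or "rate_hz" not in meta:
        raise ValueError("trace CSV missing unit/rate_hz metadata header")
    return Trace(values=np.array(values, dtype=np.float64), rate_hz=float(meta["rate_hz"]),
                 t0_s=float(meta.get("t0_s", 0.0)), unit=meta["unit"])
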