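"""Movie, ROI and spike-table I/O plus per-ROI trace extraction.

Conventions: pixel coordinates are 0-based ``(row, col)``; frames are
0-based; times are seconds.  Movies are multi-page TIFF stacks shaped
``(frames, rows, cols)`` or ``(frames, rows, cols, channels)``.
"""
from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from shapely import contains_xy
from shapely.geometry import Polygon

from .core import FluorescenceTrace, SpikeTrain

__all__ = [
    "Movie",
    "ROISet",
    "read_movie",
    "write_movie",
    "read_rois",
    "read_spikes",
    "extract_trace",
    "write_traces",
    "read_traces",
]


@dataclass
class Movie:
    """Image time series with frame-rate metadata."""

    data: np.ndarray
    frame_rate: float
    channel_names: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim not in (3, 4):
            raise ValueError("movie must be (T, H, W) or (T, H, W, C)")
        if self.data.shape[0] < 1:
            raise ValueError("movie must contain at least one frame")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")

    @property
    def n_frames(self) -> int:
        return int(self.data.shape[0])

    @property
    def n_channels(self) -> int:
        return int(self.data.shape[3]) if self.data.ndim == 4 else 1

    @property
    def frame_shape(self) -> tuple[int, int]:
        return int(self.data.shape[1]), int(self.data.shape[2])


@dataclass
class ROISet:
    """Named pixel sets for neurons plus an optional background region."""

    rois: dict[int, np.ndarray]               # roi_id -> (N, 2) int pixels
    background_roi: np.ndarray | None = None  # (N, 2) int pixels

    def __post_init__(self) -> None:
        for rid, pix in self.rois.items():
            pix = np.asarray(pix, dtype=int)
            if pix.ndim != 2 or pix.shape[1] != 2 or pix.shape[0] == 0:
                raise ValueError(f"ROI {rid}: pixel set must be non-empty (N, 2)")
            self.rois[rid] = pix
        self._warn_overlap()

    def _warn_overlap(self) -> None:
        seen: set[tuple[int, int]] = set()
        for rid, pix in self.rois.items():
            px = set(map(tuple, pix))
            if seen & px:
                warnings.warn(f"ROI {rid} overlaps a previous ROI",
                              stacklevel=3)
            seen |= px

    def validate_bounds(self, frame_shape: tuple[int, int]) -> None:
        h, w = frame_shape
        for rid, pix in self.rois.items():
            if (pix < 0).any() or (pix[:, 0] >= h).any() or (pix[:, 1] >= w).any():
                raise ValueError(f"ROI {rid} has pixels outside {frame_shape}")


def read_movie(path, frame_rate: float, channel_axis: int | None = None
               ) -> Movie:
    """Read a multi-page TIFF stack, preserving dimensions and dtype.

    A trailing axis of length ≤ 4 is treated as the channel axis; pass
    ``channel_axis`` to override the guess for unusual shapes.
    """
    try:
        data = tifffile.imread(path)
    except Exception as exc:  # tifffile raises various error types
        raise IOError(f"cannot read TIFF movie {path}: {exc}") from exc
    data = np.asarray(data)
    if data.ndim == 2:
        data = data[None]
    if data.size == 0:
        raise IOError(f"TIFF movie {path} contains no frames")
    if data.ndim == 4 and channel_axis is not None and channel_axis != 3:
        data = np.moveaxis(data, channel_axis, 3)
    if data.ndim == 4 and channel_axis is None and data.shape[-1] > 4:
        # channels-second layout (T, C, H, W) written by other tools
        if data.shape[1] <= 4:
            data = np.moveaxis(data, 1, 3)
        else:
            raise IOError(f"cannot locate channel axis in shape {data.shape}")
    return Movie(data=data, frame_rate=frame_rate)


def write_movie(movie: Movie, path, dtype=np.uint16) -> None:
    """Write a movie as a multi-page TIFF, clipping into the dtype range."""
    data = movie.data
    if np.issubdtype(np.dtype(dtype), np.integer):
        info = np.iinfo(dtype)
        data = np.clip(np.round(data), info.min, info.max).astype(dtype)
    tifffile.imwrite(path, data)


def _rasterize_polygon(vertices: np.ndarray,
                       bound: float = 1e6) -> np.ndarray:
    """Pixels whose centers (row+0.5, col+0.5) fall inside the polygon."""
    poly = Polygon(vertices)
    if not poly.is_valid or poly.area == 0:
        raise ValueError("polygon is degenerate")
    rmin, cmin, rmax, cmax = poly.bounds
    rows = np.arange(int(np.floor(rmin)), int(np.ceil(rmax)) + 1)
    cols = np.arange(int(np.floor(cmin)), int(np.ceil(cmax)) + 1)
    rr, cc = np.meshgrid(rows, cols, indexing="ij")
    inside = contains_xy(poly, rr.ravel() + 0.5, cc.ravel() + 0.5)
    pix = np.column_stack([rr.ravel()[inside], cc.ravel()[inside]])
    if pix.shape[0] == 0:
        raise ValueError("polygon covers no pixel centers")
    return pix


def read_rois(path, image_shape: tuple[int, int] | None = None) -> ROISet:
    """Read ROI definitions from a JSON polygon list or a label-mask TIFF.

    JSON layout::

        {"rois": [{"id": 1, "polygon": [[r, c], ...]}, ...],
         "background": {"polygon": [[r, c], ...]}}

    Polygons are rasterized with a pixel-center-inside rule.  In a label
    mask, each distinct non-zero label becomes one ROI.
    """
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        labels = tifffile.imread(path)
        if labels.ndim != 2:
            raise ValueError("label mask must be a single 2-D image")
        rois = {}
        for lab in np.unique(labels):
            if lab == 0:
                continue
            rois[int(lab)] = np.column_stack(np.nonzero(labels == lab))
        roiset = ROISet(rois=rois)
    else:
        with open(path) as fh:
            doc = json.load(fh)
        rois = {int(entry["id"]):
                _rasterize_polygon(np.asarray(entry["polygon"], dtype=float))
                for entry in doc["rois"]}
        bg = None
        if doc.get("background"):
            bg = _rasterize_polygon(
                np.asarray(doc["background"]["polygon"], dtype=float))
        roiset = ROISet(rois=rois, background_roi=bg)
    if image_shape is not None:
        roiset.validate_bounds(image_shape)
    return roiset


def read_spikes(path, duration: float | None = None) -> SpikeTrain:
    """Read spike times from a CSV with a ``time_s`` column."""
    df = pd.read_csv(path)
    if "time_s" not in df.columns:
        raise ValueError(f"{path}: spike CSV must have a 'time_s' column")
    t = df["time_s"].to_numpy(dtype=float)
    if t.size and np.any(np.diff(t) <= 0):
        raise ValueError(f"{path}: spike times must be strictly increasing")
    if duration is None:
        duration = float(t[-1]) if t.size else 1.0
    return SpikeTrain(times=t, duration=duration)


def _background_per_frame(movie: Movie, rois: ROISet, channel: int
                          ) -> np.ndarray:
    """Per-frame background: mean of the background ROI when supplied,
    otherwise the 1st percentile of each frame (common-practice fallback;
    the choice is configurable through the ROI file)."""
    data = movie.data if movie.data.ndim == 3 else movie.data[..., channel]
    if rois.background_roi is not None:
        bg = rois.background_roi
        return data[:, bg[:, 0], bg[:, 1]].mean(axis=1)
    return np.percentile(data.reshape(movie.n_frames, -1), 1, axis=1)


def extract_trace(movie: Movie, rois: ROISet, roi_id: int,
                  channel: int = 0) -> FluorescenceTrace:
    """Background-subtracted mean fluorescence of one ROI per frame."""
    if roi_id not in rois.rois:
        raise KeyError(f"ROI {roi_id} not present (have {sorted(rois.rois)})")
    rois.validate_bounds(movie.frame_shape)
    data = movie.data if movie.data.ndim == 3 else movie.data[..., channel]
    pix = rois.rois[roi_id]
    raw = data[:, pix[:, 0], pix[:, 1]].mean(axis=1)
    values = raw - _background_per_frame(movie, rois, channel)
    return FluorescenceTrace(values=values, frame_rate=movie.frame_rate,
                             roi_id=roi_id)


def write_traces(traces: list[FluorescenceTrace], path) -> None:
    """Write traces as a long-format CSV (time_s, roi_id, F)."""
    frames = [pd.DataFrame({"time_s": tr.times, "roi_id": tr.roi_id,
                            "F": tr.values}) for tr in traces]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False,
                                                float_format="%.6f")


def read_traces(path, frame_rate: float) -> list[FluorescenceTrace]:
    """Read a long-format trace CSV back into per-ROI traces."""
    df = pd.read_csv(path)
    for col in ("time_s", "roi_id", "F"):
        if col not in df.columns:
            raise ValueError(f"{path}: trace CSV must have a '{col}' column")
    out = []
    for rid, grp in df.groupby("roi_id", sort=True):
        grp = grp.sort_values("time_s")
        out.append(FluorescenceTrace(values=grp["F"].to_numpy(dtype=float),
                                     frame_rate=frame_rate, roi_id=rid))
    return out
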