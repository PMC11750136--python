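"""Spatially binned occupancy/event maps and their correlation.

The arena is divided into square bins (default 50 px). The occupancy map
accumulates time (1/fps s per frame) in the bin containing the nose; the
event map accumulates detected calcium events at their mapped positions.
Column-wise Pearson correlation between the two maps quantifies how closely
population activity tracks where the animal spends its time; zone event
ratios and their across-animal correlation with behavioral indices quantify
the novelty bias.

Bins are half-open ``[k*bin, (k+1)*bin)``; points on the right/bottom arena
edge fall into the last bin. ``grid[row, col]`` follows image convention:
row indexes y (downward), col indexes x.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Optional, Sequence

import numpy as np
from scipy import stats as spstats

from .behavior import ZoneOccupancy
from .io_formats import ArenaLayout, PoseTrack

__all__ = [
    "HeatMap",
    "CorrelationProfile",
    "occupancy_map",
    "event_map",
    "column_correlation",
    "zone_event_ratio",
    "ratio_index_correlation",
    "nose_distance_vector",
]


@dataclass(frozen=True)
class HeatMap:
    """A 2-D spatial accumulator over the arena (seconds or event counts)."""

    grid: np.ndarray  # (rows, cols), nonnegative
    bin_px: float
    origin: tuple[float, float] = (0.0, 0.0)
    units: str = "seconds"
    n_clamped: int = 0  # points outside the arena pulled into an edge bin

    @property
    def total(self) -> float:
        return float(self.grid.sum())


@dataclass(frozen=True)
class CorrelationProfile:
    """Per-column Pearson r between two heatmaps; NaN where undefined."""

    r: np.ndarray
    n_valid: int

    @property
    def valid(self) -> np.ndarray:
        return self.r[np.isfinite(self.r)]

    @property
    def median_r(self) -> float:
        v = self.valid
        return float(np.median(v)) if v.size else math.nan


def _grid_shape(arena_size_px: tuple[float, float], bin_px: float) -> tuple[int, int]:
    w, h = arena_size_px
    return int(np.ceil(h / bin_px)), int(np.ceil(w / bin_px))


def _bin_points(
    xy: np.ndarray, arena_size_px: tuple[float, float], bin_px: float
) -> tuple[np.ndarray, np.ndarray, int]:
    """Map points to (row, col) bins; clamp strays up to 1 px outside."""
    w, h = arena_size_px
    x = xy[:, 0]
    y = xy[:, 1]
    outside = (x < 0) | (x > w) | (y < 0) | (y > h)
    n_clamped = int(np.count_nonzero(outside))
    x = np.clip(x, 0.0, np.nextafter(w, -np.inf))
    y = np.clip(y, 0.0, np.nextafter(h, -np.inf))
    rows = np.floor(y / bin_px).astype(int)
    cols = np.floor(x / bin_px).astype(int)
    nrows, ncols = _grid_shape(arena_size_px, bin_px)
    rows = np.minimum(rows, nrows - 1)
    cols = np.minimum(cols, ncols - 1)
    return rows, cols, n_clamped


def occupancy_map(track: PoseTrack, layout: ArenaLayout, bin_px: float = 50.0) -> HeatMap:
    """Cumulative-time heatmap: each frame adds 1/fps seconds to its bin.

    Mass conservation holds exactly: the grid total equals
    ``n_frames / fps`` (integer counts are accumulated, then scaled once).
    """
    rows, cols, n_clamped = _bin_points(track.nose_xy, layout.arena_size_px, bin_px)
    shape = _grid_shape(layout.arena_size_px, bin_px)
    counts = np.zeros(shape, dtype=np.int64)
    np.add.at(counts, (rows, cols), 1)
    return HeatMap(
        grid=counts * (1.0 / track.fps),
        bin_px=bin_px,
        units="seconds",
        n_clamped=n_clamped,
    )


def event_map(
    positions_px: np.ndarray, layout: ArenaLayout, bin_px: float = 50.0
) -> HeatMap:
    """Cumulative-event heatmap: counts of events per spatial bin."""
    positions_px = np.asarray(positions_px, dtype=float).reshape(-1, 2)
    shape = _grid_shape(layout.arena_size_px, bin_px)
    counts = np.zeros(shape, dtype=np.int64)
    if len(positions_px):
        rows, cols, n_clamped = _bin_points(positions_px, layout.arena_size_px, bin_px)
        np.add.at(counts, (rows, cols), 1)
    else:
        n_clamped = 0
    return HeatMap(grid=counts.astype(float), bin_px=bin_px, units="counts", n_clamped=n_clamped)


def column_correlation(
    time_map: HeatMap,
    ev_map: HeatMap,
    axis: Literal["column", "row"] = "column",
    interior_only: bool = False,
) -> CorrelationProfile:
    """Pearson r between matching columns of the time and event maps.

    A "column" is a constant-x strip of the binned arena image (axis="row"
    correlates constant-y strips instead). Columns where either vector has
    zero variance are undefined (NaN) and excluded from ``n_valid``;
    ``interior_only`` drops the outermost strips before correlating.
    """
    a = np.asarray(time_map.grid, dtype=float)
    b = np.asarray(ev_map.grid, dtype=float)
    if a.shape != b.shape or time_map.bin_px != ev_map.bin_px:
        raise ValueError("heatmaps must share shape and bin geometry")
    if axis == "row":
        a, b = a.T, b.T
    sl = slice(1, -1) if interior_only and a.shape[1] > 2 else slice(None)
    a = a[:, sl]
    b = b[:, sl]
    rs = np.full(a.shape[1], np.nan)
    for j in range(a.shape[1]):
        u, v = a[:, j], b[:, j]
        if u.std() == 0 or v.std() == 0:
            continue
        rs[j] = spstats.pearsonr(u, v).statistic
    return CorrelationProfile(r=rs, n_valid=int(np.isfinite(rs).sum()))


def zone_event_ratio(
    event_frames: np.ndarray, occupancy: ZoneOccupancy, zone_a: str, zone_b: str
) -> float:
    """Ratio of event counts between two interaction zones.

    Events are attributed to zones through the per-frame zone labels of the
    behavioral track. Returns ``inf`` when zone_b has no events but zone_a
    does, and ``nan`` (undefined) when neither zone has events; these markers
    are excluded (never treated as numbers) by the cohort-level correlation.
    """
    labels = occupancy.labels
    known = set(labels.tolist()) | set(occupancy.zone_time_s)
    for z in (zone_a, zone_b):
        if z not in known:
            raise ValueError(f"unknown zone {z!r}")
    ev = np.asarray(event_frames, dtype=int)
    n_a = int(np.count_nonzero(labels[ev] == zone_a))
    n_b = int(np.count_nonzero(labels[ev] == zone_b))
    if n_b == 0:
        return math.inf if n_a > 0 else math.nan
    return n_a / n_b


def ratio_index_correlation(
    pairs: Sequence[tuple[float, Optional[float]]],
) -> tuple[float, float, int, int]:
    """Pearson correlation between zone event ratios and behavioral indices.

    Non-finite ratios (``inf``/``nan`` markers) and undefined indices are
    excluded; at least 3 finite pairs must remain. Returns
    ``(r, two-sided p, n_used, n_excluded)``.
    """
    finite = [
        (r, i)
        for r, i in pairs
        if i is not None and math.isfinite(r) and math.isfinite(i)
    ]
    n_excluded = len(pairs) - len(finite)
    if len(finite) < 3:
        raise ValueError("need at least 3 finite (ratio, index) pairs")
    x = np.array([p[0] for p in finite])
    y = np.array([p[1] for p in finite])
    res = spstats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue), len(finite), n_excluded


def nose_distance_vector(track: PoseTrack, center_xy: tuple[float, float], px_per_cm: Optional[float] = None) -> np.ndarray:
    """Per-frame Euclidean distance from the nose to a chamber center.

    Returned in pixels, or centimeters when ``px_per_cm`` is given.
    """
    d = np.linalg.norm(track.nose_xy - np.asarray(center_xy, dtype=float), axis=1)
    return d / px_per_cm if px_per_cm else d
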