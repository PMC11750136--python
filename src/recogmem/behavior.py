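"""Zone assignment, interaction times, and behavioral indices.

Each video frame is assigned to at most one interaction zone from the nose
position; cumulative zone times yield the sociability index (conspecific vs
object) and discrimination index (novel vs familiar), with the within-subject
exclusion rule applied at saline treatment.

Boundary conventions (tested explicitly): zone membership uses strict
inequality at the outer radius, a frame exactly on the boundary is outside;
frames equidistant from two candidate chamber centers are assigned to no zone.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .io_formats import ArenaLayout, PoseTrack

__all__ = [
    "ZoneOccupancy",
    "SessionIndices",
    "ExclusionRecord",
    "assign_zones",
    "sociability_index",
    "discrimination_index",
    "apply_exclusion",
    "locomotion",
]

#: label used for frames outside every interaction zone
NO_ZONE = "none"


@dataclass(frozen=True)
class ZoneOccupancy:
    """Per-frame zone labels and cumulative per-zone interaction times."""

    labels: np.ndarray  # (n,) unicode array of chamber labels or NO_ZONE
    zone_time_s: dict[str, float]  # cumulative seconds per chamber label
    fps: float

    def time_in(self, zone: str) -> float:
        return self.zone_time_s.get(zone, 0.0)

    def frames_in(self, zone: str) -> np.ndarray:
        return np.nonzero(self.labels == zone)[0]


@dataclass(frozen=True)
class SessionIndices:
    """Summary behavioral measures for one session phase."""

    sociability_index: Optional[float]
    discrimination_index: Optional[float]
    zone_time_s: dict[str, float]
    distance_cm: float
    mean_velocity_cm_s: float


@dataclass(frozen=True)
class ExclusionRecord:
    subject: str
    saline_di: float
    rule: str = "saline discrimination index < 0.5"


def assign_zones(track: PoseTrack, layout: ArenaLayout) -> ZoneOccupancy:
    """Label every frame with the interaction zone containing the nose.

    In ``radial`` mode a frame is in chamber *k*'s zone iff the nose-to-center
    distance is strictly less than ``radial_radius_px``; in ``annulus`` mode
    iff ``edge_radius <= d < edge_radius + margin``. When several chambers'
    zones contain the frame it is assigned to the nearest center; an exact
    distance tie assigns no zone (conservative, avoids double counting).
    Cumulative interaction time is frame count / fps.
    """
    n = track.n_frames
    centers = np.array([c.center_xy for c in layout.chambers], dtype=float)
    names = [c.label for c in layout.chambers]
    labels = np.full(n, NO_ZONE, dtype=object)
    if len(names):
        # (n, k) distances from nose to each chamber center
        d = np.linalg.norm(track.nose_xy[:, None, :] - centers[None, :, :], axis=2)
        in_zone = np.zeros_like(d, dtype=bool)
        for j, ch in enumerate(layout.chambers):
            inner, outer = layout.zone_radius_px(ch)
            in_zone[:, j] = (d[:, j] >= inner) & (d[:, j] < outer)
        d_masked = np.where(in_zone, d, np.inf)
        best = np.argmin(d_masked, axis=1)
        best_d = d_masked[np.arange(n), best]
        any_zone = np.isfinite(best_d)
        # exact ties between candidate centers -> no zone
        tie = (d_masked == best_d[:, None]).sum(axis=1) > 1
        for i in np.nonzero(any_zone & ~tie)[0]:
            labels[i] = names[best[i]]
    zone_time = {
        name: float(np.count_nonzero(labels == name)) / track.fps for name in names
    }
    return ZoneOccupancy(labels=labels.astype(str), zone_time_s=zone_time, fps=track.fps)


def sociability_index(t_mouse_s: float, t_object_s: float) -> Optional[float]:
    """Conspecific interaction time over total interaction time.

    ``t_mouse / (t_mouse + t_object)``; 0.5 means no preference. Returns
    ``None`` (undefined) when both times are zero.
    """
    if t_mouse_s < 0 or t_object_s < 0:
        raise ValueError("interaction times must be nonnegative")
    total = t_mouse_s + t_object_s
    if total == 0:
        return None
    return t_mouse_s / total


def discrimination_index(t_novel_s: float, t_familiar_s: float) -> Optional[float]:
    """Novel-stimulus interaction time over total interaction time.

    ``t_novel / (t_novel + t_familiar)``; 0.5 is chance. Returns ``None``
    when both times are zero.
    """
    if t_novel_s < 0 or t_familiar_s < 0:
        raise ValueError("interaction times must be nonnegative")
    total = t_novel_s + t_familiar_s
    if total == 0:
        return None
    return t_novel_s / total


def apply_exclusion(
    saline_di_by_subject: dict[str, Optional[float]],
) -> tuple[list[str], list[ExclusionRecord]]:
    """Apply the within-subject exclusion rule.

    Subjects whose saline-treatment discrimination index is below 0.5 are
    excluded (a subject that cannot discriminate under vehicle cannot show a
    drug effect); DI of exactly 0.5 is retained. Returns (retained subjects,
    exclusion report). A missing or undefined saline DI is an error.
    """
    retained: list[str] = []
    report: list[ExclusionRecord] = []
    for subject, di in saline_di_by_subject.items():
        if di is None:
            raise ValueError(f"subject {subject!r}: saline discrimination index missing")
        if di < 0.5:
            report.append(ExclusionRecord(subject=subject, saline_di=float(di)))
        else:
            retained.append(subject)
    return retained, report


def locomotion(track: PoseTrack, px_per_cm: float) -> tuple[float, float]:
    """Total path length (cm) and mean velocity (cm/s) from the nose track."""
    if track.n_frames < 2:
        raise ValueError("need at least 2 frames")
    if px_per_cm <= 0:
        raise ValueError("px_per_cm must be positive")
    steps = np.linalg.norm(np.diff(track.nose_xy, axis=0), axis=1)
    dist_cm = float(steps.sum()) / px_per_cm
    return dist_cm, dist_cm / track.duration_s
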