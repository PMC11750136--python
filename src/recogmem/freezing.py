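"""Freezing detection from per-frame pixel-change fractions.

The trace-fear-conditioning analysis scores an animal as freezing when the
fraction of pixels changing between consecutive video frames stays below
0.1% for more than 1 s. This module consumes the precomputed per-frame
changed-pixel fraction series (the tracker computes it internally from
video); both comparisons are strict: values must be < threshold, and a run
must be strictly longer than ``min_dur_s`` (a run of exactly
``min_dur_s * fps`` frames is not a bout).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .io_formats import PhaseWindow

__all__ = ["FreezingResult", "detect_freezing", "percent_freezing"]


@dataclass(frozen=True)
class FreezingResult:
    """Detected freezing bouts (non-overlapping, each > min duration)."""

    bouts: tuple[tuple[float, float], ...]  # (start_s, end_s)
    threshold: float
    min_dur_s: float
    fps: float
    duration_s: float

    @property
    def total_frozen_s(self) -> float:
        return sum(e - s for s, e in self.bouts)


def detect_freezing(
    pixel_change: np.ndarray,
    fps: float,
    threshold: float = 0.001,
    min_dur_s: float = 1.0,
) -> FreezingResult:
    """Find maximal sub-threshold runs longer than ``min_dur_s``.

    ``pixel_change`` holds per-frame changed-pixel fractions in [0, 1]. A
    frame is motionless when its value is strictly below ``threshold``
    (default 0.1%); maximal runs of motionless frames strictly longer than
    ``min_dur_s`` become bouts. Bout bounds are reported in seconds: a run of
    frames [i, j] spans ``i/fps`` to ``(j+1)/fps``.
    """
    x = np.asarray(pixel_change, dtype=float)
    if fps <= 0:
        raise ValueError("fps must be positive")
    if np.any((x < 0) | (x > 1)):
        raise ValueError("pixel-change fractions must lie in [0, 1]")
    frozen = x < threshold
    bouts: list[tuple[float, float]] = []
    if frozen.any():
        padded = np.concatenate([[False], frozen, [False]]).astype(int)
        edges = np.diff(padded)
        starts = np.nonzero(edges == 1)[0]
        ends = np.nonzero(edges == -1)[0]  # exclusive
        min_frames = min_dur_s * fps
        for s, e in zip(starts, ends):
            if (e - s) > min_frames:
                bouts.append((s / fps, e / fps))
    return FreezingResult(
        bouts=tuple(bouts),
        threshold=threshold,
        min_dur_s=min_dur_s,
        fps=fps,
        duration_s=len(x) / fps,
    )


def percent_freezing(
    result: FreezingResult, windows: Sequence[PhaseWindow]
) -> dict[str, float]:
    """Percent of each protocol phase spent frozen.

    Bouts straddling a window edge contribute only their overlap. Windows
    must be non-empty and within the recording.
    """
    out: dict[str, float] = {}
    for w in windows:
        if w.end_s <= w.start_s:
            raise ValueError(f"window {w.label!r} is empty")
        if w.start_s < 0 or w.start_s >= result.duration_s:
            raise ValueError(f"window {w.label!r} outside the recording")
        frozen = 0.0
        for s, e in result.bouts:
            frozen += max(0.0, min(e, w.end_s) - max(s, w.start_s))
        out[w.label] = 100.0 * frozen / (w.end_s - w.start_s)
    return out
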