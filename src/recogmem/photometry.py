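"""Photometry signal conditioning and calcium-event detection.

The conditioning chain mirrors the acquisition pipeline: zero-phase
Butterworth low-pass at 40 Hz, session z-scoring of the calcium-dependent
channel, down-sampling to the 60 Hz behavioral frame rate, then discrete
event detection as upward crossings of the z-score above a threshold
(default 2.58, the two-sided alpha = 0.01 normal quantile).

An event is the onset of a threshold crossing (``z[i-1] <= theta < z[i]``),
not every suprathreshold sample: event *counts* are what enter the spatial
analysis. An optional refractory period (default 0 s) suppresses crossings
closer than the given gap.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
from scipy import signal as sps

from .io_formats import PhotometrySignal, PoseTrack

__all__ = [
    "EventTrain",
    "lowpass",
    "zscore",
    "resample_to",
    "detect_events",
    "events_to_positions",
    "condition",
]

#: two-sided 1% normal quantile; the default event threshold in z units
DEFAULT_THRESHOLD = 2.58


@dataclass(frozen=True)
class EventTrain:
    """Detected calcium events (times strictly increasing, within recording)."""

    time_s: np.ndarray
    sample_index: np.ndarray
    threshold: float

    def __post_init__(self) -> None:
        if len(self.time_s) > 1 and not np.all(np.diff(self.time_s) > 0):
            raise ValueError("event times must be strictly increasing")

    @property
    def n_events(self) -> int:
        return len(self.time_s)


def lowpass(sig: PhotometrySignal, cutoff_hz: float = 40.0, order: int = 4) -> PhotometrySignal:
    """Zero-phase Butterworth low-pass of both channels (DC gain 1).

    Applied forward-backward (``filtfilt``) so transients are not delayed
    relative to the behavioral clock. Requires ``fs > 2 * cutoff_hz``.
    """
    if sig.fs <= 2 * cutoff_hz:
        raise ValueError(
            f"cannot low-pass at {cutoff_hz} Hz: sampling rate {sig.fs} Hz "
            "does not satisfy the Nyquist condition"
        )
    sos = sps.butter(order, cutoff_hz, btype="low", fs=sig.fs, output="sos")
    return replace(
        sig,
        f470=sps.sosfiltfilt(sos, sig.f470),
        f415=sps.sosfiltfilt(sos, sig.f415),
        z=None,
    )


def zscore(
    sig: PhotometrySignal,
    baseline_window_s: Optional[tuple[float, float]] = None,
    regress_isosbestic: bool = False,
) -> PhotometrySignal:
    """z-score the calcium-dependent channel against a baseline window.

    ``z = (f470 - mean_baseline) / sd_baseline``; the default baseline is the
    whole session. When ``regress_isosbestic`` is set, a least-squares fit of
    the isosbestic channel onto f470 is subtracted first (motion correction;
    off by default as the acquisition already separates the channels by
    lock-in demodulation).
    """
    f = sig.f470
    if regress_isosbestic:
        A = np.column_stack([sig.f415, np.ones_like(sig.f415)])
        coef, *_ = np.linalg.lstsq(A, f, rcond=None)
        f = f - A @ coef
    if baseline_window_s is None:
        mask = np.ones(sig.n_samples, dtype=bool)
    else:
        t0, t1 = baseline_window_s
        if t1 - t0 < 10.0:
            raise ValueError("baseline window must span at least 10 s")
        mask = (sig.time_s >= t0) & (sig.time_s < t1)
        if not mask.any():
            raise ValueError("baseline window contains no samples")
    mu = float(f[mask].mean())
    sd = float(f[mask].std(ddof=0))
    if sd == 0:
        raise ValueError("zero baseline variance: cannot z-score")
    return replace(sig, z=(f - mu) / sd)


def resample_to(sig: PhotometrySignal, target_hz: float = 60.0) -> PhotometrySignal:
    """Down-sample all channels onto a uniform grid at ``target_hz``.

    The output grid is ``k / target_hz`` aligned to t = 0 with
    ``floor(duration * target_hz) + 1`` samples. An anti-alias low-pass at
    0.45 * target_hz is applied before interpolation unless the signal is
    already at the target rate. Up-sampling is refused.
    """
    if target_hz > sig.fs * (1 + 1e-9):
        raise ValueError("resample_to only down-samples")
    duration = sig.duration_s
    n_out = int(np.floor(duration * target_hz)) + 1
    t_out = np.arange(n_out) / target_hz
    t_out = t_out[t_out <= sig.time_s[-1] + 1e-12]

    def _one(x: np.ndarray) -> np.ndarray:
        if sig.fs > target_hz * (1 + 1e-9):
            sos = sps.butter(4, 0.45 * target_hz, btype="low", fs=sig.fs, output="sos")
            x = sps.sosfiltfilt(sos, x)
        return np.interp(t_out, sig.time_s, x)

    return PhotometrySignal(
        time_s=t_out,
        f470=_one(sig.f470),
        f415=_one(sig.f415),
        fs=target_hz,
        z=None if sig.z is None else _one(sig.z),
    )


def detect_events(
    sig: PhotometrySignal,
    threshold: float = DEFAULT_THRESHOLD,
    refractory_s: float = 0.0,
    rearm_z: Optional[float] = None,
) -> EventTrain:
    """Detect calcium events as upward crossings of the z-score.

    An event occurs at sample *i* (i >= 1) when ``z[i-1] <= threshold <
    z[i]``; a single suprathreshold excursion yields exactly one event
    regardless of its duration. A trace that starts above threshold does not
    register an event until it first falls to or below the threshold and
    crosses again.

    Two optional guards suppress re-triggering on noise while a slow
    transient hovers near the threshold: ``refractory_s`` discards crossings
    closer than the given gap to the previous event, and ``rearm_z``
    (hysteresis) discards crossings until the trace has first fallen below
    the re-arm level. Both default off, preserving plain rising-edge
    semantics.
    """
    if sig.z is None:
        raise ValueError("z-score not computed; run zscore() first")
    z = sig.z
    rising = np.nonzero((z[:-1] <= threshold) & (z[1:] > threshold))[0] + 1
    if rearm_z is not None and rising.size:
        if rearm_z >= threshold:
            raise ValueError("rearm_z must lie below the threshold")
        # keep only the first crossing after each excursion below the re-arm
        # level (Schmitt trigger); the detector starts armed
        below_idx = np.nonzero(z < rearm_z)[0]
        pos = np.searchsorted(below_idx, rising) - 1
        last_below = np.where(pos >= 0, below_idx[np.maximum(pos, 0)], -1)
        first = np.concatenate([[True], last_below[1:] != last_below[:-1]])
        rising = rising[first]
    if refractory_s > 0 and rising.size:
        kept = [rising[0]]
        min_gap = refractory_s
        for i in rising[1:]:
            if sig.time_s[i] - sig.time_s[kept[-1]] >= min_gap:
                kept.append(i)
        rising = np.asarray(kept)
    return EventTrain(
        time_s=sig.time_s[rising],
        sample_index=rising.astype(int),
        threshold=float(threshold),
    )


def events_to_positions(events: EventTrain, track: PoseTrack) -> np.ndarray:
    """Map each event to the nose position at the nearest behavioral frame.

    Requires the photometry and behavioral clocks to agree: every event time
    must fall within half a frame of some tracked frame and inside the track
    duration.

    Returns an (n_events, 2) pixel array.
    """
    if events.n_events == 0:
        return np.empty((0, 2), dtype=float)
    half_frame = 0.5 / track.fps
    idx = np.rint(events.time_s * track.fps).astype(int)
    if np.any(idx < 0) or np.any(idx >= track.n_frames):
        raise ValueError("event time outside the tracked session")
    dt = np.abs(events.time_s - track.time_s[idx])
    if np.any(dt > half_frame + 1e-9):
        raise ValueError("photometry/behavior clock mismatch beyond half a frame")
    return track.nose_xy[idx].copy()


def event_frames(events: EventTrain, track: PoseTrack) -> np.ndarray:
    """Behavioral frame index of each event (same matching as positions)."""
    if events.n_events == 0:
        return np.empty(0, dtype=int)
    idx = np.rint(events.time_s * track.fps).astype(int)
    if np.any(idx < 0) or np.any(idx >= track.n_frames):
        raise ValueError("event time outside the tracked session")
    return idx


def condition(
    sig: PhotometrySignal,
    cutoff_hz: float = 40.0,
    target_hz: float = 60.0,
    baseline_window_s: Optional[tuple[float, float]] = None,
    regress_isosbestic: bool = False,
) -> PhotometrySignal:
    """Full conditioning chain: low-pass, z-score, down-sample to 60 Hz."""
    out = lowpass(sig, cutoff_hz=cutoff_hz)
    out = zscore(out, baseline_window_s=baseline_window_s, regress_isosbestic=regress_isosbestic)
    if out.fs > target_hz * (1 + 1e-9):
        out = resample_to(out, target_hz=target_hz)
    return out
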