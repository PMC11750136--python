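"""File ingestion and result serialization for the recognition-memory pipeline.

Every external file the pipeline touches is read here into validated in-memory
domain objects, so downstream analysis modules never see raw CSV/YAML.

External formats
----------------
* Pose CSV: the three-header-row dialect written by markerless pose trackers
  (``scorer`` / ``bodyparts`` / ``coords``), one row per video frame, with a
  ``nose`` bodypart carrying ``x``, ``y`` and ``likelihood`` columns.
* Photometry CSV: columns ``time_s``, ``f470`` (calcium-dependent channel) and
  ``f415`` (isosbestic channel).
* Arena layout and session protocol: YAML (or JSON) documents validated
  against pydantic schemas (:class:`ArenaLayout`, :class:`SessionSpec`).

Coordinate convention: video pixel space, origin top-left, x increasing to the
right, y increasing downward, 0-based frame indices.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, ValidationError, model_validator

__all__ = [
    "PoseTrack",
    "PhotometrySignal",
    "Chamber",
    "ArenaLayout",
    "PhaseWindow",
    "SessionSpec",
    "FormatError",
    "read_pose_table",
    "write_pose_table",
    "read_photometry_table",
    "write_photometry_table",
    "read_layout",
    "read_session",
    "write_results",
    "interpolate_low_confidence",
]

#: significant digits used for all serialized floats (byte-stable output)
FLOAT_DIGITS = 9


class FormatError(ValueError):
    """Raised when an input file violates its documented format or schema."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PoseTrack:
    """Per-frame nose coordinates from markerless tracking.

    Attributes
    ----------
    frame_index : (n,) int array, 0-based
    time_s : (n,) float array, seconds; ``frame_index / fps``
    nose_xy : (n, 2) float array, pixels (origin top-left, y down)
    confidence : (n,) float array in [0, 1]
    fps : frames per second of the source video (25 or 60 in typical sessions)
    """

    frame_index: np.ndarray
    time_s: np.ndarray
    nose_xy: np.ndarray
    confidence: np.ndarray
    fps: float

    def __post_init__(self) -> None:
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        n = len(self.frame_index)
        if not (len(self.time_s) == len(self.confidence) == self.nose_xy.shape[0] == n):
            raise ValueError("PoseTrack field lengths disagree")
        if n > 1 and not np.all(np.diff(self.time_s) > 0):
            raise ValueError("time_s must be strictly increasing")
        if np.any(np.abs(self.time_s - self.frame_index / self.fps) > 1e-6):
            raise ValueError("time_s inconsistent with frame_index / fps")
        if np.any((self.confidence < 0) | (self.confidence > 1)):
            raise ValueError("confidence must lie in [0, 1]")

    @property
    def n_frames(self) -> int:
        return len(self.frame_index)

    @property
    def duration_s(self) -> float:
        """Recording duration = number of frames / fps."""
        return self.n_frames / self.fps


@dataclass
class PhotometrySignal:
    """Uniformly sampled fiber-photometry channels.

    ``f470`` is the calcium-dependent channel, ``f415`` the isosbestic
    (calcium-independent) channel. ``z`` is populated by the conditioning
    chain (:mod:`recogmem.photometry`) and is absent until computed.
    """

    time_s: np.ndarray
    f470: np.ndarray
    f415: np.ndarray
    fs: float
    z: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        n = len(self.time_s)
        if not (len(self.f470) == len(self.f415) == n):
            raise ValueError("PhotometrySignal field lengths disagree")
        if n >= 2:
            dt = np.diff(self.time_s)
            if np.any(dt <= 0):
                raise ValueError("time_s must be strictly increasing")
            med = np.median(dt)
            if np.any(np.abs(dt - med) > 0.01 * med):
                raise ValueError("sampling jitter exceeds 1% of the median step")

    @property
    def n_samples(self) -> int:
        return len(self.time_s)

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs


class Chamber(BaseModel):
    """A pencil chamber (stimulus enclosure) placed in the arena."""

    model_config = ConfigDict(extra="forbid")

    label: str
    center_xy: tuple[float, float]
    edge_radius_px: float

    @model_validator(mode="after")
    def _check(self) -> "Chamber":
        if self.edge_radius_px <= 0:
            raise ValueError(f"chamber {self.label!r}: edge_radius_px must be > 0")
        return self


class ArenaLayout(BaseModel):
    """Arena geometry and interaction-zone definition.

    Two zone conventions are supported, matching the two analysis pipelines
    used for the behavioral tests:

    * ``annulus`` — the interaction zone is the ring between the chamber edge
      and ``annulus_margin_cm`` (default 3 cm) beyond it.
    * ``radial`` — the zone is a disc of ``radial_radius_px`` around the
      chamber center point (100 px for social tests, 50 px for object tests).
    """

    model_config = ConfigDict(extra="forbid")

    arena_size_px: tuple[float, float]
    px_per_cm: float
    chambers: list[Chamber]
    zone_mode: Literal["annulus", "radial"] = "radial"
    annulus_margin_cm: float = 3.0
    radial_radius_px: float = 100.0

    @model_validator(mode="after")
    def _check(self) -> "ArenaLayout":
        w, h = self.arena_size_px
        if w <= 0 or h <= 0:
            raise ValueError("arena_size_px must be positive")
        if self.px_per_cm <= 0:
            raise ValueError("px_per_cm must be > 0")
        if self.annulus_margin_cm <= 0:
            raise ValueError("annulus_margin_cm must be > 0")
        if self.radial_radius_px <= 0:
            raise ValueError("radial_radius_px must be > 0")
        labels = [c.label for c in self.chambers]
        if len(set(labels)) != len(labels):
            raise ValueError("chamber labels must be unique")
        for c in self.chambers:
            x, y = c.center_xy
            if not (0 <= x <= w and 0 <= y <= h):
                raise ValueError(
                    f"chamber {c.label!r} center {c.center_xy} lies outside the "
                    f"arena bounds {self.arena_size_px}"
                )
        return self

    def zone_radius_px(self, chamber: Chamber) -> tuple[float, float]:
        """Inner and outer zone radius (px) for a chamber under ``zone_mode``."""
        if self.zone_mode == "radial":
            return 0.0, self.radial_radius_px
        inner = chamber.edge_radius_px
        return inner, inner + self.annulus_margin_cm * self.px_per_cm


class PhaseWindow(BaseModel):
    """One protocol phase (e.g. pretest, sociability, discrimination)."""

    model_config = ConfigDict(extra="forbid")

    label: str
    start_s: float
    end_s: float

    @model_validator(mode="after")
    def _check(self) -> "PhaseWindow":
        if self.end_s <= self.start_s:
            raise ValueError(f"phase {self.label!r}: end_s must exceed start_s")
        return self


class SessionSpec(BaseModel):
    """Protocol structure of one behavioral session.

    ``stimuli`` maps each phase label to a ``{chamber label: stimulus}``
    assignment, with stimuli drawn from ``object / conspecific / novel /
    familiar``. ``treatment`` labels the pharmacological condition
    (``saline`` / ``cno``) for the within-subject chemogenetic comparisons.
    """

    model_config = ConfigDict(extra="forbid")

    phases: list[PhaseWindow]
    stimuli: dict[str, dict[str, str]] = {}
    treatment: Optional[str] = None

    @model_validator(mode="after")
    def _check(self) -> "SessionSpec":
        ordered = sorted(self.phases, key=lambda p: p.start_s)
        for a, b in zip(ordered, ordered[1:]):
            if b.start_s < a.end_s:
                raise ValueError(f"phases {a.label!r} and {b.label!r} overlap")
        labels = {p.label for p in self.phases}
        for phase in self.stimuli:
            if phase not in labels:
                raise ValueError(f"stimuli reference unknown phase {phase!r}")
        return self

    def phase(self, label: str) -> PhaseWindow:
        for p in self.phases:
            if p.label == label:
                return p
        raise KeyError(label)

    def validate_against(self, layout: ArenaLayout, duration_s: float) -> None:
        """Check phase windows fit the recording and chambers exist."""
        chamber_labels = {c.label for c in layout.chambers}
        for p in self.phases:
            if p.end_s > duration_s + 1e-9:
                raise ValueError(
                    f"phase {p.label!r} ends at {p.end_s} s, beyond the "
                    f"{duration_s} s recording"
                )
        for phase, assignment in self.stimuli.items():
            for chamber in assignment:
                if chamber not in chamber_labels:
                    raise ValueError(
                        f"phase {phase!r} assigns a stimulus to unknown "
                        f"chamber {chamber!r}"
                    )


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------


def read_pose_table(path: str | Path, fps: float, bodypart: str = "nose") -> PoseTrack:
    """Read a three-header-row pose-estimation CSV into a :class:`PoseTrack`.

    The dialect has header rows ``scorer``, ``bodyparts`` and ``coords``
    (x / y / likelihood) followed by one row per frame; the first column is
    the frame index. Time is derived as ``frame_index / fps``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path, header=[0, 1, 2], index_col=0)
    except Exception as exc:  # noqa: BLE001 - surface as format error
        raise FormatError(f"{path}: not a three-header-row pose CSV ({exc})") from exc
    cols = {}
    for coord in ("x", "y", "likelihood"):
        matches = [
            c for c in df.columns if c[1] == bodypart and c[2] == coord
        ]
        if not matches:
            raise FormatError(
                f"{path}: missing column bodyparts={bodypart!r} coords={coord!r}"
            )
        cols[coord] = matches[0]
    sub = df[[cols["x"], cols["y"], cols["likelihood"]]]
    arr = sub.apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
    bad = np.nonzero(np.any(~np.isfinite(arr), axis=1))[0]
    if bad.size:
        raise FormatError(f"{path}: non-numeric cell in data row {int(bad[0])}")
    n = arr.shape[0]
    idx = np.arange(n)
    return PoseTrack(
        frame_index=idx,
        time_s=idx / fps,
        nose_xy=arr[:, :2].copy(),
        confidence=np.clip(arr[:, 2], 0.0, 1.0),
        fps=float(fps),
    )


def write_pose_table(track: PoseTrack, path: str | Path, scorer: str = "recogmem") -> None:
    """Write a :class:`PoseTrack` in the three-header-row pose CSV dialect."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        fh.write(f"scorer,{scorer},{scorer},{scorer}\n")
        fh.write("bodyparts,nose,nose,nose\n")
        fh.write("coords,x,y,likelihood\n")
        for i in range(track.n_frames):
            x, y = track.nose_xy[i]
            fh.write(
                f"{int(track.frame_index[i])},{_fmt(x)},{_fmt(y)},{_fmt(track.confidence[i])}\n"
            )


def read_photometry_table(path: str | Path) -> PhotometrySignal:
    """Read a photometry CSV (``time_s``, ``f470``, ``f415``).

    The sampling rate is estimated as the reciprocal of the median time step;
    jitter beyond 1% of that step or non-monotone time raises
    :class:`FormatError`.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # noqa: BLE001
        raise FormatError(f"{path}: unreadable CSV ({exc})") from exc
    for col in ("time_s", "f470", "f415"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    if len(df) < 2:
        raise FormatError(f"{path}: need at least 2 samples")
    t = df["time_s"].to_numpy(dtype=float)
    dt = np.diff(t)
    if np.any(dt <= 0):
        raise FormatError(f"{path}: time_s is not strictly increasing")
    med = float(np.median(dt))
    if np.any(np.abs(dt - med) > 0.01 * med):
        raise FormatError(f"{path}: sampling jitter exceeds 1%")
    return PhotometrySignal(
        time_s=t,
        f470=df["f470"].to_numpy(dtype=float),
        f415=df["f415"].to_numpy(dtype=float),
        fs=1.0 / med,
    )


def write_photometry_table(sig: PhotometrySignal, path: str | Path) -> None:
    path = Path(path)
    with path.open("w", newline="") as fh:
        fh.write("time_s,f470,f415\n")
        for i in range(sig.n_samples):
            fh.write(f"{_fmt(sig.time_s[i])},{_fmt(sig.f470[i])},{_fmt(sig.f415[i])}\n")


def _load_structured(path: Path) -> dict:
    text = path.read_text()
    if path.suffix.lower() == ".json":
        return json.loads(text)
    return yaml.safe_load(text)


def read_layout(path: str | Path) -> ArenaLayout:
    """Read and validate an arena layout config (YAML or JSON)."""
    path = Path(path)
    try:
        return ArenaLayout.model_validate(_load_structured(path))
    except ValidationError as exc:
        raise FormatError(f"{path}: invalid arena layout: {exc}") from exc


def read_session(path: str | Path) -> SessionSpec:
    """Read and validate a session protocol config (YAML or JSON)."""
    path = Path(path)
    try:
        return SessionSpec.model_validate(_load_structured(path))
    except ValidationError as exc:
        raise FormatError(f"{path}: invalid session spec: {exc}") from exc


# ---------------------------------------------------------------------------
# low-confidence gap handling
# ---------------------------------------------------------------------------


def interpolate_low_confidence(track: PoseTrack, min_confidence: float = 0.6) -> tuple[PoseTrack, float]:
    """Linearly interpolate nose positions at low-confidence frames.

    Frames with ``confidence < min_confidence`` are replaced by linear
    interpolation between the neighboring valid frames; leading/trailing gaps
    are held at the nearest valid sample. Returns the cleaned track and the
    fraction of frames interpolated (a per-session QC metric).
    """
    ok = track.confidence >= min_confidence
    frac = 1.0 - ok.mean() if track.n_frames else 0.0
    if ok.all():
        return track, 0.0
    if not ok.any():
        raise ValueError("no frames at or above the confidence threshold")
    t = track.time_s
    xy = track.nose_xy.copy()
    for k in range(2):
        xy[:, k] = np.interp(t, t[ok], track.nose_xy[ok, k])
    return replace(track, nose_xy=xy), float(frac)


# ---------------------------------------------------------------------------
# result serialization
# ---------------------------------------------------------------------------


def _fmt(x: float) -> str:
    """Format a float with FLOAT_DIGITS significant digits (byte-stable)."""
    if isinstance(x, (int, np.integer)):
        return str(int(x))
    if not math.isfinite(x):
        return "inf" if x > 0 else ("-inf" if x < 0 else "nan")
    return format(float(x), f".{FLOAT_DIGITS}g")


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        x = float(obj)
        return float(_fmt(x)) if math.isfinite(x) else _fmt(x)
    if isinstance(obj, (np.integer, int)):
        return int(obj)
    if isinstance(obj, np.ndarray):
        return _jsonable(obj.tolist())
    return obj


def write_matrix_csv(grid: np.ndarray, path: str | Path) -> None:
    """Write a dense 2-D matrix as CSV (no header), floats at 9 sig. digits."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        for row in np.atleast_2d(grid):
            fh.write(",".join(_fmt(v) for v in row) + "\n")


def write_results(results: dict, out_dir: str | Path) -> list[Path]:
    """Serialize a results bundle to ``out_dir``; returns the files written.

    Recognized keys:

    * ``summary`` (dict) -> ``summary.json`` (sorted keys, 9-sig-digit floats)
    * ``heatmaps`` (dict name -> HeatMap-like with ``grid``/``bin_px``/
      ``origin``/``units``) -> ``<name>.csv`` + ``<name>.meta.json`` sidecar
    * ``tables`` (dict name -> pandas DataFrame) -> ``<name>.csv``

    Output is byte-stable: identical inputs produce identical bytes.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    summary = results.get("summary")
    if summary is not None:
        p = out / "summary.json"
        p.write_text(json.dumps(_jsonable(summary), indent=2, sort_keys=True) + "\n")
        written.append(p)

    for name, hm in (results.get("heatmaps") or {}).items():
        p = out / f"{name}.csv"
        write_matrix_csv(np.asarray(hm.grid), p)
        written.append(p)
        meta = {
            "bin_px": hm.bin_px,
            "origin_xy_px": list(hm.origin),
            "units": hm.units,
            "coordinate_convention": "origin top-left, x right, y down, 0-based frames",
        }
        ps = out / f"{name}.meta.json"
        ps.write_text(json.dumps(_jsonable(meta), indent=2, sort_keys=True) + "\n")
        written.append(ps)

    for name, df in (results.get("tables") or {}).items():
        p = out / f"{name}.csv"
        with p.open("w", newline="") as fh:
            fh.write(",".join(map(str, df.columns)) + "\n")
            for _, row in df.iterrows():
                fh.write(",".join(_fmt(v) if isinstance(v, (float, np.floating)) else str(v) for v in row) + "\n")
        written.append(p)

    return written
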