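import numpy as np
import pytest

from recogmem.io_formats import ArenaLayout, Chamber, PoseTrack


def make_track(xy: np.ndarray, fps: float = 25.0, confidence=None) -> PoseTrack:
    """Build a PoseTrack from an (n, 2) array of nose positions."""
    xy = np.asarray(xy, dtype=float)
    n = len(xy)
    idx = np.arange(n)
    conf = np.ones(n) if confidence is None else np.asarray(confidence, dtype=float)
    return PoseTrack(frame_index=idx, time_s=idx / fps, nose_xy=xy, confidence=conf, fps=fps)


@pytest.fixture
def radial_layout() -> ArenaLayout:
    """500 px square arena, two chambers, 100 px radial zones (social test)."""
    return ArenaLayout(
        arena_size_px=(500.0, 500.0),
        px_per_cm=10.0,
        chambers=[
            Chamber(label="novel", center_xy=(125.0, 125.0), edge_radius_px=40.0),
            Chamber(label="familiar", center_xy=(375.0, 375.0), edge_radius_px=40.0),
        ],
        zone_mode="radial",
        radial_radius_px=100.0,
    )


@pytest.fixture
def annulus_layout() -> ArenaLayout:
    """Same arena with 3 cm annulus zones (chemogenetic-test convention)."""
    return ArenaLayout(
        arena_size_px=(500.0, 500.0),
        px_per_cm=10.0,
        chambers=[
            Chamber(label="novel", center_xy=(125.0, 125.0), edge_radius_px=40.0),
            Chamber(label="familiar", center_xy=(375.0, 375.0), edge_radius_px=40.0),
        ],
        zone_mode="annulus",
        annulus_margin_cm=3.0,
    )
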