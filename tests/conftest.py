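import numpy as np
import pandas as pd
import pytest

from swimquad import ArenaSpec, TrajectorySet


@pytest.fixture
def arena() -> ArenaSpec:
    """Standard observation window: 1150 µm side, 10 µm cells."""
    return ArenaSpec()


def make_traj(tracks: dict[int, np.ndarray], fps: float, frames: dict[int, np.ndarray] | None = None) -> TrajectorySet:
    """Build a TrajectorySet from {particle_id: (n, 2) positions}.

    Positions are sampled at consecutive frames 0..n-1 unless ``frames``
    gives explicit frame indices per particle.
    """
    rows = []
    for pid, xy in tracks.items():
        xy = np.asarray(xy, dtype=float)
        fr = frames[pid] if frames else np.arange(len(xy))
        for f, (x, y) in zip(fr, xy):
            rows.append((int(f), pid, x, y))
    df = pd.DataFrame(rows, columns=["frame", "particle", "x", "y"])
    return TrajectorySet(df, fps=fps)


def straight_track(start, velocity, n_frames, fps):
    """Constant-velocity positions: start + v * t."""
    t = np.arange(n_frames)[:, None] / fps
    return np.asarray(start)[None, :] + np.asarray(velocity)[None, :] * t
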