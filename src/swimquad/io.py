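"""Reading and writing the tracker delimited-text schema.

The exchange format is a comma-separated table with a header row and
columns (frame, particle, x, y); metadata lines starting with ``#`` are
permitted before the header and written by this package on output
(version, seed, parameters).  Coordinates may be in pixels or µm; pixel
files are converted on ingestion via the arena's px_scale.

Fixed-point (stationary-cell) files use the same reader: any delimited
table with ``x`` and ``y`` columns works, so a StationarySet written by
:func:`write_fixed_points` feeds straight into the placement simulator.
"""

from __future__ import annotations

from importlib.metadata import PackageNotFoundError, version
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .core import ArenaSpec, PointFrame, StationarySet, TrajectorySet

__all__ = [
    "read_tracks",
    "write_tracks",
    "read_fixed_points",
    "write_fixed_points",
    "write_frames",
    "read_frames",
    "metadata_header",
]

try:
    _VERSION = version("swimquad")
except PackageNotFoundError:  # pragma: no cover
    _VERSION = "unknown"


def metadata_header(**params) -> str:
    """Comment header recording provenance of an output file."""
    lines = [f"# swimquad {_VERSION}"]
    for k, v in params.items():
        lines.append(f"# {k}: {v}")
    return "\n".join(lines) + "\n"


def _read_table(path: str | Path, columns: dict[str, str] | None) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, comment="#")
    except Exception as e:
        raise ValueError(f"{path}: malformed tracker file: {e}") from e
    if columns:
        df = df.rename(columns={v: k for k, v in columns.items()})
    return df


def read_tracks(
    path: str | Path,
    fps: float,
    units: str = "um",
    arena: ArenaSpec | None = None,
    columns: dict[str, str] | None = None,
) -> TrajectorySet:
    """Load a tracker export as a TrajectorySet.

    ``units`` is "um" or "px"; pixel coordinates are scaled by
    ``arena.px_scale``.  ``columns`` optionally maps the canonical names
    (frame, particle, x, y) to the file's column names.
    """
    df = _read_table(path, columns)
    missing = [c for c in TrajectorySet.COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    if units == "px":
        if arena is None:
            raise ValueError("pixel-unit input requires an ArenaSpec for px_scale")
        df = df.copy()
        df[["x", "y"]] = df[["x", "y"]] * arena.px_scale
    elif units != "um":
        raise ValueError(f"units must be 'um' or 'px', got {units!r}")
    bad = ~np.isfinite(df[["x", "y"]].to_numpy()).all(axis=1)
    if bad.any():
        lineno = int(df.index[bad][0]) + 2  # +1 header, +1 one-based
        raise ValueError(f"{path}: non-finite coordinate near line {lineno}")
    return TrajectorySet(df, fps=fps)


def write_tracks(path: str | Path, traj: TrajectorySet, **meta) -> None:
    with open(path, "w") as fh:
        fh.write(metadata_header(fps=traj.fps, **meta))
        traj.data.to_csv(fh, index=False)


def write_frames(path: str | Path, frames: Sequence[PointFrame], **meta) -> None:
    """Write placement frames in the tracker schema (particle ids are
    per-frame ordinals; fixed points keep the leading ids)."""
    rows = []
    for f in frames:
        for pid, (x, y) in enumerate(f.points):
            rows.append((f.frame_index, pid, x, y))
    df = pd.DataFrame(rows, columns=["frame", "particle", "x", "y"])
    with open(path, "w") as fh:
        fh.write(metadata_header(**meta))
        df.to_csv(fh, index=False)


def read_frames(path: str | Path, units: str = "um", arena: ArenaSpec | None = None) -> list[PointFrame]:
    """Load per-frame point patterns from a tracker-schema file."""
    df = _read_table(path, None)
    if units == "px":
        if arena is None:
            raise ValueError("pixel-unit input requires an ArenaSpec for px_scale")
        df[["x", "y"]] = df[["x", "y"]] * arena.px_scale
    elif units != "um":
        raise ValueError(f"units must be 'um' or 'px', got {units!r}")
    return [
        PointFrame(int(f), sub[["x", "y"]].to_numpy())
        for f, sub in df.groupby("frame")
    ]


def write_fixed_points(path: str | Path, stationary: StationarySet, **meta) -> None:
    with open(path, "w") as fh:
        fh.write(metadata_header(**meta))
        stationary.records.to_csv(fh, index=False)


def read_fixed_points(
    path: str | Path, units: str = "um", arena: ArenaSpec | None = None
) -> np.ndarray:
    """Read pinned coordinates: any delimited table with x, y columns."""
    df = _read_table(path, None)
    if "x" not in df.columns or "y" not in df.columns:
        raise ValueError(f"{path}: fixed-points file needs x and y columns")
    pts = df[["x", "y"]].to_numpy(dtype=float)
    if units == "px":
        if arena is None:
            raise ValueError("pixel-unit input requires an ArenaSpec for px_scale")
        pts = pts * arena.px_scale
    elif units != "um":
        raise ValueError(f"units must be 'um' or 'px', got {units!r}")
    return pts
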