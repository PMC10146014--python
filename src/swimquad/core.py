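"""Shared domain types for quadrat analysis of microswimmer point patterns.

Coordinates are carried internally in micrometres (µm); tracker exports in
pixels are converted on ingestion via :attr:`ArenaSpec.px_scale`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

# Defaults reflecting the quasi-2D observation chamber: a 1944 px square
# field of view covering 1.15 x 1.15 mm^2, cells ~10 µm in diameter.
DEFAULT_WINDOW_UM = 1150.0
DEFAULT_WINDOW_PX = 1944.0
DEFAULT_PX_SCALE = DEFAULT_WINDOW_UM / DEFAULT_WINDOW_PX
DEFAULT_CELL_DIAMETER_UM = 10.0


@dataclass(frozen=True)
class ArenaSpec:
    """Square observation window geometry.

    Parameters
    ----------
    a : float
        Window side length in µm.
    px_scale : float
        µm per pixel conversion factor for tracker files in pixel units.
    d : float
        Cell diameter in µm (used for area/volume fractions and the
        hard-core seat model).
    """

    a: float = DEFAULT_WINDOW_UM
    px_scale: float = DEFAULT_PX_SCALE
    d: float = DEFAULT_CELL_DIAMETER_UM

    def __post_init__(self) -> None:
        if self.a <= 0:
            raise ValueError(f"window side must be positive, got {self.a}")
        if self.px_scale <= 0:
            raise ValueError(f"px_scale must be positive, got {self.px_scale}")
        if self.d < 0:
            raise ValueError(f"cell diameter must be non-negative, got {self.d}")

    @property
    def area(self) -> float:
        """Window area S = a^2 in µm^2."""
        return self.a * self.a

    @property
    def cell_area(self) -> float:
        """Area of one cell disk, pi (d/2)^2, in µm^2."""
        return np.pi * (self.d / 2.0) ** 2


@dataclass(frozen=True)
class PartitionSpec:
    """m x m equal partition of the window into N = m^2 sections."""

    m: int

    def __post_init__(self) -> None:
        if not isinstance(self.m, (int, np.integer)) or self.m < 1:
            raise ValueError(f"grid divisor m must be an integer >= 1, got {self.m}")

    @property
    def n_sections(self) -> int:
        """Number of sections N = m^2."""
        return int(self.m) ** 2

    def section_area(self, arena: ArenaSpec) -> float:
        """Section area D = S / N in µm^2."""
        return arena.area / self.n_sections


@dataclass(frozen=True)
class PointFrame:
    """One frame of cell-center coordinates, in µm, inside [0, a]^2."""

    frame_index: int
    points: np.ndarray  # shape (n, 2)

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float).reshape(-1, 2)
        if pts.size and not np.all(np.isfinite(pts)):
            raise ValueError(f"frame {self.frame_index}: non-finite coordinates")
        object.__setattr__(self, "points", pts)

    @property
    def n(self) -> int:
        return self.points.shape[0]


@dataclass
class CountHistogram:
    """Pooled quadrat-count frequencies with dispersion summary.

    ``counts_per_bin`` maps occupancy x to the number of section-frame
    samples with that occupancy.  ``variance`` is the sample variance
    (denominator ``n_samples - 1``).
    """

    counts_per_bin: dict[int, int]
    n_samples: int
    mean: float
    variance: float
    vmr: float

    def frequencies(self) -> pd.Series:
        """Occupancy histogram as a Series indexed by occupancy x."""
        xs = sorted(self.counts_per_bin)
        return pd.Series([self.counts_per_bin[x] for x in xs], index=xs, name="frequency")

    def empirical_pmf(self) -> dict[int, float]:
        return {x: c / self.n_samples for x, c in self.counts_per_bin.items()}


@dataclass
class TrajectorySet:
    """Per-particle time series of positions.

    ``data`` has columns (frame, particle, x, y); x and y in µm.  ``fps``
    is the frame rate of the *analyzed* stream (it changes under frame
    thinning).  Frame indices are integers, strictly increasing within a
    particle; gaps are permitted and denote missed detections.
    """

    data: pd.DataFrame
    fps: float

    COLUMNS = ("frame", "particle", "x", "y")

    def __post_init__(self) -> None:
        if self.fps <= 0:
            raise ValueError(f"fps must be positive, got {self.fps}")
        missing = [c for c in self.COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"trajectory table missing columns {missing}")
        df = self.data.loc[:, list(self.COLUMNS)].copy()
        df["frame"] = df["frame"].astype(np.int64)
        df = df.sort_values(["particle", "frame"], kind="stable").reset_index(drop=True)
        grp = df.groupby("particle")["frame"]
        if (grp.diff().dropna() <= 0).any():
            raise ValueError("frame indices must be strictly increasing per particle")
        self.data = df

    @property
    def n_particles(self) -> int:
        return self.data["particle"].nunique()

    def frames(self) -> list[PointFrame]:
        """Re-group the trajectories into per-frame point patterns."""
        out = []
        for f, sub in self.data.groupby("frame"):
            out.append(PointFrame(int(f), sub[["x", "y"]].to_numpy()))
        return out

    def per_frame_counts(self) -> pd.Series:
        return self.data.groupby("frame").size()


@dataclass
class StationarySet:
    """Detected stationary (adhered) cells.

    One entry per particle: its id, representative coordinate (mean
    position over the qualifying low-speed run) and dwell duration in
    seconds.
    """

    records: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["particle", "x", "y", "dwell_s"])
    )

    def __len__(self) -> int:
        return len(self.records)

    @property
    def particle_ids(self) -> list:
        return list(self.records["particle"])

    def positions(self) -> np.ndarray:
        return self.records[["x", "y"]].to_numpy(dtype=float).reshape(-1, 2)
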