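"""Monte Carlo placement of hard disks in a square window.

Each frame places ``n_total`` cell centers uniformly in [0, a)^2 subject to
the excluded-volume (EV) constraint that no two centers are closer than the
cell diameter d.  An optional set of *fixed points* — stationary (adhered)
cells detected from trajectories — is pinned at identical coordinates in
every frame, and mobile cells are placed around them under the same hard
constraint.

Placement follows random-sequential-adsorption (RSA) ordering: a proposed
coordinate that violates the constraint against any already-accepted cell
is discarded and redrawn.  The implementation batches proposals and
resolves conflicts by always redrawing the later-indexed cell of a
conflicting pair, which reproduces the sequential-insertion distribution
while staying vectorized.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .core import DEFAULT_CELL_DIAMETER_UM, DEFAULT_WINDOW_UM, PointFrame

__all__ = ["PlacementConfig", "PlacementError", "place_cells_ev", "simulate_frames"]

# Proposals allowed per cell before the frame is declared infeasible.
REJECTION_BUDGET = 10_000
# Fail fast above this packing fraction; RSA jams well below close packing.
MAX_AREA_FRACTION = 0.3


class PlacementError(RuntimeError):
    """A cell exhausted its proposal budget — packing is infeasible."""


@dataclass(frozen=True)
class PlacementConfig:
    """Geometry, density and reproducibility of a placement run.

    a : window side (µm); d : hard-core diameter (µm); n_total : number of
    cells per frame *including* the pinned ``fixed_points``; n_frames :
    number of independent frames; seed : RNG seed (one stream per run).
    """

    n_total: int
    a: float = DEFAULT_WINDOW_UM
    d: float = DEFAULT_CELL_DIAMETER_UM
    fixed_points: np.ndarray = field(default_factory=lambda: np.empty((0, 2)))
    n_frames: int = 900
    seed: int = 0

    def __post_init__(self) -> None:
        fp = np.asarray(self.fixed_points, dtype=float).reshape(-1, 2)
        object.__setattr__(self, "fixed_points", fp)
        if self.a <= 0:
            raise ValueError(f"window side must be positive, got {self.a}")
        if self.d < 0:
            raise ValueError(f"diameter must be non-negative, got {self.d}")
        if self.n_frames < 1:
            raise ValueError(f"n_frames must be >= 1, got {self.n_frames}")
        if self.n_total < len(fp):
            raise ValueError(
                f"n_total={self.n_total} smaller than {len(fp)} fixed points"
            )
        phi = self.n_total * np.pi * (self.d / 2) ** 2 / self.a**2
        if phi >= MAX_AREA_FRACTION:
            raise ValueError(
                f"area fraction {phi:.3f} exceeds feasibility guard "
                f"{MAX_AREA_FRACTION}; RSA placement unreliable"
            )
        if fp.size:
            if np.any(fp < 0) or np.any(fp >= self.a):
                raise ValueError("fixed points must lie inside [0, a)^2")
            if len(fp) > 1 and self.d > 0:
                dmin = cKDTree(fp).query_pairs(self.d, output_type="ndarray")
                # query_pairs uses r-inclusive; distances exactly d are legal
                if len(dmin):
                    dd = np.linalg.norm(fp[dmin[:, 0]] - fp[dmin[:, 1]], axis=1)
                    if np.any(dd < self.d):
                        raise ValueError("fixed points violate the pairwise distance d")

    @property
    def n_mobile(self) -> int:
        return self.n_total - len(self.fixed_points)


def _place_one_frame(
    rng: np.random.Generator, a: float, d: float, fixed: np.ndarray, n_mobile: int
) -> np.ndarray:
    """Sequential RSA placement of ``n_mobile`` points around ``fixed``;
    returns the full (n_fixed + n_mobile, 2) array, fixed points first.

    Each cell in turn draws uniform proposals until one clears distance d
    (closed constraint: separation exactly d is accepted) to every
    already-placed cell, up to REJECTION_BUDGET proposals.
    """
    n_fixed = len(fixed)
    n_pts = n_fixed + n_mobile
    pts = np.empty((n_pts, 2))
    pts[:n_fixed] = fixed
    if d == 0 or n_pts < 2:
        pts[n_fixed:] = rng.uniform(0.0, a, size=(n_mobile, 2))
        return pts

    d2 = d * d
    for i in range(n_fixed, n_pts):
        placed = pts[:i]
        for _ in range(REJECTION_BUDGET):
            p = rng.uniform(0.0, a, size=2)
            if i == 0 or np.min(np.sum((placed - p) ** 2, axis=1)) >= d2:
                pts[i] = p
                break
        else:
            raise PlacementError(
                f"cell {i} exceeded {REJECTION_BUDGET} placement proposals; "
                "density infeasible for hard-disk placement"
            )
    return pts


def place_cells_ev(
    config: PlacementConfig, rng: np.random.Generator | None = None
) -> PointFrame:
    """Place one frame of hard disks; fixed points occupy the leading rows.

    Every pair of returned centers is at Euclidean distance >= d, all
    coordinates lie in [0, a)^2, and runs are reproducible for a fixed
    ``config.seed``.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    pts = _place_one_frame(
        rng, config.a, config.d, config.fixed_points, config.n_mobile
    )
    return PointFrame(0, pts)


def simulate_frames(config: PlacementConfig) -> list[PointFrame]:
    """Independent placement frames sharing one random stream.

    Frames are i.i.d. draws of the EV placement (fixed points identical in
    all frames); independence comes from continued draws of a single
    generator seeded from ``config.seed``, keeping the whole run
    reproducible with one integer.
    """
    rng = np.random.default_rng(config.seed)
    frames = []
    for i in range(config.n_frames):
        try:
            pts = _place_one_frame(
                rng, config.a, config.d, config.fixed_points, config.n_mobile
            )
        except PlacementError as e:
            raise PlacementError(f"frame {i}: {e}") from e
        frames.append(PointFrame(i, pts))
    return frames
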