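"""Quadrat (partitioning-method) dispersion statistics.

The observation window is divided into an m x m grid of N = m^2 equal
sections; cells are counted per section per frame, counts are pooled over
frames into an occupancy histogram, and the variance-to-mean ratio (VMR)
of the pooled counts measures the departure from complete spatial
randomness: VMR < 1 - 1/N indicates avoidance beyond the finite-window
(binomial) null, VMR > 1 - 1/N clumping or environmental inhomogeneity.

Boundary rule: a cell center lying exactly on an internal section boundary
belongs to the section on its right/upper side (sections are half-open
[low, high) boxes); a center exactly on the outer window edge x = a or
y = a is clamped into the last row/column.

Also provided: Kullback-Leibler divergence of the empirical occupancy
histogram from a model pmf, cell area/volume fractions, and a radial
distribution function g(r) estimator with translational edge correction.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .core import ArenaSpec, CountHistogram, PartitionSpec, PointFrame

__all__ = [
    "count_quadrats",
    "pooled_histogram",
    "vmr_curve",
    "kl_divergence",
    "area_fraction",
    "volume_fraction",
    "radial_distribution",
]


def _section_indices(
    coords: np.ndarray, a: float, m: int, frame_index: int
) -> np.ndarray:
    if coords.size and (np.any(coords < 0) or np.any(coords > a)):
        raise ValueError(
            f"frame {frame_index}: point outside window [0, {a}]^2"
        )
    # floor(x m / a) implements the half-open [low, high) rule: a point
    # exactly on an internal boundary gets the higher (right/upper) index.
    idx = np.floor(coords * m / a).astype(np.int64)
    return np.minimum(idx, m - 1)  # clamp x == a into the last section


def count_quadrats(
    frame: PointFrame, arena: ArenaSpec, part: PartitionSpec
) -> np.ndarray:
    """Count cells in each section of the m x m grid.

    Returns an (m, m) integer array indexed [col, row] with column 0 at
    x=0 and row 0 at y=0; the grid total equals the frame's point count.
    """
    m = part.m
    ij = _section_indices(frame.points, arena.a, m, frame.frame_index)
    grid = np.zeros((m, m), dtype=np.int64)
    if len(ij):
        np.add.at(grid, (ij[:, 0], ij[:, 1]), 1)
    return grid


def _all_counts(
    frames: Sequence[PointFrame], arena: ArenaSpec, part: PartitionSpec
) -> np.ndarray:
    """Flat array of all N * n_frames section counts."""
    if not frames:
        raise ValueError("need at least one frame")
    return np.concatenate(
        [count_quadrats(f, arena, part).ravel() for f in frames]
    )


def pooled_histogram(
    frames: Sequence[PointFrame], arena: ArenaSpec, part: PartitionSpec
) -> CountHistogram:
    """Pool section counts over all frames into an occupancy histogram.

    The mean is total points / (N * n_frames); the variance is the sample
    variance of the pooled counts (denominator n_samples - 1).
    """
    counts = _all_counts(frames, arena, part)
    freq = np.bincount(counts)
    mean = float(np.mean(counts))
    variance = float(np.var(counts, ddof=1)) if len(counts) > 1 else 0.0
    vmr = variance / mean if mean > 0 else float("nan")
    return CountHistogram(
        counts_per_bin={int(x): int(c) for x, c in enumerate(freq) if c > 0},
        n_samples=len(counts),
        mean=mean,
        variance=variance,
        vmr=vmr,
    )


def vmr_curve(
    frames: Sequence[PointFrame],
    arena: ArenaSpec,
    m_list: Iterable[int],
) -> pd.DataFrame:
    """VMR as a function of the number of sections N = m^2.

    Returns one row per grid divisor m with columns
    (m, N, mean, variance, vmr).
    """
    ms = list(m_list)
    if not ms:
        raise ValueError("m_list must be non-empty")
    rows = []
    for m in ms:
        part = PartitionSpec(m)
        h = pooled_histogram(frames, arena, part)
        rows.append(
            {"m": m, "N": part.n_sections, "mean": h.mean,
             "variance": h.variance, "vmr": h.vmr}
        )
    return pd.DataFrame(rows)


def kl_divergence(
    hist: CountHistogram, model_pmf: Mapping[int, float]
) -> float:
    """Kullback-Leibler divergence D(empirical || model), natural log.

    Sums q(x) ln(q(x)/p(x)) over occupancies x with empirical mass
    q(x) > 0.  Returns ``inf`` when the model assigns zero probability to
    an occupied bin.  The model pmf must sum to 1 within 1e-9 over the
    bins provided (tails may be omitted only if negligible).
    """
    total = float(sum(model_pmf.values()))
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"model pmf sums to {total}, expected 1 within 1e-9")
    q = hist.empirical_pmf()
    kl = 0.0
    for x, qx in q.items():
        px = model_pmf.get(x, 0.0)
        if px <= 0.0:
            warnings.warn(
                f"model probability 0 at occupied bin x={x}: KL divergence infinite"
            )
            return float("inf")
        kl += qx * np.log(qx / px)
    return max(kl, 0.0)


def area_fraction(mean_cells: float, arena: ArenaSpec) -> float:
    """Fraction of the 2D window covered by cell disks:
    n_mean * pi (d/2)^2 / a^2."""
    if mean_cells < 0:
        raise ValueError(f"mean cell count must be non-negative, got {mean_cells}")
    return mean_cells * arena.cell_area / arena.area


def volume_fraction(
    mean_cells: float, arena: ArenaSpec, thickness: float
) -> float:
    """Fraction of the quasi-2D chamber volume occupied by cell spheres:
    n_mean * (4/3) pi (d/2)^3 / (a^2 * thickness)."""
    if mean_cells < 0:
        raise ValueError(f"mean cell count must be non-negative, got {mean_cells}")
    if thickness <= 0:
        raise ValueError(f"chamber thickness must be positive, got {thickness}")
    sphere = (4.0 / 3.0) * np.pi * (arena.d / 2.0) ** 3
    return mean_cells * sphere / (arena.area * thickness)


def radial_distribution(
    frames: Sequence[PointFrame],
    arena: ArenaSpec,
    r_max: float,
    bin_width: float,
) -> pd.DataFrame:
    """Radial distribution function g(r) pooled over frames.

    Pair separations are binned in annuli of width ``bin_width`` up to
    ``r_max`` and normalized so a homogeneous Poisson pattern gives
    g(r) -> 1.  Edge effects are handled by the translational correction:
    each ordered pair with displacement (dx, dy) carries weight
    a^2 / ((a - |dx|)(a - |dy|)), the inverse of the fraction of
    translations keeping both points in the window.

    Frames with fewer than 2 points are skipped (a warning reports how
    many).  Returns columns (r, g) with r at bin centers.
    """
    if not 0 < r_max < arena.a / 2:
        raise ValueError(f"need 0 < r_max < a/2, got r_max={r_max}")
    if bin_width <= 0:
        raise ValueError(f"bin_width must be positive, got {bin_width}")
    a = arena.a
    edges = np.arange(0.0, r_max + bin_width, bin_width)
    edges = edges[edges <= r_max + 1e-9]
    n_bins = len(edges) - 1
    weight_sum = np.zeros(n_bins)
    pair_norm = 0.0  # sum over frames of n (n - 1)
    skipped = 0
    for frame in frames:
        pts = frame.points
        n = len(pts)
        if n < 2:
            skipped += 1
            continue
        diff = pts[:, None, :] - pts[None, :, :]
        iu = np.triu_indices(n, k=1)
        dx = np.abs(diff[..., 0][iu])
        dy = np.abs(diff[..., 1][iu])
        r = np.hypot(dx, dy)
        sel = r < edges[-1]
        if np.any(sel):
            w = a * a / ((a - dx[sel]) * (a - dy[sel]))
            which = np.digitize(r[sel], edges) - 1
            np.add.at(weight_sum, which, 2.0 * w)  # ordered pairs
        pair_norm += n * (n - 1)
    if skipped:
        warnings.warn(f"radial_distribution: skipped {skipped} frames with <2 points")
    if pair_norm == 0:
        raise ValueError("no frame had >= 2 points")
    annulus = np.pi * (edges[1:] ** 2 - edges[:-1] ** 2)
    # ordered-pair estimator: g = a^4/(n(n-1) annulus) * sum 1/gamma, with
    # the pair weight stored as a^2/gamma, so one factor a^2 remains here
    g = weight_sum * a * a / (pair_norm * annulus)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return pd.DataFrame({"r": centers, "g": g})
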