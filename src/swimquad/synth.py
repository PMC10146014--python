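"""Synthetic microswimmer trajectories standing in for microscopy video.

Generates tracker-format trajectories of flagellated swimmers in a
circular quasi-2D well with a central square observation window:
persistent-random-walk movers (heading diffuses, speed fixed per cell),
pinned stationary cells, hard-core excluded volume, reflection at the
chamber wall, and an optional initial transient in which the in-window
cell count decays exponentially to its steady value.  Only positions
inside the observation window are emitted — the tracker sees a finite
field of view — so per-frame counts fluctuate through influx/outflux
exactly as in the experiment the generator emulates.

The emitted table is the raw 30 fps stream, so downstream frame thinning
is exercised end to end; a ground-truth record carries the planted
stationary ids/positions and the true per-frame window counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .core import (
    DEFAULT_CELL_DIAMETER_UM,
    DEFAULT_WINDOW_UM,
    TrajectorySet,
)

__all__ = ["SynthConfig", "GroundTruth", "generate_tracks"]


@dataclass(frozen=True)
class SynthConfig:
    """Study conditions of the emulated recording.

    Defaults mirror the experimental setup the analysis was designed for:
    a 2 mm circular well, a 1.15 mm square observation window, ~10 µm
    cells swimming at ~100 µm/s, recorded at 30 fps for 15 min after the
    transient.  ``transient_extra`` adds that fraction of extra in-window
    cells at t=0 which leave with exponential lifetime
    ``transient_tau_s``, reproducing the count decay seen right after
    loading the chamber.
    """

    n_cells: int
    n_stationary: int = 0
    arena_diameter: float = 2000.0
    window_side: float = DEFAULT_WINDOW_UM
    speed_mean: float = 100.0
    speed_sd: float = 10.0
    rot_diffusion: float = 0.5  # rad^2/s heading diffusivity
    fps_raw: float = 30.0
    duration_s: float = 900.0
    transient_extra: float = 0.0  # fraction of n_cells added initially
    transient_tau_s: float = 300.0
    d: float = DEFAULT_CELL_DIAMETER_UM
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_stationary > self.n_cells:
            raise ValueError("n_stationary cannot exceed n_cells")
        if self.window_side * np.sqrt(2.0) > self.arena_diameter:
            raise ValueError("observation window does not fit inside the arena")
        if self.speed_mean < 0 or self.speed_sd < 0:
            raise ValueError("speeds must be non-negative")
        if self.fps_raw <= 0 or self.duration_s <= 0:
            raise ValueError("fps_raw and duration_s must be positive")
        if self.transient_extra < 0 or self.transient_tau_s <= 0:
            raise ValueError("invalid transient parameters")


@dataclass
class GroundTruth:
    """Planted truth emitted alongside the tracks."""

    stationary_ids: list[int]
    stationary_positions: np.ndarray
    window_counts: pd.Series  # per emitted frame, cells inside the window
    config: SynthConfig = field(repr=False, default=None)

    def to_json_dict(self) -> dict:
        return {
            "stationary_ids": [int(i) for i in self.stationary_ids],
            "stationary_positions": self.stationary_positions.tolist(),
            "window_counts": {int(k): int(v) for k, v in self.window_counts.items()},
        }


def _initial_positions(
    rng: np.random.Generator,
    n: int,
    n_window: int,
    R: float,
    half_w: float,
    d: float,
) -> np.ndarray:
    """RSA-place n cells in the disk of radius R (centered at origin), the
    first ``n_window`` of them restricted to the central square window."""
    pts = np.empty((n, 2))
    d2 = d * d
    for i in range(n):
        for _ in range(10_000):
            if i < n_window:
                p = rng.uniform(-half_w, half_w, size=2)
            else:
                p = rng.uniform(-R, R, size=2)
                if p @ p > R * R:
                    continue
            if i == 0 or np.min(np.sum((pts[:i] - p) ** 2, axis=1)) >= d2:
                pts[i] = p
                break
        else:
            raise RuntimeError("infeasible initial packing for synthetic arena")
    return pts


def generate_tracks(config: SynthConfig) -> tuple[TrajectorySet, GroundTruth]:
    """Simulate the recording and return (trajectories, ground truth).

    Stationary cells occupy particle ids 0 .. n_stationary-1 and are
    pinned inside the window for the whole recording.  Movers take
    persistent-random-walk steps of length v/fps with heading diffusion
    ``rot_diffusion``; a step that would leave the arena or land within d
    of another cell is rejected (the cell waits one frame, heading
    randomized on overlap).  Fully reproducible from ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    R = config.arena_diameter / 2.0
    half_w = config.window_side / 2.0
    dt = 1.0 / config.fps_raw
    n_frames = int(round(config.duration_s * config.fps_raw))
    n_extra = int(round(config.transient_extra * config.n_cells))
    n = config.n_cells + n_extra
    ns = config.n_stationary

    # place stationary cells and transient extras inside the window so the
    # initial in-window count starts high; steady movers fill the arena
    order_window = ns + n_extra
    pts = np.empty((n, 2))
    # interleave: stationary first, then extras, then movers
    init = _initial_positions(rng, n, order_window, R - config.d / 2, half_w, config.d)
    pts[:ns] = init[:ns]
    extras_init = init[ns : ns + n_extra]
    movers_init = init[ns + n_extra :]
    pts[ns : config.n_cells] = movers_init
    pts[config.n_cells :] = extras_init

    speeds = np.clip(
        rng.normal(config.speed_mean, config.speed_sd, size=n), 0.0, None
    )
    speeds[:ns] = 0.0
    heading = rng.uniform(0.0, 2.0 * np.pi, size=n)
    # transient cells leave the chamber with exponential lifetimes
    death = np.full(n, np.inf)
    if n_extra:
        death[config.n_cells :] = rng.exponential(
            config.transient_tau_s, size=n_extra
        )
    alive = np.ones(n, dtype=bool)

    sigma_h = np.sqrt(2.0 * config.rot_diffusion * dt)
    r_lim = R - config.d / 2.0
    frames_out, pids_out, xs_out, ys_out = [], [], [], []
    window_counts = np.zeros(n_frames, dtype=np.int64)

    for t in range(n_frames):
        if t > 0:
            alive &= death > t * dt
            heading += sigma_h * rng.standard_normal(n)
            prop = pts + (speeds * dt)[:, None] * np.column_stack(
                [np.cos(heading), np.sin(heading)]
            )
            # reflect at the circular wall
            rad = np.linalg.norm(prop, axis=1)
            out = rad > r_lim
            if np.any(out):
                # fold the radial excess back inside and flip heading
                unit = prop[out] / rad[out, None]
                prop[out] = unit * (2 * r_lim - rad[out])[:, None]
                heading[out] += np.pi
            prop[:ns] = pts[:ns]  # pinned
            prop[~alive] = pts[~alive]
            # hard-core: reject steps that land within d of another cell
            live = np.nonzero(alive)[0]
            if config.d > 0 and len(live) > 1:
                sub = prop[live]
                pairs = cKDTree(sub).query_pairs(config.d, output_type="ndarray")
                if len(pairs):
                    sep = np.linalg.norm(
                        sub[pairs[:, 0]] - sub[pairs[:, 1]], axis=1
                    )
                    pairs = pairs[sep < config.d]
                if len(pairs):
                    bad = live[np.unique(pairs)]
                    bad = bad[bad >= ns]
                    prop[bad] = pts[bad]  # wait in place this frame
                    heading[bad] = rng.uniform(0, 2 * np.pi, size=len(bad))
            pts = prop
        in_win = (
            alive
            & (np.abs(pts[:, 0]) <= half_w)
            & (np.abs(pts[:, 1]) <= half_w)
        )
        idx = np.nonzero(in_win)[0]
        window_counts[t] = len(idx)
        frames_out.append(np.full(len(idx), t, dtype=np.int64))
        pids_out.append(idx)
        xs_out.append(pts[idx, 0] + half_w)
        ys_out.append(pts[idx, 1] + half_w)

    df = pd.DataFrame(
        {
            "frame": np.concatenate(frames_out),
            "particle": np.concatenate(pids_out),
            "x": np.concatenate(xs_out),
            "y": np.concatenate(ys_out),
        }
    )
    traj = TrajectorySet(df, fps=config.fps_raw)
    truth = GroundTruth(
        stationary_ids=list(range(ns)),
        stationary_positions=init[:ns] + half_w,
        window_counts=pd.Series(window_counts, index=range(n_frames)),
        config=config,
    )
    return traj, truth
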