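"""Trajectory-level preprocessing: frame thinning, steady-state trimming
and stationary-cell detection.

A raw 30 fps tracker stream is thinned to 1 fps before quadrat analysis;
the initial transient — cells flowing in/out of the field of view right
after the chamber is loaded — is trimmed by detecting when the per-frame
cell count plateaus; and adhered ("stationary") cells are identified as
particles that stay below a speed threshold for longer than a minimum
dwell, yielding the pinned coordinates consumed by the placement
simulator.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import StationarySet, TrajectorySet

__all__ = [
    "thin_frames",
    "detect_steady_state",
    "trim_transient",
    "fit_transient_decay",
    "detect_stationary",
    "SPEED_MAX_UM_S",
    "MIN_DWELL_S",
    "FALLBACK_TRIM_S",
]

# Stationary-cell rule: speed strictly below 18 µm/s sustained for
# strictly more than 30 s.
SPEED_MAX_UM_S = 18.0
MIN_DWELL_S = 30.0
# Conservative transient trim when no plateau is detected: 20 min.
FALLBACK_TRIM_S = 1200.0


def thin_frames(traj: TrajectorySet, stride: int) -> TrajectorySet:
    """Keep only frames whose index is a multiple of ``stride``.

    Kept frames are renumbered by ``index // stride`` and the stream's
    fps is divided by the stride, so a 30 fps recording thinned with
    stride 30 becomes a 1 fps stream with consecutive integer indices.
    """
    if not isinstance(stride, (int, np.integer)) or stride < 1:
        raise ValueError(f"stride must be an integer >= 1, got {stride}")
    if stride == 1:
        return traj
    df = traj.data[traj.data["frame"] % stride == 0].copy()
    df["frame"] = df["frame"] // stride
    return TrajectorySet(df, fps=traj.fps / stride)


@dataclass
class SteadyStateResult:
    """Outcome of transient detection: first steady frame and whether the
    fallback trim was used."""

    frame: int
    fallback_used: bool
    block_means: np.ndarray


def detect_steady_state(
    counts: np.ndarray | pd.Series,
    fps: float,
    window_s: float = 120.0,
    rel_tol: float = 0.05,
    fallback_s: float = FALLBACK_TRIM_S,
) -> SteadyStateResult:
    """Find the first frame from which the in-window cell count is steady.

    The count series is averaged over consecutive non-overlapping windows
    of ``window_s`` seconds; the earliest window from which every
    subsequent window-to-window relative change stays below ``rel_tol``
    marks the steady state.  If no such window exists (or fewer than two
    windows fit), the configured fallback trim is returned with a warning.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.size == 0:
        raise ValueError("counts must be non-empty")
    if fps <= 0:
        raise ValueError(f"fps must be positive, got {fps}")
    w = max(int(round(window_s * fps)), 1)
    n_blocks = len(counts) // w
    fallback_frame = min(int(round(fallback_s * fps)), len(counts) - 1)
    if n_blocks < 2:
        warnings.warn("count series shorter than two averaging windows; using fallback trim")
        return SteadyStateResult(fallback_frame, True, np.array([]))
    blocks = counts[: n_blocks * w].reshape(n_blocks, w).mean(axis=1)
    rel = np.abs(np.diff(blocks)) / np.where(blocks[:-1] > 0, blocks[:-1], np.nan)
    ok = rel < rel_tol
    if not ok[-1]:
        warnings.warn("no steady plateau detected; using fallback trim")
        return SteadyStateResult(fallback_frame, True, blocks)
    # earliest block index from which all later changes are below tol
    bad = np.nonzero(~ok)[0]
    first_block = int(bad[-1] + 1) if len(bad) else 0
    return SteadyStateResult(first_block * w, False, blocks)


def trim_transient(
    traj: TrajectorySet,
    window_s: float = 120.0,
    rel_tol: float = 0.05,
    fallback_s: float = FALLBACK_TRIM_S,
) -> tuple[TrajectorySet, SteadyStateResult]:
    """Drop the initial transient of a trajectory stream.

    Applies :func:`detect_steady_state` to the per-frame counts and
    removes all earlier frames (frame indices are preserved).
    """
    counts = traj.per_frame_counts()
    full = counts.reindex(
        range(int(counts.index.min()), int(counts.index.max()) + 1), fill_value=0
    )
    res = detect_steady_state(
        full.to_numpy(), traj.fps, window_s=window_s, rel_tol=rel_tol,
        fallback_s=fallback_s,
    )
    cut = int(full.index[0]) + res.frame
    out = TrajectorySet(traj.data[traj.data["frame"] >= cut], fps=traj.fps)
    return out, res


def fit_transient_decay(
    counts: np.ndarray | pd.Series,
    fps: float,
    t_min_s: float = 20.0,
) -> tuple[float, float, float]:
    """Fit A exp(-t/tau) + B to the per-frame in-window counts.

    Characterizes the post-loading transient; the first ``t_min_s``
    seconds are excluded so early non-exponential mixing (cells
    redistributing across the chamber) does not bias the decay constant.
    Returns (A, tau_s, B).
    """
    from scipy.optimize import curve_fit

    counts = np.asarray(counts, dtype=float)
    t = np.arange(len(counts)) / fps
    sel = t >= t_min_s
    if sel.sum() < 10:
        raise ValueError("count series too short to fit a transient")
    tail = counts[-max(len(counts) // 10, 10):].mean()
    p0 = [max(counts[sel][0] - tail, 1.0), max(t[-1] / 5.0, 1.0), tail]
    popt, _ = curve_fit(
        lambda tt, A, tau, B: A * np.exp(-tt / tau) + B,
        t[sel], counts[sel], p0=p0, maxfev=20_000,
    )
    return float(popt[0]), float(popt[1]), float(popt[2])


def detect_stationary(
    traj: TrajectorySet,
    speed_max: float = SPEED_MAX_UM_S,
    min_duration_s: float = MIN_DWELL_S,
) -> StationarySet:
    """Identify stationary (adhered) cells from the analyzed stream.

    The per-frame speed of a particle is the displacement between
    consecutive analyzed frames times fps.  A particle qualifies when it
    has a run of consecutive frames — gaps (missed detections) break a
    run — whose speeds are all strictly below ``speed_max`` and whose
    dwell exceeds ``min_duration_s`` strictly.  The dwell of a run with
    k positions is k / fps (each detection representing one frame
    period), so at 1 fps a run must contain at least 31 low-speed
    positions to exceed a 30 s minimum.

    Each qualifying particle contributes one stationary point: the mean
    position over its longest qualifying run.
    """
    if speed_max <= 0:
        raise ValueError(f"speed_max must be positive, got {speed_max}")
    fps = traj.fps
    rows = []
    for pid, sub in traj.data.groupby("particle"):
        f = sub["frame"].to_numpy()
        xy = sub[["x", "y"]].to_numpy()
        if len(f) < 2:
            continue
        step = np.diff(f)
        speed = np.linalg.norm(np.diff(xy, axis=0), axis=1) * fps
        # a segment is "slow" only if it joins adjacent analyzed frames
        slow = (speed < speed_max) & (step == 1)
        best = None  # (dwell, start, stop) over positions [start, stop]
        i = 0
        while i < len(slow):
            if not slow[i]:
                i += 1
                continue
            j = i
            while j < len(slow) and slow[j]:
                j += 1
            n_pos = j - i + 1  # segments i..j-1 span positions i..j
            dwell = n_pos / fps
            if best is None or dwell > best[0]:
                best = (dwell, i, j)
            i = j
        if best is not None and best[0] > min_duration_s:
            dwell, i, j = best
            mean_xy = xy[i : j + 1].mean(axis=0)
            rows.append(
                {"particle": pid, "x": mean_xy[0], "y": mean_xy[1], "dwell_s": dwell}
            )
    df = pd.DataFrame(rows, columns=["particle", "x", "y", "dwell_s"])
    return StationarySet(df)
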