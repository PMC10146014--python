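"""Closed-form count-distribution nulls for quadrat occupancy.

Three nested models for the number of cells found in one of N equal
sections of a finite window:

* **hypergeometric** — the window is discretized into M = S/A seats of one
  cell area A each; a section holds K = D/A seats; n cells occupy n
  distinct seats.  This is the finite-cell-size (excluded-area) null.
* **binomial** — the A -> 0 (M -> infinity) limit at fixed p = K/M = 1/N:
  point cells placed independently.
* **Poisson** — the additional n -> infinity, p -> 0 limit at fixed
  lambda = n p: the infinite-space, complete-spatial-randomness null.

The variance-to-mean ratio (VMR) of each model is the reference line the
measured quadrat VMR is compared against: 1 for Poisson, 1 - 1/N for
binomial, and (1 - 1/N)(M - n)/(M - 1) for the hypergeometric model.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import ArenaSpec, PartitionSpec

__all__ = [
    "ModelParams",
    "hypergeometric_pmf",
    "hypergeometric_moments",
    "binomial_pmf",
    "binomial_moments",
    "poisson_pmf",
    "poisson_moments",
    "hypergeometric_to_binomial_limit_check",
    "seat_model_params",
    "model_table",
    "model_summary",
]


@dataclass(frozen=True)
class ModelParams:
    """Parameters of the seat-model nulls.

    M seats in the window, K seats per section, n cells; p = K/M = 1/N is
    the per-cell probability of landing in a given section and
    lam = n p the matching Poisson mean.
    """

    M: int
    K: int
    n: int
    N: int | None = None

    def __post_init__(self) -> None:
        for name in ("M", "K", "n"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)):
                raise TypeError(f"{name} must be an integer, got {type(v).__name__}")
        if self.M < 1:
            raise ValueError(f"M must be positive, got {self.M}")
        if self.K < 0 or self.K > self.M:
            raise ValueError(f"need 0 <= K <= M, got K={self.K}, M={self.M}")
        if self.n < 0 or self.n > self.M:
            raise ValueError(f"need 0 <= n <= M, got n={self.n}, M={self.M}")
        if self.N is not None and self.N < 1:
            raise ValueError(f"N must be positive, got {self.N}")

    @property
    def p(self) -> float:
        return self.K / self.M

    @property
    def lam(self) -> float:
        return self.n * self.p

    @property
    def n_sections(self) -> int:
        """N: explicit if given, else M/K rounded."""
        if self.N is not None:
            return self.N
        if self.K == 0:
            raise ValueError("N undefined when K=0 and N not given")
        return round(self.M / self.K)


def hypergeometric_pmf(params: ModelParams, x: int | np.ndarray) -> float | np.ndarray:
    """P(X = x) = C(K,x) C(M-K, n-x) / C(M,n).

    Zero outside the support max(0, n-(M-K)) <= x <= min(K, n).
    Evaluated through log-gamma arithmetic (scipy), stable for M up to
    ~1e8 where naive factorials overflow.
    """
    x = np.asarray(x)
    if np.any(x < 0):
        raise ValueError("occupancy x must be non-negative")
    out = stats.hypergeom.pmf(x, params.M, params.K, params.n)
    return float(out) if out.ndim == 0 else out


def hypergeometric_moments(params: ModelParams) -> tuple[float, float, float]:
    """(mean, variance, VMR) of the seat-model hypergeometric null.

    mean = nK/M; variance = nK/M (1 - K/M)(M - n)/(M - 1);
    VMR = (1 - 1/N)(M - n)/(M - 1) with 1/N = K/M.
    """
    M, K, n = params.M, params.K, params.n
    if M == 1:
        raise ValueError("moments undefined for M=1 (variance denominator M-1)")
    mean = n * K / M
    fpc = (M - n) / (M - 1)  # finite-population correction
    variance = mean * (1 - K / M) * fpc
    vmr = (1 - K / M) * fpc
    return mean, variance, vmr


def binomial_pmf(n: int, p: float, x: int | np.ndarray) -> float | np.ndarray:
    """P(X = x) for the point-cell (binomial) null."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p must lie in [0, 1], got {p}")
    if n < 0:
        raise ValueError(f"n must be non-negative, got {n}")
    out = stats.binom.pmf(np.asarray(x), n, p)
    return float(out) if out.ndim == 0 else out


def binomial_moments(n: int, p: float, N: int | None = None) -> tuple[float, float, float]:
    """(mean, variance, VMR): np, np(1-p), 1-p.

    When ``N`` is given, ``p`` defaults from it as 1/N if p is None.
    """
    if p is None:
        if N is None:
            raise ValueError("need p or N")
        p = 1.0 / N
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p must lie in [0, 1], got {p}")
    mean = n * p
    variance = n * p * (1 - p)
    return mean, variance, 1 - p


def poisson_pmf(lam: float, x: int | np.ndarray) -> float | np.ndarray:
    """P(X = x) = exp(-lam) lam^x / x!."""
    if lam < 0:
        raise ValueError(f"lambda must be non-negative, got {lam}")
    out = stats.poisson.pmf(np.asarray(x), lam)
    return float(out) if out.ndim == 0 else out


def poisson_moments(lam: float) -> tuple[float, float, float]:
    """(mean, variance, VMR) = (lam, lam, 1)."""
    if lam < 0:
        raise ValueError(f"lambda must be non-negative, got {lam}")
    return lam, lam, 1.0


def hypergeometric_to_binomial_limit_check(
    p: float, n: int, M_sequence: Sequence[int]
) -> pd.DataFrame:
    """Sup-norm distance between hypergeometric(M, round(pM), n) and
    binomial(n, p) pmfs along an increasing sequence of seat counts M.

    As the seat count grows at fixed section probability p, the
    excluded-area null converges to the point-cell null; the returned
    table (columns M, sup_dev) quantifies the convergence.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p must lie in [0, 1], got {p}")
    Ms = list(M_sequence)
    if any(m2 <= m1 for m1, m2 in zip(Ms, Ms[1:])):
        raise ValueError("M_sequence must be strictly increasing")
    xs = np.arange(n + 1)
    b = binomial_pmf(n, p, xs)
    rows = []
    for M in Ms:
        K = round(p * M)
        if K > M or n > M:
            raise ValueError(f"invalid seat model at M={M}: K={K}, n={n}")
        h = hypergeometric_pmf(ModelParams(M=M, K=K, n=n), xs)
        rows.append({"M": M, "sup_dev": float(np.max(np.abs(h - b)))})
    return pd.DataFrame(rows)


def seat_model_params(
    arena: ArenaSpec, part: PartitionSpec, n: int, footprint: str = "circle"
) -> tuple[ModelParams, dict]:
    """Map physical window/partition geometry to integer seat counts.

    The seat area A is the cell's circumscribing-circle area pi (d/2)^2
    (``footprint="circle"``, default) or the square d^2
    (``footprint="square"``).  M = S/A and K = D/A are rounded to the
    nearest integer; the rounding residuals are reported in the returned
    metadata dict since the discrete seat model does not address
    non-divisible areas.
    """
    if footprint == "circle":
        A = arena.cell_area
    elif footprint == "square":
        A = arena.d**2
    else:
        raise ValueError(f"footprint must be 'circle' or 'square', got {footprint!r}")
    if A <= 0:
        raise ValueError("seat area must be positive (cell diameter d > 0 required)")
    M_exact = arena.area / A
    K_exact = part.section_area(arena) / A
    M, K = round(M_exact), round(K_exact)
    meta = {
        "footprint": footprint,
        "seat_area_um2": A,
        "M_exact": M_exact,
        "K_exact": K_exact,
        "M_rounding": M - M_exact,
        "K_rounding": K - K_exact,
    }
    return ModelParams(M=M, K=K, n=n, N=part.n_sections), meta


# ---------------------------------------------------------------------------
# export helpers

def model_table(model: str, x: Iterable[int], **kw) -> pd.DataFrame:
    """Tabulate (x, pmf, cumulative) for one of the three nulls.

    ``model`` is "hypergeometric" (kw: params), "binomial" (kw: n, p) or
    "poisson" (kw: lam).
    """
    xs = np.asarray(list(x), dtype=int)
    if model == "hypergeometric":
        pmf = hypergeometric_pmf(kw["params"], xs)
    elif model == "binomial":
        pmf = binomial_pmf(kw["n"], kw["p"], xs)
    elif model == "poisson":
        pmf = poisson_pmf(kw["lam"], xs)
    else:
        raise ValueError(f"unknown model {model!r}")
    return pd.DataFrame({"x": xs, "pmf": pmf, "cumulative": np.cumsum(pmf)})


def model_summary(params: ModelParams) -> dict:
    """JSON-ready summary: parameters and (mean, variance, vmr) of all
    three nulls at matched parameters."""
    hm = hypergeometric_moments(params)
    bm = binomial_moments(params.n, params.p)
    pm = poisson_moments(params.lam)
    return {
        "params": {
            "M": params.M,
            "K": params.K,
            "n": params.n,
            "N": params.n_sections,
            "p": params.p,
            "lam": params.lam,
        },
        "hypergeometric": dict(zip(("mean", "variance", "vmr"), hm)),
        "binomial": dict(zip(("mean", "variance", "vmr"), bm)),
        "poisson": dict(zip(("mean", "variance", "vmr"), pm)),
    }


def write_model_outputs(path_prefix: str | Path, params: ModelParams) -> None:
    """Write the pmf table (TSV) and moment summary (JSON) for ``params``."""
    prefix = Path(path_prefix)
    xs = range(0, min(params.K, params.n) + 1)
    model_table("hypergeometric", xs, params=params).to_csv(
        prefix.with_suffix(".tsv"), sep="\t", index=False
    )
    prefix.with_suffix(".json").write_text(json.dumps(model_summary(params), indent=2))
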