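"""Vocabulary growth, Heaps'-law and Menzerath-type fits.

As a genome is scanned, the number of distinct canonical k-mers V grows
sublinearly with the number of k-mer tokens n processed. Heaps' law models
this as V(n) = K * n^beta with 0 <= beta <= 1: beta near 0 means the
vocabulary is exhausted almost immediately (small k), beta near 1 means
nearly every token is new (large k relative to genome size). The
Menzerath-type relation fits the vocabulary density M(n) = V(n)/n = A * n^b
directly; when the curve is exactly Heapsian, b = beta - 1, so the
discrepancy delta = b - (beta - 1) measures departure from a single
power-law growth regime.

Both fits are nonlinear least squares in linear space (scipy
``curve_fit``), initialized from a log-log linear regression.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .io import Genome
from .spectrum import canonical_token_stream

__all__ = [
    "GrowthCurve",
    "HeapsFit",
    "MenzerathFit",
    "growth_from_tokens",
    "vocabulary_growth",
    "fit_heaps",
    "fit_menzerath",
]


@dataclass(frozen=True)
class GrowthCurve:
    """(tokens processed, distinct tokens seen) at evenly spaced checkpoints."""

    n: np.ndarray
    V: np.ndarray
    k: int | None = None

    def __post_init__(self) -> None:
        n = np.asarray(self.n, dtype=float)
        V = np.asarray(self.V, dtype=float)
        object.__setattr__(self, "n", n)
        object.__setattr__(self, "V", V)
        if n.size < 1 or n.size != V.size:
            raise ValueError("growth curve needs matching non-empty n and V")
        if np.any(np.diff(n) <= 0):
            raise ValueError("token counts must be strictly increasing")
        if np.any(np.diff(V) < 0):
            raise ValueError("vocabulary size must be non-decreasing")
        if np.any(V > n):
            raise ValueError("cannot see more distinct tokens than tokens")

    @property
    def n_checkpoints(self) -> int:
        return int(self.n.size)


@dataclass(frozen=True)
class HeapsFit:
    """Parameters of V(n) = K * n^beta with goodness of fit.

    beta is not clipped at 1: values >= 1 flag super-linear breakdown of
    sublinear growth rather than being hidden.
    """

    K: float
    beta: float
    r_squared: float
    converged: bool = True


@dataclass(frozen=True)
class MenzerathFit:
    """Parameters of M(n) = V/n = A * n^b plus delta = b - (beta - 1)."""

    A: float
    b: float
    delta: float
    r_squared: float
    converged: bool = True


def growth_from_tokens(tokens: np.ndarray, n_checkpoints: int = 100) -> GrowthCurve:
    """Growth curve of an arbitrary token stream.

    Checkpoint i (1-based) records (n, V) after ceil(i * total /
    n_checkpoints) tokens, i.e. at each 1% of the stream for the default
    100 checkpoints.
    """
    tokens = np.asarray(tokens)
    total = tokens.size
    if total < n_checkpoints:
        raise ValueError(
            f"stream has {total} tokens; need at least {n_checkpoints} "
            "(one per checkpoint)"
        )
    # V at prefix length j = number of first occurrences among tokens[:j]
    _, first_idx = np.unique(tokens, return_index=True)
    new = np.zeros(total, dtype=np.int64)
    new[first_idx] = 1
    cum_v = np.cumsum(new)
    i = np.arange(1, n_checkpoints + 1)
    n_at = np.ceil(i * total / n_checkpoints).astype(np.int64)
    n_at = np.unique(n_at)  # guards against duplicate checkpoints
    return GrowthCurve(n=n_at, V=cum_v[n_at - 1])


def vocabulary_growth(
    genome: Genome | str, k: int, n_checkpoints: int = 100
) -> GrowthCurve:
    """Single-pass canonical k-mer vocabulary growth over a genome.

    Checkpoints are placed on the token (window) stream: the last checkpoint
    equals the total number of clean windows, and V <= n holds exactly at
    every point. Records are streamed in file order.
    """
    tokens = canonical_token_stream(genome, k)
    curve = growth_from_tokens(tokens, n_checkpoints=n_checkpoints)
    return GrowthCurve(n=curve.n, V=curve.V, k=k)


def _power_law_init(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Slope/intercept of the log-log regression as (scale, exponent)."""
    mask = (x > 0) & (y > 0)
    res = stats.linregress(np.log(x[mask]), np.log(y[mask]))
    return math.exp(res.intercept), res.slope


def _fit_power(
    x: np.ndarray, y: np.ndarray, exponent_extra_starts: tuple[float, ...] = ()
) -> tuple[float, float, float, bool]:
    """Least-squares fit of y = scale * x^exponent in linear space.

    Returns (scale, exponent, r_squared, converged); falls back to the
    log-log estimate if every optimizer start fails.
    """
    scale0, exp0 = _power_law_init(x, y)
    starts = [(scale0, exp0)] + [(scale0, e) for e in exponent_extra_starts]
    best: tuple[float, float] | None = None
    best_ss = np.inf
    for p0 in starts:
        try:
            with np.errstate(over="ignore", invalid="ignore"):
                popt, _ = optimize.curve_fit(
                    lambda t, a, b: a * np.power(t, b),
                    x.astype(float),
                    y.astype(float),
                    p0=p0,
                    maxfev=20000,
                )
        except RuntimeError:
            continue
        ss = float(np.sum((y - popt[0] * np.power(x, popt[1])) ** 2))
        if ss < best_ss:
            best_ss, best = ss, (float(popt[0]), float(popt[1]))
    if best is None:
        scale, exponent, converged = scale0, exp0, False
    else:
        (scale, exponent), converged = best, True
    pred = scale * np.power(x.astype(float), exponent)
    ss_res = float(np.sum((y - pred) ** 2))
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    return scale, exponent, r2, converged


def fit_heaps(curve: GrowthCurve) -> HeapsFit:
    """Fit V(n) = K * n^beta to a growth curve (>= 3 points)."""
    if curve.n_checkpoints < 3:
        raise ValueError("need at least 3 checkpoints to fit Heaps' law")
    K, beta, r2, converged = _fit_power(
        curve.n, curve.V, exponent_extra_starts=(0.1, 0.5, 0.9)
    )
    return HeapsFit(K=K, beta=beta, r_squared=r2, converged=converged)


def fit_menzerath(curve: GrowthCurve, heaps: HeapsFit | None = None) -> MenzerathFit:
    """Fit M(n) = V/n = A * n^b and compare with the Heaps prediction.

    delta = b - (beta - 1) with beta from ``heaps`` (fitted on the same
    curve when not supplied); |delta| near 0 means the two growth accounts
    agree.
    """
    if curve.n_checkpoints < 3:
        raise ValueError("need at least 3 checkpoints to fit the Menzerath relation")
    if heaps is None:
        heaps = fit_heaps(curve)
    density = curve.V / curve.n
    A, b, r2, converged = _fit_power(
        curve.n.astype(float), density, exponent_extra_starts=(-0.1, -0.5, -0.9)
    )
    delta = b - (heaps.beta - 1.0)
    return MenzerathFit(A=A, b=b, delta=delta, r_squared=r2, converged=converged)
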