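"""Heavy-tailed rank-frequency models for k-mer spectra.

Three models of the normalized frequency f at rank r:

* Zipf:               f(r) = C / r, with C pinned to the rank-1 frequency;
* Zipf-Mandelbrot:    f(r) = C / (r + q)^s — the shift q flattens the head,
  the exponent s sets the decay steepness; q -> 0 recovers a pure power law;
* truncated power law: f(r) = C * r^(-alpha) * exp(-lambda * r) — algebraic
  decay with an exponential cutoff of rate lambda; lambda -> 0 recovers a
  pure power law.

The normalization constants of the textbook forms (the generalized harmonic
number for Zipf-Mandelbrot, an incomplete-gamma integral for the truncated
power law) are replaced by the free scale C, since the observed tables are
already normalized. Fitting is nonlinear least squares in linear frequency
space — the convention under which the R^2 reported alongside is defined,
and which weights the high-frequency head of the spectrum — with a fixed
multi-start grid so results are deterministic. AIC uses the Gaussian
least-squares likelihood, the unique family under which least squares is
maximum likelihood: AIC = n*ln(SSres/n) + 2p up to a constant shared by all
models on the same table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .spectrum import RankFrequencyTable

__all__ = [
    "ZipfModel",
    "ZipfMandelbrotModel",
    "TruncatedPowerLawModel",
    "FitResult",
    "ModelChoice",
    "predict",
    "fit_zipf",
    "fit_zipf_mandelbrot",
    "fit_truncated_power_law",
    "r_squared",
    "aic",
    "select_model",
    "correlate_fit_quality",
    "CorrelationReport",
]

# Multi-start initial values spanning the parameter ranges seen in genomic
# spectra (decay exponents from sub-1 to >10, shifts from near-Zipf to
# strongly smoothed heads, cutoffs from none to pronounced).
_DECAY_STARTS = (0.3, 1.0, 3.0, 10.0)
_SHIFT_STARTS = (0.1, 10.0, 1000.0)
_CUTOFF_STARTS = (0.0, 1e-4, 1e-2)


@dataclass(frozen=True)
class ZipfModel:
    """f(r) = C / r."""

    C: float

    def __post_init__(self) -> None:
        if not 0 < self.C <= 1:
            raise ValueError("Zipf scale C must lie in (0, 1]")

    def predict(self, ranks: np.ndarray) -> np.ndarray:
        ranks = _check_ranks(ranks)
        return self.C / ranks


@dataclass(frozen=True)
class ZipfMandelbrotModel:
    """f(r) = C / (r + q)^s."""

    C: float
    s: float
    q: float

    def __post_init__(self) -> None:
        if self.C <= 0 or self.s <= 0 or self.q < 0:
            raise ValueError("require C > 0, s > 0, q >= 0")

    def predict(self, ranks: np.ndarray) -> np.ndarray:
        ranks = _check_ranks(ranks)
        return self.C / np.power(ranks + self.q, self.s)


@dataclass(frozen=True)
class TruncatedPowerLawModel:
    """f(r) = C * r^(-alpha) * exp(-lambda * r)."""

    C: float
    alpha: float
    lam: float

    def __post_init__(self) -> None:
        if self.C <= 0 or self.alpha < 0 or self.lam < 0:
            raise ValueError("require C > 0, alpha >= 0, lambda >= 0")

    def predict(self, ranks: np.ndarray) -> np.ndarray:
        ranks = _check_ranks(ranks)
        return self.C * np.power(ranks, -self.alpha) * np.exp(-self.lam * ranks)


RankModel = ZipfModel | ZipfMandelbrotModel | TruncatedPowerLawModel

_MODEL_NAMES = {
    ZipfModel: "zipf",
    ZipfMandelbrotModel: "zipf_mandelbrot",
    TruncatedPowerLawModel: "truncated_power_law",
}


def _check_ranks(ranks: np.ndarray) -> np.ndarray:
    ranks = np.asarray(ranks, dtype=float)
    if np.any(ranks < 1):
        raise ValueError("ranks start at 1")
    return ranks


def predict(model: RankModel, ranks: np.ndarray) -> np.ndarray:
    """Model frequencies at the given ranks (strictly positive, decreasing)."""
    return model.predict(ranks)


@dataclass(frozen=True)
class FitResult:
    """One fitted rank-frequency model with its goodness-of-fit summary."""

    model: str
    params: RankModel
    r_squared: float
    ss_res: float
    ss_tot: float
    aic: float
    n_points: int
    p_free: int
    converged: bool
    degenerate: bool = False

    def predict(self, ranks: np.ndarray) -> np.ndarray:
        return self.params.predict(ranks)


def r_squared(observed: np.ndarray, predicted: np.ndarray) -> float:
    """Coefficient of determination 1 - SSres/SStot in linear space.

    Negative when predictions are worse than the horizontal mean baseline;
    NaN when SStot is zero (constant observations — degenerate).
    """
    observed = np.asarray(observed, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if observed.shape != predicted.shape:
        raise ValueError("observed and predicted must have equal length")
    ss_res = float(np.sum((observed - predicted) ** 2))
    ss_tot = float(np.sum((observed - observed.mean()) ** 2))
    if ss_tot == 0.0:
        return float("nan")
    return 1.0 - ss_res / ss_tot


def aic(ss_res: float, n_points: int, p_free: int) -> float:
    """AIC under the Gaussian least-squares likelihood.

    AIC = n * ln(SSres/n) + 2p, dropping the additive constant that is
    shared by every model fitted to the same table; lower is better. A
    perfect fit (SSres = 0) returns -inf.
    """
    if n_points < 2:
        raise ValueError("AIC needs at least 2 points")
    if ss_res < 0:
        raise ValueError("SSres cannot be negative")
    if ss_res == 0.0:
        return float("-inf")
    return n_points * math.log(ss_res / n_points) + 2 * p_free


def _summarize(
    model: RankModel, table: RankFrequencyTable, p_free: int, converged: bool
) -> FitResult:
    obs = table.frequencies
    pred = model.predict(table.ranks)
    ss_res = float(np.sum((obs - pred) ** 2))
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    degenerate = ss_tot == 0.0 or table.m < 2
    r2 = float("nan") if degenerate else 1.0 - ss_res / ss_tot
    a = aic(ss_res, table.m, p_free) if table.m >= 2 else float("nan")
    return FitResult(
        model=_MODEL_NAMES[type(model)],
        params=model,
        r_squared=r2,
        ss_res=ss_res,
        ss_tot=ss_tot,
        aic=a,
        n_points=table.m,
        p_free=p_free,
        converged=converged,
        degenerate=degenerate,
    )


def fit_zipf(table: RankFrequencyTable, free_scale: bool = False) -> FitResult:
    """Zipf fit f(r) = C / r.

    By default C is pinned to the observed rank-1 frequency (one free
    parameter, no optimization). With ``free_scale`` C is fitted by least
    squares instead (two-parameter variant kept behind this flag).
    """
    freqs = table.frequencies
    if free_scale:
        ranks = table.ranks.astype(float)
        c = float(np.sum(freqs / ranks) / np.sum(1.0 / ranks**2))
        c = min(max(c, np.finfo(float).tiny), 1.0)
        return _summarize(ZipfModel(C=c), table, p_free=2, converged=True)
    return _summarize(ZipfModel(C=float(freqs[0])), table, p_free=1, converged=True)


# Upper caps keep the least-squares problem bounded: a shift or decay far
# beyond these is unidentifiable on any table this package produces (the
# model is indistinguishable from its limiting form there), and the flat
# ridge q -> inf with C ~ q^s would otherwise never terminate.
_MAX_EXPONENT = 60.0
_MAX_SHIFT = 1e6
_MAX_CUTOFF = 5.0
_MAX_SCALE = 1e30


def _multistart_fit(
    table: RankFrequencyTable,
    func,
    jac,
    starts: list[tuple[float, ...]],
    bounds: tuple[tuple[float, ...], tuple[float, ...]],
) -> tuple[np.ndarray | None, bool]:
    """Bounded trust-region least squares from every start; best SSres wins.

    A start that exhausts its evaluation budget still contributes its best
    iterate, but only budget-converged solutions set the converged flag.
    """
    ranks = table.ranks.astype(float)
    freqs = table.frequencies
    best_popt = None
    best_ss = np.inf
    converged = False
    for p0 in starts:
        p0 = np.clip(p0, bounds[0], bounds[1])
        try:
            with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
                res = optimize.least_squares(
                    lambda p: func(ranks, *p) - freqs,
                    p0,
                    jac=lambda p: jac(ranks, *p),
                    bounds=bounds,
                    x_scale="jac",
                    max_nfev=2000,
                )
        except ValueError:
            continue
        ss = float(np.sum((freqs - func(ranks, *res.x)) ** 2))
        if ss < best_ss:
            best_ss, best_popt = ss, res.x
            converged = res.status > 0
    return best_popt, converged


def fit_zipf_mandelbrot(table: RankFrequencyTable) -> FitResult:
    """Least-squares Zipf-Mandelbrot fit over a fixed multi-start grid.

    Needs at least 4 points (more points than the 3 free parameters). The
    scale is initialized from the rank-1 frequency consistently with each
    (s, q) start; the best sum of squared residuals across starts is kept.
    """
    if table.m < 4:
        raise ValueError("Zipf-Mandelbrot fit needs at least 4 ranks")
    f1 = float(table.frequencies[0])

    def zm(r, c, s, q):
        return c / np.power(r + q, s)

    def zm_jac(r, c, s, q):
        base = np.power(r + q, -s)
        return np.stack(
            [base, -c * np.log(r + q) * base, -c * s * np.power(r + q, -s - 1)],
            axis=1,
        )

    starts = [
        (f1 * (1.0 + q0) ** s0, s0, q0)
        for s0 in _DECAY_STARTS
        for q0 in _SHIFT_STARTS
    ]
    bounds = (
        (np.finfo(float).tiny, 1e-9, 0.0),
        (_MAX_SCALE, _MAX_EXPONENT, _MAX_SHIFT),
    )
    popt, ok = _multistart_fit(table, zm, zm_jac, starts, bounds)
    if popt is None:
        model = ZipfMandelbrotModel(C=f1, s=1.0, q=1e-9)
        return _summarize(model, table, p_free=3, converged=False)
    model = ZipfMandelbrotModel(C=float(popt[0]), s=float(popt[1]), q=float(popt[2]))
    return _summarize(model, table, p_free=3, converged=ok)


def fit_truncated_power_law(table: RankFrequencyTable) -> FitResult:
    """Least-squares truncated-power-law fit over a fixed multi-start grid.

    The cutoff grid includes 0, so a pure power law is always among the
    starting points; needs at least 4 ranks.
    """
    if table.m < 4:
        raise ValueError("truncated power law fit needs at least 4 ranks")
    f1 = float(table.frequencies[0])

    def tpl(r, c, a, lam):
        return c * np.power(r, -a) * np.exp(-lam * r)

    def tpl_jac(r, c, a, lam):
        base = np.power(r, -a) * np.exp(-lam * r)
        return np.stack([base, -c * np.log(r) * base, -c * r * base], axis=1)

    starts = [
        (f1 * math.exp(lam0), a0, lam0)
        for a0 in _DECAY_STARTS
        for lam0 in _CUTOFF_STARTS
    ]
    bounds = (
        (np.finfo(float).tiny, 0.0, 0.0),
        (_MAX_SCALE, _MAX_EXPONENT, _MAX_CUTOFF),
    )
    popt, ok = _multistart_fit(table, tpl, tpl_jac, starts, bounds)
    if popt is None:
        model = TruncatedPowerLawModel(C=f1, alpha=1.0, lam=0.0)
        return _summarize(model, table, p_free=3, converged=False)
    model = TruncatedPowerLawModel(
        C=float(popt[0]), alpha=float(popt[1]), lam=float(popt[2])
    )
    return _summarize(model, table, p_free=3, converged=ok)


@dataclass(frozen=True)
class ModelChoice:
    """Outcome of the k-dependent model-selection rule."""

    chosen: str
    reason: str
    negative_r2_flags: dict[str, bool] = field(default_factory=dict)


def select_model(k: int, fits: dict[str, FitResult]) -> ModelChoice:
    """Choose between Zipf-Mandelbrot and truncated power law for one table.

    For word lengths 3-6 both models perform well and the lower-AIC one is
    taken (truncated power law on ties, reflecting its slight edge there).
    Above k = 6 sparse spectra systematically break the truncated power law
    (negative R^2 for most genomes), so Zipf-Mandelbrot is the default
    unless its own R^2 is negative. Negative-R^2 fits are flagged either way.
    """
    if "zipf_mandelbrot" not in fits or "truncated_power_law" not in fits:
        raise ValueError("selection needs both zipf_mandelbrot and truncated_power_law fits")
    zm = fits["zipf_mandelbrot"]
    tpl = fits["truncated_power_law"]
    flags = {
        name: bool(fit.r_squared < 0) if not math.isnan(fit.r_squared) else False
        for name, fit in fits.items()
    }
    if 3 <= k <= 6:
        if tpl.aic <= zm.aic:
            chosen, reason = "truncated_power_law", (
                f"k={k} in 3..6: truncated power law AIC {tpl.aic:.2f} <= "
                f"Zipf-Mandelbrot AIC {zm.aic:.2f}"
            )
        else:
            chosen, reason = "zipf_mandelbrot", (
                f"k={k} in 3..6: Zipf-Mandelbrot AIC {zm.aic:.2f} < "
                f"truncated power law AIC {tpl.aic:.2f}"
            )
    elif k > 6:
        if not math.isnan(zm.r_squared) and zm.r_squared < 0:
            chosen, reason = "truncated_power_law", (
                f"k={k} > 6 but Zipf-Mandelbrot R^2 is negative; falling back"
            )
        else:
            chosen, reason = "zipf_mandelbrot", (
                f"k={k} > 6: truncated power law avoided (sparse-spectrum failure mode)"
            )
    else:
        better = min(fits.items(), key=lambda kv: kv[1].aic)
        chosen, reason = better[0], f"k={k} < 3: lowest AIC"
    return ModelChoice(chosen=chosen, reason=reason, negative_r2_flags=flags)


@dataclass(frozen=True)
class CorrelationReport:
    """Spearman correlations of fit quality against a genome covariate."""

    strata: tuple[str, ...]
    rho: tuple[float, ...]
    p_value: tuple[float, ...]
    n: tuple[int, ...]


def correlate_fit_quality(
    r2_values: np.ndarray,
    covariate: np.ndarray,
    quartile_stratify: bool = False,
) -> CorrelationReport:
    """Spearman rank correlation between R^2 values and a covariate.

    With ``quartile_stratify`` the genomes are split into covariate
    quartiles and the correlation is computed within each (n >= 5 required
    per stratum); useful for exposing non-monotone (e.g. U-shaped)
    relations such as GC content versus goodness of fit. Constant inputs
    yield NaN rho, flagged by the NaN itself.
    """
    r2_values = np.asarray(r2_values, dtype=float)
    covariate = np.asarray(covariate, dtype=float)
    if r2_values.shape != covariate.shape:
        raise ValueError("r2 and covariate vectors must have equal length")

    def _spearman(a, b):
        if a.size < 5:
            raise ValueError("need at least 5 observations per stratum")
        if np.all(a == a[0]) or np.all(b == b[0]):
            return float("nan"), float("nan")
        res = stats.spearmanr(a, b)
        return float(res.statistic), float(res.pvalue)

    strata, rhos, ps, ns = ["overall"], [], [], [r2_values.size]
    rho, p = _spearman(covariate, r2_values)
    rhos.append(rho)
    ps.append(p)
    if quartile_stratify:
        edges = np.quantile(covariate, [0.25, 0.5, 0.75])
        bins = np.digitize(covariate, edges)  # 0..3
        for b, label in enumerate(["Q1", "Q2", "Q3", "Q4"]):
            mask = bins == b
            rho, p = _spearman(covariate[mask], r2_values[mask])
            strata.append(label)
            rhos.append(rho)
            ps.append(p)
            ns.append(int(mask.sum()))
    return CorrelationReport(
        strata=tuple(strata), rho=tuple(rhos), p_value=tuple(ps), n=tuple(ns)
    )
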