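"""Null-model genomes and divergence between fitted rank-frequency curves.

Two controls are provided: a uniform base shuffle, which preserves each
record's base composition and length exactly while destroying all
positional structure, and a Markov-chain generator (order 0-2) that
preserves short-range composition estimated from a source genome. Fitted
model curves for real and control genomes are compared on a common rank
support via the Kolmogorov-Smirnov distance and the base-2 Jensen-Shannon
divergence, both bounded in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import Genome, SequenceRecord
from .models import (
    FitResult,
    RankModel,
    fit_truncated_power_law,
    fit_zipf_mandelbrot,
)
from .spectrum import count_canonical_kmers, to_rank_frequency

__all__ = [
    "DivergenceResult",
    "ComparisonReport",
    "shuffle_genome",
    "markov_genome",
    "ks_distance",
    "js_divergence",
    "curve_ks_distance",
    "curve_js_divergence",
    "compare_real_vs_null",
]


@dataclass(frozen=True)
class DivergenceResult:
    """KS distance and base-2 JS divergence between two curves on a support."""

    ks: float
    js: float
    support_size: int


def shuffle_genome(genome: Genome, seed: int) -> Genome:
    """Uniformly permute the bases of each record independently.

    Per-record base multisets, lengths and identifiers are preserved;
    deterministic for a given seed.
    """
    rng = np.random.default_rng(seed)
    records = []
    for rec in genome:
        arr = np.frombuffer(rec.sequence.encode("ascii"), dtype=np.uint8)
        shuffled = rng.permutation(arr)
        records.append(
            SequenceRecord(
                identifier=rec.identifier,
                sequence=shuffled.tobytes().decode("ascii"),
                description=rec.description,
            )
        )
    return Genome(records=tuple(records))


def _estimate_transitions(genome: Genome, order: int) -> np.ndarray:
    """(order+1)-mer counts over clean windows -> transition matrix.

    Rows are contexts (packed 2-bit codes), columns the next base. Rows
    never observed fall back to the uniform distribution.
    """
    n_ctx = 4**order
    counts = np.zeros((n_ctx, 4), dtype=np.int64)
    code = np.full(256, -1, dtype=np.int8)
    for i, b in enumerate(b"ACGT"):
        code[b] = i
    w = order + 1
    for rec in genome:
        vals = code[np.frombuffer(rec.sequence.encode("ascii"), dtype=np.uint8)]
        n = vals.size
        if n < w:
            continue
        ok = vals >= 0
        valid = np.ones(n - w + 1, dtype=bool)
        packed = np.zeros(n - w + 1, dtype=np.int64)
        for j in range(w):
            valid &= ok[j : n - w + 1 + j]
            packed = (packed << 2) | np.where(ok, vals, 0).astype(np.int64)[
                j : n - w + 1 + j
            ]
        packed = packed[valid]
        np.add.at(counts, (packed >> 2, packed & 3), 1)
    rows = counts.astype(float)
    zero = rows.sum(axis=1) == 0
    rows[zero] = 1.0
    return rows / rows.sum(axis=1, keepdims=True)


def markov_genome(
    source: Genome | np.ndarray,
    order: int,
    length: int,
    seed: int,
    identifier: str = "markov",
) -> Genome:
    """Sample a single-record genome from a Markov chain of the given order.

    ``source`` is either a genome (transitions estimated from its
    (order+1)-mer frequencies) or an explicit transition array: shape (4,)
    for order 0, or (4^order, 4) rows of next-base probabilities.
    Deterministic per seed.
    """
    if order not in (0, 1, 2):
        raise ValueError("supported Markov orders are 0, 1 and 2")
    if length < order + 1:
        raise ValueError("length must be at least order + 1")
    if isinstance(source, Genome):
        trans = _estimate_transitions(source, order)
        if order == 0:
            trans = trans[0]
    else:
        trans = np.asarray(source, dtype=float)
        expected = (4,) if order == 0 else (4**order, 4)
        if trans.shape != expected:
            raise ValueError(f"transition array must have shape {expected}")
        sums = trans.sum(axis=-1)
        if np.any(sums <= 0):
            raise ValueError("transition rows must have positive mass")
        trans = trans / np.expand_dims(sums, -1) if trans.ndim == 2 else trans / sums

    rng = np.random.default_rng(seed)
    ascii_bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    if order == 0:
        draws = rng.choice(4, size=length, p=trans)
        seq = ascii_bases[draws].tobytes().decode("ascii")
        return Genome(records=(SequenceRecord(identifier, seq),))

    # stationary-ish start: draw the initial context from row-marginal usage
    ctx_weights = trans.sum(axis=1)
    ctx = int(rng.choice(trans.shape[0], p=ctx_weights / ctx_weights.sum()))
    mask = 4**order
    cum = np.cumsum(trans, axis=1)
    u = rng.random(length - order)
    out = np.empty(length, dtype=np.int64)
    c = ctx
    for j in range(order):  # spell the starting context
        out[order - 1 - j] = c & 3
        c >>= 2
    for i in range(length - order):
        b = int(np.searchsorted(cum[ctx], u[i], side="right"))
        b = min(b, 3)
        out[order + i] = b
        ctx = (ctx * 4 + b) % mask
    seq = ascii_bases[out].tobytes().decode("ascii")
    return Genome(records=(SequenceRecord(identifier, seq),))


def ks_distance(p: np.ndarray, q: np.ndarray) -> float:
    """Max absolute gap between the cumulative sums of two probability vectors."""
    p, q = _as_prob_pair(p, q)
    return float(np.max(np.abs(np.cumsum(p) - np.cumsum(q))))


def js_divergence(p: np.ndarray, q: np.ndarray) -> float:
    """Base-2 Jensen-Shannon divergence, bounded in [0, 1].

    JS = (KL(P||M) + KL(Q||M)) / 2 with M = (P+Q)/2; zero-probability
    cells contribute nothing to their own KL term.
    """
    p, q = _as_prob_pair(p, q)
    m = 0.5 * (p + q)
    return 0.5 * _kl2(p, m) + 0.5 * _kl2(q, m)


def _kl2(p: np.ndarray, q: np.ndarray) -> float:
    mask = p > 0
    return float(np.sum(p[mask] * np.log2(p[mask] / q[mask])))


def _as_prob_pair(p, q) -> tuple[np.ndarray, np.ndarray]:
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise ValueError("probability vectors must have equal length")
    return p / p.sum(), q / q.sum()


def _curve_pair(
    model_a: RankModel | FitResult, model_b: RankModel | FitResult, support: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(model_a, FitResult):
        model_a = model_a.params
    if isinstance(model_b, FitResult):
        model_b = model_b.params
    support = np.asarray(support, dtype=float)
    return model_a.predict(support), model_b.predict(support)


def curve_ks_distance(model_a, model_b, support: np.ndarray) -> float:
    """KS distance between two fitted curves renormalized on ``support``."""
    pa, pb = _curve_pair(model_a, model_b, support)
    return ks_distance(pa, pb)


def curve_js_divergence(model_a, model_b, support: np.ndarray) -> float:
    """Base-2 JS divergence between two fitted curves renormalized on ``support``."""
    pa, pb = _curve_pair(model_a, model_b, support)
    return js_divergence(pa, pb)


@dataclass(frozen=True)
class ComparisonReport:
    """Fits and divergences for one genome versus its null controls.

    ``fits[variant][model]`` holds the FitResult for variant in
    {"real", "shuffled", "markov"}; ``divergences[variant][model]`` the
    DivergenceResult of that variant's curve against the real one.
    """

    k: int
    fits: dict[str, dict[str, FitResult]]
    divergences: dict[str, dict[str, DivergenceResult]]


def compare_real_vs_null(
    genome: Genome,
    k: int,
    seed: int,
    markov_order: int = 1,
    include_markov: bool = True,
) -> ComparisonReport:
    """Fit ZM and TPL to a genome, its shuffle and a Markov control.

    Divergences are computed between predicted curves on the common rank
    support 1..min(m_real, m_null), each curve renormalized there. The
    Markov control matches the real genome's length and short-range
    composition at the stated order.
    """
    variants = {"real": genome, "shuffled": shuffle_genome(genome, seed)}
    if include_markov:
        variants["markov"] = markov_genome(
            genome, order=markov_order, length=genome.total_length, seed=seed + 1
        )
    fits: dict[str, dict[str, FitResult]] = {}
    supports: dict[str, int] = {}
    for name, g in variants.items():
        table = to_rank_frequency(count_canonical_kmers(g, k))
        supports[name] = table.m
        fits[name] = {
            "zipf_mandelbrot": fit_zipf_mandelbrot(table),
            "truncated_power_law": fit_truncated_power_law(table),
        }
    divergences: dict[str, dict[str, DivergenceResult]] = {}
    for name in variants:
        if name == "real":
            continue
        m = min(supports["real"], supports[name])
        support = np.arange(1, m + 1)
        divergences[name] = {}
        for model_name in ("zipf_mandelbrot", "truncated_power_law"):
            ks = curve_ks_distance(
                fits["real"][model_name], fits[name][model_name], support
            )
            js = curve_js_divergence(
                fits["real"][model_name], fits[name][model_name], support
            )
            divergences[name][model_name] = DivergenceResult(
                ks=ks, js=js, support_size=m
            )
    return ComparisonReport(k=k, fits=fits, divergences=divergences)
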