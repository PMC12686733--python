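"""Synthetic fixtures with known statistical structure.

Every pipeline stage is testable without downloads: rank-frequency tables
drawn exactly from (or multinomially sampled around) a chosen heavy-tailed
model, token streams with controllable vocabulary-growth regimes, and DNA
genomes mixing an order-0 background of prescribed GC content with tandem
repeats that inject heavy-tailed spectra. All generators are
seed-deterministic and emit the package's standard types.

Heaps-type fixtures are token streams rather than DNA so the true growth
regime is controllable independently of k-mer overlap effects; DNA-level
growth behaviour is exercised through :func:`kmerlex.nulls.markov_genome`
and :func:`synth_repeat_mix_genome`.
"""

from __future__ import annotations

import numpy as np

from .io import Genome, SequenceRecord
from .models import RankModel
from .spectrum import RankFrequencyTable

__all__ = [
    "synth_rank_table",
    "synth_token_stream",
    "synth_repeat_mix_genome",
    "synth_hierarchical_repeat_genome",
]


def exact_frequencies(model: RankModel, m: int) -> np.ndarray:
    """Model frequencies on ranks 1..m, renormalized to sum to 1."""
    ranks = np.arange(1, m + 1, dtype=float)
    f = model.predict(ranks)
    return f / f.sum()


def synth_rank_table(
    model: RankModel,
    m: int,
    n_draws: int | None = None,
    seed: int = 0,
) -> RankFrequencyTable:
    """Rank-frequency table drawn from a heavy-tailed model.

    Without ``n_draws`` the table holds the exact normalized model
    frequencies over ranks 1..m. With ``n_draws`` those frequencies are
    replaced by a multinomial sample of that many tokens; zero-count ranks
    are dropped and the table re-ranked, mimicking finite-genome sampling.
    """
    if m < 4:
        raise ValueError("need at least 4 ranks")
    p = exact_frequencies(model, m)
    if n_draws is None:
        # normalized frequencies double as counts; the table renormalizes
        return RankFrequencyTable(counts=p)
    rng = np.random.default_rng(seed)
    counts = rng.multinomial(n_draws, p)
    counts = counts[counts > 0]
    counts = np.sort(counts)[::-1].astype(float)
    return RankFrequencyTable(counts=counts)


def synth_token_stream(
    vocabulary_size: int,
    token_model: RankModel,
    n_tokens: int,
    seed: int = 0,
) -> np.ndarray:
    """i.i.d. token stream over a finite vocabulary with model probabilities.

    The classic generative route to Heaps-type growth: with the vocabulary
    much larger than the stream nearly every token is new (beta -> 1), with
    a tiny vocabulary the stream saturates (beta -> 0), and intermediate
    regimes give sublinear growth.
    """
    if vocabulary_size < 2:
        raise ValueError("vocabulary must have at least 2 token types")
    p = exact_frequencies(token_model, vocabulary_size)
    rng = np.random.default_rng(seed)
    return rng.choice(vocabulary_size, size=n_tokens, p=p)


def synth_repeat_mix_genome(
    unit: str,
    copies: int,
    background_length: int,
    gc: float = 0.5,
    seed: int = 0,
    identifier: str = "repeat_mix",
) -> Genome:
    """Order-0 background with a tandem-repeat block spliced in.

    ``copies`` tandem copies of ``unit`` are inserted at a random position
    of an i.i.d. background with the stated GC fraction — a minimal stand-in
    for the repetitive regions that drive heavy-tailed k-mer spectra.
    ``copies=0`` yields pure background.
    """
    if not unit:
        raise ValueError("repeat unit must be non-empty")
    if copies < 0 or background_length < 1:
        raise ValueError("copies must be >= 0 and background_length >= 1")
    if not 0.0 <= gc <= 1.0:
        raise ValueError("gc must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    draws = rng.choice(4, size=background_length, p=p)
    background = np.frombuffer(b"ACGT", dtype=np.uint8)[draws].tobytes().decode("ascii")
    pos = int(rng.integers(0, background_length + 1))
    seq = background[:pos] + unit.upper() * copies + background[pos:]
    return Genome(records=(SequenceRecord(identifier, seq),))


def synth_hierarchical_repeat_genome(
    n_families: int = 800,
    unit_length: int = 10,
    copy_decay: float = 0.8,
    repeat_total: int = 15_000,
    background_length: int = 30_000,
    gc: float = 0.3,
    seed: int = 0,
    identifier: str = "hier_repeat",
) -> Genome:
    """Genome with many repeat families whose copy numbers follow a power law.

    Family j (1-based) receives a share proportional to j**(-copy_decay) of
    ``repeat_total`` bases (at least one copy each); each family is a random
    tandem unit of ``unit_length`` bases drawn at the stated GC, and the
    tandem blocks are spliced at random positions into an order-0 background
    of the same composition. Unlike a single tandem repeat, the power-law
    copy spectrum across hundreds of short families produces a smoothly
    decaying, heavy-tailed k-mer spectrum — the desk-scale analogue of the
    multi-scale repeat hierarchies of real genomes. Deterministic per seed.
    """
    if n_families < 1 or unit_length < 1:
        raise ValueError("need n_families >= 1 and unit_length >= 1")
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    ascii_bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    weights = np.arange(1, n_families + 1, dtype=float) ** -copy_decay
    copies = np.maximum(
        1, np.round(weights / weights.sum() * repeat_total / unit_length)
    ).astype(int)
    pieces = [
        ascii_bases[rng.choice(4, size=unit_length, p=p)].tobytes().decode("ascii") * c
        for c in copies
    ]
    background = (
        ascii_bases[rng.choice(4, size=background_length, p=p)]
        .tobytes()
        .decode("ascii")
    )
    cuts = np.sort(rng.integers(0, background_length + 1, size=len(pieces)))
    order = rng.permutation(len(pieces))
    out: list[str] = []
    prev = 0
    for cut, idx in zip(cuts, order):
        out.append(background[prev:cut])
        out.append(pieces[idx])
        prev = cut
    out.append(background[prev:])
    return Genome(records=(SequenceRecord(identifier, "".join(out)),))
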