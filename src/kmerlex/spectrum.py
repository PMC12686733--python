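"""Canonical k-mer spectra, rank-frequency tables, Lorenz curves and Gini.

A k-mer and its reverse complement are the same word read off opposite
strands; counting the lexicographically smaller of the two (the *canonical*
form) collapses that strand redundancy. Counting slides a width-k window at
step 1 over each record independently; any window containing a non-ACGT
character (N or another ambiguity code) is skipped.

Internally k-mers are packed into 2-bit-per-base integer codes (A=0, C=1,
G=2, T=3), so lexicographic order on strings equals numeric order on codes
and whole genomes are processed as numpy arrays. This keeps k <= 31 in an
int64; the package targets k <= 15.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import Genome, SequenceRecord

__all__ = [
    "KmerSpectrum",
    "RankFrequencyTable",
    "LorenzCurve",
    "canonicalize",
    "reverse_complement",
    "count_canonical_kmers",
    "canonical_token_stream",
    "expected_canonical_count",
    "to_rank_frequency",
    "lorenz_curve",
    "gini",
]

_BASES = "ACGT"
_CODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def reverse_complement(seq: str) -> str:
    """Reverse complement of an A/C/G/T string."""
    return seq.translate(_COMPLEMENT)[::-1]


def canonicalize(kmer: str) -> str:
    """Return min(kmer, reverse_complement(kmer)) lexicographically.

    Idempotent; palindromic k-mers (their own reverse complement) map to
    themselves. The k-mer must contain only A/C/G/T.
    """
    if any(c not in _BASES for c in kmer):
        raise ValueError(f"cannot canonicalize ambiguous k-mer {kmer!r}")
    rc = reverse_complement(kmer)
    return kmer if kmer <= rc else rc


def expected_canonical_count(k: int) -> int:
    """Number of distinct canonical k-mers over the DNA alphabet.

    Even k: (4^k + 4^(k/2)) / 2 — the 4^(k/2) reverse-complement palindromes
    are their own canonical form. Odd k: 4^k / 2 exactly, because an
    odd-length word can never equal its reverse complement (its middle base
    would have to be self-complementary).
    """
    if k <= 0:
        raise ValueError("k must be a positive integer")
    if k % 2 == 0:
        return (4**k + 4 ** (k // 2)) // 2
    return 4**k // 2


def _encode_record(seq: str) -> np.ndarray:
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _record_kmer_codes(seq: str, k: int) -> np.ndarray:
    """Packed codes of all clean width-k windows of one record, in order."""
    n = len(seq)
    if n < k:
        return np.empty(0, dtype=np.int64)
    vals = _encode_record(seq)
    invalid = vals < 0
    codes = np.zeros(n - k + 1, dtype=np.int64)
    safe = np.where(invalid, 0, vals).astype(np.int64)
    for i in range(k):
        codes = (codes << 2) | safe[i : n - k + 1 + i]
    # window is clean iff no invalid base among its k positions
    bad = np.zeros(n + 1, dtype=np.int64)
    np.cumsum(invalid, out=bad[1:])
    clean = (bad[k:] - bad[:-k]) == 0
    return codes[clean]


def _revcomp_codes(codes: np.ndarray, k: int) -> np.ndarray:
    rc = np.zeros_like(codes)
    fwd = codes.copy()
    for _ in range(k):
        rc = (rc << 2) | (3 - (fwd & 3))
        fwd >>= 2
    return rc


def _canonical_codes(codes: np.ndarray, k: int) -> np.ndarray:
    return np.minimum(codes, _revcomp_codes(codes, k))


def _decode(code: int, k: int) -> str:
    out = []
    for _ in range(k):
        out.append(_BASES[code & 3])
        code >>= 2
    return "".join(reversed(out))


def canonical_token_stream(genome: Genome | str, k: int) -> np.ndarray:
    """Canonical k-mer codes in genome order, one per clean window.

    Records are streamed in file order; windows never span record
    boundaries. This is the token stream underlying both the spectrum and
    the vocabulary-growth curve.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if isinstance(genome, str):
        genome = Genome(records=(SequenceRecord("seq", genome),))
    parts = [_record_kmer_codes(r.sequence, k) for r in genome]
    if not parts:
        return np.empty(0, dtype=np.int64)
    codes = np.concatenate(parts)
    return _canonical_codes(codes, k)


@dataclass(frozen=True)
class KmerSpectrum:
    """Canonical k-mer -> count map for one genome at one word length."""

    k: int
    counts: dict[str, int]

    @property
    def total_tokens(self) -> int:
        return sum(self.counts.values())

    @property
    def distinct(self) -> int:
        return len(self.counts)

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if len(self.counts) > expected_canonical_count(self.k):
            raise ValueError("more distinct k-mers than canonically possible")


def count_canonical_kmers(genome: Genome | str, k: int) -> KmerSpectrum:
    """Count canonical k-mers across all records of ``genome``.

    Raises ``ValueError`` if no record yields a single clean window.
    """
    tokens = canonical_token_stream(genome, k)
    if tokens.size == 0:
        raise ValueError(
            f"no clean width-{k} windows in genome (k larger than every "
            "record, or all windows ambiguous)"
        )
    codes, counts = np.unique(tokens, return_counts=True)
    mapping = {_decode(int(c), k): int(n) for c, n in zip(codes, counts)}
    return KmerSpectrum(k=k, counts=mapping)


@dataclass(frozen=True)
class RankFrequencyTable:
    """Counts sorted descending, normalized to frequencies summing to 1.

    Ties in count are broken lexicographically by k-mer (when k-mers are
    known) so rank assignment is deterministic.
    """

    counts: np.ndarray
    k: int | None = None
    kmers: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=float)
        object.__setattr__(self, "counts", counts)
        if counts.size == 0:
            raise ValueError("rank-frequency table must be non-empty")
        if np.any(counts <= 0):
            raise ValueError("all counts must be positive")
        if np.any(np.diff(counts) > 0):
            raise ValueError("counts must be non-increasing")

    @property
    def m(self) -> int:
        return int(self.counts.size)

    @property
    def ranks(self) -> np.ndarray:
        return np.arange(1, self.m + 1)

    @property
    def frequencies(self) -> np.ndarray:
        return self.counts / self.counts.sum()


def to_rank_frequency(spectrum: KmerSpectrum) -> RankFrequencyTable:
    """Build the rank-frequency table of a spectrum.

    Descending count order; count ties broken by lexicographic k-mer order.
    """
    if not spectrum.counts:
        raise ValueError("cannot rank an empty spectrum")
    items = sorted(spectrum.counts.items(), key=lambda kv: (-kv[1], kv[0]))
    kmers = tuple(kmer for kmer, _ in items)
    counts = np.array([c for _, c in items], dtype=float)
    return RankFrequencyTable(counts=counts, k=spectrum.k, kmers=kmers)


@dataclass(frozen=True)
class LorenzCurve:
    """Cumulative-share curve of frequencies sorted ascending.

    ``x`` is the cumulative population share i/m, ``y`` the cumulative
    frequency share; both run from (0,0) to (1,1) and y <= x throughout.
    """

    x: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        x = np.asarray(self.x, dtype=float)
        y = np.asarray(self.y, dtype=float)
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)
        if x[0] != 0.0 or y[0] != 0.0 or x[-1] != 1.0 or abs(y[-1] - 1.0) > 1e-9:
            raise ValueError("Lorenz curve must run from (0,0) to (1,1)")


def lorenz_curve(table: RankFrequencyTable) -> LorenzCurve:
    """Lorenz curve of k-mer usage: shares cumulated over ascending counts."""
    freqs = np.sort(table.frequencies)  # ascending
    y = np.concatenate(([0.0], np.cumsum(freqs)))
    y[-1] = 1.0  # exact endpoint despite rounding
    x = np.arange(table.m + 1) / table.m
    return LorenzCurve(x=x, y=y)


def gini(curve: LorenzCurve | RankFrequencyTable) -> float:
    """Gini coefficient: 1 - 2 * (trapezoid area under the Lorenz curve).

    0 for perfectly equal usage; approaches 1 - 1/m when a single k-mer
    carries essentially all tokens among m distinct ones.
    """
    if isinstance(curve, RankFrequencyTable):
        curve = lorenz_curve(curve)
    area = float(np.trapezoid(curve.y, curve.x))
    return 1.0 - 2.0 * area
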