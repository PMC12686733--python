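"""Reading and writing genome sequences.

FASTA ingestion (plain or gzip-compressed, detected by content) into a
:class:`Genome` of uppercase sequence records, plus GC-content computation
over unambiguous bases. Parsing is delegated to :mod:`Bio.SeqIO`.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "SequenceRecord",
    "Genome",
    "FastaFormatError",
    "read_fasta",
    "write_fasta",
    "compute_gc",
]

_UNAMBIGUOUS = frozenset("ACGT")


class FastaFormatError(ValueError):
    """Raised when a file cannot be parsed as FASTA."""


@dataclass(frozen=True)
class SequenceRecord:
    """One named sequence, stored uppercase.

    ``identifier`` is the header token up to the first whitespace;
    ``description`` retains the full header line.
    """

    identifier: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.identifier:
            raise ValueError("sequence record identifier must be non-empty")
        if self.sequence != self.sequence.upper():
            object.__setattr__(self, "sequence", self.sequence.upper())

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class Genome:
    """An ordered collection of sequence records (chromosomes/contigs/plasmids).

    All records in a file are kept, including secondary records such as
    plasmids.
    """

    records: tuple[SequenceRecord, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        object.__setattr__(self, "records", tuple(self.records))

    @property
    def total_length(self) -> int:
        return sum(len(r) for r in self.records)

    @property
    def gc_content(self) -> float:
        return compute_gc(self)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)


def _is_gzip(path: Path) -> bool:
    with open(path, "rb") as fh:
        return fh.read(2) == b"\x1f\x8b"


def read_fasta(path: str | Path) -> Genome:
    """Read a FASTA file (optionally gzip-compressed) into a :class:`Genome`.

    Multi-line sequences are concatenated and uppercased; record order is
    preserved. Gzip is detected by magic bytes as well as the ``.gz`` suffix.

    Raises
    ------
    FileNotFoundError
        If ``path`` does not exist.
    FastaFormatError
        If the file is empty or not valid FASTA.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such FASTA file: {path}")
    opener = gzip.open if (_is_gzip(path) or path.suffix == ".gz") else open
    records: list[SequenceRecord] = []
    with opener(path, "rt") as handle:
        try:
            for rec in SeqIO.parse(handle, "fasta"):
                if not rec.id:
                    raise FastaFormatError(f"{path}: FASTA entry with empty header")
                records.append(
                    SequenceRecord(
                        identifier=rec.id,
                        sequence=str(rec.seq).upper(),
                        description=rec.description,
                    )
                )
        except ValueError as exc:  # SeqIO signals malformed FASTA this way
            raise FastaFormatError(f"{path}: {exc}") from exc
    if not records:
        raise FastaFormatError(f"{path}: no FASTA records found")
    return Genome(records=tuple(records))


def write_fasta(genome: Genome, path: str | Path, line_width: int = 60) -> Path:
    """Write ``genome`` as FASTA with fixed line width (default 60).

    Round-trips through :func:`read_fasta`. A ``.gz`` suffix triggers gzip
    compression.
    """
    if len(genome) == 0:
        raise ValueError("refusing to write an empty genome")
    path = Path(path)
    seq_records = [
        SeqRecord(Seq(r.sequence), id=r.identifier, description=_extra_description(r))
        for r in genome
    ]
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "wt") as handle:
        writer = SeqIO.FastaIO.FastaWriter(handle, wrap=line_width)
        writer.write_file(seq_records)
    return path


def _extra_description(record: SequenceRecord) -> str:
    # biopython prepends the id to the description on output; strip it here
    desc = record.description
    if desc.startswith(record.identifier):
        desc = desc[len(record.identifier) :].strip()
    return desc


def compute_gc(genome: Genome | SequenceRecord | str) -> float:
    """GC fraction over unambiguous bases: (G + C) / (A + C + G + T).

    Ambiguity codes (N and friends) are excluded from both numerator and
    denominator. Raises ``ValueError`` if no unambiguous base is present.
    """
    if isinstance(genome, str):
        seqs = [genome.upper()]
    elif isinstance(genome, SequenceRecord):
        seqs = [genome.sequence]
    else:
        seqs = [r.sequence for r in genome]
    gc = acgt = 0
    for seq in seqs:
        gc += seq.count("G") + seq.count("C")
        acgt += sum(seq.count(b) for b in "ACGT")
    if acgt == 0:
        raise ValueError("GC content undefined: no unambiguous (A/C/G/T) bases")
    return gc / acgt
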