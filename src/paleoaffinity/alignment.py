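"""Protein multiple-sequence alignments and gap-column filtering."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .substitution import AMINO_ACIDS, MISSING_CHARS

_VALID_CHARS = set(AMINO_ACIDS) | {"-", "X"}


@dataclass
class Alignment:
    """An aligned set of amino-acid sequences.

    ``records`` is an ordered list of (id, sequence) pairs; every sequence
    has the same length over the 20 amino acids plus gap '-' (and 'X' for
    unknown residues, treated as missing data downstream).
    """

    records: list[tuple[str, str]]

    def __post_init__(self):
        if not self.records:
            raise ValueError("alignment must contain at least one sequence")
        ids = [rid for rid, _ in self.records]
        if len(set(ids)) != len(ids):
            raise ValueError("sequence ids must be unique")
        lengths = {len(seq) for _, seq in self.records}
        if len(lengths) != 1:
            raise ValueError(f"sequences have unequal lengths: {sorted(lengths)}")
        for rid, seq in self.records:
            bad = set(seq.upper()) - _VALID_CHARS
            if bad:
                raise ValueError(f"invalid characters {sorted(bad)} in sequence {rid!r}")
        self.records = [(rid, seq.upper()) for rid, seq in self.records]

    @property
    def n_sequences(self) -> int:
        return len(self.records)

    @property
    def n_columns(self) -> int:
        return len(self.records[0][1])

    @property
    def ids(self) -> list[str]:
        return [rid for rid, _ in self.records]

    def sequence(self, rid: str) -> str:
        for r, seq in self.records:
            if r == rid:
                return seq
        raise KeyError(f"no sequence with id {rid!r}")

    def column(self, j: int) -> list[str]:
        return [seq[j] for _, seq in self.records]

    def gap_fraction(self, j: int) -> float:
        col = self.column(j)
        return sum(c == "-" for c in col) / len(col)

    @classmethod
    def from_fasta(cls, path: str | Path) -> "Alignment":
        records = [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]
        return cls(records)

    def to_fasta(self, path: str | Path) -> None:
        recs = [SeqRecord(Seq(seq), id=rid, description="") for rid, seq in self.records]
        SeqIO.write(recs, str(path), "fasta")


@dataclass
class GapFilterReport:
    """Bookkeeping for a gap-column filtering pass."""

    gap_tolerance: float
    removed_columns: list[int]          # 0-based indices in the input
    column_map: dict[int, int]          # old index -> new index for kept columns

    @property
    def n_removed(self) -> int:
        return len(self.removed_columns)


def filter_gap_columns(
    alignment: Alignment, gap_tolerance: float = 0.95
) -> tuple[Alignment, GapFilterReport]:
    """Drop alignment columns whose gap fraction exceeds ``gap_tolerance``.

    Parameters
    ----------
    alignment : Alignment
    gap_tolerance : float in (0, 1]
        Columns with gap fraction strictly greater than this are removed
        (default 0.95: a column survives unless >95% of sequences are
        gapped there).

    Returns
    -------
    (Alignment, GapFilterReport)
        The filtered alignment and a report with removed columns and the
        old-to-new column index map.
    """
    if not 0 < gap_tolerance <= 1:
        raise ValueError(f"gap_tolerance must be in (0, 1], got {gap_tolerance}")
    keep, removed = [], []
    for j in range(alignment.n_columns):
        (removed if alignment.gap_fraction(j) > gap_tolerance else keep).append(j)
    if not keep:
        raise ValueError("gap filtering removed every column")
    records = [(rid, "".join(seq[j] for j in keep)) for rid, seq in alignment.records]
    report = GapFilterReport(
        gap_tolerance=gap_tolerance,
        removed_columns=removed,
        column_map={old: new for new, old in enumerate(keep)},
    )
    return Alignment(records), report


def is_missing(char: str) -> bool:
    """True for characters treated as missing data ('-', 'X', '?', ...)."""
    return char.upper() in MISSING_CHARS
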