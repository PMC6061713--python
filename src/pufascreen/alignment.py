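"""Paralog/ortholog alignment container and reference-coordinate mapping.

Sequence records carry a ``<species>|<paralog>`` identifier so that alignment
columns can be grouped by paralog (e.g. the PUFA-sensitive TRPL/TRPgamma
group versus the insensitive TRP group).  One record is designated the
reference; its non-gap columns define the 1-based residue numbering used
throughout the screen (TRPL numbering in the default fixtures).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

GAP = "-"
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_VALID_CHARS = frozenset(AMINO_ACIDS + AMINO_ACIDS.lower() + GAP + "Xx")

_FORMATS = {"fasta": "fasta", "clustal": "clustal"}


@dataclass(frozen=True)
class AlignedRecord:
    """One aligned sequence tagged with its species and paralog labels."""

    species: str
    paralog: str
    sequence: str

    @property
    def id(self) -> str:
        return f"{self.species}|{self.paralog}"


@dataclass
class ParalogAlignment:
    """Equal-length aligned sequences partitioned by paralog.

    Attributes
    ----------
    records
        Aligned records; all sequences must have equal length.
    reference_id
        ``<species>|<paralog>`` of the record defining residue numbering.
    """

    records: list[AlignedRecord]
    reference_id: str

    def __post_init__(self) -> None:
        if not self.records:
            raise ValueError("alignment has no records")
        length = len(self.records[0].sequence)
        for rec in self.records:
            if len(rec.sequence) != length:
                raise ValueError(
                    f"ragged alignment: record {rec.id!r} has length "
                    f"{len(rec.sequence)}, expected {length}"
                )
            bad = set(rec.sequence) - _VALID_CHARS
            if bad:
                raise ValueError(
                    f"record {rec.id!r} contains non amino-acid characters: "
                    f"{sorted(bad)}"
                )
        if self.reference_id not in {r.id for r in self.records}:
            raise ValueError(f"reference record {self.reference_id!r} not in alignment")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def n_columns(self) -> int:
        return len(self.records[0].sequence)

    @property
    def reference(self) -> AlignedRecord:
        for rec in self.records:
            if rec.id == self.reference_id:
                return rec
        raise AssertionError("unreachable")  # guarded in __post_init__

    def paralogs(self) -> list[str]:
        seen: dict[str, None] = {}
        for rec in self.records:
            seen.setdefault(rec.paralog, None)
        return list(seen)

    def group(self, paralogs: str | Sequence[str]) -> list[AlignedRecord]:
        if isinstance(paralogs, str):
            paralogs = [paralogs]
        wanted = set(paralogs)
        found = [r for r in self.records if r.paralog in wanted]
        missing = wanted - {r.paralog for r in found}
        if missing:
            raise ValueError(f"paralog labels absent from alignment: {sorted(missing)}")
        return found

    def to_matrix(self, records: Sequence[AlignedRecord] | None = None) -> np.ndarray:
        """Upper-cased character matrix (records x columns)."""
        recs = self.records if records is None else records
        return np.array([list(r.sequence.upper()) for r in recs])


def _parse_id(identifier: str) -> tuple[str, str]:
    if "|" not in identifier:
        raise ValueError(
            f"record id {identifier!r} does not follow '<species>|<paralog>'"
        )
    species, paralog = identifier.split("|", 1)
    if not species or not paralog:
        raise ValueError(f"record id {identifier!r} has an empty species or paralog")
    return species, paralog


def read_alignment(
    path: str | Path, reference_id: str, format: str = "fasta"
) -> ParalogAlignment:
    """Parse an aligned FASTA or Clustal file into a :class:`ParalogAlignment`.

    Raises ``ValueError`` naming the offending record for ragged alignments,
    unknown characters, malformed IDs or a missing reference.
    """
    if format not in _FORMATS:
        raise ValueError(f"unsupported alignment format {format!r}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records = [
        AlignedRecord(*_parse_id(rec.id), str(rec.seq))
        for rec in SeqIO.parse(str(path), _FORMATS[format])
    ]
    return ParalogAlignment(records=records, reference_id=reference_id)


def write_alignment(
    alignment: ParalogAlignment, path: str | Path, format: str = "fasta"
) -> None:
    """Write the alignment back out (byte-exact round trip for FASTA)."""
    if format not in _FORMATS:
        raise ValueError(f"unsupported alignment format {format!r}")
    seq_records = [
        SeqRecord(Seq(rec.sequence), id=rec.id, description="")
        for rec in alignment.records
    ]
    SeqIO.write(seq_records, str(path), _FORMATS[format])


@dataclass
class ReferenceMap:
    """Bidirectional map between alignment columns and reference positions."""

    column_to_position: dict[int, int]
    position_to_column: dict[int, int]

    def position(self, column: int) -> int | None:
        return self.column_to_position.get(column)

    def column(self, position: int) -> int:
        try:
            return self.position_to_column[position]
        except KeyError:
            raise KeyError(f"reference position {position} not present in alignment")


def map_to_reference(alignment: ParalogAlignment) -> ReferenceMap:
    """Number each non-gap reference column with the next 1-based residue position.

    Gap columns in the reference map to no position.  An all-gap reference is
    rejected.
    """
    col_to_pos: dict[int, int] = {}
    pos = 0
    for col, char in enumerate(alignment.reference.sequence):
        if char != GAP:
            pos += 1
            col_to_pos[col] = pos
    if pos == 0:
        raise ValueError(
            f"reference record {alignment.reference_id!r} contains only gaps"
        )
    return ReferenceMap(
        column_to_position=col_to_pos,
        position_to_column={p: c for c, p in col_to_pos.items()},
    )
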