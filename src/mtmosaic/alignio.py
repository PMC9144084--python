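"""Aligned-sequence containers, FASTA/GenBank ingest, and region surgery.

Every downstream statistic operates on a :class:`MultipleAlignment`, a thin
wrapper around a 2-D byte matrix of aligned residues.  Coordinates are
1-based inclusive *alignment columns* throughout the package, matching how
breakpoints are conventionally printed in mitochondrial recombination
reports; :func:`ungapped_coordinate` provides a read-only conversion into a
single record's gap-free coordinate system.

Alphabet policy: residues are uppercased on ingest; ``U`` is treated as
``T``; IUPAC ambiguity codes other than ``N`` are mapped to ``N`` (missing
data); ``-`` and ``.`` are gaps (``.`` normalised to ``-``).  Anything else
is rejected with the offending character and position.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO

__all__ = [
    "AlignmentError",
    "SequenceRecord",
    "MultipleAlignment",
    "RegionSpec",
    "read_fasta",
    "write_fasta",
    "read_genbank",
    "extract_region",
    "delete_regions",
    "ungapped_length",
    "ungapped_coordinate",
    "read_regions",
    "write_regions",
]

GAP = ord("-")
MISSING = ord("N")
_BASES = frozenset(b"ACGT")
_AMBIGUITY = set(b"RYSWKMBDHV")


class AlignmentError(ValueError):
    """Raised for malformed alignments, regions, or residue strings."""


def _normalize_residues(raw: str, record_id: str) -> str:
    out = []
    for pos, ch in enumerate(raw.upper(), start=1):
        c = ord(ch)
        if c in _BASES or c == GAP or c == MISSING:
            out.append(ch)
        elif ch == "U":
            out.append("T")
        elif ch == ".":
            out.append("-")
        elif c in _AMBIGUITY:
            out.append("N")
        else:
            raise AlignmentError(
                f"illegal character {ch!r} at position {pos} in record {record_id!r}"
            )
    return "".join(out)


@dataclass(frozen=True)
class SequenceRecord:
    """One sequence: accession-like id, free-text description, residues."""

    id: str
    residues: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise AlignmentError("record id must be non-empty")
        object.__setattr__(
            self, "residues", _normalize_residues(self.residues, self.id)
        )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class RegionSpec:
    """A 1-based inclusive column interval, optionally labelled."""

    start: int
    end: int
    label: str = ""

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise AlignmentError(
                f"invalid region ({self.start}, {self.end}): need 1 <= start <= end"
            )

    @property
    def span(self) -> int:
        return self.end - self.start + 1

    def check_within(self, length: int) -> None:
        if self.end > length:
            raise AlignmentError(
                f"region ({self.start}, {self.end}) exceeds alignment length {length}"
            )


class MultipleAlignment:
    """An ordered set of equal-length gapped sequences.

    Ingest order is preserved and used for every deterministic tie-break
    downstream.  The residue matrix is exposed as ``matrix`` (uint8 ASCII
    codes, shape ``(n_records, length)``).
    """

    def __init__(self, records: Sequence[SequenceRecord]):
        records = list(records)
        if len(records) < 2:
            raise AlignmentError("an alignment needs at least 2 records")
        length = len(records[0])
        for rec in records[1:]:
            if len(rec) != length:
                raise AlignmentError(
                    f"record {rec.id!r} has length {len(rec)}, expected {length}"
                )
        ids = [r.id for r in records]
        if len(set(ids)) != len(ids):
            dup = next(i for i in ids if ids.count(i) > 1)
            raise AlignmentError(f"duplicate record id {dup!r}")
        self.records: list[SequenceRecord] = records
        self.length: int = length
        self.ids: list[str] = ids
        self._index = {rid: k for k, rid in enumerate(ids)}
        self.matrix: np.ndarray = np.frombuffer(
            "".join(r.residues for r in records).encode("ascii"), dtype=np.uint8
        ).reshape(len(records), length)
        self.matrix.setflags(write=False)
        self._base_mask: np.ndarray | None = None

    def __len__(self) -> int:
        return len(self.records)

    def __getitem__(self, rid: str) -> SequenceRecord:
        return self.records[self._index[rid]]

    def row(self, rid: str) -> np.ndarray:
        """Byte row of one record (uint8, read-only)."""
        return self.matrix[self._index[rid]]

    def index_of(self, rid: str) -> int:
        return self._index[rid]

    def subset(self, ids: Iterable[str]) -> "MultipleAlignment":
        """Sub-alignment of the given records, in the order requested."""
        return MultipleAlignment([self[i] for i in ids])

    def base_mask(self) -> np.ndarray:
        """Boolean matrix: True where the residue is an unambiguous base."""
        if self._base_mask is None:
            m = self.matrix
            bm = (m == ord("A")) | (m == ord("C")) | (m == ord("G")) | (m == ord("T"))
            bm.setflags(write=False)
            self._base_mask = bm
        return self._base_mask


def read_fasta(path: str | Path) -> MultipleAlignment:
    """Read an aligned FASTA file into a :class:`MultipleAlignment`.

    Unequal record lengths raise :class:`AlignmentError` naming the
    offending record; illegal characters raise with character and position.
    """
    records = [
        SequenceRecord(id=rec.id, residues=str(rec.seq), description=rec.description)
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    if not records:
        raise AlignmentError(f"no FASTA records found in {path}")
    return MultipleAlignment(records)


def write_fasta(aln: MultipleAlignment, path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in aln.records:
            header = rec.id if not rec.description else f"{rec.id} {rec.description}"
            fh.write(f">{header}\n")
            for i in range(0, len(rec.residues), width):
                fh.write(rec.residues[i : i + width] + "\n")


def read_genbank(path: str | Path) -> list[SequenceRecord]:
    """Read GenBank flat-file records (id + sequence only; features ignored)."""
    out = [
        SequenceRecord(id=rec.id, residues=str(rec.seq), description=rec.description)
        for rec in SeqIO.parse(str(path), "genbank")
    ]
    if not out:
        raise AlignmentError(f"no GenBank records found in {path}")
    return out


def _column_selector(length: int, regions: Iterable[RegionSpec]) -> np.ndarray:
    """Boolean mask over 0-based columns covered by the union of regions."""
    mask = np.zeros(length, dtype=bool)
    for reg in regions:
        reg.check_within(length)
        mask[reg.start - 1 : reg.end] = True
    return mask


def extract_region(aln: MultipleAlignment, region: RegionSpec) -> MultipleAlignment:
    """Sub-alignment of columns ``start..end`` inclusive."""
    region.check_within(aln.length)
    s, e = region.start - 1, region.end
    return MultipleAlignment(
        [
            SequenceRecord(r.id, r.residues[s:e], r.description)
            for r in aln.records
        ]
    )


def delete_regions(
    aln: MultipleAlignment, regions: Sequence[RegionSpec]
) -> MultipleAlignment:
    """Remove the union of the region columns; remaining order preserved.

    Overlapping regions are permitted; the result length is the original
    length minus the size of the column union.
    """
    drop = _column_selector(aln.length, regions)
    keep = ~drop
    if keep.sum() == 0:
        raise AlignmentError("deleting these regions would leave an empty alignment")
    return MultipleAlignment(
        [
            SequenceRecord(r.id, "".join(np.array(list(r.residues))[keep]), r.description)
            for r in aln.records
        ]
    )


def ungapped_length(record: SequenceRecord, region: RegionSpec) -> int:
    """Number of non-gap residues of ``record`` inside ``region``."""
    region.check_within(len(record))
    seg = record.residues[region.start - 1 : region.end]
    return len(seg) - seg.count("-")


def ungapped_coordinate(record: SequenceRecord, column: int) -> int | None:
    """1-based position of alignment ``column`` in the record's gap-free
    sequence, or None if the record has a gap there.  Read-only convenience;
    all package-internal coordinates stay in alignment-column space."""
    if not (1 <= column <= len(record)):
        raise AlignmentError(f"column {column} outside 1..{len(record)}")
    if record.residues[column - 1] == "-":
        return None
    return column - record.residues.count("-", 0, column)


def read_regions(path: str | Path) -> list[RegionSpec]:
    """Read a 3-column tab-separated region file: label, start, end (1-based)."""
    out = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise AlignmentError(f"{path}:{ln}: expected 3 tab-separated fields")
            label, start, end = parts
            out.append(RegionSpec(int(start), int(end), label))
    return out


def write_regions(regions: Sequence[RegionSpec], path: str | Path) -> None:
    with open(path, "w") as fh:
        for reg in regions:
            fh.write(f"{reg.label}\t{reg.start}\t{reg.end}\n")
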