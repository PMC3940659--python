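"""Reading and writing of sequence and region-annotation files.

Protein sequences travel as multi-record FASTA; region annotations (amyloidogenic
regions, low-complexity regions, disorder segments) travel as TSV tables with
1-based inclusive coordinates, the convention used throughout the package.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"
AMBIGUOUS_AA = "XBZUO"
VALID_AA = set(STANDARD_AA) | set(AMBIGUOUS_AA)

REGION_KINDS = ("AR", "LCR", "DISORDER", "OVERLAP")

REGION_TABLE_COLUMNS = ["protein_id", "kind", "start", "end", "subsequence"]


class FastaParseError(ValueError):
    """Raised when a FASTA file is structurally malformed."""


class RegionValidationError(ValueError):
    """Raised when a region-table row fails validation against its protein."""


@dataclass(frozen=True)
class ProteinRecord:
    """An identified amino-acid sequence.

    ``sequence`` is upper-case over the 20 standard residues plus the
    ambiguity letters X, B, Z, U, O; ``description`` keeps any FASTA header
    text after the first whitespace.
    """

    id: str
    sequence: str
    source: str = ""
    description: str = ""

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        bad = set(seq) - VALID_AA
        if bad:
            raise ValueError(
                f"protein {self.id!r}: invalid characters {sorted(bad)}"
            )
        if set(seq) & set(AMBIGUOUS_AA):
            warnings.warn(
                f"protein {self.id!r} contains ambiguity letters", stacklevel=2
            )

    @property
    def length(self) -> int:
        return len(self.sequence)

    def slice(self, start: int, end: int) -> str:
        """Subsequence at 1-based inclusive coordinates [start, end]."""
        if not (1 <= start <= end <= self.length):
            raise ValueError(
                f"protein {self.id!r}: slice ({start},{end}) out of bounds "
                f"for length {self.length}"
            )
        return self.sequence[start - 1 : end]


@dataclass(frozen=True)
class RegionTableRow:
    """One validated annotation row: a typed interval on a named protein."""

    protein_id: str
    kind: str
    start: int
    end: int
    subsequence: str = ""

    def __post_init__(self) -> None:
        if self.kind not in REGION_KINDS:
            raise RegionValidationError(f"unknown region kind {self.kind!r}")
        if not (1 <= self.start <= self.end):
            raise RegionValidationError(
                f"{self.protein_id}: bad interval ({self.start},{self.end})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def read_fasta(path: str | Path, source: str = "") -> list[ProteinRecord]:
    """Read a multi-record FASTA file into :class:`ProteinRecord` objects.

    The header token before the first whitespace becomes the id; the rest is
    kept as ``description``.  An empty file yields an empty list with a
    warning.  A sequence line appearing before any header is a parse error
    naming the offending line.
    """
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            if not stripped.startswith(">"):
                raise FastaParseError(
                    f"{path}:{lineno}: sequence data before first FASTA header"
                )
            break
        else:
            warnings.warn(f"{path}: empty FASTA file", stacklevel=2)
            return []
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        desc = rec.description
        if desc.startswith(rec.id):
            desc = desc[len(rec.id) :].strip()
        records.append(
            ProteinRecord(
                id=rec.id,
                sequence=str(rec.seq).upper().replace("-", ""),
                source=source,
                description=desc,
            )
        )
    if not records:
        warnings.warn(f"{path}: empty FASTA file", stacklevel=2)
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    seq_records = [
        SeqRecord(Seq(r.sequence), id=r.id, description=r.description)
        for r in records
    ]
    SeqIO.write(seq_records, str(path), "fasta")


def _protein_index(proteins: Sequence[ProteinRecord]) -> dict[str, ProteinRecord]:
    return {p.id: p for p in proteins}


def read_region_table(
    path: str | Path, proteins: Sequence[ProteinRecord]
) -> list[RegionTableRow]:
    """Read a region TSV and validate every row against the protein set.

    Required columns: protein_id, kind, start, end; optional: subsequence.
    Missing subsequences are filled from the protein sequence; present ones
    must match it exactly.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"protein_id": str})
    required = {"protein_id", "kind", "start", "end"}
    missing = required - set(df.columns)
    if missing:
        raise RegionValidationError(f"{path}: missing columns {sorted(missing)}")
    index = _protein_index(proteins)
    rows: list[RegionTableRow] = []
    for i, rec in enumerate(df.itertuples(index=False)):
        pid = str(rec.protein_id)
        if pid not in index:
            raise RegionValidationError(f"{path} row {i}: unknown protein {pid!r}")
        protein = index[pid]
        start, end = int(rec.start), int(rec.end)
        if start > end:
            raise RegionValidationError(
                f"{path} row {i}: start {start} > end {end}"
            )
        if not (1 <= start and end <= protein.length):
            raise RegionValidationError(
                f"{path} row {i}: ({start},{end}) outside protein "
                f"{pid} of length {protein.length}"
            )
        sub = getattr(rec, "subsequence", "")
        sub = "" if (sub is None or (isinstance(sub, float))) else str(sub)
        expected = protein.slice(start, end)
        if sub:
            if sub.upper() != expected:
                raise RegionValidationError(
                    f"{path} row {i}: subsequence {sub!r} does not match "
                    f"protein {pid} at ({start},{end})"
                )
        else:
            sub = expected
        rows.append(
            RegionTableRow(
                protein_id=pid,
                kind=str(rec.kind).upper(),
                start=start,
                end=end,
                subsequence=sub,
            )
        )
    return rows


def write_region_table(rows: Iterable[RegionTableRow], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            {
                "protein_id": r.protein_id,
                "kind": r.kind,
                "start": r.start,
                "end": r.end,
                "subsequence": r.subsequence,
            }
            for r in rows
        ],
        columns=REGION_TABLE_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)
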