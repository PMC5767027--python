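"""Readers and writers for the external formats the toolkit touches.

No science lives here — only faithful parsing with validation: FASTA
(with optional assembler-header coverage extraction), samtools-depth-like
per-base depth tables, and 12-column tabular alignments (BLAST ``-outfmt 6``).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Iterable, Optional, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq

__all__ = [
    "Contig",
    "EndTag",
    "AlignmentRecord",
    "read_fasta",
    "write_fasta",
    "parse_assembler_coverage_header",
    "read_depth_table",
    "read_tabular_alignments",
    "write_tabular_alignments",
    "reverse_complement",
]

_VALID_DNA = re.compile(r"^[ACGTN]+$")

# SPAdes: NODE_3_length_1212_cov_7.51 ; MEGAHIT: "k141_5 flag=1 multi=12.0000 len=5021"
_SPADES_COV = re.compile(r"_cov_([0-9]+(?:\.[0-9]+)?)(?:_|$)")
_MEGAHIT_COV = re.compile(r"(?:^|\s)multi=([0-9]+(?:\.[0-9]+)?)(?:\s|$)")


def reverse_complement(sequence: str) -> str:
    """Reverse complement of an upper-case DNA string (N maps to N)."""
    return str(Seq(sequence).reverse_complement())


@dataclass
class Contig:
    """An assembled sequence with optional coverage information.

    ``header_coverage`` is the assembler-reported k-mer coverage scalar
    parsed from the FASTA header (SPAdes/MEGAHIT dialects); ``depth`` is a
    per-base read-depth vector of the same length as the sequence.
    """

    id: str
    sequence: str
    description: str = ""
    header_coverage: Optional[float] = None
    depth: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("contig id must be non-empty")
        self.sequence = self.sequence.upper()
        if not self.sequence:
            raise ValueError(f"contig {self.id!r}: empty sequence")
        if not _VALID_DNA.match(self.sequence):
            bad = sorted(set(self.sequence) - set("ACGTN"))
            raise ValueError(
                f"contig {self.id!r}: characters outside ACGTN: {bad}"
            )
        if self.header_coverage is not None and self.header_coverage < 0:
            raise ValueError(f"contig {self.id!r}: negative header coverage")
        if self.depth is not None:
            self.depth = np.asarray(self.depth, dtype=float)
            if self.depth.shape != (len(self.sequence),):
                raise ValueError(
                    f"contig {self.id!r}: depth length {self.depth.shape} "
                    f"!= sequence length {len(self.sequence)}"
                )
            if (self.depth < 0).any():
                raise ValueError(f"contig {self.id!r}: negative depth values")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class EndTag:
    """A single-pass Sanger read from one terminus of a known insert."""

    insert_id: str
    end_label: str  # "L" or "R"
    sequence: str

    def __post_init__(self) -> None:
        if self.end_label not in ("L", "R"):
            raise ValueError(
                f"end tag {self.insert_id!r}: end_label must be L or R, "
                f"got {self.end_label!r}"
            )
        object.__setattr__(self, "sequence", self.sequence.upper())
        if not _VALID_DNA.match(self.sequence):
            raise ValueError(f"end tag {self.insert_id!r}: invalid DNA")

    @property
    def tag_id(self) -> str:
        return f"{self.insert_id}__{self.end_label}"


@dataclass(frozen=True)
class AlignmentRecord:
    """One row of a 12-column tabular alignment (BLAST ``-outfmt 6``).

    Subject coordinates with ``s_start > s_end`` encode a minus-strand hit,
    as BLAST emits them.
    """

    query_id: str
    subject_id: str
    pct_identity: float
    aln_length: int
    mismatches: int
    gap_opens: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    evalue: float
    bitscore: float

    def __post_init__(self) -> None:
        if self.q_start > self.q_end:
            raise ValueError(
                f"alignment {self.query_id}->{self.subject_id}: q_start > q_end"
            )
        if not 0 <= self.pct_identity <= 100:
            raise ValueError("pct_identity outside [0, 100]")

    @property
    def minus_strand(self) -> bool:
        return self.s_start > self.s_end

    @property
    def subject_interval(self) -> tuple[int, int]:
        """Subject span as a 0-based half-open, strand-normalized interval."""
        lo, hi = sorted((self.s_start, self.s_end))
        return lo - 1, hi


def parse_assembler_coverage_header(
    header: str, dialect: str = "auto"
) -> Optional[float]:
    """Extract the coverage scalar an assembler embeds in a FASTA header.

    ``dialect`` is one of ``spades`` (``..._cov_7.51``), ``megahit``
    (``multi=12.0000``) or ``auto`` (try SPAdes, then MEGAHIT). Returns
    ``None`` when the pattern does not match — absence is a value here,
    not an error.
    """
    if dialect not in ("spades", "megahit", "auto"):
        raise ValueError(f"unknown header dialect {dialect!r}")
    if dialect in ("spades", "auto"):
        m = _SPADES_COV.search(header)
        if m:
            return float(m.group(1))
    if dialect in ("megahit", "auto"):
        m = _MEGAHIT_COV.search(header)
        if m:
            return float(m.group(1))
    return None


def read_fasta(
    path: str | Path,
    id_parser: Optional[Callable[[str], Optional[float]]] = None,
) -> list[Contig]:
    """Read contigs from FASTA.

    Ids are the first whitespace-delimited token of the header; the rest is
    kept as description. Sequences are upper-cased; characters outside
    ACGTN are rejected. ``id_parser`` receives the full header line
    (without ``>``) and may return a coverage scalar to store as
    ``header_coverage`` — pass ``parse_assembler_coverage_header`` or a
    ``functools.partial`` of it to pick a dialect.
    """
    path = Path(path)
    contigs: list[Contig] = []
    seen: set[str] = set()
    for i, rec in enumerate(SeqIO.parse(str(path), "fasta")):
        if rec.id in seen:
            raise ValueError(f"{path}: duplicate FASTA id {rec.id!r}")
        seen.add(rec.id)
        seq = str(rec.seq)
        if not seq:
            raise ValueError(f"{path}: record {i} ({rec.id!r}) is empty")
        header = rec.description
        cov = id_parser(header) if id_parser is not None else None
        desc = header.split(None, 1)[1] if " " in header else ""
        contigs.append(
            Contig(id=rec.id, sequence=seq, description=desc, header_coverage=cov)
        )
    if not contigs:
        raise ValueError(f"{path}: no FASTA records found")
    return contigs


def write_fasta(contigs: Iterable[Contig], path: str | Path, width: int = 60) -> None:
    """Write contigs as FASTA, wrapping sequence lines at ``width`` columns."""
    path = Path(path)
    with open(path, "w") as fh:
        for c in contigs:
            header = f">{c.id} {c.description}".rstrip()
            fh.write(header + "\n")
            for i in range(0, len(c.sequence), width):
                fh.write(c.sequence[i : i + width] + "\n")


def read_depth_table(path: str | Path, contigs: Sequence[Contig]) -> list[Contig]:
    """Attach per-base depth vectors from a samtools-depth-like table.

    The table is 3-column TSV: contig id, 1-based position, depth.
    Positions absent from the table default to depth 0. Every contig id
    appearing in the table must exist in ``contigs``; positions must lie
    within the contig. Modifies the contigs in place and returns them.
    """
    path = Path(path)
    by_id = {c.id: c for c in contigs}
    depths = {c.id: np.zeros(len(c), dtype=float) for c in contigs}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ValueError(
                    f"{path}:{lineno}: expected 3 tab-separated columns, "
                    f"got {len(parts)}"
                )
            cid, pos_s, depth_s = parts
            if cid not in by_id:
                raise ValueError(f"{path}:{lineno}: unknown contig id {cid!r}")
            pos = int(pos_s)
            depth = float(depth_s)
            if not 1 <= pos <= len(by_id[cid]):
                raise ValueError(
                    f"{path}:{lineno}: position {pos} out of range for "
                    f"contig {cid!r} (length {len(by_id[cid])})"
                )
            if depth < 0:
                raise ValueError(f"{path}:{lineno}: negative depth")
            depths[cid][pos - 1] = depth
    for cid, vec in depths.items():
        by_id[cid].depth = vec
    return list(contigs)


def read_tabular_alignments(path: str | Path) -> list[AlignmentRecord]:
    """Parse a 12-column tabular alignment file (BLAST ``-outfmt 6``)."""
    path = Path(path)
    records: list[AlignmentRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 12:
                raise ValueError(
                    f"{path}:{lineno}: expected 12 columns, got {len(parts)}"
                )
            try:
                rec = AlignmentRecord(
                    query_id=parts[0],
                    subject_id=parts[1],
                    pct_identity=float(parts[2]),
                    aln_length=int(parts[3]),
                    mismatches=int(parts[4]),
                    gap_opens=int(parts[5]),
                    q_start=int(parts[6]),
                    q_end=int(parts[7]),
                    s_start=int(parts[8]),
                    s_end=int(parts[9]),
                    evalue=float(parts[10]),
                    bitscore=float(parts[11]),
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
            records.append(rec)
    return records


def write_tabular_alignments(
    records: Iterable[AlignmentRecord], path: str | Path
) -> None:
    """Write alignment records back out as 12-column TSV."""
    with open(path, "w") as fh:
        for r in records:
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        r.query_id, r.subject_id, f"{r.pct_identity:.2f}",
                        r.aln_length, r.mismatches, r.gap_opens,
                        r.q_start, r.q_end, r.s_start, r.s_end,
                        f"{r.evalue:.3g}", f"{r.bitscore:.1f}",
                    )
                )
                + "\n"
            )
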