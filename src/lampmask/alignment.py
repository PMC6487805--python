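"""Alignment input/output and structured header parsing.

Records carry their group (taxon) membership in the FASTA/Clustal
identifier itself, using a delimiter-separated grammar::

    >TaxonID<delim>GeneID<delim>StrainID     (3 fields)
    >TaxonID<delim>StrainID                  (2 fields)

The default delimiter is the em-dash. Strains with an identical taxon
label form one group; group order and record order follow the input.

Two Clustal dialects are accepted: plain blocks, and blocks whose lines
end in a cumulative (gap-free) residue count. Internally coordinates are
0-based half-open; every user-facing report is 1-based inclusive.
"""

from __future__ import annotations

import io
import logging
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import AlignIO

from .errors import (
    AlignmentShapeError,
    AlphabetError,
    InsufficientGroupsError,
    MalformedHeaderError,
    WriteError,
)

logger = logging.getLogger(__name__)

EM_DASH = "—"

DNA_BASES = frozenset("ACGT")
GAP = "-"
#: IUPAC nucleotide ambiguity codes and the bases they may stand for.
IUPAC_AMBIGUITY: Mapping[str, frozenset[str]] = {
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}
ALPHABET = DNA_BASES | set(IUPAC_AMBIGUITY) | {GAP}

LINE_TERMINATORS = {"unix": "\n", "windows": "\r\n"}


@dataclass(frozen=True)
class StrainRecord:
    """One aligned sequence with its parsed taxon/gene/strain identity."""

    taxon_id: str
    strain_id: str
    sequence: str
    raw_header: str
    gene_id: str | None = None

    def __post_init__(self) -> None:
        if not self.taxon_id or not self.strain_id:
            raise MalformedHeaderError(
                f"empty taxon or strain label in header {self.raw_header!r}"
            )
        if not self.sequence:
            raise AlignmentShapeError(
                f"record {self.raw_header!r} has an empty sequence"
            )
        bad = sorted(set(self.sequence) - ALPHABET)
        if bad:
            raise AlphabetError(
                f"record {self.raw_header!r} contains non-nucleotide "
                f"characters: {', '.join(bad)}"
            )


@dataclass
class GroupedAlignment:
    """Ordered records partitioned into taxon groups; the unit of analysis."""

    records: list[StrainRecord]
    groups: dict[str, list[int]]
    n_columns: int

    @classmethod
    def from_records(cls, records: Sequence[StrainRecord]) -> "GroupedAlignment":
        if not records:
            raise AlignmentShapeError("alignment contains no records")
        lengths = {len(r.sequence) for r in records}
        if len(lengths) != 1:
            raise AlignmentShapeError(
                f"ragged alignment: sequence lengths {sorted(lengths)}"
            )
        groups: dict[str, list[int]] = {}
        for i, rec in enumerate(records):
            groups.setdefault(rec.taxon_id, []).append(i)
        if len(groups) < 2:
            raise InsufficientGroupsError(
                "at least 2 taxon groups are required, found "
                f"{len(groups)} ({', '.join(groups)})"
            )
        return cls(list(records), groups, lengths.pop())

    @property
    def group_labels(self) -> list[str]:
        return list(self.groups)

    def column(self, index: int) -> str:
        """Characters of alignment column `index` (0-based), input order."""
        return "".join(r.sequence[index] for r in self.records)

    def members(self, group: str) -> list[StrainRecord]:
        return [self.records[i] for i in self.groups[group]]


def parse_header(
    header: str, delimiter: str = EM_DASH
) -> tuple[str, str | None, str]:
    """Split a record header into (taxon_id, gene_id or None, strain_id).

    The leading ``>`` is optional; fields are whitespace-trimmed. Two
    fields mean the gene label was omitted.
    """
    if not header or not delimiter:
        raise MalformedHeaderError("header and delimiter must be non-empty")
    text = header.lstrip(">").strip()
    fields = [f.strip() for f in text.split(delimiter)]
    if len(fields) == 2:
        taxon, strain = fields
        gene = None
    elif len(fields) == 3:
        taxon, gene, strain = fields
    else:
        raise MalformedHeaderError(
            f"header {header!r} splits into {len(fields)} field(s) on "
            f"{delimiter!r}; expected 2 or 3"
        )
    if not taxon or not fields[-1]:
        raise MalformedHeaderError(f"empty field in header {header!r}")
    return taxon, gene, strain


def _normalise_sequence(seq: str, header: str, seen_u: list[bool]) -> str:
    seq = seq.upper()
    if "U" in seq:
        if not seen_u[0]:
            logger.info("transliterating RNA 'U' to 'T' on ingest")
            seen_u[0] = True
        seq = seq.replace("U", "T")
    return seq


def _as_handle(source: str | Path | io.TextIOBase) -> io.TextIOBase:
    if isinstance(source, io.TextIOBase):
        return source
    if isinstance(source, Path):
        return open(source, "r", encoding="utf-8")
    # A plain string is a path unless it contains a newline (raw text).
    if "\n" not in source and os.path.exists(source):
        return open(source, "r", encoding="utf-8")
    return io.StringIO(source)


def read_alignment(
    source: str | Path | io.TextIOBase,
    format: str = "clustal",
    delimiter: str = EM_DASH,
) -> GroupedAlignment:
    """Read a Clustal or aligned-FASTA file into a GroupedAlignment.

    `source` may be a path, an open text handle, or the raw file text.
    Both Clustal dialects (with or without per-line cumulative residue
    counts) are accepted. Sequences are uppercased and RNA ``U`` is
    transliterated to ``T``.
    """
    if format not in {"clustal", "fasta"}:
        raise ValueError(f"unknown alignment format {format!r}")
    handle = _as_handle(source)
    try:
        try:
            msa = AlignIO.read(handle, format)
        except ValueError as exc:
            msg = str(exc)
            if "length" in msg.lower():
                raise AlignmentShapeError(f"ragged alignment: {msg}") from exc
            raise AlignmentShapeError(
                f"could not parse input as {format}: {msg}"
            ) from exc
    finally:
        if handle is not source:
            handle.close()

    seen_u = [False]
    records: list[StrainRecord] = []
    for rec in msa:
        # FASTA keeps the full header in .description; Clustal names are
        # single whitespace-free tokens held in .id.
        header = rec.description if format == "fasta" and rec.description else rec.id
        taxon, gene, strain = parse_header(header, delimiter)
        seq = _normalise_sequence(str(rec.seq), header, seen_u)
        records.append(
            StrainRecord(
                taxon_id=taxon,
                strain_id=strain,
                gene_id=gene,
                sequence=seq,
                raw_header=header,
            )
        )
    return GroupedAlignment.from_records(records)


# ---------------------------------------------------------------------------
# writers


def _record_name(rec: StrainRecord, delimiter: str = EM_DASH) -> str:
    parts = [rec.taxon_id]
    if rec.gene_id:
        parts.append(rec.gene_id)
    parts.append(rec.strain_id)
    return delimiter.join(parts)


def write_fasta(aln: GroupedAlignment, path: str | Path) -> Path:
    """Write the alignment as aligned multi-FASTA (60-column wrap)."""
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        for rec in aln.records:
            fh.write(f">{_record_name(rec)}\n")
            for i in range(0, len(rec.sequence), 60):
                fh.write(rec.sequence[i : i + 60] + "\n")
    return path


def write_clustal(
    aln: GroupedAlignment,
    path: str | Path,
    cumulative_counts: bool = False,
    block_width: int = 60,
) -> Path:
    """Write Clustal format, optionally with per-line cumulative residue
    counts (gap-free running totals, the ClustalW "with numbers" dialect).
    """
    path = Path(path)
    names = [_record_name(r) for r in aln.records]
    width = max(len(n) for n in names) + 3
    residues_so_far = [0] * len(aln.records)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("CLUSTAL multiple sequence alignment\n\n\n")
        for start in range(0, aln.n_columns, block_width):
            for i, rec in enumerate(aln.records):
                chunk = rec.sequence[start : start + block_width]
                line = f"{names[i]:<{width}}{chunk}"
                if cumulative_counts:
                    residues_so_far[i] += sum(1 for c in chunk if c != GAP)
                    line += f" {residues_so_far[i]}"
                fh.write(line + "\n")
            fh.write("\n")
    return path


def write_processed_alignment(
    aln: GroupedAlignment,
    verdicts: Sequence,
    counts: Mapping[str, Sequence[int]],
    path: str | Path,
    line_endings: str = "unix",
    fragment_len: int = 20,
    block_width: int = 60,
) -> Path:
    """Write the processed alignment with per-group mutation marks.

    Clustal-style blocks; beneath each block, one mark line per group
    (``*`` under that group's taxon-specific columns) and one count line
    per group giving the number of its taxon-specific mutations in each
    `fragment_len`-column fragment overlapping the block.
    """
    if len(verdicts) != aln.n_columns:
        raise AlignmentShapeError(
            f"{len(verdicts)} verdicts for {aln.n_columns} columns"
        )
    if block_width % fragment_len != 0:
        raise ValueError("block_width must be a multiple of fragment_len")
    eol = LINE_TERMINATORS[line_endings]
    path = Path(path)
    names = [_record_name(r) for r in aln.records]
    label_names = {g: f"specific[{g}]" for g in aln.groups}
    count_names = {g: f"counts/{fragment_len}nt[{g}]" for g in aln.groups}
    width = (
        max(
            [len(n) for n in names]
            + [len(n) for n in label_names.values()]
            + [len(n) for n in count_names.values()]
        )
        + 3
    )
    try:
        with open(path, "w", encoding="utf-8", newline="") as fh:
            fh.write(
                "Processed alignment (all coordinates 1-based inclusive)" + eol
            )
            fh.write(eol)
            for start in range(0, aln.n_columns, block_width):
                end = min(start + block_width, aln.n_columns)
                fh.write(f"Columns {start + 1}-{end}" + eol)
                for i, rec in enumerate(aln.records):
                    fh.write(f"{names[i]:<{width}}{rec.sequence[start:end]}" + eol)
                for g in aln.groups:
                    marks = "".join(
                        "*" if g in verdicts[c].specific_for else "."
                        for c in range(start, end)
                    )
                    fh.write(f"{label_names[g]:<{width}}{marks}" + eol)
                    frag_lo = start // fragment_len
                    frag_hi = (end - 1) // fragment_len
                    block_counts = " ".join(
                        str(counts[g][f])
                        for f in range(frag_lo, frag_hi + 1)
                        if f < len(counts[g])
                    )
                    fh.write(f"{count_names[g]:<{width}}{block_counts}" + eol)
                fh.write(eol)
    except OSError as exc:
        raise WriteError(f"could not write {path}: {exc}") from exc
    return path
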