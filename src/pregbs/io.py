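"""Readers and writers for the plain-text formats the pipeline touches.

Coordinates are 0-based half-open (BED convention) everywhere in memory;
1-based coordinates appear only in human-readable reports and are labeled
as such.  Sequences are normalized to uppercase on input: soft-masked
(lowercase) genome sequence is searched like any other sequence, and any
character outside the IUPAC nucleotide alphabet is a format error.
"""

from __future__ import annotations

import sys
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import pandas as pd
from Bio import AlignIO

log = logging.getLogger("pregbs")

#: Full IUPAC nucleotide alphabet accepted in sequence input.
IUPAC_ALPHABET = frozenset("ACGTRYSWKMBDHVN")


class FormatError(ValueError):
    """A malformed input file; the message names the file and line."""


@dataclass(frozen=True)
class SequenceRecord:
    """A named nucleotide sequence, uppercased."""

    name: str
    sequence: str

    def __len__(self) -> int:  # pragma: no cover - trivial
        return len(self.sequence)


@dataclass(frozen=True, order=True)
class GenomeInterval:
    """A 0-based half-open genomic interval.

    ``payload`` carries any extra BED columns verbatim; it never takes part
    in equality-by-position comparisons done by callers.
    """

    chrom: str
    start: int
    end: int
    strand: str = "+"
    payload: tuple[str, ...] = field(default=(), compare=False)

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start: {self.start}")
        if self.end <= self.start:
            raise ValueError(f"empty or inverted interval: [{self.start},{self.end})")
        if self.strand not in ("+", "-"):
            raise ValueError(f"bad strand: {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class AlignmentBlock:
    """One pairwise alignment block (reference row first, MAF semantics).

    Starts are 0-based on the stated strand; a minus-strand start counts
    from the end of the source sequence.  ``ref_text``/``tgt_text`` are the
    gapped rows ('-' is the only gap character) and have equal length.
    """

    ref_name: str
    ref_start: int
    ref_size: int
    ref_strand: str
    ref_src_size: int
    ref_text: str
    tgt_name: str
    tgt_start: int
    tgt_size: int
    tgt_strand: str
    tgt_src_size: int
    tgt_text: str

    def __post_init__(self) -> None:
        if len(self.ref_text) != len(self.tgt_text):
            raise FormatError(
                f"gapped rows differ in length: {len(self.ref_text)} vs {len(self.tgt_text)}"
            )
        for label, text, size in (
            ("reference", self.ref_text, self.ref_size),
            ("target", self.tgt_text, self.tgt_size),
        ):
            ungapped = len(text) - text.count("-")
            if ungapped != size:
                raise FormatError(
                    f"{label} row declares size {size} but has {ungapped} bases"
                )


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a FASTA file into normalized (uppercase) records.

    The reader is deliberately line-aware so that format errors can name
    the offending line, which generic parsers do not surface.
    """
    path = Path(path)
    records: list[SequenceRecord] = []
    name: str | None = None
    chunks: list[str] = []

    def flush() -> None:
        if name is not None:
            records.append(SequenceRecord(name, "".join(chunks)))

    with open(path, encoding="utf-8") as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line:
                continue
            if line.startswith(">"):
                header = line[1:].strip()
                if not header:
                    raise FormatError(f"{path}:{lineno}: empty FASTA header")
                flush()
                name, chunks = header.split()[0], []
            else:
                if name is None:
                    raise FormatError(
                        f"{path}:{lineno}: sequence data before any FASTA header"
                    )
                seq = line.strip().upper()
                bad = set(seq) - IUPAC_ALPHABET
                if bad:
                    raise FormatError(
                        f"{path}:{lineno}: illegal sequence character(s) "
                        f"{''.join(sorted(bad))!r}"
                    )
                chunks.append(seq)
    flush()
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 60) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        for rec in records:
            handle.write(f">{rec.name}\n")
            for i in range(0, len(rec.sequence), width):
                handle.write(rec.sequence[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# BED

def read_bed(path: str | Path) -> list[GenomeInterval]:
    """Read BED3+ into intervals; extra columns are kept as opaque payload."""
    path = Path(path)
    out: list[GenomeInterval] = []
    with open(path, encoding="utf-8") as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: expected >=3 tab-separated fields")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates") from exc
            strand = fields[5] if len(fields) > 5 and fields[5] in "+-" else "+"
            try:
                out.append(
                    GenomeInterval(chrom, start, end, strand, tuple(fields[3:]))
                )
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return out


def write_bed(intervals: Iterable[GenomeInterval], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        for iv in intervals:
            fields = [iv.chrom, str(iv.start), str(iv.end), *iv.payload]
            handle.write("\t".join(fields) + "\n")


# ---------------------------------------------------------------------------
# MAF

def _strand_char(value: int) -> str:
    return "+" if value == 1 else "-"


def read_maf(path: str | Path) -> Iterator[AlignmentBlock]:
    """Stream pairwise alignment blocks from a MAF file.

    Exactly two sequence rows per block are required, reference first.
    MAF start/strand semantics are preserved verbatim on the block.
    """
    path = Path(path)
    for i, msa in enumerate(AlignIO.parse(str(path), "maf")):
        if len(msa) != 2:
            raise FormatError(
                f"{path}: alignment block {i} has {len(msa)} sequence rows, expected 2"
            )
        ref, tgt = msa[0], msa[1]
        try:
            yield AlignmentBlock(
                ref_name=ref.id,
                ref_start=int(ref.annotations["start"]),
                ref_size=int(ref.annotations["size"]),
                ref_strand=_strand_char(ref.annotations["strand"]),
                ref_src_size=int(ref.annotations["srcSize"]),
                ref_text=str(ref.seq).upper(),
                tgt_name=tgt.id,
                tgt_start=int(tgt.annotations["start"]),
                tgt_size=int(tgt.annotations["size"]),
                tgt_strand=_strand_char(tgt.annotations["strand"]),
                tgt_src_size=int(tgt.annotations["srcSize"]),
                tgt_text=str(tgt.seq).upper(),
            )
        except FormatError as exc:
            raise FormatError(f"{path}: block {i}: {exc}") from exc


def write_maf(blocks: Iterable[AlignmentBlock], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        handle.write("##maf version=1\n")
        for b in blocks:
            handle.write("a score=0.0\n")
            handle.write(
                f"s {b.ref_name} {b.ref_start} {b.ref_size} {b.ref_strand} "
                f"{b.ref_src_size} {b.ref_text}\n"
            )
            handle.write(
                f"s {b.tgt_name} {b.tgt_start} {b.tgt_size} {b.tgt_strand} "
                f"{b.tgt_src_size} {b.tgt_text}\n"
            )
            handle.write("\n")


# ---------------------------------------------------------------------------
# Tabular reports

def write_report(rows: Sequence[dict], path: str | Path, columns: list[str] | None = None) -> None:
    """Write homogeneous records as a TSV with header.

    Column order is that of the first record (or the explicit ``columns``);
    all records must share the same keys.
    """
    rows = list(rows)
    if rows:
        keys = list(rows[0].keys())
        for i, row in enumerate(rows[1:], start=1):
            if list(row.keys()) != keys:
                raise ValueError(f"record {i} has different fields than record 0")
        if columns is None:
            columns = keys
    elif columns is None:
        columns = []
    frame = pd.DataFrame(rows, columns=columns)
    frame.to_csv(path, sep="\t", index=False)


def read_report(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def setup_logging(level: str = "INFO") -> None:
    logging.basicConfig(
        stream=sys.stderr,
        level=getattr(logging, level.upper()),
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
    )
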