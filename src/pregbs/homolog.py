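"""Projection of reference motif occurrences through pairwise alignments.

Each human occurrence is looked up in an interval index over the reference
rows of a MAF alignment and its homologous, strictly gapless motif-length
sequence is extracted from the target row.  Homologs spanning any gap
column (an insertion or deletion in either genome) are rejected, as are
occurrences not covered end-to-end by a single block — only positionally
comparable homologs enter the variant analysis.
"""

from __future__ import annotations

import logging
from collections import Counter

import numpy as np
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal

from intervaltree import IntervalTree

from .io import AlignmentBlock, read_maf
from .motif import MotifOccurrence, reverse_complement

log = logging.getLogger("pregbs")

Status = Literal["ok", "indel", "unaligned", "partial"]


@dataclass(frozen=True)
class HomologRecord:
    """A human occurrence paired with its gapless homolog, or a rejection reason."""

    occurrence: MotifOccurrence
    species: str
    status: Status
    homolog_seq: str | None = None

    def __post_init__(self) -> None:
        if (self.status == "ok") != (self.homolog_seq is not None):
            raise ValueError("homolog_seq must be present iff status == 'ok'")


def _flip_block(b: AlignmentBlock) -> AlignmentBlock:
    """Reverse-complement both rows so the reference row is forward-strand."""
    return AlignmentBlock(
        ref_name=b.ref_name,
        ref_start=b.ref_src_size - b.ref_start - b.ref_size,
        ref_size=b.ref_size,
        ref_strand="+",
        ref_src_size=b.ref_src_size,
        ref_text=reverse_complement(b.ref_text),
        tgt_name=b.tgt_name,
        tgt_start=b.tgt_src_size - b.tgt_start - b.tgt_size,
        tgt_size=b.tgt_size,
        tgt_strand="-" if b.tgt_strand == "+" else "+",
        tgt_src_size=b.tgt_src_size,
        tgt_text=reverse_complement(b.tgt_text),
    )


class _IndexedBlock:
    """A block with a precomputed reference-offset → column lookup."""

    __slots__ = ("block", "ref_cols")

    def __init__(self, block: AlignmentBlock):
        self.block = block
        # column index of each reference base, in reference order
        codes = np.frombuffer(block.ref_text.encode("ascii"), dtype=np.uint8)
        self.ref_cols = np.flatnonzero(codes != ord("-"))


class AlignmentIndex:
    """Interval-searchable projection index over reference coordinates.

    Overlapping reference blocks are all kept; ties among fully covering
    blocks are resolved at projection time (longest reference overlap, then
    lexicographic (tgt_name, tgt_start)).
    """

    def __init__(self) -> None:
        self._trees: dict[str, IntervalTree] = {}

    def add(self, block: AlignmentBlock) -> None:
        if block.ref_strand == "-":
            block = _flip_block(block)
        chrom = block.ref_name.split(".", 1)[-1]
        tree = self._trees.setdefault(chrom, IntervalTree())
        tree.addi(block.ref_start, block.ref_start + block.ref_size, _IndexedBlock(block))

    def query(self, chrom: str, start: int, end: int) -> list[_IndexedBlock]:
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        return [iv.data for iv in tree.overlap(start, end)]


def index_alignment(blocks: Iterable[AlignmentBlock]) -> AlignmentIndex:
    """Build a projection index; reference rows must all come from one genome."""
    index = AlignmentIndex()
    ref_genomes = set()
    for block in blocks:
        ref_genomes.add(block.ref_name.split(".", 1)[0])
        index.add(block)
    if len(ref_genomes) > 1:
        raise ValueError(f"reference rows from multiple genomes: {sorted(ref_genomes)}")
    return index


def project_occurrence(
    index: AlignmentIndex, occ: MotifOccurrence, species: str = ""
) -> HomologRecord:
    """Project one occurrence; all failure modes are statuses, never errors.

    * ``unaligned`` — no block covers any base of the occurrence;
    * ``partial``   — covered, but by no single block end-to-end;
    * ``indel``     — the covering columns contain a gap in either row;
    * ``ok``        — gapless; the homolog is the target-row slice, already
      oriented to the human forward strand by MAF semantics.
    """
    start, end = occ.interval.start, occ.interval.end
    overlapping = index.query(occ.interval.chrom, start, end)
    if not overlapping:
        return HomologRecord(occ, species, "unaligned")
    covering = [
        ib for ib in overlapping
        if ib.block.ref_start <= start and ib.block.ref_start + ib.block.ref_size >= end
    ]
    if not covering:
        return HomologRecord(occ, species, "partial")
    best = min(covering, key=lambda ib: (ib.block.tgt_name, ib.block.tgt_start))
    block = best.block
    col_lo = best.ref_cols[start - block.ref_start]
    col_hi = best.ref_cols[end - 1 - block.ref_start] + 1
    if col_hi - col_lo != end - start:
        # gap columns in the reference row inside the span (target insertion)
        return HomologRecord(occ, species, "indel")
    tgt_slice = block.tgt_text[col_lo:col_hi]
    if "-" in tgt_slice:
        return HomologRecord(occ, species, "indel")
    return HomologRecord(occ, species, "ok", tgt_slice)


def collect_homologs(
    occurrences: Iterable[MotifOccurrence],
    alignment: str | Path | Iterable[AlignmentBlock],
    species: str,
) -> list[HomologRecord]:
    """Project every occurrence through one species alignment.

    ``alignment`` may be a MAF path or an iterable of blocks.  Summary
    counts by status are logged.
    """
    if isinstance(alignment, (str, Path)):
        blocks: Iterable[AlignmentBlock] = read_maf(alignment)
    else:
        blocks = alignment
    index = index_alignment(blocks)
    records = [project_occurrence(index, occ, species) for occ in occurrences]
    summary = Counter(rec.status for rec in records)
    log.info("homologs for %s: %s", species, dict(summary))
    return records
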