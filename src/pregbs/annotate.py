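"""Regulatory labeling of motif occurrences by annotation-track overlap.

An occurrence is "regulatory" when it overlaps (>=1 bp, half-open
semantics) at least one interval of any provided track — DNase I
hypersensitive sites, GR ChIP-seq peaks or conserved non-coding elements.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from intervaltree import IntervalTree

from .io import GenomeInterval
from .motif import MotifOccurrence


@dataclass(frozen=True)
class RegulatoryLabel:
    regulatory: bool
    hits: tuple[tuple[str, GenomeInterval], ...]

    def __post_init__(self) -> None:
        if self.regulatory != bool(self.hits):
            raise ValueError("regulatory iff hits non-empty")


class IntervalIndex:
    """Per-chromosome interval tree supporting O(log n + k) overlap queries."""

    def __init__(self, intervals: Iterable[GenomeInterval] = ()):
        self._trees: dict[str, IntervalTree] = {}
        # the serial keeps duplicate track intervals distinct inside the tree
        for serial, iv in enumerate(intervals):
            self._trees.setdefault(iv.chrom, IntervalTree()).addi(
                iv.start, iv.end, (serial, iv)
            )

    def overlapping(self, q: GenomeInterval) -> list[GenomeInterval]:
        tree = self._trees.get(q.chrom)
        if tree is None:
            return []
        return [
            iv
            for _, iv in sorted(
                (hit.data for hit in tree.overlap(q.start, q.end)),
                key=lambda pair: (pair[1].start, pair[1].end, pair[0]),
            )
        ]


def build_interval_index(track: Iterable[GenomeInterval]) -> IntervalIndex:
    return IntervalIndex(track)


def overlaps_any(index: IntervalIndex, q: GenomeInterval) -> bool:
    """True iff some track interval shares >=1 bp with ``q`` (half-open)."""
    return bool(index.overlapping(q))


def classify_regulatory(
    occurrences: Sequence[MotifOccurrence],
    tracks: Mapping[str, Iterable[GenomeInterval]],
    flank: int = 0,
) -> tuple[list[RegulatoryLabel], dict]:
    """Label each occurrence by overlap with any named track.

    ``flank`` widens the query interval symmetrically (default 0: the
    13 bp occurrence itself is the query).  Returns the labels (aligned
    with ``occurrences``) and a summary with regulatory / non-regulatory
    totals plus per-track hit counts.
    """
    indexes = {name: build_interval_index(track) for name, track in tracks.items()}
    labels: list[RegulatoryLabel] = []
    per_track: Counter = Counter()
    for occ in occurrences:
        q = GenomeInterval(
            occ.interval.chrom,
            max(0, occ.interval.start - flank),
            occ.interval.end + flank,
            occ.interval.strand,
        )
        hits: list[tuple[str, GenomeInterval]] = []
        for name, index in indexes.items():
            track_hits = index.overlapping(q)
            if track_hits:
                per_track[name] += 1
            hits.extend((name, iv) for iv in track_hits)
        labels.append(RegulatoryLabel(bool(hits), tuple(hits)))
    n_reg = sum(1 for lab in labels if lab.regulatory)
    summary = {
        "regulatory": n_reg,
        "non_regulatory": len(labels) - n_reg,
        "per_track": dict(per_track),
    }
    return labels, summary
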