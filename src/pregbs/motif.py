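"""Degenerate IUPAC motif compilation and double-stranded genome scanning.

The motif of interest is the glucocorticoid receptor (GR) consensus core
``GnACAnnnTGTnC``: eight fixed positions and five unconstrained spacer
positions.  It is its own reverse complement, so a match has no
identifiable strand; occurrences are therefore deduplicated per genomic
interval (one occurrence per interval, never one per strand).

Matching semantics: a wildcard position accepts any *real* base (A/C/G/T);
``N`` in the genome matches nothing, including wildcards.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable

from .io import GenomeInterval, SequenceRecord

#: IUPAC degeneracy → set of concrete bases it matches.
IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"), "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"), "W": frozenset("AT"),
    "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"), "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

_COMPLEMENT = {
    "A": "T", "C": "G", "G": "C", "T": "A",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D", "N": "N", "-": "-",
}


def reverse_complement(seq: str) -> str:
    """Reverse-complement an IUPAC string (case-insensitive, case-preserving on output: upper)."""
    try:
        return "".join(_COMPLEMENT[b] for b in reversed(seq.upper()))
    except KeyError as exc:
        raise ValueError(f"illegal nucleotide character {exc.args[0]!r}") from None


@dataclass(frozen=True)
class DegenerateMotif:
    """A compiled fixed-length IUPAC pattern.

    ``fixed_positions`` maps 1-based position → allowed base set for every
    position that constrains the sequence; ``wildcard_positions`` holds the
    N positions.  The two partitions cover every position exactly once.
    """

    pattern: str
    length: int
    fixed_positions: dict[int, frozenset[str]]
    wildcard_positions: frozenset[int]

    @property
    def is_palindromic(self) -> bool:
        """True when the pattern equals its own reverse complement."""
        return self.pattern.upper() == reverse_complement(self.pattern)

    def matches(self, window: str) -> bool:
        """Check a single window of exactly motif length (forward strand)."""
        if len(window) != self.length:
            return False
        w = window.upper()
        for pos, allowed in self.fixed_positions.items():
            if w[pos - 1] not in allowed:
                return False
        for pos in self.wildcard_positions:
            if w[pos - 1] not in "ACGT":
                return False
        return True


def compile_motif(pattern: str) -> DegenerateMotif:
    """Compile an IUPAC pattern ('n'/'N' = any real base) into a motif."""
    if not pattern:
        raise ValueError("empty motif pattern")
    upper = pattern.upper()
    fixed: dict[int, frozenset[str]] = {}
    wild: set[int] = set()
    for i, code in enumerate(upper, start=1):
        if code not in IUPAC_SETS:
            raise ValueError(f"illegal IUPAC code {pattern[i - 1]!r} at position {i}")
        if code == "N":
            wild.add(i)
        else:
            fixed[i] = IUPAC_SETS[code]
    return DegenerateMotif(
        pattern=pattern,
        length=len(pattern),
        fixed_positions=fixed,
        wildcard_positions=frozenset(wild),
    )


@dataclass(frozen=True)
class MotifOccurrence:
    """A motif hit: interval plus the matched genome substring (forward orientation)."""

    interval: GenomeInterval
    matched_seq: str
    source_genome: str = ""

    @property
    def key(self) -> tuple[str, int, int]:
        return (self.interval.chrom, self.interval.start, self.interval.end)


def _regex_for(motif: DegenerateMotif) -> re.Pattern:
    # lookahead so overlapping windows are all reported
    classes = []
    for i in range(1, motif.length + 1):
        allowed = motif.fixed_positions.get(i, IUPAC_SETS["N"])
        classes.append("[" + "".join(sorted(allowed)) + "]")
    return re.compile("(?=(" + "".join(classes) + "))")


def scan_sequence(
    motif: DegenerateMotif, record: SequenceRecord, source_genome: str = ""
) -> list[MotifOccurrence]:
    """Find all occurrences of the motif in one sequence, both strands.

    A reverse-strand match is reported as its forward-coordinate interval
    with strand '-'; an interval matching on both strands is reported once
    with strand '+'.  For a palindromic motif such as the GR core this
    exactly halves the raw two-strand hit list.
    """
    seq = record.sequence.upper()
    if motif.length > len(seq):
        return []
    hits: dict[int, str] = {}
    for m in _regex_for(motif).finditer(seq):
        hits[m.start()] = "+"
    rc_motif = compile_motif(reverse_complement(motif.pattern))
    for m in _regex_for(rc_motif).finditer(seq):
        hits.setdefault(m.start(), "-")
    out = []
    for start in sorted(hits):
        end = start + motif.length
        out.append(
            MotifOccurrence(
                interval=GenomeInterval(record.name, start, end, hits[start]),
                matched_seq=seq[start:end],
                source_genome=source_genome,
            )
        )
    return out


def scan_genome(
    motif: DegenerateMotif,
    genome: Iterable[SequenceRecord],
    source_genome: str = "",
    chroms: set[str] | None = None,
) -> list[MotifOccurrence]:
    """Concatenate per-sequence scans in stable (sequence, coordinate) order."""
    out: list[MotifOccurrence] = []
    for record in genome:
        if chroms is not None and record.name not in chroms:
            continue
        out.extend(scan_sequence(motif, record, source_genome))
    return out


#: The GR consensus core motif used throughout the analysis.
GR_MOTIF_PATTERN = "GnACAnnnTGTnC"

#: The ancestral, CpG-retaining (pre-GBS) version of the same core.
PRE_GBS_PATTERN = "GnACGnnnTGTnC"
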