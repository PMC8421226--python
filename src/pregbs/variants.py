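"""Classification of homologous motif variants and pre-GBS selection.

A gapless homolog of a human GR motif is compared to the consensus core
``GnACAnnnTGTnC`` at its eight fixed positions.  Homologs differing at a
single fixed position, and only at position 5 or position 9, are the
informative class: because the motif is its own reverse complement, a
variant at position 9 on the forward strand is a variant at position 5 on
the reverse strand, so position-9 variants are folded onto the position-5
frame by complementing the variant base ("pooled" variants).

A pooled G means the homolog retains a CpG dinucleotide exactly where the
modern human motif carries TpG (or, equivalently, CA on the other strand)
— the signature of a methylation–deamination origin.  Human motifs with at
least one pooled-G homolog in another species are the candidate pre-GBSs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal

from .homolog import HomologRecord
from .motif import DegenerateMotif, MotifOccurrence, _COMPLEMENT

Kind = Literal["identical", "single5", "single9", "other"]

#: The two pseudo-palindromic variant positions of the GR core (1-based).
VARIANT_POS = 5


@dataclass(frozen=True)
class VariantClass:
    """Outcome of comparing one homolog to the motif consensus."""

    kind: Kind
    raw_nt: str | None = None     # base at the variant position, as read
    pooled_nt: str | None = None  # same base expressed in the position-5 frame

    def __post_init__(self) -> None:
        has = self.kind in ("single5", "single9")
        if has != (self.raw_nt is not None) or has != (self.pooled_nt is not None):
            raise ValueError("raw_nt/pooled_nt present iff kind is single5/single9")


def _partner_position(motif: DegenerateMotif, pos: int) -> int:
    return motif.length + 1 - pos


def classify_homolog(
    homolog_seq: str, motif: DegenerateMotif, variant_pos: int = VARIANT_POS
) -> VariantClass:
    """Classify one motif-length homolog against the consensus.

    ``identical``: all fixed positions match.  ``single5``/``single9``:
    exactly one fixed-position mismatch, at ``variant_pos`` or its
    reverse-complement partner.  Anything else (including any N at a fixed
    position) is ``other``.  Wildcard positions never constrain.
    """
    if len(homolog_seq) != motif.length:
        raise ValueError(
            f"homolog length {len(homolog_seq)} != motif length {motif.length}"
        )
    if not motif.is_palindromic:
        raise ValueError("variant pooling requires a self-reverse-complementary motif")
    seq = homolog_seq.upper()
    partner = _partner_position(motif, variant_pos)
    mismatches = {
        pos
        for pos, allowed in motif.fixed_positions.items()
        if seq[pos - 1] not in allowed
    }
    if not mismatches:
        return VariantClass("identical")
    if mismatches == {variant_pos}:
        raw = seq[variant_pos - 1]
        if raw in "ACGT":
            return VariantClass("single5", raw_nt=raw, pooled_nt=raw)
    elif mismatches == {partner}:
        raw = seq[partner - 1]
        if raw in "ACGT":
            return VariantClass("single9", raw_nt=raw, pooled_nt=_COMPLEMENT[raw])
    return VariantClass("other")


@dataclass
class VariantSpectrum:
    """Per-species tallies of pooled position-5 variant bases."""

    species: str
    counts: dict[str, int] = field(default_factory=lambda: {"C": 0, "G": 0, "T": 0})
    identical_count: int = 0
    other_count: int = 0

    @property
    def n_variants(self) -> int:
        return sum(self.counts.values())

    @property
    def total(self) -> int:
        return self.n_variants + self.identical_count + self.other_count

    @property
    def fraction_g(self) -> float | None:
        """G fraction among pooled variants; None when no variants exist."""
        n = self.n_variants
        return self.counts["G"] / n if n else None


def tally_spectra(
    records: Iterable[HomologRecord],
    motif: DegenerateMotif,
    variant_pos: int = VARIANT_POS,
) -> dict[str, VariantSpectrum]:
    """Tally pooled variant spectra per species over ok-status records."""
    spectra: dict[str, VariantSpectrum] = {}
    for rec in records:
        if rec.status != "ok":
            continue
        spec = spectra.setdefault(rec.species, VariantSpectrum(rec.species))
        vc = classify_homolog(rec.homolog_seq, motif, variant_pos)
        if vc.kind == "identical":
            spec.identical_count += 1
        elif vc.kind == "other":
            spec.other_count += 1
        else:
            spec.counts[vc.pooled_nt] += 1
    return spectra


@dataclass(frozen=True)
class PreGBSRecord:
    """A human motif supported as deamination-derived by >=1 species homolog."""

    occurrence: MotifOccurrence
    supports: tuple[tuple[str, str], ...]  # (species, homolog_seq), pooled G each

    def __post_init__(self) -> None:
        if not self.supports:
            raise ValueError("a pre-GBS record needs at least one supporting species")


def select_pre_gbs(
    records: Iterable[HomologRecord],
    motif: DegenerateMotif,
    variant_pos: int = VARIANT_POS,
) -> tuple[list[PreGBSRecord], int, int]:
    """Select pre-GBS candidates: homologs whose pooled variant base is G.

    Returns ``(records, total, unique)`` where ``total`` counts
    (occurrence, species) support pairs and ``unique`` counts distinct human
    intervals — duplicates arising from support in several species collapse
    onto one record keyed by the human interval alone.
    """
    by_site: dict[tuple[str, int, int], tuple[MotifOccurrence, list[tuple[str, str]]]] = {}
    total = 0
    for rec in records:
        if rec.status != "ok":
            continue
        vc = classify_homolog(rec.homolog_seq, motif, variant_pos)
        if vc.pooled_nt == "G":
            total += 1
            occ, supports = by_site.setdefault(rec.occurrence.key, (rec.occurrence, []))
            supports.append((rec.species, rec.homolog_seq))
    out = [
        PreGBSRecord(occ, tuple(supports))
        for occ, supports in sorted(by_site.values(), key=lambda t: t[0].key)
    ]
    return out, total, len(out)
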