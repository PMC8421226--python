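"""Synthetic genome evolution with CpG hypermutability.

The generator plants CpG-containing pre-GBS motifs (``GnACGnnnTGTnC``) and
modern TpG motifs (``GnACAnnnTGTnC``) into an i.i.d. ancestral background,
then evolves two descendant lineages independently under a one-generation
Bernoulli substitution model:

* every site substitutes to each different base with probability mu/3;
* the C of a CpG dinucleotide (and, strand-symmetrically, the G — the C of
  the opposite strand) transitions C→T (G→A) with elevated probability
  ``min(1, lambda*mu/3)``, lambda-fold the baseline C→T channel, while its
  two transversion channels stay at mu/3.  Methylated-CpG deamination is
  10–50x faster than deamination of unmodified cytosine, hence the default
  lambda=20 (the midpoint of that range); lambda=1 reduces exactly to the
  background model and is the simulator's null.

Small indels (per-site probability delta, geometric lengths, mean 2) are
optional.  The emitted MAF alignment is the exact simulation record — no
realignment — so projection through it is ground truth.  A regulatory BED
covers each planted site with probability rho when its human-lineage copy
is a deamination-derived modern motif, and rho0 otherwise, emulating
selection preferentially preserving newly functional sites.

All randomness flows through numpy Generators spawned per lineage and per
operation from one seed, so e.g. enabling indels does not perturb the
substitution draws.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .annotate import classify_regulatory
from .homolog import HomologRecord, collect_homologs
from .io import (
    AlignmentBlock,
    GenomeInterval,
    SequenceRecord,
    write_bed,
    write_fasta,
    write_maf,
)
from .motif import (
    GR_MOTIF_PATTERN,
    PRE_GBS_PATTERN,
    MotifOccurrence,
    compile_motif,
    scan_genome,
)
from .stats import chisq_uniform, fisher_one_sided, ContingencyTable2x2, labels_by_key
from .variants import select_pre_gbs, tally_spectra, VariantSpectrum

_BASES = "ACGT"
_GAP = ord("-")

REF_GENOME = "simH"   # human-like lineage (alignment reference)
TGT_GENOME = "simO"   # other-species lineage
CHROM = "chr1"


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic dataset.

    ``lam`` is the CpG deamination rate multiplier (the measured range for
    5mC is 10–50x); ``mu`` the per-site, per-lineage substitution probability;
    ``delta`` the per-site indel event probability.  ``rho``/``rho0`` are
    the regulatory-track coverage probabilities for deamination-derived
    versus other planted sites.
    """

    length: int = 2_000_000
    gc_content: float = 0.41
    n_cpg_sites: int = 500
    n_tpg_sites: int = 1500
    mu: float = 0.02
    lam: float = 20.0
    delta: float = 0.001
    indel_mean: float = 2.0
    rho: float = 0.9
    rho0: float = 0.3
    track_padding: int = 25
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("gc_content", "mu", "delta", "rho", "rho0"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name}={value} outside [0, 1]")
        if not 0.0 < self.gc_content < 1.0:
            raise ValueError("gc_content must be in (0, 1)")
        if self.lam < 1.0:
            raise ValueError("lambda must be >= 1")
        n_planted = self.n_cpg_sites + self.n_tpg_sites
        if self.length < 50 * n_planted:
            raise ValueError(
                f"genome length {self.length} too small for {n_planted} planted sites "
                f"(need >= {50 * n_planted})"
            )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path, encoding="utf-8") as handle:
            raw = yaml.safe_load(handle) or {}
        if "lambda" in raw:
            raw["lam"] = raw.pop("lambda")
        return cls(**raw)


@dataclass
class PlantedSite:
    anc_start: int
    planted_class: str   # "cpg" | "tpg"
    planted_seq: str


def _rng(seed: int, *stream: int) -> np.random.Generator:
    return np.random.default_rng([seed & 0x7FFFFFFF, *stream])


def _codes_to_str(codes: np.ndarray) -> str:
    return codes.astype(np.uint8).tobytes().decode("ascii")


def _instantiate(pattern: str, rng: np.random.Generator) -> str:
    return "".join(
        _BASES[rng.integers(4)] if code in "nN" else code for code in pattern
    )


def make_ancestor(
    config: SimulationConfig, seed: int | None = None
) -> tuple[SequenceRecord, list[PlantedSite]]:
    """Draw the ancestral genome with planted, non-overlapping motif instances."""
    seed = config.seed if seed is None else seed
    rng = _rng(seed, 0)
    L = config.length
    gc = config.gc_content
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    codes = rng.choice(np.frombuffer(_BASES.encode(), dtype=np.uint8), size=L, p=probs)

    motif_len = len(GR_MOTIF_PATTERN)
    occupied = np.zeros(L, dtype=bool)
    sites: list[PlantedSite] = []
    classes = ["cpg"] * config.n_cpg_sites + ["tpg"] * config.n_tpg_sites
    max_attempts = 50 * max(1, len(classes))
    attempts = 0
    for klass in classes:
        pattern = PRE_GBS_PATTERN if klass == "cpg" else GR_MOTIF_PATTERN
        while True:
            attempts += 1
            if attempts > max_attempts:
                raise RuntimeError(
                    f"could not place {len(classes)} non-overlapping sites in {L} bp"
                )
            start = int(rng.integers(0, L - motif_len + 1))
            if not occupied[start : start + motif_len].any():
                break
        instance = _instantiate(pattern, rng)
        codes[start : start + motif_len] = np.frombuffer(
            instance.encode(), dtype=np.uint8
        )
        occupied[start : start + motif_len] = True
        sites.append(PlantedSite(start, klass, instance))
    sites.sort(key=lambda s: s.anc_start)
    return SequenceRecord(CHROM, _codes_to_str(codes)), sites


@dataclass
class LineageResult:
    """One evolved lineage, as an exact edit record against the ancestor."""

    sub: np.ndarray            # substituted base codes per ancestor position
    del_mask: np.ndarray       # ancestor positions deleted in this lineage
    ins_after: dict[int, str]  # ancestor position -> bases inserted after it
    derived: SequenceRecord
    derived_pos: np.ndarray    # ancestor position -> derived coordinate

    def site_intact(self, start: int, end: int) -> bool:
        """True when [start, end) maps gaplessly into the derived genome."""
        if self.del_mask[start:end].any():
            return False
        return not any(start <= s < end - 1 for s in self.ins_after)

    def derived_interval(self, start: int, end: int) -> tuple[int, int]:
        return int(self.derived_pos[start]), int(self.derived_pos[end - 1]) + 1


def _substitute(
    anc: np.ndarray, config: SimulationConfig, rng: np.random.Generator
) -> np.ndarray:
    """Apply one generation of substitutions simultaneously from the ancestor."""
    L = anc.size
    A, C, G, T = (np.uint8(ord(b)) for b in _BASES)
    is_c, is_g = anc == C, anc == G
    cpg = np.zeros(L, dtype=bool)
    cpg[:-1] = is_c[:-1] & is_g[1:]          # C of a CpG
    cpg_g = np.zeros(L, dtype=bool)
    cpg_g[1:] = cpg[:-1]                      # its G (opposite-strand C)

    mu3 = config.mu / 3.0
    p_deam = min(1.0, config.lam * mu3)

    r = rng.random(L)
    pick = rng.random(L)
    out = anc.copy()

    # baseline: substitute to one of the three other bases, uniformly
    plain = ~(cpg | cpg_g)
    mutate = plain & (r < config.mu)
    base_idx = np.searchsorted(
        np.frombuffer(_BASES.encode(), dtype=np.uint8), anc[mutate]
    )
    offset = 1 + (pick[mutate] * 3).astype(np.int64)
    lut = np.frombuffer(_BASES.encode(), dtype=np.uint8)
    out[mutate] = lut[(base_idx + offset) % 4]

    # CpG cytosine: elevated C->T transition, baseline transversions
    c_deam = cpg & (r < p_deam)
    c_tv = cpg & (r >= p_deam) & (r < p_deam + 2 * mu3)
    out[c_deam] = T
    out[c_tv] = np.where(pick[c_tv] < 0.5, A, G)

    # CpG guanine (opposite-strand cytosine): G->A, baseline transversions
    g_deam = cpg_g & (r < p_deam)
    g_tv = cpg_g & (r >= p_deam) & (r < p_deam + 2 * mu3)
    out[g_deam] = A
    out[g_tv] = np.where(pick[g_tv] < 0.5, C, T)
    return out


def evolve_lineage(
    ancestor: SequenceRecord, config: SimulationConfig, lineage_seed: int
) -> LineageResult:
    """Evolve one descendant; the edit record doubles as the true alignment."""
    anc = np.frombuffer(ancestor.sequence.encode(), dtype=np.uint8).copy()
    L = anc.size
    sub = _substitute(anc, config, _rng(lineage_seed, 1))

    del_mask = np.zeros(L, dtype=bool)
    ins_after: dict[int, str] = {}
    if config.delta > 0:
        rng = _rng(lineage_seed, 2)
        events = np.flatnonzero(rng.random(L) < config.delta)
        for site in events:
            length = int(rng.geometric(1.0 / config.indel_mean))
            if rng.random() < 0.5:
                ins_after[int(site)] = "".join(_BASES[rng.integers(4)] for _ in range(length))
            else:
                del_mask[site : site + length] = True

    keep = ~del_mask
    ins_len = np.zeros(L, dtype=np.int64)
    for site, seq in ins_after.items():
        ins_len[site] += len(seq)
    kept_before = np.concatenate(([0], np.cumsum(keep)[:-1]))
    ins_before = np.concatenate(([0], np.cumsum(ins_len)[:-1]))
    derived_pos = kept_before + ins_before

    # assemble the derived sequence: kept bases with insertions spliced in
    sub_kept = sub[keep]
    kept_upto = np.cumsum(keep)  # number of kept ancestor positions <= i
    pieces: list[str] = []
    prev = 0
    for site in sorted(ins_after):
        cut = int(kept_upto[site])
        pieces.append(_codes_to_str(sub_kept[prev:cut]))
        pieces.append(ins_after[site])
        prev = cut
    pieces.append(_codes_to_str(sub_kept[prev:]))
    derived = SequenceRecord(CHROM, "".join(pieces))
    return LineageResult(sub, del_mask, ins_after, derived, derived_pos)


def compose_alignment(lin1: LineageResult, lin2: LineageResult) -> AlignmentBlock:
    """Merge two ancestor-anchored edit records into one pairwise MAF block.

    Columns where both lineages deleted the ancestral base are dropped;
    insertion columns carry a gap in the sister row (lineage-1 insertions
    are emitted before lineage-2 insertions anchored at the same site).
    """
    both_deleted = lin1.del_mask & lin2.del_mask
    keep_cols = ~both_deleted
    row1 = np.where(lin1.del_mask, np.uint8(_GAP), lin1.sub)[keep_cols]
    row2 = np.where(lin2.del_mask, np.uint8(_GAP), lin2.sub)[keep_cols]

    col_of = np.cumsum(keep_cols)  # number of kept columns <= ancestor pos
    inserts: list[tuple[int, int, str, int]] = []  # (col, order, seq, row)
    for site, seq in lin1.ins_after.items():
        inserts.append((int(col_of[site]), 0, seq, 1))
    for site, seq in lin2.ins_after.items():
        inserts.append((int(col_of[site]), 1, seq, 2))
    inserts.sort(key=lambda t: (t[0], t[1]))

    pieces1: list[str] = []
    pieces2: list[str] = []
    prev = 0
    for col, _, seq, row in inserts:
        pieces1.append(_codes_to_str(row1[prev:col]))
        pieces2.append(_codes_to_str(row2[prev:col]))
        if row == 1:
            pieces1.append(seq)
            pieces2.append("-" * len(seq))
        else:
            pieces1.append("-" * len(seq))
            pieces2.append(seq)
        prev = col
    pieces1.append(_codes_to_str(row1[prev:]))
    pieces2.append(_codes_to_str(row2[prev:]))
    text1, text2 = "".join(pieces1), "".join(pieces2)

    size1 = len(lin1.derived.sequence)
    size2 = len(lin2.derived.sequence)
    return AlignmentBlock(
        ref_name=f"{REF_GENOME}.{CHROM}", ref_start=0, ref_size=size1,
        ref_strand="+", ref_src_size=size1, ref_text=text1,
        tgt_name=f"{TGT_GENOME}.{CHROM}", tgt_start=0, tgt_size=size2,
        tgt_strand="+", tgt_src_size=size2, tgt_text=text2,
    )


@dataclass
class TruthRecord:
    """Ground truth for one planted site, in ancestor and both descendants."""

    anc_start: int
    planted_class: str
    planted_seq: str
    ref_start: int            # -1 when the site is indel-disrupted in that lineage
    ref_end: int
    tgt_start: int
    tgt_end: int
    ref_class: str            # consensus | pre | other | disrupted
    tgt_class: str
    deamination_derived: bool
    regulatory: bool


@dataclass
class SimulatedDataset:
    config: SimulationConfig
    seed: int
    ancestor: SequenceRecord
    ref: SequenceRecord
    tgt: SequenceRecord
    block: AlignmentBlock
    regulatory_track: list[GenomeInterval]
    truth: list[TruthRecord]

    def truth_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(t) for t in self.truth])


def _post_class(lin: LineageResult, site: PlantedSite, motif_len: int,
                consensus, pre) -> tuple[str, int, int]:
    start, end = site.anc_start, site.anc_start + motif_len
    if not lin.site_intact(start, end):
        return "disrupted", -1, -1
    d_start, d_end = lin.derived_interval(start, end)
    seq = lin.derived.sequence[d_start:d_end]
    if consensus.matches(seq):
        klass = "consensus"
    elif pre.matches(seq):
        klass = "pre"
    else:
        klass = "other"
    return klass, d_start, d_end


def simulate_dataset(config: SimulationConfig, seed: int | None = None) -> SimulatedDataset:
    """Run the full generator in memory: genomes, alignment, tracks, truth."""
    seed = config.seed if seed is None else seed
    ancestor, sites = make_ancestor(config, seed)
    lin_ref = evolve_lineage(ancestor, config, seed * 2 + 1)
    lin_tgt = evolve_lineage(ancestor, config, seed * 2 + 2)
    block = compose_alignment(lin_ref, lin_tgt)

    consensus = compile_motif(GR_MOTIF_PATTERN)
    pre = compile_motif(PRE_GBS_PATTERN)
    motif_len = consensus.length
    track_rng = _rng(seed, 3)
    truth: list[TruthRecord] = []
    track: list[GenomeInterval] = []
    for site in sites:
        ref_class, r_lo, r_hi = _post_class(lin_ref, site, motif_len, consensus, pre)
        tgt_class, t_lo, t_hi = _post_class(lin_tgt, site, motif_len, consensus, pre)
        derived = site.planted_class == "cpg" and ref_class == "consensus"
        cover_p = config.rho if derived else config.rho0
        regulatory = bool(track_rng.random() < cover_p)
        if regulatory and r_lo >= 0:
            pad = config.track_padding
            track.append(
                GenomeInterval(CHROM, max(0, r_lo - pad), r_hi + pad)
            )
        truth.append(
            TruthRecord(
                site.anc_start, site.planted_class, site.planted_seq,
                r_lo, r_hi, t_lo, t_hi, ref_class, tgt_class, derived, regulatory,
            )
        )
    track.sort(key=lambda iv: (iv.chrom, iv.start))
    return SimulatedDataset(
        config, seed, ancestor, lin_ref.derived, lin_tgt.derived, block, track, truth
    )


def emit_dataset(config: SimulationConfig, outdir: str | Path,
                 seed: int | None = None) -> dict[str, Path]:
    """Write the dataset to disk; byte-identical for identical (config, seed)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ds = simulate_dataset(config, seed)
    paths = {
        "ref_fasta": outdir / "human_like.fa",
        "tgt_fasta": outdir / "other_species.fa",
        "maf": outdir / "alignment.maf",
        "regulatory_bed": outdir / "regulatory.bed",
        "truth": outdir / "truth.tsv",
    }
    write_fasta([ds.ref], paths["ref_fasta"])
    write_fasta([ds.tgt], paths["tgt_fasta"])
    write_maf([ds.block], paths["maf"])
    write_bed(ds.regulatory_track, paths["regulatory_bed"])
    ds.truth_frame().to_csv(paths["truth"], sep="\t", index=False)
    return paths


# ---------------------------------------------------------------------------
# Desk-scale pipeline runs over simulated data


@dataclass
class PipelineResult:
    occurrences: list[MotifOccurrence]
    homologs: list[HomologRecord]
    spectrum: VariantSpectrum
    pre_gbs_total: int
    pre_gbs_unique: int
    regulatory_table: ContingencyTable2x2 | None
    fisher_p: float
    labels: dict[tuple[str, int, int], bool]


def analyze_dataset(ds: SimulatedDataset, species: str = TGT_GENOME) -> PipelineResult:
    """Run scan → homologs → classify → annotate → tests on one dataset."""
    motif = compile_motif(GR_MOTIF_PATTERN)
    occurrences = scan_genome(motif, [ds.ref], source_genome=REF_GENOME)
    homologs = collect_homologs(occurrences, [ds.block], species)
    spectra = tally_spectra(homologs, motif)
    spectrum = spectra.get(species, VariantSpectrum(species))
    _, total, unique = select_pre_gbs(homologs, motif)

    reg_labels, _ = classify_regulatory(occurrences, {"regulatory": ds.regulatory_track})
    labels = labels_by_key(occurrences, reg_labels)
    cells = {"reg": {"G": 0, "CT": 0}, "nonreg": {"G": 0, "CT": 0}}
    from .variants import classify_homolog  # local to avoid cycle at import time

    for rec in homologs:
        if rec.status != "ok":
            continue
        vc = classify_homolog(rec.homolog_seq, motif)
        if vc.pooled_nt is None:
            continue
        row = "reg" if labels.get(rec.occurrence.key, False) else "nonreg"
        cells[row]["G" if vc.pooled_nt == "G" else "CT"] += 1
    if any(cells[row][col] for row in cells for col in ("G", "CT")):
        table = ContingencyTable2x2(
            cells["reg"]["G"], cells["reg"]["CT"],
            cells["nonreg"]["G"], cells["nonreg"]["CT"],
        )
        fisher_p = fisher_one_sided(table).p_value
    else:
        table = None
        fisher_p = float("nan")
    return PipelineResult(
        occurrences, homologs, spectrum, total, unique, table, fisher_p, labels
    )


def recovery_experiment(
    lams: Sequence[float],
    config: SimulationConfig | None = None,
    seed: int = 0,
    replicates: int = 3,
) -> pd.DataFrame:
    """Measure pooled-G recovery across a deamination-multiplier grid.

    For each lambda, ``replicates`` independent genomes are generated and
    their variant spectra pooled before computing the G fraction and the
    uniformity chi-square — replication stabilizes the desk-scale spectra
    without touching the per-genome study conditions.
    """
    base = config or SimulationConfig()
    rows = []
    for lam_index, lam in enumerate(lams):
        counts = {"C": 0, "G": 0, "T": 0}
        for rep in range(replicates):
            cfg = replace(base, lam=float(lam))
            ds = simulate_dataset(cfg, seed=seed + 1000 * lam_index + rep)
            result = analyze_dataset(ds)
            for nt in counts:
                counts[nt] += result.spectrum.counts[nt]
        n = sum(counts.values())
        chi2 = chisq_uniform(counts) if n else None
        rows.append(
            {
                "lambda": lam,
                "n_variants": n,
                "count_C": counts["C"],
                "count_G": counts["G"],
                "count_T": counts["T"],
                "fraction_G": counts["G"] / n if n else float("nan"),
                "chi2_statistic": chi2.statistic if chi2 else float("nan"),
                "chi2_p": chi2.p_value if chi2 else float("nan"),
                "chi2_stars": chi2.stars if chi2 else "",
            }
        )
    return pd.DataFrame(rows)


def regulatory_power_experiment(
    config: SimulationConfig,
    n_replicates: int = 100,
    seed: int = 0,
    alpha: float = 0.05,
) -> tuple[float, list[float]]:
    """Fraction of replicate genomes where the one-sided Fisher test rejects."""
    p_values = []
    for rep in range(n_replicates):
        ds = simulate_dataset(config, seed=seed + rep)
        p_values.append(analyze_dataset(ds).fisher_p)
    rejections = sum(1 for p in p_values if p < alpha)
    return rejections / n_replicates, p_values
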