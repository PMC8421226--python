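"""The three statistical procedures of the analysis.

* Chi-square goodness of fit of the pooled C/G/T variant spectrum against
  a uniform null (df=2) — flags genomes with an excess of CG→CA
  transitions.  Significance stars follow the figure-legend thresholds:
  ``**`` for P < 0.0001 and ``*`` for 0.0001 <= P < 0.005.
* Fisher's one-sided exact test on the 2x2 table (regulatory /
  non-regulatory) x (pooled G / pooled C+T), alternative: the regulatory
  row is enriched for pooled G (star at P < 0.05).
* The upper hypergeometric tail P(X >= k) used for the genome-wide
  regulatory-overlap significance, evaluated in log space so it is safe at
  genome scale.

The uniform chi-square null is an interpretive choice (the original
three-category display does not state its contrast) and is isolated here
so it can be swapped.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd
from scipy import stats as sps

from .annotate import RegulatoryLabel
from .homolog import HomologRecord
from .motif import DegenerateMotif
from .variants import VariantSpectrum, classify_homolog

#: Figure-legend star thresholds for the chi-square test.
CHI2_STAR_STRONG = 1e-4
CHI2_STAR_WEAK = 5e-3
FISHER_STAR = 0.05


@dataclass(frozen=True)
class TestResult:
    p_value: float
    statistic: float | None = None
    df: int | None = None
    stars: str = ""

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value out of range: {self.p_value}")


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Rows: regulatory / non-regulatory; columns: pooled G / pooled C+T."""

    a: int  # regulatory, G
    b: int  # regulatory, C+T
    c: int  # non-regulatory, G
    d: int  # non-regulatory, C+T

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("negative cell count")
        if self.a + self.b + self.c + self.d == 0:
            raise ValueError("empty table")


def _chi2_stars(p: float) -> str:
    if p < CHI2_STAR_STRONG:
        return "**"
    if p < CHI2_STAR_WEAK:
        return "*"
    return ""


def chisq_uniform(counts: Mapping[str, int]) -> TestResult:
    """Goodness of fit of {C,G,T} variant counts against uniform (df=2)."""
    observed = [counts.get(nt, 0) for nt in "CGT"]
    total = sum(observed)
    if total == 0:
        raise ValueError("chi-square test needs at least one observation")
    statistic, p = sps.chisquare(observed)
    return TestResult(p_value=float(p), statistic=float(statistic), df=2,
                      stars=_chi2_stars(float(p)))


def fisher_one_sided(table: ContingencyTable2x2) -> TestResult:
    """Exact one-sided test: regulatory row enriched for pooled G.

    Degenerate margins (an all-zero row or column) give p=1 by convention.
    """
    _, p = sps.fisher_exact(
        [[table.a, table.b], [table.c, table.d]], alternative="greater"
    )
    p = float(p)
    return TestResult(p_value=p, stars="*" if p < FISHER_STAR else "")


def hypergeom_tail(N: int, K: int, n: int, k: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n), computed in log space.

    N: population size; K: successes in the population; n: draws;
    k: observed successes.  k beyond min(K, n) yields 0 (empty tail).
    """
    if not (0 <= K <= N and 0 <= n <= N and 0 <= k):
        raise ValueError(f"inconsistent parameters N={N} K={K} n={n} k={k}")
    if k == 0:
        return 1.0
    if k > min(K, n):
        return 0.0
    # survival function; scipy evaluates the tail stably via log pmf sums
    return float(sps.hypergeom.sf(k - 1, N, K, n))


def spectrum_report(
    records: Iterable[HomologRecord],
    motif: DegenerateMotif,
    labels: Mapping[tuple[str, int, int], bool] | None = None,
) -> pd.DataFrame:
    """Assemble per-species variant fractions and both tests into a table.

    ``labels`` maps a human occurrence key (chrom, start, end) to its
    regulatory status; when omitted the Fisher columns are NA.  Species
    with zero pooled variants get NA p-values.
    """
    per_species: dict[str, dict] = {}
    for rec in records:
        if rec.status != "ok":
            continue
        acc = per_species.setdefault(
            rec.species,
            {"spectrum": VariantSpectrum(rec.species),
             "reg": {"G": 0, "CT": 0}, "nonreg": {"G": 0, "CT": 0}},
        )
        vc = classify_homolog(rec.homolog_seq, motif)
        spec = acc["spectrum"]
        if vc.kind == "identical":
            spec.identical_count += 1
        elif vc.kind == "other":
            spec.other_count += 1
        else:
            spec.counts[vc.pooled_nt] += 1
            if labels is not None:
                row = "reg" if labels.get(rec.occurrence.key, False) else "nonreg"
                acc[row]["G" if vc.pooled_nt == "G" else "CT"] += 1

    rows = []
    for species in sorted(per_species):
        acc = per_species[species]
        spec: VariantSpectrum = acc["spectrum"]
        n = spec.n_variants
        row = {
            "species": species,
            "n_homologs": spec.total,
            "n_variants": n,
            "fraction_C": spec.counts["C"] / n if n else math.nan,
            "fraction_G": spec.counts["G"] / n if n else math.nan,
            "fraction_T": spec.counts["T"] / n if n else math.nan,
            "chi2_p": math.nan,
            "chi2_stars": "",
            "reg_G": acc["reg"]["G"],
            "reg_CT": acc["reg"]["CT"],
            "nonreg_G": acc["nonreg"]["G"],
            "nonreg_CT": acc["nonreg"]["CT"],
            "fisher_p": math.nan,
            "fisher_stars": "",
        }
        if n:
            chi2 = chisq_uniform(spec.counts)
            row["chi2_p"], row["chi2_stars"] = chi2.p_value, chi2.stars
            if labels is not None and (
                acc["reg"]["G"] + acc["reg"]["CT"] + acc["nonreg"]["G"] + acc["nonreg"]["CT"]
            ):
                fisher = fisher_one_sided(
                    ContingencyTable2x2(
                        acc["reg"]["G"], acc["reg"]["CT"],
                        acc["nonreg"]["G"], acc["nonreg"]["CT"],
                    )
                )
                row["fisher_p"], row["fisher_stars"] = fisher.p_value, fisher.stars
        rows.append(row)
    return pd.DataFrame(rows)


def labels_by_key(
    occurrences, regulatory_labels: Iterable[RegulatoryLabel]
) -> dict[tuple[str, int, int], bool]:
    """Zip occurrences with their labels into the mapping spectrum_report wants."""
    return {
        occ.key: lab.regulatory for occ, lab in zip(occurrences, regulatory_labels)
    }
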