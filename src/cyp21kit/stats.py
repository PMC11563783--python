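"""Cohort-level statistics: allele spectrum, genotype-phenotype tables,
concordance, positive predictive rates and tie-corrected Spearman rank
correlation.

All denominators follow the allele-counting convention of the source cohort:
rates are per *allele* (2 x n patients), so a duplicated allele counts once
even though it carries an extra gene copy.  Patients whose genotype group is
D (unknown-effect variant) are excluded from the genotype-phenotype
cross-tabulation, the concordance rate, the positive predictive rates and
the rank correlation: no phenotype expectation exists for them.

The Spearman statistic is computed from first principles (mid-ranks for
ties, then the product-moment correlation of the rank vectors) rather than
delegated to a statistics library; the test-suite cross-checks it against
both a brute-force counting oracle and an independent library routine.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .alleles import AlleleSpec, Category
from .errors import UndefinedStatisticError
from .grouping import (
    GenotypeRecord,
    Phenotype,
    SeverityClass,
    expected_phenotype,
    group_of_record,
)
from .locus import LocusModel

__all__ = [
    "CrossTab",
    "CohortStats",
    "allele_key",
    "allele_frequency_table",
    "category_proportions",
    "crosstab_group_phenotype",
    "concordance_rate",
    "positive_predictive_rate",
    "spearman_tie_corrected",
    "midranks",
    "compute_cohort_stats",
    "GROUP_CODES",
    "PHENOTYPE_CODES",
]

GROUPS = (SeverityClass.NULL, SeverityClass.A, SeverityClass.B, SeverityClass.C)
PHENOTYPES = (Phenotype.SW, Phenotype.SV, Phenotype.NC)

#: ordinal codings used for the rank correlation (only the order matters)
GROUP_CODES = {SeverityClass.NULL: 1, SeverityClass.A: 2, SeverityClass.B: 3, SeverityClass.C: 4}
PHENOTYPE_CODES = {Phenotype.SW: 1, Phenotype.SV: 2, Phenotype.NC: 3}


@dataclass(frozen=True)
class CrossTab:
    """Genotype-group x phenotype counts over group-classified patients."""

    counts: pd.DataFrame  # index Null/A/B/C, columns SW/SV/NC

    @property
    def n_classified(self) -> int:
        return int(self.counts.to_numpy().sum())

    def cell(self, group: SeverityClass, phenotype: Phenotype) -> int:
        return int(self.counts.loc[group.value, phenotype.value])


@dataclass(frozen=True)
class CohortStats:
    allele_counts: pd.DataFrame
    total_alleles: int
    category_proportions: Dict[str, float]
    crosstab: CrossTab
    concordance: float
    ppv: Dict[str, float]
    rho: float


def allele_key(a: AlleleSpec) -> str:
    """Frequency-table key: structural subtype, or the joined token list."""
    if a.category in (Category.DELETION, Category.DUPLICATION):
        return a.subtype or "UNCLASSIFIED"
    return "+".join(a.variants)


def _all_alleles(records: Sequence[GenotypeRecord]) -> List[Tuple[str, AlleleSpec]]:
    out = []
    for r in records:
        out.append((r.patient_id, r.allele1))
        out.append((r.patient_id, r.allele2))
    return out


def allele_frequency_table(records: Sequence[GenotypeRecord]) -> pd.DataFrame:
    """Per-allele-class counts and rates (denominator: 2 x n patients).

    Raises ValueError listing the offending patient ids if any structural
    allele lacks a classified subtype.
    """
    alleles = _all_alleles(records)
    bad = sorted(
        {pid for pid, a in alleles
         if a.category in (Category.DELETION, Category.DUPLICATION) and a.subtype is None}
    )
    if bad:
        raise ValueError(f"unclassified structural alleles for patients: {bad}")
    denom = len(alleles)
    counts: Dict[str, int] = {}
    for _, a in alleles:
        key = allele_key(a)
        counts[key] = counts.get(key, 0) + 1
    df = pd.DataFrame(
        {"count": pd.Series(counts, dtype=int)}
    ).sort_values("count", ascending=False)
    df["rate"] = df["count"] / denom if denom else 0.0
    df.index.name = "allele"
    return df


def category_proportions(records: Sequence[GenotypeRecord]) -> Dict[str, float]:
    """Taxonomy-category fractions of all alleles, with deletion sub-splits.

    ``deletion_complete`` covers whole-gene losses (solo deletions and CAH-X
    TNXA/TNXB chimeras); ``deletion_partial_chimera`` the CYP21A1P/CYP21A2
    partial chimeras.
    """
    alleles = [a for _, a in _all_alleles(records)]
    n = len(alleles)
    if n == 0:
        return {k: 0.0 for k in (
            "microconversion", "novel_variant", "deletion",
            "deletion_complete", "deletion_partial_chimera", "duplication")}
    def frac(pred):
        return sum(1 for a in alleles if pred(a)) / n
    complete = frac(
        lambda a: a.category == Category.DELETION
        and (a.subtype == "DEL_SOLO" or (a.subtype or "").startswith("CAHX_"))
    )
    partial = frac(
        lambda a: a.category == Category.DELETION
        and a.subtype is not None
        and a.subtype.startswith("CH")
    )
    return {
        "microconversion": frac(lambda a: a.category == Category.MICROCONVERSION),
        "novel_variant": frac(lambda a: a.category == Category.NOVEL_VARIANT),
        "deletion": frac(lambda a: a.category == Category.DELETION),
        "deletion_complete": complete,
        "deletion_partial_chimera": partial,
        "duplication": frac(lambda a: a.category == Category.DUPLICATION),
    }


def crosstab_group_phenotype(
    model: LocusModel, records: Sequence[GenotypeRecord]
) -> CrossTab:
    """4x3 genotype-group x phenotype counts; group-D patients are excluded."""
    counts = pd.DataFrame(
        0,
        index=[g.value for g in GROUPS],
        columns=[p.value for p in PHENOTYPES],
        dtype=int,
    )
    for r in records:
        g = group_of_record(model, r)
        if g == SeverityClass.D or r.phenotype == Phenotype.UNKNOWN:
            continue
        counts.loc[g.value, r.phenotype.value] += 1
    return CrossTab(counts=counts)


def concordance_rate(ct: CrossTab) -> float:
    """Fraction of classified patients whose phenotype matches their group's
    expected phenotype."""
    n = ct.n_classified
    if n == 0:
        raise UndefinedStatisticError("concordance undefined on an empty cross-tab")
    hits = sum(ct.cell(g, expected_phenotype(g)) for g in GROUPS)
    return hits / n


def positive_predictive_rate(ct: CrossTab, group: SeverityClass) -> float:
    """Within one genotype group, the fraction showing the expected phenotype."""
    row = ct.counts.loc[group.value]
    total = int(row.sum())
    if total == 0:
        raise UndefinedStatisticError(f"no patients in group {group.value}")
    return ct.cell(group, expected_phenotype(group)) / total


# ---------------------------------------------------------------------------
# tie-corrected Spearman


def midranks(values: Sequence[float]) -> np.ndarray:
    """Mid-ranks (1-based; tied values share the mean of their rank block)."""
    x = np.asarray(values, dtype=float)
    order = np.argsort(x, kind="stable")
    ranks = np.empty(len(x), dtype=float)
    i = 0
    while i < len(x):
        j = i
        while j + 1 < len(x) and x[order[j + 1]] == x[order[i]]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    return ranks


def spearman_tie_corrected(pairs: Sequence[Tuple[float, float]]) -> float:
    """Spearman rank correlation with mid-rank tie handling.

    Computed from the definition: replace each margin by its mid-ranks and
    take the product-moment correlation of the two rank vectors.

    Raises UndefinedStatisticError for n < 2 or a zero-variance margin.
    """
    if len(pairs) < 2:
        raise UndefinedStatisticError("rank correlation needs at least two pairs")
    x = midranks([p[0] for p in pairs])
    y = midranks([p[1] for p in pairs])
    dx = x - x.mean()
    dy = y - y.mean()
    sxx = float(dx @ dx)
    syy = float(dy @ dy)
    if sxx == 0.0 or syy == 0.0:
        raise UndefinedStatisticError("rank correlation undefined for a constant margin")
    return float(dx @ dy) / (sxx * syy) ** 0.5


# ---------------------------------------------------------------------------
# one-call summary


def compute_cohort_stats(
    model: LocusModel, records: Sequence[GenotypeRecord]
) -> CohortStats:
    """All cohort-level statistics in one pass."""
    freq = allele_frequency_table(records)
    ct = crosstab_group_phenotype(model, records)
    pairs = []
    for r in records:
        g = group_of_record(model, r)
        if g == SeverityClass.D or r.phenotype == Phenotype.UNKNOWN:
            continue
        pairs.append((GROUP_CODES[g], PHENOTYPE_CODES[r.phenotype]))
    return CohortStats(
        allele_counts=freq,
        total_alleles=2 * len(records),
        category_proportions=category_proportions(records),
        crosstab=ct,
        concordance=concordance_rate(ct),
        ppv={g.value: positive_predictive_rate(ct, g) for g in GROUPS
             if int(ct.counts.loc[g.value].sum()) > 0},
        rho=spearman_tie_corrected(pairs),
    )
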