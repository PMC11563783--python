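"""Diploid severity grouping and expected phenotype.

21-OHD genotypes are tiered Null/A/B/C by in-vitro residual 21-hydroxylase
activity of the constituent alleles (Null ~0%, A <1%, B 1-2%, C 20-60%), with
class D for variants of unknown effect.  Because one working-enough allele
suffices in a recessive disease, the diploid group is set by the *milder* of
the two alleles; any allele of unknown effect makes the genotype group D.

Allele-level rules encoded here:

* whole-gene deletions (solo and CAH-X) score Null;
* every I2G-carrying partial chimera (CH1/2/3/5/6/7/8) scores Null - the
  cohort evidence forces this below class A: an I2G/CH1 genotype groups A
  and an p.R357W/CH1 genotype groups Null, which is only consistent if the
  chimera itself is Null;
* the promoter-only chimeras CH4/CH9 (promoter conversion + p.P31L) score C;
* point-variant alleles score the most severe class among their tokens; an
  unrecognized token makes the allele class D unless a known Null-class token
  is already present (nothing can be more severe than Null);
* duplicated alleles that retain an intact extra CYP21A2 copy score C by
  default - the intact copy rescues complete loss of function, leaving the
  mild residual impairment observed in the cohort's duplication carriers -
  while a CYP21A2/CYP21A1P chimera without an intact extra copy scores by
  its tokens like a point allele.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional, Tuple

from .alleles import AlleleSpec, Category
from .locus import I2G_CARRYING_CHIMERAS, LocusModel

__all__ = [
    "SeverityClass",
    "Phenotype",
    "GenotypeRecord",
    "severity_of_allele",
    "assign_group",
    "expected_phenotype",
    "group_of_record",
]


class SeverityClass(str, enum.Enum):
    """Ordinal severity tiers; NULL < A < B < C by residual activity, D incomparable."""

    NULL = "Null"
    A = "A"
    B = "B"
    C = "C"
    D = "D"

    @property
    def rank(self) -> int:
        """Position in the residual-activity order (D has none)."""
        order = {"Null": 0, "A": 1, "B": 2, "C": 3}
        if self.value not in order:
            raise ValueError("class D has no position in the severity order")
        return order[self.value]


class Phenotype(str, enum.Enum):
    SW = "SW"  # salt wasting
    SV = "SV"  # simple virilizing
    NC = "NC"  # non-classic
    UNKNOWN = "UNKNOWN"


@dataclass(frozen=True)
class GenotypeRecord:
    """One patient: two structurally resolved alleles plus clinical fields.

    ``lrs_calls`` / ``conv_calls`` hold the verbatim per-allele report strings
    of the long-read assay and of the conventional MLPA+Long-PCR assay (when
    recorded); the severity group is always recomputable from the alleles.
    """

    patient_id: str
    sex: str  # M | F
    age_years: float
    phenotype: Phenotype
    allele1: AlleleSpec
    allele2: AlleleSpec
    lrs_calls: Optional[Tuple[str, str]] = None
    conv_calls: Optional[Tuple[str, str]] = None
    group_reported: Optional[SeverityClass] = None
    notes: str = ""

    @property
    def alleles(self) -> Tuple[AlleleSpec, AlleleSpec]:
        return (self.allele1, self.allele2)


_SEVERITY_KEY = {"NULL": SeverityClass.NULL, "A": SeverityClass.A,
                 "B": SeverityClass.B, "C": SeverityClass.C}


def _point_class(model: LocusModel, tokens) -> SeverityClass:
    classes = []
    unknown = False
    for tok in tokens:
        cls = model.severity_class(tok)
        if cls is None:
            unknown = True
        else:
            classes.append(_SEVERITY_KEY[cls])
    if not classes:
        return SeverityClass.D
    most_severe = min(classes, key=lambda c: c.rank)
    if unknown and most_severe != SeverityClass.NULL:
        # an unscored token could be anything up to Null; only a known Null
        # token already dominates every possibility
        return SeverityClass.D
    return most_severe


def severity_of_allele(
    model: LocusModel,
    a: AlleleSpec,
    dup_rescued_class: SeverityClass = SeverityClass.C,
) -> SeverityClass:
    """Severity class of one allele (never raises; D is the fallback)."""
    if a.category == Category.DELETION:
        if a.subtype in ("DEL_SOLO",) or (a.subtype or "").startswith("CAHX_"):
            return SeverityClass.NULL
        if a.subtype in I2G_CARRYING_CHIMERAS:
            return SeverityClass.NULL
        if a.subtype in ("CH4", "CH9"):
            return SeverityClass.C
        return SeverityClass.D  # unclassified structural allele
    if a.category == Category.DUPLICATION:
        if a.has_intact_copy:
            return dup_rescued_class
        return _point_class(model, a.variants)
    return _point_class(model, a.variants)


def assign_group(a1: SeverityClass, a2: SeverityClass) -> SeverityClass:
    """Diploid group: the milder allele rules; class D dominates everything."""
    if SeverityClass.D in (a1, a2):
        return SeverityClass.D
    return max(a1, a2, key=lambda c: c.rank)


def expected_phenotype(group: SeverityClass) -> Phenotype:
    """Phenotype each genotype group predicts (Null/A -> SW, B -> SV, C -> NC)."""
    return {
        SeverityClass.NULL: Phenotype.SW,
        SeverityClass.A: Phenotype.SW,
        SeverityClass.B: Phenotype.SV,
        SeverityClass.C: Phenotype.NC,
        SeverityClass.D: Phenotype.UNKNOWN,
    }[group]


def group_of_record(model: LocusModel, record: GenotypeRecord) -> SeverityClass:
    """Recompute a patient's genotype group from the two alleles."""
    return assign_group(
        severity_of_allele(model, record.allele1),
        severity_of_allele(model, record.allele2),
    )
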