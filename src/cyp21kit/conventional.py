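"""In-silico MLPA + Long-PCR reporting for a true diploid genotype.

The conventional work-up this module emulates combines two assays:

* **MLPA** measures probe dosage at six CYP21A2 landmarks (exons 1, 3, 4, 6,
  7 and the intron-2 splice site) and six TNXB probes (exon 35 twice, exons
  19/20/29/31).  Exons 2, 5, 8, 9, 10 and TNXB exons 40-44 carry no probe, so
  deletion spans over those regions are inferences, not observations.
* **Long-PCR sequencing** amplifies the active gene and reports point
  variants, but cannot type structural junctions and occasionally masks
  variants sitting on pseudogene-derived segments (the promoter conversion of
  CH4, the exon-1 conversion of CH6, p.V282L on an integrated exon 7-8 copy).

Because the probe panel is blind outside its landmarks, structurally distinct
alleles collapse onto identical reports: all three CAH-X TNXA/TNXB chimeras
print as ``Exon 1-10 Del``, and a CH1 chimera prints as ``Exon 1-3 Del``.
The per-structure report strings are encoded in :data:`CANONICAL_DELETION_CALL`
(validated in the test-suite against the span-inference rule where the two
agree) and reproduce the conventional-assay column of the reference cohort.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Tuple

from .alleles import AlleleSpec, Category
from .grouping import GenotypeRecord
from .io import calls_equivalent
from .locus import LocusModel

__all__ = [
    "DropoutVector",
    "ConventionalReport",
    "allele_site_presence",
    "simulate_probe_dropout",
    "render_deletion_call",
    "render_longpcr_call",
    "render_lrs_call",
    "simulate_report",
    "compare_reports",
    "cohort_discordances",
    "CANONICAL_DELETION_CALL",
]

#: Reported deletion string per catalogued structural subtype (None: the
#: conventional work-up reports point variants instead of a deletion).
CANONICAL_DELETION_CALL: Dict[str, Optional[str]] = {
    "DEL_SOLO": "Exon 1-10 Del",
    "CAHX_CH1": "Exon 1-10 Del",
    "CAHX_CH2": "Exon 1-10 Del",
    "CAHX_CH3": "Exon 1-10 Del",
    "CH1": "Exon 1-3 Del",
    "CH2": "Exon 1-4 Del",
    "CH3": "Exon 1-7 Del",
    "CH4": None,  # reported as p.P31L
    "CH6": None,  # reported as I2G
    "CH8": "Exon 1-10 Del",
    "DUP_E7E8": None,  # reported as the point variants minus p.V282L
}

#: Long-PCR point-variant masking per structural subtype.
_LONGPCR_STRUCTURAL_TOKENS: Dict[str, Tuple[str, ...]] = {
    "CH4": ("p.P31L",),
    "CH6": ("I2G",),
}


@dataclass(frozen=True)
class DropoutVector:
    """Diploid copy-dosage per probed site (0, 1, 2 or 3+)."""

    dosages: Tuple[Tuple[str, int], ...]  # (site_id, dosage), panel order

    def dosage(self, site_id: str) -> int:
        for s, d in self.dosages:
            if s == site_id:
                return d
        raise KeyError(site_id)

    @property
    def calls(self) -> Tuple[Tuple[str, str], ...]:
        return tuple((s, "3+" if d >= 3 else str(d)) for s, d in self.dosages)


@dataclass(frozen=True)
class ConventionalReport:
    """Simulated MLPA + Long-PCR result for one diploid genotype.

    The assay itself is unphased; per-allele attribution of the calls mirrors
    how such results are recorded once parental origin is established, and
    ``phase_known`` stays False unless parental genomes were supplied.
    """

    patient_id: str
    allele_calls: Tuple[str, str]
    dropout: DropoutVector
    unphased: bool = True
    phase_known: bool = False


def allele_site_presence(model: LocusModel, a: AlleleSpec) -> Dict[str, int]:
    """Gene-origin copy count contributed by one allele at every model site.

    Pseudogene-converted spans and deleted genes contribute 0 at their sites;
    a duplicated allele contributes one count per copy.  Point-variant alleles
    retain gene dosage everywhere except at mutation-specific probe landmarks
    (the intron-2 splice probe, the exon-3 8 bp-deletion site) whose target
    sequence a pseudogene-derived conversion destroys.
    """
    presence = {s.site_id: 1 for s in model.sites}
    if a.category == Category.DELETION:
        ch = model.chimeras.get(a.subtype) if a.subtype else None
        if ch is None:
            # unclassified structural loss: treat as whole-gene absent
            for s in model.cyp21a2_sites:
                presence[s.site_id] = 0
        elif ch.whole_gene_absent:
            for s in model.cyp21a2_sites:
                presence[s.site_id] = 0
            if "TNXB_E35_120bp_del" in ch.tnxb_signature:
                presence["TNXB_E35"] = 0
        elif ch.span_end is not None:
            end = model.order(ch.span_end)
            for s in model.cyp21a2_sites:
                if s.order_index < end or (ch.partial_end and s.order_index == end):
                    presence[s.site_id] = 0
        return presence
    if a.category == Category.DUPLICATION:
        return {s.site_id: a.n_copies for s in model.sites}
    # point-variant allele: only mutation-specific landmarks lose their target
    for tok in a.variants:
        canon = model.canonical_token(tok)
        site = model.variant_sites.get(canon)
        if site in ("I2G_SITE", "DEL8BP_SITE") and canon in model.pseudogene_derived:
            presence[site] = 0
    return presence


def simulate_probe_dropout(model: LocusModel, g: GenotypeRecord) -> DropoutVector:
    """Diploid probe dosage: the sum of both alleles' gene-origin presence."""
    p1 = allele_site_presence(model, g.allele1)
    p2 = allele_site_presence(model, g.allele2)
    panel = model.probe_panel.probed_sites
    return DropoutVector(dosages=tuple((s, p1[s] + p2[s]) for s in panel))


def _missing_probed_exons(model: LocusModel, a: AlleleSpec) -> Tuple[int, ...]:
    presence = allele_site_presence(model, a)
    return tuple(
        model.exon_number(s)
        for s in model.probe_panel.probed_a2_exons
        if presence[s] == 0
    )


def render_deletion_call(
    model: LocusModel, a: AlleleSpec, style: str = "span"
) -> Optional[str]:
    """Deletion string the conventional work-up reports for one allele.

    ``style="span"`` (default) gives the span-inferred report: for catalogued
    structures, the validated canonical string; for any other dropout
    pattern, the minimal span from the first through the last missing probed
    exon, extended to exon 10 when no CYP21A2 probe remains downstream.
    ``style="probes"`` lists the missing probed exons verbatim with no span
    inference (the raw per-probe reading some laboratories print).
    Returns None when no deletion is reported.
    """
    missing = _missing_probed_exons(model, a)
    if style == "probes":
        if not missing:
            return None
        return f"Exon {', '.join(str(x) for x in missing)} Del"
    if a.subtype in CANONICAL_DELETION_CALL:
        return CANONICAL_DELETION_CALL[a.subtype]
    if not missing:
        return None
    first, last = missing[0], missing[-1]
    probed = [model.exon_number(s) for s in model.probe_panel.probed_a2_exons]
    if not any(x > last for x in probed):
        last = 10
    return f"Exon {first} Del" if first == last else f"Exon {first}-{last} Del"


def _mask_longpcr_tokens(model: LocusModel, tokens: Sequence[str]) -> Tuple[str, ...]:
    out = []
    for tok in tokens:
        canon = model.canonical_token(tok)
        if canon == "UTR5":
            continue  # promoter conversion is not reported by Long-PCR
        out.append(tok)
    return tuple(out)


def render_longpcr_call(model: LocusModel, a: AlleleSpec) -> Tuple[str, ...]:
    """Point-variant tokens Long-PCR sequencing reports for one allele.

    Masking rules: the CH4 chimera yields only p.P31L (its promoter
    conversion goes unreported), CH6 yields only I2G, duplicated exon 7-8
    integrations drop p.V282L (Long-PCR off-target), and promoter tokens are
    never echoed.  Idempotent: re-rendering an allele built from the output
    tokens returns them unchanged.
    """
    if a.category == Category.DELETION:
        return _LONGPCR_STRUCTURAL_TOKENS.get(a.subtype or "", ())
    if a.category == Category.DUPLICATION:
        toks = [
            t for t in a.variants if model.canonical_token(t) != "p.V282L"
        ]
        return _mask_longpcr_tokens(model, toks)
    return _mask_longpcr_tokens(model, a.variants)


def render_lrs_call(model: LocusModel, a: AlleleSpec) -> str:
    """Default long-read-assay call string for one allele.

    Used when a cohort record does not carry a verbatim long-read string
    (synthetic cohorts); real records keep their printed strings.
    """
    if a.category == Category.DELETION:
        sub = a.subtype or ""
        if sub == "DEL_SOLO":
            return "del (CYP21A2)"
        if sub.startswith("CAHX_"):
            return f"del (CAH-X-{sub[5:]})"
        ch = model.chimeras.get(sub)
        if ch is not None and ch.span_end is not None:
            end = model.order(ch.span_end)
            exons = [
                model.exon_number(s.site_id)
                for s in model.exon_sites
                if s.order_index < end or (ch.partial_end and s.order_index == end)
            ]
            last = max(exons)
            part = "part of " if ch.partial_end else ""
            span = f"exon 1-{last}" if last > 1 else "exon 1"
            return f"UTR5, {part}{span} ({sub})"
        return f"chimera ({sub})"
    if a.category == Category.DUPLICATION and a.has_intact_copy:
        return f"Exon 7-8 integration ({', '.join(a.variants)})"
    return ", ".join(a.variants)


def simulate_report(model: LocusModel, g: GenotypeRecord) -> ConventionalReport:
    """Predict the full MLPA + Long-PCR report for one patient."""
    calls = []
    for a in g.alleles:
        deletion = render_deletion_call(model, a)
        if deletion is not None:
            calls.append(deletion)
        else:
            toks = render_longpcr_call(model, a)
            calls.append(", ".join(toks) if toks else "negative")
    return ConventionalReport(
        patient_id=g.patient_id,
        allele_calls=(calls[0], calls[1]),
        dropout=simulate_probe_dropout(model, g),
    )


def compare_reports(
    model: LocusModel,
    truth: GenotypeRecord,
    conv: ConventionalReport,
    recorded_overrides: Optional[Dict[Tuple[str, int], str]] = None,
) -> Tuple[bool, ...]:
    """Per-allele discordance flags between the long-read truth and a
    conventional report.

    ``recorded_overrides`` maps ``(patient_id, allele_index)`` to a replacement
    conventional string, injecting dataset facts no probe model can predict
    (a sporadically missed point call, a donor-sperm pregnancy leaving the
    paternal allele origin unresolvable).

    Raises ValueError when the two reports name different patients.
    """
    if conv.patient_id != truth.patient_id:
        raise ValueError(
            f"patient id mismatch: truth {truth.patient_id!r} vs report {conv.patient_id!r}"
        )
    flags = []
    for idx, allele in enumerate(truth.alleles):
        lrs = (
            truth.lrs_calls[idx]
            if truth.lrs_calls is not None
            else render_lrs_call(model, allele)
        )
        conv_str = conv.allele_calls[idx]
        if recorded_overrides:
            conv_str = recorded_overrides.get((truth.patient_id, idx), conv_str)
        flags.append(not calls_equivalent(lrs, conv_str, model))
    return tuple(flags)


def cohort_discordances(
    model: LocusModel,
    records: Sequence[GenotypeRecord],
    use_recorded: bool = True,
    recorded_overrides: Optional[Dict[Tuple[str, int], str]] = None,
) -> int:
    """Total discordant allele-level results over a cohort.

    ``use_recorded=True`` compares the long-read calls against the recorded
    conventional-assay columns (skipping records without them);
    ``use_recorded=False`` compares against the simulator's predictions.
    """
    total = 0
    for r in records:
        if use_recorded:
            if r.conv_calls is None:
                continue
            conv = ConventionalReport(
                patient_id=r.patient_id,
                allele_calls=r.conv_calls,
                dropout=simulate_probe_dropout(model, r),
            )
        else:
            conv = simulate_report(model, r)
        total += sum(compare_reports(model, r, conv, recorded_overrides))
    return total
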