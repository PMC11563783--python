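"""Synthetic 21-OHD cohort generation.

The generator draws diploid genotypes from the reference cohort's empirical
allele spectrum (two independent allele draws per patient - a Hardy-Weinberg
-like pairing, the simplest defensible null given that no mating or
ascertainment structure is known), derives the severity group, samples the
phenotype from the group-conditional phenotype distribution observed in the
reference cohort, and produces the paired conventional-assay report through
the probe-panel simulator.  Reporting artifacts seen in real data can be
injected at configurable rates:

* ``missed_point_call`` - a point variant sporadically dropped from the
  conventional report (as happens when one parental variant escapes the
  Long-PCR read-out);
* ``phase_unavailable`` - a patient whose allele parental origin the
  unphased assay cannot resolve (e.g. a donor-sperm pregnancy).

Group-D genotypes have no phenotype expectation, so their phenotype is drawn
uniformly and the record is flagged; cohort statistics exclude them, matching
how such patients are handled in the reference analysis.  Everything is
reproducible from the integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .alleles import AlleleSpec
from .conventional import ConventionalReport, simulate_report, render_lrs_call
from .errors import ConfigurationError
from .grouping import (
    GenotypeRecord,
    Phenotype,
    SeverityClass,
    assign_group,
    group_of_record,
    severity_of_allele,
)
from .io import load_reference_cohort, parse_report_call
from .locus import LocusModel, load_locus_model
from .stats import GROUPS, PHENOTYPES, allele_key, crosstab_group_phenotype

__all__ = ["SimConfig", "default_sim_config", "sample_allele", "generate_cohort"]


@dataclass(frozen=True)
class SimConfig:
    """Synthetic-cohort parameters.

    ``allele_freqs`` maps allele-class keys (see :func:`~cyp21kit.stats.allele_key`)
    to draw probabilities; ``allele_variants`` maps each key to the concrete
    allele specifications it may instantiate, with weights.  Defaults are the
    reference cohort's empirical distributions.
    """

    n_patients: int
    seed: int
    allele_freqs: Dict[str, float]
    allele_variants: Dict[str, Tuple[Tuple[AlleleSpec, float], ...]]
    phenotype_given_group: Dict[SeverityClass, Dict[Phenotype, float]]
    artifact_rates: Dict[str, float] = field(
        default_factory=lambda: {"missed_point_call": 0.0, "phase_unavailable": 0.0}
    )
    sex_male_prob: float = 44 / 67
    age_pool: Tuple[float, ...] = ()

    def validate(self) -> None:
        tot = sum(self.allele_freqs.values())
        if abs(tot - 1.0) > 1e-9:
            raise ConfigurationError(f"allele_freqs sum to {tot!r}, not 1")
        if any(p < 0 for p in self.allele_freqs.values()):
            raise ConfigurationError("allele_freqs contains a negative probability")
        for g, row in self.phenotype_given_group.items():
            s = sum(row.values())
            if abs(s - 1.0) > 1e-9:
                raise ConfigurationError(
                    f"phenotype distribution for group {g.value} sums to {s!r}, not 1"
                )
        for key in self.allele_freqs:
            if key not in self.allele_variants or not self.allele_variants[key]:
                raise ConfigurationError(f"no allele variant registered for key {key!r}")
        for k, v in self.artifact_rates.items():
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"artifact rate {k}={v!r} outside [0, 1]")


def default_sim_config(
    n_patients: int,
    seed: int,
    artifact_rates: Optional[Dict[str, float]] = None,
    model: Optional[LocusModel] = None,
) -> SimConfig:
    """Build the default configuration from the packaged reference cohort."""
    model = model or load_locus_model()
    records = load_reference_cohort()

    counts: Dict[str, int] = {}
    variants: Dict[str, Dict[AlleleSpec, int]] = {}
    for r in records:
        for a in (r.allele1, r.allele2):
            key = allele_key(a)
            counts[key] = counts.get(key, 0) + 1
            variants.setdefault(key, {})
            variants[key][a] = variants[key].get(a, 0) + 1
    denom = sum(counts.values())
    freqs = {k: c / denom for k, c in counts.items()}
    allele_variants = {
        k: tuple((spec, n / counts[k]) for spec, n in specs.items())
        for k, specs in variants.items()
    }

    ct = crosstab_group_phenotype(model, records)
    cond: Dict[SeverityClass, Dict[Phenotype, float]] = {}
    for g in GROUPS:
        row = ct.counts.loc[g.value]
        total = int(row.sum())
        cond[g] = {p: (int(row[p.value]) / total if total else 0.0) for p in PHENOTYPES}

    cfg = SimConfig(
        n_patients=n_patients,
        seed=seed,
        allele_freqs=freqs,
        allele_variants=allele_variants,
        phenotype_given_group=cond,
        artifact_rates=artifact_rates
        or {"missed_point_call": 0.0, "phase_unavailable": 0.0},
        sex_male_prob=sum(1 for r in records if r.sex == "M") / len(records),
        age_pool=tuple(r.age_years for r in records),
    )
    cfg.validate()
    return cfg


_SPECTRUM_CACHE: Dict[int, tuple] = {}


def _spectrum(cfg: SimConfig) -> tuple:
    cached = _SPECTRUM_CACHE.get(id(cfg))
    if cached is None or cached[0] is not cfg:
        keys = sorted(cfg.allele_freqs)
        probs = np.array([cfg.allele_freqs[k] for k in keys])
        cached = (cfg, keys, np.cumsum(probs / probs.sum()))
        _SPECTRUM_CACHE[id(cfg)] = cached
    return cached


def sample_allele(cfg: SimConfig, rng: np.random.Generator) -> AlleleSpec:
    """Draw one allele from the configured spectrum."""
    _, keys, cum = _spectrum(cfg)
    key = keys[int(np.searchsorted(cum, rng.random(), side="right"))]
    specs = cfg.allele_variants[key]
    if len(specs) == 1:
        return specs[0][0]
    w = np.array([wt for _, wt in specs])
    return specs[int(rng.choice(len(specs), p=w / w.sum()))][0]


def _sample_phenotype(
    cfg: SimConfig, group: SeverityClass, rng: np.random.Generator
) -> Tuple[Phenotype, bool]:
    if group == SeverityClass.D:
        return PHENOTYPES[int(rng.integers(0, 3))], True
    row = cfg.phenotype_given_group[group]
    probs = np.array([row[p] for p in PHENOTYPES])
    if probs.sum() == 0:
        return PHENOTYPES[int(rng.integers(0, 3))], True
    return PHENOTYPES[int(rng.choice(3, p=probs / probs.sum()))], False


def generate_cohort(
    cfg: SimConfig, model: Optional[LocusModel] = None
) -> Tuple[List[GenotypeRecord], List[ConventionalReport]]:
    """Generate ``cfg.n_patients`` records with paired conventional reports."""
    cfg.validate()
    model = model or load_locus_model()
    rng = np.random.default_rng(cfg.seed)
    records: List[GenotypeRecord] = []
    reports: List[ConventionalReport] = []
    for i in range(cfg.n_patients):
        a1 = sample_allele(cfg, rng)
        a2 = sample_allele(cfg, rng)
        group = assign_group(
            severity_of_allele(model, a1), severity_of_allele(model, a2)
        )
        phenotype, flagged = _sample_phenotype(cfg, group, rng)
        sex = "M" if rng.random() < cfg.sex_male_prob else "F"
        age = float(rng.choice(cfg.age_pool)) if cfg.age_pool else 1.0
        notes = "phenotype drawn uniformly (group D)" if flagged else ""
        record = GenotypeRecord(
            patient_id=f"S{i + 1}",
            sex=sex,
            age_years=age,
            phenotype=phenotype,
            allele1=a1,
            allele2=a2,
            lrs_calls=(render_lrs_call(model, a1), render_lrs_call(model, a2)),
            notes=notes,
        )
        report = simulate_report(model, record)
        calls = list(report.allele_calls)
        note_bits = [notes] if notes else []

        p_miss = cfg.artifact_rates.get("missed_point_call", 0.0)
        for idx in (0, 1):
            parsed = parse_report_call(calls[idx], model)
            is_token_list = parsed[0] == "TOKENS" and len(parsed[1]) > 0
            toks = [t.strip() for t in calls[idx].split(",") if t.strip()]
            if is_token_list and toks and rng.random() < p_miss:
                drop = int(rng.integers(0, len(toks)))
                kept = toks[:drop] + toks[drop + 1 :]
                calls[idx] = ", ".join(kept) if kept else "negative"
                note_bits.append(f"missed point call on allele {idx + 1}")

        if rng.random() < cfg.artifact_rates.get("phase_unavailable", 0.0):
            idx = int(rng.integers(0, 2))
            calls[idx] = "undetermined origin"
            note_bits.append(f"allele {idx + 1} origin unresolved (unphased assay)")

        record = replace(
            record, conv_calls=(calls[0], calls[1]), notes="; ".join(note_bits)
        )
        report = ConventionalReport(
            patient_id=report.patient_id,
            allele_calls=(calls[0], calls[1]),
            dropout=report.dropout,
        )
        records.append(record)
        reports.append(report)
    return records, reports
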