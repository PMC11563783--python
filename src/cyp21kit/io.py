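"""Cohort file readers/writers and report-string normalization.

The cohort schema is a UTF-8 TSV (or JSON array) with columns::

    patient_id  sex  age_years  phenotype  allele1  allele2  extra_copy
    lrs_allele1  lrs_allele2  conv_allele1  conv_allele2  genotype_group  notes

``allele1``/``allele2`` use the allele mini-grammar (see :mod:`.alleles`);
``extra_copy`` is ``intact`` when the duplication allele of the row carries an
additional intact CYP21A2 copy; the ``lrs_*`` / ``conv_*`` columns keep the
two assays' per-allele report strings verbatim as printed by the respective
pipeline, and ``genotype_group`` is the recorded severity group (always
recomputable from the alleles).  Reading then writing a canonical file is
byte-identical.

Report strings from different pipelines spell the same call many ways
(``R357W`` vs ``p.R357W``, ``p.L308Ffs*`` vs ``p.L308Ffs*6``, legacy residue
numbering, a deletion phrased as ``del (CYP21A2)`` vs ``Exon 1-10 Del``).
:func:`parse_report_call` reduces any such string to a canonical call tuple
and :func:`normalize_report_string` to a canonical string; comparison of
assay results is done on these canonical forms.  Two semantics matter:

* a call *phrased as a deletion* (``del (...)``, ``Exon m-n Del``) is compared
  on the CYP21A2 exon span it removes, so ``del (CYP21A2)`` equals
  ``Exon 1-10 Del`` - the phrasing differs, the finding does not;
* a call naming a *structure beyond a bare exon span* (a CAH-X type with its
  TNXB signature, a CYP21A1P/CYP21A2 chimera call, an exon 7-8 integration)
  is a distinct canonical form, because the structural typing is information
  the bare deletion span does not carry;
* promoter-conversion tokens (``UTR5``) are dropped from point-variant lists:
  neither assay reports promoter status as a separate finding.
"""

from __future__ import annotations

import csv
import io as _io
import json
import re
from pathlib import Path
from typing import List, Optional, Sequence, Tuple, Union

from .alleles import AlleleSpec, format_allele, parse_allele
from .errors import CohortParseError
from .grouping import GenotypeRecord, Phenotype, SeverityClass
from .locus import LocusModel, load_locus_model

__all__ = [
    "COHORT_COLUMNS",
    "read_cohort",
    "write_cohort",
    "load_reference_cohort",
    "parse_report_call",
    "normalize_report_string",
    "calls_equivalent",
]

COHORT_COLUMNS = (
    "patient_id",
    "sex",
    "age_years",
    "phenotype",
    "allele1",
    "allele2",
    "extra_copy",
    "lrs_allele1",
    "lrs_allele2",
    "conv_allele1",
    "conv_allele2",
    "genotype_group",
    "notes",
)

_DEFAULT_MODEL: Optional[LocusModel] = None


def _default_model() -> LocusModel:
    global _DEFAULT_MODEL
    if _DEFAULT_MODEL is None:
        _DEFAULT_MODEL = load_locus_model()
    return _DEFAULT_MODEL


# ---------------------------------------------------------------------------
# report-string normalization

_FS_SUFFIX = re.compile(r"(fs)\*\d*$")
_BARE_PROTEIN = re.compile(r"^[A-Z]\d+(?:[A-Za-z*]|_[A-Z]\d+).*$")
_UTR5_PARENS = re.compile(r"UTR5\s*\([^)]*\)")


def _normalize_token(model: LocusModel, tok: str) -> str:
    """Canonicalize one variant token spelling."""

    def _known(t: str) -> bool:
        return t in model.variant_sites or t in model.severity or t in model.pseudogene_derived

    t = tok.strip()
    if not t:
        return t
    compact = t.replace(" ", "")
    if compact.startswith("c."):
        t = compact
    if t.startswith("UTR5"):
        return "UTR5"
    t = model.canonical_token(t)
    if _known(t):
        return t
    if _BARE_PROTEIN.match(t) and not t.startswith(("p.", "c.")):
        t = model.canonical_token("p." + t)
        if _known(t):
            return t
    stripped = model.canonical_token(_FS_SUFFIX.sub(r"\1", t))
    if _known(stripped):
        return stripped
    return t


def _chimera_exon_span(model: LocusModel, chimera_id: str) -> Tuple[int, int]:
    """CYP21A2 exon span fully removed/converted by a catalogued chimera."""
    ch = model.chimeras[chimera_id]
    if ch.whole_gene_absent:
        return (1, 10)
    if ch.span_end is None:
        raise ValueError(f"chimera {chimera_id} has no defined span")
    end = model.order(ch.span_end)
    exons = [model.exon_number(s.site_id) for s in model.exon_sites if s.order_index < end]
    return (min(exons), max(exons))


_DEL_SPAN = re.compile(r"^Exon\s+(\d+)\s*-\s*(\d+)\s+Del$", re.IGNORECASE)
_DEL_ONE = re.compile(r"^Exon\s+(\d+)\s+Del$", re.IGNORECASE)
_DEL_LIST = re.compile(r"^Exon\s+((?:\d+\s*,\s*)+\d+)\s+Del$", re.IGNORECASE)
_DEL_PHRASE = re.compile(r"^del\s*\((.+)\)$", re.IGNORECASE)
_CAHX = re.compile(r"CAH-?X[- ]?CH\s*([1-3])", re.IGNORECASE)
_CHIMERA = re.compile(r"\(\s*(CH[1-9])\s*\)")
_INTEGRATION = re.compile(r"^Exon\s*7\s*-\s*8\s+integration(?:\s*\((.*)\))?$", re.IGNORECASE)


def parse_report_call(s: str, model: Optional[LocusModel] = None) -> tuple:
    """Reduce one per-allele report string to its canonical call tuple.

    Canonical forms are ``("TOKENS", (tok, ...))`` (sorted, promoter tokens
    dropped; the empty tuple is a negative result), ``("DEL", first, last)``
    for a bare exon-span deletion, ``("DEL_PROBES", (exon, ...))`` for a
    per-probe deletion listing, ``("CAHX", n)``, ``("CHIMERA", "CHn")``,
    ``("DUP_E7E8", (tok, ...))`` and ``("UNDETERMINED",)`` for an allele whose
    origin the assay could not resolve.
    """
    model = model or _default_model()
    s = s.strip()
    if s in ("", "-", "—", "–") or s.lower() in ("negative", "none", "nan"):
        return ("TOKENS", ())
    low = s.lower()
    if "sperm" in low or "undetermined" in low:
        return ("UNDETERMINED",)

    m = _INTEGRATION.match(s)
    if m:
        toks = tuple(
            sorted(
                _normalize_token(model, t)
                for t in (m.group(1) or "").split(",")
                if t.strip()
            )
        )
        return ("DUP_E7E8", toks)

    m = _DEL_PHRASE.match(s)
    if m:
        inner = m.group(1).strip()
        xm = _CAHX.search(inner)
        if xm:
            return ("CAHX", int(xm.group(1)))
        if inner.upper() in ("CYP21A2",):
            return ("DEL", 1, 10)
        cm = re.fullmatch(r"CH([1-9])", inner.upper())
        if cm and f"CH{cm.group(1)}" in model.chimeras:
            return ("DEL",) + _chimera_exon_span(model, f"CH{cm.group(1)}")
        return ("DEL", 1, 10)

    if _CAHX.search(s) and "(" not in s:
        return ("CAHX", int(_CAHX.search(s).group(1)))

    m = _CHIMERA.search(s)
    if m:
        return ("CHIMERA", m.group(1))

    m = _DEL_SPAN.match(s)
    if m:
        return ("DEL", int(m.group(1)), int(m.group(2)))
    m = _DEL_ONE.match(s)
    if m:
        n = int(m.group(1))
        return ("DEL", n, n)
    m = _DEL_LIST.match(s)
    if m:
        exons = tuple(int(x) for x in re.split(r"\s*,\s*", m.group(1)))
        return ("DEL_PROBES", exons)

    s = _UTR5_PARENS.sub("UTR5", s)
    toks = [_normalize_token(model, t) for t in s.split(",") if t.strip()]
    toks = [t for t in toks if t and t != "UTR5"]
    return ("TOKENS", tuple(sorted(toks)))


def _render_call(call: tuple) -> str:
    kind = call[0]
    if kind == "TOKENS":
        return ", ".join(call[1]) if call[1] else "negative"
    if kind == "DEL":
        _, a, b = call
        return f"Exon {a} Del" if a == b else f"Exon {a}-{b} Del"
    if kind == "DEL_PROBES":
        return f"Exon {', '.join(str(x) for x in call[1])} Del"
    if kind == "CAHX":
        return f"del (CAH-X-CH{call[1]})"
    if kind == "CHIMERA":
        return f"chimera ({call[1]})"
    if kind == "DUP_E7E8":
        return f"Exon 7-8 integration ({', '.join(call[1])})"
    if kind == "UNDETERMINED":
        return "undetermined origin (donor sperm)"
    raise ValueError(f"unknown canonical call kind {kind!r}")


def normalize_report_string(s: str, model: Optional[LocusModel] = None) -> str:
    """Canonical string form of a report string; idempotent by construction."""
    return _render_call(parse_report_call(s, model))


def calls_equivalent(a: str, b: str, model: Optional[LocusModel] = None) -> bool:
    """Whether two per-allele report strings describe the same finding.

    An ``UNDETERMINED`` call is never equivalent to anything: the assay made
    no origin-resolved call, so it cannot agree with one.
    """
    ca, cb = parse_report_call(a, model), parse_report_call(b, model)
    if ca[0] == "UNDETERMINED" or cb[0] == "UNDETERMINED":
        return False
    return ca == cb


# ---------------------------------------------------------------------------
# cohort files


def _record_from_fields(fields: List[str], rownum: int) -> GenotypeRecord:
    if len(fields) < len(COHORT_COLUMNS) - 1:  # notes may be omitted
        raise CohortParseError(
            f"row {rownum}: expected {len(COHORT_COLUMNS)} columns, got {len(fields)}"
        )
    fields = fields + [""] * (len(COHORT_COLUMNS) - len(fields))
    d = dict(zip(COHORT_COLUMNS, fields))
    try:
        allele1 = parse_allele(d["allele1"])
        allele2 = parse_allele(d["allele2"])
    except ValueError as exc:
        raise CohortParseError(f"row {rownum}: {exc}") from exc
    if d["extra_copy"]:
        if d["extra_copy"] != "intact":
            raise CohortParseError(
                f"row {rownum}: extra_copy must be 'intact' or empty, got {d['extra_copy']!r}"
            )
        target = allele1 if allele1.copies else allele2
        if not target.copies:
            raise CohortParseError(
                f"row {rownum}: extra_copy recorded but neither allele is a duplication"
            )
        patched = AlleleSpec(
            category=target.category,
            subtype=target.subtype,
            variants=target.variants,
            copies=target.copies + ((),),
        )
        if target is allele1:
            allele1 = patched
        else:
            allele2 = patched
    try:
        phenotype = Phenotype(d["phenotype"])
    except ValueError:
        raise CohortParseError(
            f"row {rownum}: phenotype must be one of SW/SV/NC, got {d['phenotype']!r}"
        ) from None
    try:
        age = float(d["age_years"])
    except ValueError:
        raise CohortParseError(f"row {rownum}: age_years is not a decimal") from None
    group = None
    if d["genotype_group"]:
        try:
            group = SeverityClass(d["genotype_group"])
        except ValueError:
            raise CohortParseError(
                f"row {rownum}: unknown genotype group {d['genotype_group']!r}"
            ) from None
    if d["sex"] not in ("M", "F"):
        raise CohortParseError(f"row {rownum}: sex must be M or F, got {d['sex']!r}")
    lrs = (d["lrs_allele1"], d["lrs_allele2"]) if (d["lrs_allele1"] or d["lrs_allele2"]) else None
    conv = (
        (d["conv_allele1"], d["conv_allele2"])
        if (d["conv_allele1"] or d["conv_allele2"])
        else None
    )
    return GenotypeRecord(
        patient_id=d["patient_id"],
        sex=d["sex"],
        age_years=age,
        phenotype=phenotype,
        allele1=allele1,
        allele2=allele2,
        lrs_calls=lrs,
        conv_calls=conv,
        group_reported=group,
        notes=d["notes"],
    )


def read_cohort(path: Union[str, Path]) -> List[GenotypeRecord]:
    """Read a cohort TSV or JSON file into validated records.

    Raises :class:`CohortParseError` with the offending row number on any
    schema or grammar violation.
    """
    path = Path(path)
    if path.suffix.lower() == ".json":
        rows = json.loads(path.read_text(encoding="utf-8"))
        return [
            _record_from_fields([str(r.get(c, "")) for c in COHORT_COLUMNS], i + 1)
            for i, r in enumerate(rows)
        ]
    records: List[GenotypeRecord] = []
    with open(path, encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise CohortParseError("empty file: missing header row") from None
        if tuple(header) != COHORT_COLUMNS:
            raise CohortParseError(
                f"header mismatch: expected {list(COHORT_COLUMNS)}, got {header}"
            )
        for i, fields in enumerate(reader, start=2):
            if not fields or all(not f for f in fields):
                continue
            records.append(_record_from_fields(list(fields), i))
    return records


def _format_age(age: float) -> str:
    s = repr(age)
    return s[:-2] if s.endswith(".0") else s


def _record_to_fields(r: GenotypeRecord) -> List[str]:
    extra = "intact" if (r.allele1.has_intact_copy or r.allele2.has_intact_copy) else ""
    lrs = r.lrs_calls or ("", "")
    conv = r.conv_calls or ("", "")
    return [
        r.patient_id,
        r.sex,
        _format_age(r.age_years),
        r.phenotype.value,
        format_allele(r.allele1),
        format_allele(r.allele2),
        extra,
        lrs[0],
        lrs[1],
        conv[0],
        conv[1],
        "" if r.group_reported is None else r.group_reported.value,
        r.notes,
    ]


def write_cohort(
    records: Sequence[GenotypeRecord],
    path: Union[str, Path, None] = None,
    fmt: str = "tsv",
) -> str:
    """Serialize records to the cohort schema; returns the text written.

    TSV output is canonical: a row whose notes field is empty omits the
    trailing tab, so read -> write round-trips byte-identically.
    """
    if fmt == "json":
        rows = [dict(zip(COHORT_COLUMNS, _record_to_fields(r))) for r in records]
        text = json.dumps(rows, indent=1, ensure_ascii=False) + "\n"
    elif fmt == "tsv":
        lines = ["\t".join(COHORT_COLUMNS)]
        for r in records:
            fields = _record_to_fields(r)
            if fields[-1] == "":
                fields = fields[:-1]
            lines.append("\t".join(fields))
        text = "\n".join(lines) + "\n"
    else:
        raise ValueError(f"unknown cohort format {fmt!r}")
    if path is not None:
        Path(path).write_text(text, encoding="utf-8")
    return text


def load_reference_cohort() -> List[GenotypeRecord]:
    """The packaged 67-patient 21-OHD reference cohort.

    Digitized per-patient results of a published clinical cohort in which
    every patient was genotyped both by long-read sequencing and by MLPA
    combined with Long-PCR sequencing; both assays' per-allele calls are
    carried verbatim.
    """
    from importlib import resources

    with resources.as_file(
        resources.files("cyp21kit.data").joinpath("cohort_21ohd_67.tsv")
    ) as p:
        return read_cohort(p)
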