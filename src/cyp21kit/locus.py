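"""Symbolic model of the RCCX locus.

The CYP21A2 gene and its pseudogene CYP21A1P sit in the tandem-repeat RCCX
module on 6p21.3.  Meiotic misalignment produces microconversions, whole-gene
deletions (including TNXA/TNXB chimeras that extend into TNXB, the "CAH-X"
alleles) and partial CYP21A1P/CYP21A2 chimeric genes typed by their junction
position.  All downstream reasoning in this package is done over an ordered
list of *informative landmark sites* (promoter, exons 1..10, the intron-2
splice site, the exon-3 8 bp deletion site, and the probed TNXB exons), never
over genomic coordinates: the published junctions and probe panels are defined
in exon/landmark terms, and coordinates would add nothing testable.

:func:`load_locus_model` builds a validated :class:`LocusModel` from the
packaged default YAML document (or a user-supplied override) holding:

* the ordered site list,
* the chimera junction catalogue (CH1..CH9, CAH-X CH1..CH3, solo deletion,
  exon 7-8 duplication),
* the severity table mapping variant tokens to classes Null/A/B/C,
* the set of pseudogene-derived (microconversion) tokens,
* the variant token -> landmark site lookup,
* the MLPA probe panel.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Optional

import yaml

from .errors import ConfigurationError, UnknownVariantError

__all__ = [
    "Site",
    "ChimeraDef",
    "ProbePanel",
    "LocusModel",
    "load_locus_model",
    "site_for_variant",
]

#: chimera ids whose converted span includes the intron-2 splice site, ordered
#: as in the catalogue.  CH4 and CH9 convert only the promoter/exon-1 region
#: (carrying p.P31L) and do not acquire I2G.
I2G_CARRYING_CHIMERAS = ("CH1", "CH2", "CH3", "CH5", "CH6", "CH7", "CH8")

CYP21A2_EXONS = tuple(f"E{i}" for i in range(1, 11))


@dataclass(frozen=True)
class Site:
    """One informative landmark, ordered 5'->3' along the locus."""

    site_id: str
    order_index: int
    region: str  # promoter | exon | intron_site | tnxb


@dataclass(frozen=True)
class ChimeraDef:
    """One catalogued structural allele.

    For partial CYP21A1P/CYP21A2 chimeras the pseudogene-converted span is the
    half-open site interval [UTR5, span_end); ``partial_end`` marks junctions
    falling *inside* the last converted site (CH3's junction lies within exon
    8).  Whole-gene-absent entries (solo deletion and the CAH-X TNXA/TNXB
    chimeras) carry a TNXB signature token set instead of a span.
    """

    chimera_id: str
    span_end: Optional[str] = None
    partial_end: bool = False
    carries_i2g: Optional[bool] = None
    carries_8bp_del: Optional[bool] = None
    whole_gene_absent: bool = False
    duplication: bool = False
    tnxb_signature: frozenset = frozenset()
    observed: bool = True


@dataclass(frozen=True)
class ProbePanel:
    """The CAH-MLPA probe panel, by probed landmark site."""

    a2_probe_sites: tuple
    a1p_probe_count: int
    tnxb_probe_sites: tuple  # with multiplicity, e.g. TNXB_E35 twice
    reference_area: bool = True

    @property
    def probed_sites(self) -> tuple:
        """All distinct probed sites (CYP21A2 area then TNXB area)."""
        seen: dict = {}
        for s in tuple(self.a2_probe_sites) + tuple(self.tnxb_probe_sites):
            seen.setdefault(s, None)
        return tuple(seen)

    @property
    def probed_a2_exons(self) -> tuple:
        return tuple(s for s in self.a2_probe_sites if s.startswith("E"))


@dataclass(frozen=True)
class LocusModel:
    sites: tuple
    chimeras: Mapping[str, ChimeraDef]
    severity: Mapping[str, str]  # canonical token -> NULL | A | B | C
    synonyms: Mapping[str, str]  # spelling -> canonical token
    pseudogene_derived: frozenset
    variant_sites: Mapping[str, str]  # canonical token -> site_id
    probe_panel: ProbePanel
    site_index: Mapping[str, int] = field(default_factory=dict)

    # -- site helpers -----------------------------------------------------

    def site(self, site_id: str) -> Site:
        try:
            return self.sites[self.site_index[site_id]]
        except KeyError:
            raise KeyError(f"unknown site id: {site_id!r}") from None

    def order(self, site_id: str) -> int:
        return self.site(site_id).order_index

    @property
    def cyp21a2_sites(self) -> tuple:
        """Sites belonging to the CYP21A2 gene body (everything before TNXB)."""
        return tuple(s for s in self.sites if s.region != "tnxb")

    @property
    def exon_sites(self) -> tuple:
        return tuple(s for s in self.sites if s.region == "exon" and s.site_id.startswith("E"))

    def exon_number(self, site_id: str) -> int:
        return int(site_id[1:])

    # -- token helpers ----------------------------------------------------

    def canonical_token(self, token: str) -> str:
        """Resolve a spelling synonym to its canonical variant token."""
        token = token.strip()
        return self.synonyms.get(token, token)

    def severity_class(self, token: str) -> Optional[str]:
        """Severity class of a canonical token, or None if unknown (class D)."""
        return self.severity.get(self.canonical_token(token))


def _validate(model: LocusModel) -> None:
    """Check every documented invariant; raise ConfigurationError naming the first failure."""
    ids = [s.site_id for s in model.sites]
    if len(set(ids)) != len(ids):
        raise ConfigurationError("site list contains duplicate site ids")
    orders = [s.order_index for s in model.sites]
    if orders != sorted(orders) or len(set(orders)) != len(orders):
        raise ConfigurationError("site order_index is not strictly increasing")

    exons = [s for s in model.sites if s.region == "exon" and s.site_id.startswith("E")]
    if [s.site_id for s in exons] != [f"E{i}" for i in range(1, 11)]:
        raise ConfigurationError("site list must contain exactly exon sites E1..E10 in order")

    for needed in ("UTR5", "I2G_SITE", "DEL8BP_SITE"):
        if needed not in model.site_index:
            raise ConfigurationError(f"required site {needed} missing from site list")
    if not (model.order("E2") < model.order("I2G_SITE") < model.order("E3")):
        raise ConfigurationError("I2G_SITE must lie between E2 and E3")
    if not (model.order("I2G_SITE") < model.order("DEL8BP_SITE") < model.order("E3")):
        raise ConfigurationError("DEL8BP_SITE must lie within exon 3, after I2G_SITE")

    for cid, ch in model.chimeras.items():
        if ch.span_end is not None and ch.span_end not in model.site_index:
            raise ConfigurationError(f"chimera {cid} span_end {ch.span_end!r} is not a site")
    for cid in I2G_CARRYING_CHIMERAS:
        ch = model.chimeras.get(cid)
        if ch is not None and ch.carries_i2g is False:
            raise ConfigurationError(f"chimera {cid} must carry I2G")
    for cid in ("CH4", "CH9"):
        ch = model.chimeras.get(cid)
        if ch is not None and ch.carries_i2g:
            raise ConfigurationError(f"chimera {cid} must not carry I2G")
    ch6 = model.chimeras.get("CH6")
    if ch6 is not None and ch6.span_end is not None:
        if not (ch6.carries_i2g and not ch6.carries_8bp_del):
            raise ConfigurationError("CH6 must carry I2G and exclude the 8 bp deletion")

    allowed = {"NULL", "A", "B", "C"}
    bad = set(model.severity.values()) - allowed
    if bad:
        raise ConfigurationError(f"severity classes outside {sorted(allowed)}: {sorted(bad)}")

    panel = model.probe_panel
    for s in panel.probed_sites:
        if s not in model.site_index:
            raise ConfigurationError(f"probe panel references unknown site {s!r}")
    for s in panel.tnxb_probe_sites:
        n = int(s.split("_E")[1])
        if 40 <= n <= 44:
            raise ConfigurationError(
                "TNXB probe panel must not contain probes in exons 40-44"
            )

    for token, site_id in model.variant_sites.items():
        if site_id not in model.site_index:
            raise ConfigurationError(
                f"variant {token!r} mapped to unknown site {site_id!r}"
            )


def _default_stream():
    return resources.files("cyp21kit.data").joinpath("locus_model.yaml").open("rb")


def load_locus_model(config: Optional[str] = None) -> LocusModel:
    """Load and validate a locus model.

    Parameters
    ----------
    config:
        Optional path to a YAML document following the packaged schema; when
        omitted the packaged default model is used.  Loading is deterministic.

    Raises
    ------
    ConfigurationError
        If the document violates any documented invariant; the message names
        the failing invariant.
    """
    if config is None:
        with _default_stream() as fh:
            doc = yaml.safe_load(fh)
    else:
        with open(config, "rb") as fh:
            doc = yaml.safe_load(fh)

    try:
        sites = tuple(
            Site(site_id=d["id"], order_index=i, region=d["region"])
            for i, d in enumerate(doc["sites"])
        )
        chimeras = {}
        for cid, d in doc["chimeras"].items():
            chimeras[cid] = ChimeraDef(
                chimera_id=cid,
                span_end=d.get("span_end"),
                partial_end=bool(d.get("partial_end", False)),
                carries_i2g=d.get("carries_i2g"),
                carries_8bp_del=d.get("carries_8bp_del"),
                whole_gene_absent=bool(d.get("whole_gene_absent", False)),
                duplication=bool(d.get("duplication", False)),
                tnxb_signature=frozenset(d.get("tnxb_signature", ())),
                observed=bool(d.get("observed", True)),
            )
        severity = {}
        for cls, tokens in doc["severity"].items():
            for tok in tokens:
                severity[tok] = str(cls)
        panel_doc = doc["probe_panel"]
        panel = ProbePanel(
            a2_probe_sites=tuple(panel_doc["a2_probe_sites"]),
            a1p_probe_count=int(panel_doc["a1p_probe_count"]),
            tnxb_probe_sites=tuple(panel_doc["tnxb_probe_sites"]),
            reference_area=bool(panel_doc.get("reference_area", True)),
        )
        model = LocusModel(
            sites=sites,
            chimeras=chimeras,
            severity=severity,
            synonyms=dict(doc.get("synonyms", {})),
            pseudogene_derived=frozenset(doc["pseudogene_derived"]),
            variant_sites=dict(doc["variant_sites"]),
            probe_panel=panel,
            site_index={s.site_id: i for i, s in enumerate(sites)},
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise ConfigurationError(f"malformed locus model document: {exc}") from exc

    _validate(model)
    return model


def site_for_variant(model: LocusModel, token: str) -> Site:
    """Landmark site housing a variant token.

    Raises
    ------
    UnknownVariantError
        If the token (after synonym resolution) is not in the model's
        variant-location table.  Callers may treat the location as unknown.
    """
    canon = model.canonical_token(token)
    try:
        return model.site(model.variant_sites[canon])
    except KeyError:
        raise UnknownVariantError(
            f"no landmark site registered for variant token {token!r}"
        ) from None
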