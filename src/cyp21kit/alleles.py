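"""Single-haplotype allele classification and chimera junction typing.

A phased long read spanning the whole CYP21A2 gene can be reduced to a
*marker vector*: one origin call (gene, pseudogene, absent, unknown) per
informative landmark site, plus any TNXB signature tokens observed on the
same haplotype.  Under the single-junction model every catalogued
CYP21A1P/CYP21A2 chimera has exactly one 5'-pseudogene -> 3'-gene transition,
so junction calling reduces to finding the tightest site interval separating
pseudogene-origin calls from gene-origin calls.

Alleles are classified into four taxonomy categories:

* ``MICROCONVERSION`` - every variant token is transferable from CYP21A1P;
* ``NOVEL_VARIANT``   - at least one token absent from the pseudogene;
* ``DELETION``        - whole-gene loss (solo or CAH-X TNXA/TNXB chimera) or a
  partial CYP21A1P/CYP21A2 chimera (CH1..CH9);
* ``DUPLICATION``     - a CYP21A2/CYP21A1P chimera with a pseudogene-derived
  exon 7-8 segment, with or without an accompanying intact extra copy.

The string mini-grammar used in cohort files is::

    micro:TOK[+TOK...] | novel:TOK[+TOK...] | del:solo |
    cahx:CH1|CH2|CH3 | chimera:CH1..CH9 | dup:E7E8[TOK,TOK,...]

:func:`parse_allele` and :func:`format_allele` are exact inverses.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .errors import InconsistentEvidenceError, NonCanonicalHaplotypeError
from .locus import LocusModel

__all__ = [
    "Origin",
    "Category",
    "MarkerVector",
    "JunctionCall",
    "AlleleSpec",
    "call_junction",
    "classify_chimera",
    "classify_allele",
    "build_marker_vector",
    "parse_allele",
    "format_allele",
]


class Origin(str, enum.Enum):
    """Per-site origin call on one haplotype."""

    GENE = "GENE"
    PSEUDO = "PSEUDO"
    ABSENT = "ABSENT"
    UNKNOWN = "UNKNOWN"
    #: both origins seen within one site: the junction lies inside it
    PARTIAL = "PARTIAL"


class Category(str, enum.Enum):
    MICROCONVERSION = "MICROCONVERSION"
    NOVEL_VARIANT = "NOVEL_VARIANT"
    DELETION = "DELETION"
    DUPLICATION = "DUPLICATION"


@dataclass(frozen=True)
class MarkerVector:
    """Ordered origin calls per locus-model site plus TNXB signature tokens."""

    calls: tuple  # Origin per model site, same length/order as model.sites
    tnxb_signature: frozenset = frozenset()

    def call(self, model: LocusModel, site_id: str) -> Origin:
        return self.calls[model.site_index[site_id]]


@dataclass(frozen=True)
class JunctionCall:
    """Result of junction calling on one haplotype.

    ``kind`` is one of:

    * ``none``        - all informative calls gene-origin (wild-type structure);
    * ``absent``      - whole gene absent;
    * ``junction``    - single junction strictly between ``left_site`` and
      ``right_site`` (``right_site`` is None when pseudogene origin runs off
      the 3' end of the informative map);
    * ``within_site`` - junction inside ``partial_site``.
    """

    kind: str
    left_site: Optional[str] = None
    right_site: Optional[str] = None
    partial_site: Optional[str] = None


@dataclass(frozen=True)
class UnclassifiedChimera:
    """A junction that matches no catalogue entry (not an error)."""

    junction: JunctionCall
    reason: str = "junction matches no catalogue entry"


@dataclass(frozen=True)
class AlleleSpec:
    """One haplotype's classified content."""

    category: Category
    subtype: Optional[str] = None  # chimera id, DEL_SOLO, CAHX_CHn, DUP_E7E8
    variants: tuple = ()
    #: per-copy variant token lists; length > 1 only for duplicated alleles
    #: (an empty inner tuple denotes an intact extra CYP21A2 copy)
    copies: tuple = ()

    @property
    def n_copies(self) -> int:
        return max(1, len(self.copies))

    @property
    def has_intact_copy(self) -> bool:
        return len(self.copies) > 1 and any(len(c) == 0 for c in self.copies)


# ---------------------------------------------------------------------------
# junction calling


def call_junction(model: LocusModel, mv: MarkerVector) -> JunctionCall:
    """Call the pseudogene->gene junction of one haplotype.

    Only sites of the CYP21A2 gene body are informative; TNXB landmark calls
    are ignored here (TNXB evidence enters through the signature token set).

    Raises
    ------
    NonCanonicalHaplotypeError
        If a gene-origin call precedes a pseudogene/absent-origin call 5'->3'
        (more than one junction would be required).
    ValueError
        If the vector is malformed or has no informative call.
    """
    sites = model.cyp21a2_sites
    calls = [(s, mv.calls[s.order_index]) for s in sites]
    informative = [(s, c) for s, c in calls if c != Origin.UNKNOWN]
    if len(mv.calls) != len(model.sites):
        raise ValueError("marker vector length does not match the locus site list")
    if not informative:
        raise ValueError("marker vector has no informative call")

    if all(c == Origin.ABSENT for _, c in informative):
        return JunctionCall(kind="absent")
    if all(c == Origin.GENE for _, c in informative):
        return JunctionCall(kind="none")

    partials = [s for s, c in informative if c == Origin.PARTIAL]
    if len(partials) > 1:
        raise NonCanonicalHaplotypeError(partials[0].site_id, partials[1].site_id)

    first_gene = None
    last_nongene = None
    for s, c in informative:
        if c == Origin.GENE:
            if first_gene is None:
                first_gene = s
        elif c in (Origin.PSEUDO, Origin.ABSENT):
            if first_gene is not None:
                raise NonCanonicalHaplotypeError(first_gene.site_id, s.site_id)
            last_nongene = s

    if partials:
        p = partials[0]
        # the partial site must sit between the two pure zones
        if last_nongene is not None and p.order_index < last_nongene.order_index:
            raise NonCanonicalHaplotypeError(p.site_id, last_nongene.site_id)
        if first_gene is not None and p.order_index > first_gene.order_index:
            raise NonCanonicalHaplotypeError(first_gene.site_id, p.site_id)
        return JunctionCall(kind="within_site", partial_site=p.site_id)

    return JunctionCall(
        kind="junction",
        left_site=None if last_nongene is None else last_nongene.site_id,
        right_site=None if first_gene is None else first_gene.site_id,
    )


def classify_chimera(model: LocusModel, j: JunctionCall, mv: MarkerVector):
    """Match a junction call against the chimera catalogue.

    Whole-gene-absent haplotypes resolve by TNXB signature (empty -> solo
    deletion, a CAH-X signature -> the matching CAH-X type).  Junctions match
    the catalogue entry whose converted span ends inside the junction
    interval; junctions inside the E1..E3 landmark run are disambiguated by
    whether the haplotype carries I2G and the exon-3 8 bp deletion.

    Returns a chimera id, or :class:`UnclassifiedChimera` when nothing in the
    catalogue matches (e.g. the unobserved CH5/CH7/CH9 placeholders).
    """
    if j.kind == "absent":
        sig = mv.tnxb_signature
        if not sig:
            return "DEL_SOLO"
        for cid, ch in model.chimeras.items():
            if ch.whole_gene_absent and ch.tnxb_signature and ch.tnxb_signature == sig:
                return cid
        return UnclassifiedChimera(j, reason=f"unrecognized TNXB signature {sorted(sig)}")
    if j.kind not in ("junction", "within_site"):
        raise ValueError("classify_chimera requires a junction or whole-gene absence")

    if j.kind == "within_site":
        cands = [
            ch
            for ch in model.chimeras.values()
            if ch.partial_end and ch.span_end == j.partial_site
        ]
    else:
        left = -1 if j.left_site is None else model.order(j.left_site)
        right = (
            len(model.cyp21a2_sites)
            if j.right_site is None
            else model.order(j.right_site)
        )
        cands = []
        for ch in model.chimeras.values():
            if ch.span_end is None or ch.whole_gene_absent or ch.duplication:
                continue
            if ch.partial_end:
                continue
            end = model.order(ch.span_end)
            if left < end <= right:
                cands.append(ch)

    # disambiguate by marker content where the vector is informative
    def compatible(ch) -> bool:
        for flag, site_id in ((ch.carries_i2g, "I2G_SITE"), (ch.carries_8bp_del, "DEL8BP_SITE")):
            if flag is None:
                continue
            call = mv.call(model, site_id)
            if call == Origin.UNKNOWN or call == Origin.PARTIAL:
                continue
            carried = call in (Origin.PSEUDO, Origin.ABSENT)
            if carried != flag:
                return False
        return True

    cands = [ch for ch in cands if compatible(ch)]
    if len(cands) == 1:
        return cands[0].chimera_id
    return UnclassifiedChimera(j)


# ---------------------------------------------------------------------------
# synthetic haplotype construction (inverse of junction calling)


def build_marker_vector(
    model: LocusModel,
    chimera_id: Optional[str] = None,
    point_tokens: Iterable[str] = (),
) -> MarkerVector:
    """Construct the marker vector a given structure would present.

    ``chimera_id`` None yields a wild-type-structured haplotype; point-variant
    tokens that are pseudogene-derived mark their landmark site pseudo-origin.
    This is the builder used by the synthetic cohort generator and by the
    round-trip property tests (junction calling inverts it for every
    catalogued chimera with a defined span).
    """
    calls = [Origin.GENE] * len(model.sites)
    signature: frozenset = frozenset()
    if chimera_id is not None:
        ch = model.chimeras[chimera_id]
        if ch.whole_gene_absent:
            for s in model.cyp21a2_sites:
                calls[s.order_index] = Origin.ABSENT
            signature = ch.tnxb_signature
        elif ch.span_end is not None:
            end = model.order(ch.span_end)
            for s in model.cyp21a2_sites:
                if s.order_index < end:
                    calls[s.order_index] = Origin.PSEUDO
            if ch.partial_end:
                calls[end] = Origin.PARTIAL
        elif ch.duplication:
            pass  # copy structure is carried on AlleleSpec, not the vector
        else:
            raise ValueError(f"chimera {chimera_id} has no defined span to build")
    else:
        for tok in point_tokens:
            canon = model.canonical_token(tok)
            site_id = model.variant_sites.get(canon)
            if site_id is not None and canon in model.pseudogene_derived:
                calls[model.site_index[site_id]] = Origin.PSEUDO
    return MarkerVector(calls=tuple(calls), tnxb_signature=signature)


# ---------------------------------------------------------------------------
# allele classification


def classify_allele(
    model: LocusModel,
    variants: Sequence[str] = (),
    mv: Optional[MarkerVector] = None,
    extra_copies: Optional[Sequence[Sequence[str]]] = None,
) -> AlleleSpec:
    """Classify one haplotype from its variant tokens and/or marker vector.

    Structural evidence dominates: a junction or whole-gene absence in the
    marker vector yields DELETION (with the chimera subtype), and a recorded
    multi-copy structure yields DUPLICATION.  Otherwise the allele is a
    MICROCONVERSION when every token is pseudogene-derived, else a
    NOVEL_VARIANT.  Classification is deterministic and invariant to the
    order of the variant token list.

    Raises
    ------
    ValueError
        If neither variants nor a marker vector is supplied.
    InconsistentEvidenceError
        If a wild-type-structured vector is combined with a deletion claim
        (an ``ABSENT`` call pattern elsewhere contradicting the tokens).
    """
    tokens = tuple(model.canonical_token(t) for t in variants)
    if not tokens and mv is None and not extra_copies:
        raise ValueError("classify_allele needs variant tokens or a marker vector")

    # extra_copies is structural evidence of a CYP21A2/CYP21A1P duplication
    # arrangement; an empty list records the chimeric copy alone (no intact
    # extra copy on the same chromosome)
    if extra_copies is not None:
        copies = (tokens,) + tuple(
            tuple(model.canonical_token(t) for t in c) for c in extra_copies
        )
        return AlleleSpec(
            category=Category.DUPLICATION,
            subtype="DUP_E7E8",
            variants=tokens,
            copies=copies,
        )

    if mv is not None:
        j = call_junction(model, mv)
        if j.kind == "absent":
            if tokens and any(
                model.variant_sites.get(t) is not None for t in tokens
            ):
                raise InconsistentEvidenceError(
                    "whole-gene absence cannot carry CYP21A2 point variants"
                )
            sub = classify_chimera(model, j, mv)
            return AlleleSpec(
                category=Category.DELETION,
                subtype=sub if isinstance(sub, str) else None,
                variants=tokens,
            )
        if j.kind in ("junction", "within_site"):
            sub = classify_chimera(model, j, mv)
            return AlleleSpec(
                category=Category.DELETION,
                subtype=sub if isinstance(sub, str) else None,
                variants=tokens,
            )
        # wild-type structure: fall through to token-based classification
        if not tokens:
            raise InconsistentEvidenceError(
                "wild-type-structured haplotype with no variant tokens is not a "
                "pathogenic allele"
            )

    if all(t in model.pseudogene_derived for t in tokens):
        return AlleleSpec(category=Category.MICROCONVERSION, variants=tokens)
    return AlleleSpec(category=Category.NOVEL_VARIANT, variants=tokens)


# ---------------------------------------------------------------------------
# allele mini-grammar

_DUP_RE = re.compile(r"^dup:E7E8\[(?P<toks>[^\]]*)\]$")


def parse_allele(s: str) -> AlleleSpec:
    """Parse an allele mini-grammar string into an :class:`AlleleSpec`.

    Raises ValueError naming the failing grammar production.
    """
    s = s.strip()
    if not s:
        raise ValueError("allele-string: empty input")
    m = _DUP_RE.match(s)
    if m:
        toks = tuple(t.strip() for t in m.group("toks").split(",") if t.strip())
        if not toks:
            raise ValueError("dup-production: empty token list")
        return AlleleSpec(
            category=Category.DUPLICATION,
            subtype="DUP_E7E8",
            variants=toks,
            copies=(toks,),
        )
    if ":" not in s:
        raise ValueError(f"allele-string: missing category prefix in {s!r}")
    head, _, rest = s.partition(":")
    if head == "del":
        if rest != "solo":
            raise ValueError(f"del-production: expected 'del:solo', got {s!r}")
        return AlleleSpec(category=Category.DELETION, subtype="DEL_SOLO")
    if head == "cahx":
        if rest not in ("CH1", "CH2", "CH3"):
            raise ValueError(f"cahx-production: unknown CAH-X type {rest!r}")
        return AlleleSpec(category=Category.DELETION, subtype=f"CAHX_{rest}")
    if head == "chimera":
        if not re.fullmatch(r"CH[1-9]", rest):
            raise ValueError(f"chimera-production: unknown chimera id {rest!r}")
        return AlleleSpec(category=Category.DELETION, subtype=rest)
    if head in ("micro", "novel"):
        # '+' separates tokens except inside intronic HGVS offsets (c.292+1G>A),
        # where it is always followed by a digit
        toks = tuple(t.strip() for t in re.split(r"\+(?!\d)", rest) if t.strip())
        if not toks:
            raise ValueError(f"{head}-production: empty token list")
        cat = Category.MICROCONVERSION if head == "micro" else Category.NOVEL_VARIANT
        return AlleleSpec(category=cat, variants=toks)
    raise ValueError(f"allele-string: unknown category prefix {head!r}")


def format_allele(a: AlleleSpec) -> str:
    """Serialize an :class:`AlleleSpec` back to its mini-grammar string."""
    if a.category == Category.DUPLICATION:
        return f"dup:E7E8[{','.join(a.variants)}]"
    if a.category == Category.DELETION:
        if a.subtype == "DEL_SOLO":
            return "del:solo"
        if a.subtype is not None and a.subtype.startswith("CAHX_"):
            return f"cahx:{a.subtype[5:]}"
        return f"chimera:{a.subtype}"
    head = "micro" if a.category == Category.MICROCONVERSION else "novel"
    return f"{head}:{'+'.join(a.variants)}"
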