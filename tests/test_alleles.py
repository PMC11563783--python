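"""Junction calling, chimera typing, allele taxonomy and the mini-grammar."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cyp21kit.alleles import (
    AlleleSpec,
    Category,
    MarkerVector,
    Origin,
    UnclassifiedChimera,
    build_marker_vector,
    call_junction,
    classify_allele,
    classify_chimera,
    format_allele,
    parse_allele,
)
from cyp21kit.errors import InconsistentEvidenceError, NonCanonicalHaplotypeError


def _vector(model, assignments, signature=()):
    """Marker vector with GENE everywhere except the given site->origin map."""
    calls = [Origin.GENE] * len(model.sites)
    for site_id, origin in assignments.items():
        calls[model.site_index[site_id]] = origin
    return MarkerVector(calls=tuple(calls), tnxb_signature=frozenset(signature))


# ---------------------------------------------------------------------------
# junction calling


def test_ch1_style_vector_yields_junction_between_e3_and_e4(model):
    mv = _vector(model, {s: Origin.PSEUDO for s in
                         ("UTR5", "E1", "E2", "I2G_SITE", "DEL8BP_SITE", "E3")})
    j = call_junction(model, mv)
    assert (j.kind, j.left_site, j.right_site) == ("junction", "E3", "E4")


def test_all_gene_vector_has_no_junction(model):
    j = call_junction(model, _vector(model, {}))
    assert j.kind == "none"


def test_all_absent_vector_flags_whole_gene_absence(model):
    mv = _vector(model, {s.site_id: Origin.ABSENT for s in model.cyp21a2_sites})
    assert call_junction(model, mv).kind == "absent"


def test_interleaved_origins_raise_with_both_site_ids(model):
    mv = _vector(model, {"E5": Origin.PSEUDO})  # GENE at E1..E4 precedes it
    with pytest.raises(NonCanonicalHaplotypeError) as exc:
        call_junction(model, mv)
    assert exc.value.gene_site == "UTR5"
    assert exc.value.pseudo_site == "E5"


def _oracle_junction(calls):
    """Exhaustive cut-point scan: the tightest cut consistent with the calls."""
    n = len(calls)
    feasible = []
    for k in range(n + 1):  # junction before index k
        ok = all(c != Origin.GENE for c in calls[:k]) and all(
            c not in (Origin.PSEUDO, Origin.ABSENT) for c in calls[k:]
        )
        if ok:
            feasible.append(k)
    if not feasible:
        return None
    nongene = [i for i, c in enumerate(calls) if c in (Origin.PSEUDO, Origin.ABSENT)]
    gene = [i for i, c in enumerate(calls) if c == Origin.GENE]
    return (max(nongene) if nongene else None, min(gene) if gene else None)


def test_junction_caller_matches_exhaustive_cutpoint_oracle(model):
    rng = np.random.default_rng(2021)
    sites = model.cyp21a2_sites
    n = len(sites)
    for _ in range(1000):
        k = int(rng.integers(1, n))  # at least one non-gene and one gene call
        calls = [Origin.PSEUDO] * k + [Origin.GENE] * (n - k)
        for i in range(n):  # sprinkle unknowns
            if rng.random() < 0.2:
                calls[i] = Origin.UNKNOWN
        if all(c == Origin.UNKNOWN for c in calls):
            continue
        expected = _oracle_junction(calls)
        full = list(calls) + [Origin.GENE] * (len(model.sites) - n)
        j = call_junction(model, MarkerVector(calls=tuple(full)))
        assert expected is not None
        left, right = expected
        exp_left = None if left is None else sites[left].site_id
        exp_right = None if right is None else sites[right].site_id
        if exp_left is None:
            assert j.kind == "none"
        else:
            assert (j.kind, j.left_site, j.right_site) == ("junction", exp_left, exp_right)


# ---------------------------------------------------------------------------
# chimera typing


def test_whole_gene_absent_with_exon35_deletion_signature_is_cahx_ch1(model):
    mv = _vector(
        model,
        {s.site_id: Origin.ABSENT for s in model.cyp21a2_sites},
        signature={"TNXB_E35_120bp_del"},
    )
    assert classify_chimera(model, call_junction(model, mv), mv) == "CAHX_CH1"


def test_ch6_junction_between_i2g_and_8bp_deletion(model):
    mv = _vector(model, {s: Origin.PSEUDO for s in ("UTR5", "E1", "E2", "I2G_SITE")})
    j = call_junction(model, mv)
    assert (j.left_site, j.right_site) == ("I2G_SITE", "DEL8BP_SITE")
    assert classify_chimera(model, j, mv) == "CH6"


def test_junction_between_e8_and_e9_is_ch8(model):
    mv = build_marker_vector(model, "CH8")
    j = call_junction(model, mv)
    assert (j.left_site, j.right_site) == ("E8", "E9")
    assert classify_chimera(model, j, mv) == "CH8"


def test_junction_inside_e8_is_ch3_not_ch8(model):
    mv = build_marker_vector(model, "CH3")
    j = call_junction(model, mv)
    assert j.kind == "within_site" and j.partial_site == "E8"
    assert classify_chimera(model, j, mv) == "CH3"


def test_uncatalogued_junction_returns_unclassified_result(model):
    # junction between E6 and E7: no catalogue entry ends there
    mv = _vector(model, {s: Origin.PSEUDO for s in
                         ("UTR5", "E1", "E2", "I2G_SITE", "DEL8BP_SITE", "E3",
                          "E4", "E5", "E6")})
    res = classify_chimera(model, call_junction(model, mv), mv)
    assert isinstance(res, UnclassifiedChimera)


def test_builder_and_caller_roundtrip_over_the_catalogue(model):
    for cid, ch in model.chimeras.items():
        if ch.duplication or not ch.observed:
            continue
        mv = build_marker_vector(model, cid)
        j = call_junction(model, mv)
        assert classify_chimera(model, j, mv) == cid


# ---------------------------------------------------------------------------
# allele classification


def test_pure_pseudogene_tokens_classify_as_microconversion(model):
    a = classify_allele(model, ["I2G"])
    assert (a.category, a.variants) == (Category.MICROCONVERSION, ("I2G",))


def test_non_pseudogene_token_classifies_as_novel_variant(model):
    a = classify_allele(model, ["p.R484Pfs*58"])
    assert a.category == Category.NOVEL_VARIANT
    # severity (Null) and taxonomy (novel) are independent axes
    assert a.variants == ("p.R484Pfs*58",)


def test_mixed_tokens_are_novel_and_preserve_the_token_list(model):
    a = classify_allele(model, ["I2G", "p.S126X"])
    assert a.category == Category.NOVEL_VARIANT
    assert set(a.variants) == {"I2G", "p.S126X"}


def test_three_copy_structure_classifies_as_exon78_duplication(model):
    a = classify_allele(
        model,
        ["p.V282L", "p.L308Ffs*6", "p.Q319X"],
        extra_copies=[[]],
    )
    assert (a.category, a.subtype) == (Category.DUPLICATION, "DUP_E7E8")
    assert a.has_intact_copy


def test_structural_evidence_dominates_tokens(model):
    mv = build_marker_vector(model, "CH1")
    a = classify_allele(model, [], mv=mv)
    assert (a.category, a.subtype) == (Category.DELETION, "CH1")


def test_classification_is_order_invariant(model):
    a = classify_allele(model, ["p.Q319X", "p.L308Ffs*6"])
    b = classify_allele(model, ["p.L308Ffs*6", "p.Q319X"])
    assert a.category == b.category and set(a.variants) == set(b.variants)


def test_empty_input_raises(model):
    with pytest.raises(ValueError):
        classify_allele(model, [])


def test_contradictory_evidence_raises(model):
    absent = build_marker_vector(model, "DEL_SOLO")
    with pytest.raises(InconsistentEvidenceError):
        classify_allele(model, ["p.I173N"], mv=absent)
    wildtype = build_marker_vector(model)
    with pytest.raises(InconsistentEvidenceError):
        classify_allele(model, [], mv=wildtype)


def test_fixture_reproduces_every_printed_lrs_allele_call(model, cohort):
    """Re-derive all 134 allele calls from reconstructed raw inputs."""
    n = 0
    for r in cohort:
        for recorded in r.alleles:
            if recorded.category == Category.DELETION:
                mv = build_marker_vector(model, recorded.subtype)
                redone = classify_allele(model, [], mv=mv)
            elif recorded.category == Category.DUPLICATION:
                redone = classify_allele(
                    model, list(recorded.variants),
                    extra_copies=[list(c) for c in recorded.copies[1:]],
                )
            else:
                redone = classify_allele(model, list(recorded.variants))
            assert redone.category == recorded.category, r.patient_id
            assert redone.subtype == recorded.subtype, r.patient_id
            n += 1
    assert n == 134


# ---------------------------------------------------------------------------
# mini-grammar

TOKENS = ["I2G", "p.I173N", "p.Q319X", "c.292+1G>A", "p.R484Pfs*58", "UTR5",
          "E6_CLUSTER", "p.G423_C424delinsVCL"]


@settings(derandomize=True, max_examples=200)
@given(
    st.one_of(
        st.builds(
            lambda toks, novel: AlleleSpec(
                category=Category.NOVEL_VARIANT if novel else Category.MICROCONVERSION,
                variants=tuple(toks),
            ),
            st.lists(st.sampled_from(TOKENS), min_size=1, max_size=3, unique=True),
            st.booleans(),
        ),
        st.sampled_from(
            [parse_allele(s) for s in
             ("del:solo", "cahx:CH1", "cahx:CH3", "chimera:CH4", "chimera:CH8",
              "dup:E7E8[p.V282L,p.L308Ffs*6,p.Q319X]")]
        ),
    )
)
def test_grammar_roundtrip_is_exact(spec):
    assert parse_allele(format_allele(spec)) == spec


def test_fixture_grammar_strings_roundtrip_bit_exact(cohort):
    for r in cohort:
        for a in r.alleles:
            s = format_allele(a)
            reparsed = parse_allele(s)
            assert format_allele(reparsed) == s


@pytest.mark.parametrize(
    "bad,production",
    [
        ("", "allele-string"),
        ("micro:", "micro-production"),
        ("del:partial", "del-production"),
        ("cahx:CH4", "cahx-production"),
        ("chimera:CH10", "chimera-production"),
        ("dup:E7E8[]", "dup-production"),
        ("weird:I2G", "allele-string"),
    ],
)
def test_malformed_grammar_strings_name_the_production(bad, production):
    with pytest.raises(ValueError, match=production):
        parse_allele(bad)
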