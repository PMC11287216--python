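"""Rule-engine behaviour: pathway detection, oxygen/carbon classes,
donor/acceptor profiles, OTU-level union semantics and monotonicity."""

import pytest
from hypothesis import given, settings, strategies as st

from sedguilds.classify import (
    call_otu_guild,
    classify_carbon,
    classify_markers,
    classify_oxygen,
    detect_pathways,
    donor_acceptor_profile,
)
from sedguilds.clustering import OtuCluster

GLYCOLYSIS = {"pfk", "gapdh", "pyk"}
TCA = {"glta", "sdh", "mdh"}
PPP = {"zwf", "tkt", "rpi"}
CENTRAL = GLYCOLYSIS | TCA | PPP


# -- pathway detection -------------------------------------------------------

@pytest.mark.parametrize(
    "markers, expected",
    [
        ({"rubisco", "prk"}, {"CBB"}),
        ({"rubisco"}, set()),  # conjunction: RuBisCO alone insufficient
        ({"codh_acs"}, set()),
        ({"codh_acs", "fhs"}, {"WL"}),
        ({"acly"}, {"rTCA"}),  # ATP-citrate lyase route
        ({"ccs", "ccl"}, {"rTCA"}),  # citryl-CoA synthetase/lyase couple
        ({"ccs"}, set()),
        ({"pcc", "mcr", "mcl", "acc"}, {"HP3"}),
        ({"pcc", "mcr", "mcl", "acc", "budh4"}, {"HP3", "HP3HB4"}),
    ],
)
def test_pathway_rules(markers, expected, catalog):
    assert set(detect_pathways(markers, catalog)) == expected


def test_dc4hb_requires_incomplete_3hp(catalog):
    low = detect_pathways({"budh4", "por"}, catalog)
    assert low == {"DC4HB": "low"}
    # with the full 3HP set the evidence is read as 3HP/4HB instead
    full = detect_pathways({"budh4", "por", "pcc", "mcr", "mcl", "acc"}, catalog)
    assert "DC4HB" not in full
    assert {"HP3", "HP3HB4"} <= set(full)


def test_unknown_markers_are_ignored(catalog):
    assert detect_pathways({"rubisco", "prk", "not_a_marker"}, catalog) == {"CBB": "high"}


# -- oxygen ------------------------------------------------------------------

@pytest.mark.parametrize(
    "markers, expected",
    [
        ({"cox"}, "aerobe"),
        ({"cyd"}, "aerotolerant_anaerobe"),
        ({"cox", "cyd"}, "aerobe"),  # Cox dominates
        (set(), "anaerobe"),
    ],
)
def test_oxygen_classes(markers, expected, catalog):
    assert classify_oxygen(markers, catalog) == expected


# -- carbon ------------------------------------------------------------------

def test_facultative_autotroph_needs_pathway_plus_complete_central(catalog):
    markers = {"codh_acs", "fhs"} | CENTRAL
    assert classify_carbon(markers, detect_pathways(markers, catalog), catalog) == (
        "facultative_autotroph"
    )


def test_autotroph_without_complete_central(catalog):
    markers = {"codh_acs", "fhs"} | GLYCOLYSIS
    assert classify_carbon(markers, detect_pathways(markers, catalog), catalog) == "autotroph"


def test_fermenter_needs_glycolysis_evolving_hydrogenase_no_oxidase(catalog):
    markers = GLYCOLYSIS | {"fefe"}
    assert classify_carbon(markers, {}, catalog) == "fermenter"
    # a terminal oxidase vetoes the fermenter call
    assert classify_carbon(markers | {"cyd"}, {}, catalog) == "heterotroph"
    # an uptake-only hydrogenase does not qualify
    assert classify_carbon(GLYCOLYSIS | {"nife_1a"}, {}, catalog) == "heterotroph"


def test_plain_heterotroph(catalog):
    markers = {"cox"} | GLYCOLYSIS | TCA
    assert classify_carbon(markers, {}, catalog) == "heterotroph"


def test_allow_missing_central_knob(catalog):
    from sedguilds.classify import central_complete

    nearly = GLYCOLYSIS | TCA | (PPP - {"rpi"})
    assert not central_complete(nearly, catalog, "ppp")
    assert central_complete(nearly, catalog, "ppp", allow_missing=1)


# -- donors / acceptors ------------------------------------------------------

def test_sulfur_oxidizer_profile(catalog):
    # coupling H2/sulfide/thiosulfate oxidation to O2 or S0 reduction
    donors, acceptors = donor_acceptor_profile(
        {"nife_1a", "sqo", "sox", "sreabc", "cox"}, catalog
    )
    assert donors == {"H2", "sulfide", "thiosulfate"}
    assert acceptors == {"O2", "S0_polysulfide"}


def test_hydrogenotrophic_sulfate_reducer_profile(catalog):
    donors, acceptors = donor_acceptor_profile({"nife_1c", "sat", "aprab", "dsrab"}, catalog)
    assert donors == {"H2"}
    assert acceptors == {"sulfate"}


def test_sulfate_reduction_needs_all_three_markers(catalog):
    _, acceptors = donor_acceptor_profile({"sat", "aprab"}, catalog)
    assert "sulfate" not in acceptors


def test_empty_marker_set_gives_empty_profile(catalog):
    assert donor_acceptor_profile(set(), catalog) == (frozenset(), frozenset())


def test_methanogenesis_and_nitrate_alternatives(catalog):
    _, acc = donor_acceptor_profile({"mcra", "napab"}, catalog)
    assert {"CO2_methanogenesis", "nitrate"} <= acc


# -- full call and invariants ------------------------------------------------

def test_call_invariants_hold_on_random_sets(catalog, marker_vocab):
    import numpy as np

    rng = np.random.default_rng(42)
    for _ in range(200):
        markers = {m for m in marker_vocab if rng.random() < 0.3}
        call = classify_markers(markers, catalog)
        assert (call.carbon_class in ("autotroph", "facultative_autotroph")) == bool(
            call.pathways
        )
        if call.oxygen_class == "aerobe":
            assert "O2" in call.acceptors
        if call.carbon_class == "fermenter":
            assert call.oxygen_class != "aerobe"
            assert not call.pathways


def test_identical_marker_sets_give_identical_calls(catalog):
    markers = {"rubisco", "prk", "cox", "sqo"}
    a, b = classify_markers(markers, catalog), classify_markers(set(markers), catalog)
    assert (a.pathways, a.oxygen_class, a.carbon_class, a.donors, a.acceptors) == (
        b.pathways, b.oxygen_class, b.carbon_class, b.donors, b.acceptors
    )


# -- OTU-level cross-check ---------------------------------------------------

def _otu(members):
    return OtuCluster("OTU_01", frozenset(members), sorted(members)[0])


def test_otu_union_presence_dominates_absence(catalog):
    call = call_otu_guild(_otu({"A", "B"}), {"A": set(), "B": {"cox"}}, catalog)
    assert call.oxygen_class == "aerobe"
    assert call.evidence["members"]["cox"] == ["B"]


def test_otu_union_completes_split_conjunction(catalog):
    call = call_otu_guild(_otu({"A", "B"}), {"A": {"rubisco"}, "B": {"prk"}}, catalog)
    assert set(call.pathways) == {"CBB"}


def test_single_member_otu_equals_member_call(catalog):
    markers = {"codh_acs", "fhs", "cyd"}
    solo = call_otu_guild(_otu({"A"}), {"A": markers}, catalog)
    direct = classify_markers(markers, catalog)
    assert (solo.pathways, solo.oxygen_class, solo.carbon_class) == (
        direct.pathways, direct.oxygen_class, direct.carbon_class
    )


def test_empty_otu_is_an_error(catalog):
    with pytest.raises(ValueError):
        call_otu_guild(_otu({"A"}), {"B": {"cox"}}, catalog)


# -- monotonicity ------------------------------------------------------------

@settings(max_examples=200, deadline=None, derandomize=True)
@given(data=st.data())
def test_rule_engine_monotone_in_presence_evidence(data, catalog, marker_vocab):
    """Adding a marker never removes a pathway, donor or acceptor call.

    Sole documented exception: the low-confidence DC/4-HB call is superseded
    when the added marker completes the 3HP set — in that case the 3HP/4HB
    rule covers the same evidence, so the call is refined, not lost.
    """
    markers = set(data.draw(st.sets(st.sampled_from(marker_vocab), max_size=12)))
    extra = data.draw(st.sampled_from(marker_vocab))
    before = classify_markers(markers, catalog)
    after = classify_markers(markers | {extra}, catalog)
    lost = set(before.pathways) - set(after.pathways)
    assert lost <= {"DC4HB"}
    if lost:
        assert {"HP3", "HP3HB4"} <= set(after.pathways)
    assert before.donors <= after.donors
    assert before.acceptors <= after.acceptors
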