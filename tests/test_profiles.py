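"""Depth-profile aggregation and abundance filters."""

import pytest

from sedguilds.classify import GuildCall
from sedguilds.clustering import OtuCluster
from sedguilds.profiles import abundance_filter, guild_profile, profile_table


def otu(otu_id, abundances):
    member = f"{otu_id}_m"
    return OtuCluster(otu_id, frozenset({member}), member, dict(abundances))


def call(otu_id, oxygen="aerobe", carbon="heterotroph", pathways=()):
    return GuildCall(
        otu_id=otu_id,
        pathways={p: "high" for p in pathways},
        oxygen_class=oxygen,
        carbon_class=carbon,
    )


# -- abundance filter --------------------------------------------------------

def test_exactly_at_cutoff_goes_to_other():
    o = otu("OTU_01", {0.0: 5.0, 5.0: 5.0})
    kept, other = abundance_filter([o], min_pct=5, scope="any_depth")
    assert not kept and other == [o]


def test_exceeding_at_one_depth_keeps_the_otu():
    o = otu("OTU_01", {0.0: 1.0, 5.0: 6.0})
    kept, _ = abundance_filter([o], min_pct=5, scope="any_depth")
    assert kept == [o]


def test_zero_cutoff_keeps_everything():
    otus = [otu(f"OTU_{i:02d}", {0.0: 1.0}) for i in range(4)]
    kept, other = abundance_filter(otus, min_pct=0)
    assert len(kept) == 4 and not other


def test_per_depth_scope_filters_within_each_depth():
    a = otu("OTU_01", {0.0: 6.0, 5.0: 1.0})
    b = otu("OTU_02", {0.0: 1.0, 5.0: 6.0})
    out = abundance_filter([a, b], min_pct=5, scope="per_depth")
    assert [o.otu_id for o in out[0.0][0]] == ["OTU_01"]
    assert [o.otu_id for o in out[5.0][0]] == ["OTU_02"]


# -- guild profiles ----------------------------------------------------------

def test_two_otu_renormalization_60_40():
    otus = [otu("OTU_01", {0.0: 30.0}), otu("OTU_02", {0.0: 20.0})]
    calls = {
        "OTU_01": call("OTU_01", "aerobe", "heterotroph"),
        "OTU_02": call("OTU_02", "anaerobe", "autotroph", pathways=("WL",)),
    }
    prof = guild_profile(otus, calls, 0.0)
    assert prof.guild_fractions[("aerobe", "heterotroph")] == pytest.approx(60.0)
    assert prof.guild_fractions[("anaerobe", "autotroph")] == pytest.approx(40.0)
    assert prof.pathway_fractions["WL"] == pytest.approx(40.0)


def test_single_guild_is_100_percent():
    otus = [otu("OTU_01", {0.0: 7.0}), otu("OTU_02", {0.0: 3.0})]
    calls = {o.otu_id: call(o.otu_id, "anaerobe", "fermenter") for o in otus}
    prof = guild_profile(otus, calls, 0.0)
    assert prof.guild_fractions[("anaerobe", "fermenter")] == pytest.approx(100.0)


def test_fractions_sum_to_100_within_tolerance():
    import numpy as np

    rng = np.random.default_rng(3)
    otus = [otu(f"OTU_{i:02d}", {0.0: float(x)}) for i, x in enumerate(rng.dirichlet([1] * 9) * 100)]
    kinds = [("aerobe", "heterotroph"), ("anaerobe", "autotroph"), ("anaerobe", "fermenter")]
    calls = {o.otu_id: call(o.otu_id, *kinds[i % 3]) for i, o in enumerate(otus)}
    prof = guild_profile(otus, calls, 0.0)
    assert sum(prof.guild_fractions.values()) == pytest.approx(100.0, abs=1e-9)


def test_profile_invariant_to_otu_order():
    otus = [otu("OTU_01", {0.0: 30.0}), otu("OTU_02", {0.0: 20.0}), otu("OTU_03", {0.0: 10.0})]
    calls = {o.otu_id: call(o.otu_id) for o in otus}
    a = guild_profile(otus, calls, 0.0)
    b = guild_profile(list(reversed(otus)), calls, 0.0)
    assert a.guild_fractions == b.guild_fractions


def test_missing_call_counts_as_unclassified_and_raw_mode():
    otus = [otu("OTU_01", {0.0: 30.0}), otu("OTU_02", {0.0: 20.0})]
    calls = {"OTU_01": call("OTU_01")}
    prof = guild_profile(otus, calls, 0.0, normalize=False)
    assert prof.unclassified_fraction == pytest.approx(20.0)
    assert prof.guild_fractions[("aerobe", "heterotroph")] == pytest.approx(30.0)
    # renormalized mode: the classified OTU carries the whole community
    assert guild_profile(otus, calls, 0.0).guild_fractions[
        ("aerobe", "heterotroph")
    ] == pytest.approx(100.0)


def test_multi_pathway_otu_contributes_full_abundance_to_each():
    otus = [otu("OTU_01", {0.0: 50.0}), otu("OTU_02", {0.0: 50.0})]
    calls = {
        "OTU_01": call("OTU_01", "anaerobe", "autotroph", pathways=("WL", "rTCA")),
        "OTU_02": call("OTU_02"),
    }
    prof = guild_profile(otus, calls, 0.0)
    assert prof.pathway_fractions["WL"] == pytest.approx(50.0)
    assert prof.pathway_fractions["rTCA"] == pytest.approx(50.0)


def test_profile_table_long_format():
    otus = [otu("OTU_01", {0.0: 60.0, 5.0: 40.0})]
    calls = {"OTU_01": call("OTU_01")}
    table = profile_table(otus, calls)
    assert set(table.columns) == {"depth_cm", "kind", "category", "fraction_pct"}
    assert sorted(table["depth_cm"].unique()) == [0.0, 5.0]
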