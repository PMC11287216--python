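"""QC filtering, ANI clustering (vs a brute-force oracle), representative
selection and abundance aggregation."""

import numpy as np
import pytest

from sedguilds.clustering import (
    AniMatrix,
    ClusteringInputError,
    MagRecord,
    cluster_otus,
    otu_abundance,
    qc_filter,
    select_representative,
)


def mag(mag_id, depth=0.0, comp=90.0, cont=1.0, frac=1.0):
    return MagRecord(mag_id, depth, comp, cont, frac)


def square_ani(mag_ids, pairs, default=80.0):
    """Symmetric matrix from {frozenset({a,b}): ani} overrides."""
    n = len(mag_ids)
    vals = np.full((n, n), default)
    np.fill_diagonal(vals, 100.0)
    for pair, ani in pairs.items():
        a, b = sorted(pair)
        i, j = mag_ids.index(a), mag_ids.index(b)
        vals[i, j] = vals[j, i] = ani
    return AniMatrix(mag_ids=list(mag_ids), values=vals)


def partition(otus):
    return {frozenset(o.member_mag_ids) for o in otus}


# -- QC ---------------------------------------------------------------------

@pytest.mark.parametrize(
    "comp, cont, kept",
    [
        (49.9, 5.0, False),  # fails strict > 50
        (50.0, 5.0, False),
        (60.0, 10.0, False),  # fails strict < 10
        (60.0, 9.9, True),
        (50.1, 0.0, True),
    ],
)
def test_qc_thresholds_are_strict(comp, cont, kept):
    retained, rejected = qc_filter([mag("A", comp=comp, cont=cont)])
    assert bool(retained) is kept
    assert bool(rejected) is not kept


# -- clustering -------------------------------------------------------------

def test_chain_links_into_one_otu():
    mags = [mag(x) for x in "ABC"]
    ani = square_ani(["A", "B", "C"], {frozenset("AB"): 97, frozenset("BC"): 96,
                                       frozenset("AC"): 94})
    otus = cluster_otus(ani, mags)
    assert partition(otus) == {frozenset("ABC")}


def test_all_below_threshold_gives_singletons():
    mags = [mag(x) for x in "ABC"]
    otus = cluster_otus(square_ani(["A", "B", "C"], {}, default=94.0), mags)
    assert partition(otus) == {frozenset("A"), frozenset("B"), frozenset("C")}


def test_exactly_95_does_not_link():
    mags = [mag(x) for x in "AB"]
    otus = cluster_otus(square_ani(["A", "B"], {frozenset("AB"): 95.0}), mags)
    assert len(otus) == 2


def test_mag_absent_from_matrix_is_an_error():
    with pytest.raises(ClusteringInputError, match="Z"):
        cluster_otus(square_ani(["A"], {}), [mag("A"), mag("Z")])


def test_otu_ids_are_deterministic_by_smallest_member():
    mags = [mag(x) for x in "ABCD"]
    ani = square_ani(list("ABCD"), {frozenset("CD"): 99})
    otus = cluster_otus(ani, mags)
    assert [o.otu_id for o in otus] == ["OTU_01", "OTU_02", "OTU_03"]
    assert otus[2].member_mag_ids == frozenset("CD")


def _oracle_partition(mag_ids, sym, threshold):
    """Independent transitive-closure oracle: repeated neighbour expansion."""
    unassigned = set(mag_ids)
    idx = {m: i for i, m in enumerate(mag_ids)}
    comps = set()
    while unassigned:
        seedling = unassigned.pop()
        comp = {seedling}
        frontier = {seedling}
        while frontier:
            nxt = set()
            for a in frontier:
                for b in list(unassigned):
                    if sym[idx[a], idx[b]] > threshold:
                        nxt.add(b)
                        unassigned.discard(b)
            comp |= nxt
            frontier = nxt
        comps.add(frozenset(comp))
    return comps


def test_clustering_matches_bruteforce_oracle_on_random_matrices():
    rng = np.random.default_rng(20260930)
    for _ in range(120):
        n = int(rng.integers(2, 13))
        ids = [f"M{i:02d}" for i in range(n)]
        vals = rng.uniform(85, 100, size=(n, n))
        np.fill_diagonal(vals, 100.0)
        ani = AniMatrix(mag_ids=ids, values=vals)
        otus = cluster_otus(ani, [mag(i) for i in ids], threshold_pct=95.0)
        sym = ani.symmetrized("mean")
        assert partition(otus) == _oracle_partition(ids, sym, 95.0)


def test_partition_invariant_to_input_order():
    rng = np.random.default_rng(7)
    ids = [f"M{i}" for i in range(8)]
    vals = rng.uniform(90, 100, size=(8, 8))
    np.fill_diagonal(vals, 100.0)
    ani = AniMatrix(mag_ids=ids, values=vals)
    perm = list(rng.permutation(8))
    ani_perm = AniMatrix(
        mag_ids=[ids[i] for i in perm], values=vals[np.ix_(perm, perm)]
    )
    mags = [mag(i) for i in ids]
    assert partition(cluster_otus(ani, mags)) == partition(
        cluster_otus(ani_perm, list(reversed(mags)))
    )


def test_raising_threshold_only_refines_the_partition():
    rng = np.random.default_rng(11)
    ids = [f"M{i}" for i in range(10)]
    vals = rng.uniform(90, 100, size=(10, 10))
    np.fill_diagonal(vals, 100.0)
    ani = AniMatrix(mag_ids=ids, values=vals)
    mags = [mag(i) for i in ids]
    low = partition(cluster_otus(ani, mags, threshold_pct=93.0))
    high = partition(cluster_otus(ani, mags, threshold_pct=97.0))
    for cluster_high in high:
        assert any(cluster_high <= cluster_low for cluster_low in low)


def test_missing_direction_uses_present_value():
    vals = np.array([[100.0, 97.0], [np.nan, 100.0]])
    ani = AniMatrix(mag_ids=["A", "B"], values=vals)
    assert ani.symmetrized("mean")[0, 1] == 97.0
    assert len(cluster_otus(ani, [mag("A"), mag("B")])) == 1


# -- representative selection ----------------------------------------------

def test_representative_maximizes_completeness_first():
    mags_by_id = {"A": mag("A", comp=90), "B": mag("B", comp=80, cont=0)}
    assert select_representative({"A", "B"}, mags_by_id) == "A"


def test_representative_minimizes_contamination_second():
    mags_by_id = {"A": mag("A", cont=5), "B": mag("B", cont=2)}
    assert select_representative({"A", "B"}, mags_by_id) == "B"


def test_representative_maximizes_abundance_third_then_lexicographic():
    mags_by_id = {"A": mag("A", frac=1.0), "B": mag("B", frac=3.0)}
    assert select_representative({"A", "B"}, mags_by_id) == "B"
    tied = {"B": mag("B"), "A": mag("A")}
    assert select_representative({"A", "B"}, tied) == "A"


# -- abundance aggregation ---------------------------------------------------

def test_otu_abundance_sums_members_per_depth_and_zero_fills():
    mags_by_id = {
        "A": mag("A", depth=5, frac=3.0),
        "B": mag("B", depth=5, frac=2.5),
        "C": mag("C", depth=0, frac=1.0),
    }
    ab = otu_abundance({"A", "B", "C"}, mags_by_id, depths=[0, 5, 30])
    assert ab[5.0] == pytest.approx(5.5)
    assert ab[0.0] == pytest.approx(1.0)
    assert ab[30.0] == 0.0
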