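"""Self-validation experiments: pipeline recovery of planted ground truth
and agreement of the clusterer with an independent brute-force oracle.

These routines power both the test suite and ``scripts/acceptance.py``; they
always recompute from scratch.
"""

from __future__ import annotations

import numpy as np

from .catalog import MarkerCatalog, default_catalog
from .classify import call_otu_guild, classify_markers
from .clustering import AniMatrix, MagRecord, cluster_otus, qc_filter
from .profiles import guild_profile
from .simulate import ScenarioConfig, SyntheticDataset, generate

AUTOTROPH_CLASSES = ("autotroph", "facultative_autotroph")


def bruteforce_partition(mag_ids, sym: np.ndarray, threshold: float) -> set:
    """Transitive closure by plain breadth-first neighbour expansion —
    independent of the graph-library route used by ``cluster_otus``."""
    idx = {m: i for i, m in enumerate(mag_ids)}
    unassigned = set(mag_ids)
    parts = set()
    while unassigned:
        start = unassigned.pop()
        comp, frontier = {start}, {start}
        while frontier:
            nxt = set()
            for a in frontier:
                for b in list(unassigned):
                    v = sym[idx[a], idx[b]]
                    if np.isfinite(v) and v > threshold:
                        nxt.add(b)
                        unassigned.discard(b)
            comp |= nxt
            frontier = nxt
        parts.add(frozenset(comp))
    return parts


def clustering_oracle_agreement(
    n_matrices: int = 120, seed: int = 0, max_n: int = 12, threshold: float = 95.0
) -> float:
    """% of random ANI matrices on which the clusterer matches the oracle."""
    rng = np.random.default_rng(seed)
    agree = 0
    for _ in range(n_matrices):
        n = int(rng.integers(2, max_n + 1))
        ids = [f"M{i:02d}" for i in range(n)]
        vals = rng.uniform(85.0, 100.0, size=(n, n))
        np.fill_diagonal(vals, 100.0)
        ani = AniMatrix(mag_ids=ids, values=vals)
        mags = [MagRecord(i, 0.0, 90.0, 1.0, 0.0) for i in ids]
        got = {o.member_mag_ids for o in cluster_otus(ani, mags, threshold_pct=threshold)}
        want = bruteforce_partition(ids, ani.symmetrized("mean"), threshold)
        agree += got == want
    return 100.0 * agree / n_matrices


def _pipeline_calls(data: SyntheticDataset, catalog: MarkerCatalog):
    """Run QC -> clustering -> OTU-level classification on a synthetic set."""
    retained, _ = qc_filter(data.mags)
    otus = cluster_otus(data.ani, retained, depths=list(data.config.depths_cm))
    marker_sets = {m.mag_id: m.markers for m in data.mags}
    calls = {o.otu_id: call_otu_guild(o, marker_sets, catalog) for o in otus}
    return otus, calls


def noise_free_recovery(seed: int = 0, catalog: MarkerCatalog | None = None) -> float:
    """% of synthetic OTUs whose guild call matches the planted truth when
    MAGs are complete (completeness 100, contamination 0)."""
    catalog = catalog or default_catalog()
    cfg = ScenarioConfig(
        seed=seed,
        completeness_mean=100.0,
        completeness_sd=1e-9,
        contamination_mean=0.0,
        contamination_sd=1e-9,
    )
    data = generate(cfg)
    otus, calls = _pipeline_calls(data, catalog)
    by_members = {o.member_mag_ids: o for o in otus}
    ok = 0
    total = 0
    for label, members in data.truth.otu_members.items():
        total += 1
        otu = by_members.get(frozenset(members))
        if otu is None:
            continue
        truth = data.truth.otu_guild[label]
        call = calls[otu.otu_id]
        ok += (
            call.oxygen_class == truth["oxygen_class"]
            and call.carbon_class == truth["carbon_class"]
            and frozenset(call.pathways) == truth["pathways"]
            and call.donors == truth["donors"]
            and call.acceptors == truth["acceptors"]
        )
    return 100.0 * ok / total


def depth_pattern_holds(otus, calls, depths) -> bool:
    """Qualitative redox-gradient pattern: autotroph and WL fractions
    non-decreasing with depth, aerobe fraction non-increasing."""
    profiles = [guild_profile(otus, calls, d) for d in sorted(depths)]
    autotroph = [p.carbon_fraction(*AUTOTROPH_CLASSES) for p in profiles]
    wl = [p.pathway_fractions.get("WL", 0.0) for p in profiles]
    aerobe = [p.oxygen_fraction("aerobe") for p in profiles]
    nondecr = lambda xs: all(a <= b for a, b in zip(xs, xs[1:]))  # noqa: E731
    return nondecr(autotroph) and nondecr(wl) and nondecr(aerobe[::-1])


def default_scenario_sweep(n_seeds: int = 20, seed: int = 0) -> dict:
    """Run the default scenario across seeds; report exact-partition
    recovery and qualitative depth-pattern rates (both in %)."""
    catalog = default_catalog()
    rng = np.random.default_rng(seed)
    sub_seeds = rng.integers(0, 2**31 - 1, size=n_seeds)
    part_ok = pattern_ok = 0
    for s in sub_seeds:
        data = generate(seed=int(s))
        otus, calls = _pipeline_calls(data, catalog)
        got = frozenset(o.member_mag_ids for o in otus)
        part_ok += got == data.truth.partition
        pattern_ok += depth_pattern_holds(otus, calls, data.config.depths_cm)
    return {
        "n_seeds": n_seeds,
        "partition_recovery_pct": 100.0 * part_ok / n_seeds,
        "depth_pattern_pct": 100.0 * pattern_ok / n_seeds,
    }


def monotonicity_violations(
    n_trials: int = 300, seed: int = 0, catalog: MarkerCatalog | None = None
) -> int:
    """Count of random (marker set, added marker) trials where adding a
    marker removed a donor, acceptor, or pathway call — excluding the
    documented DC/4-HB -> 3HP/4HB supersession."""
    catalog = catalog or default_catalog()
    vocab = sorted(catalog.markers)
    rng = np.random.default_rng(seed)
    violations = 0
    for _ in range(n_trials):
        markers = {m for m in vocab if rng.random() < 0.25}
        extra = vocab[int(rng.integers(len(vocab)))]
        before = classify_markers(markers, catalog)
        after = classify_markers(markers | {extra}, catalog)
        lost = set(before.pathways) - set(after.pathways)
        superseded = lost == {"DC4HB"} and {"HP3", "HP3HB4"} <= set(after.pathways)
        if (lost and not superseded) or not (
            before.donors <= after.donors and before.acceptors <= after.acceptors
        ):
            violations += 1
    return violations
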