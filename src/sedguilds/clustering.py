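"""MAG quality filtering, ANI-based OTU collapsing, representative selection
and per-depth abundance aggregation.

MAGs passing quality control (>50% estimated completeness, <10%
contamination, both strict) are collapsed into operational taxonomic units
(OTUs) wherever a chain of pairwise average-nucleotide-identity values
exceeds 95% (single-linkage connected components on the symmetrized ANI
graph). Each OTU gets one representative MAG, chosen to maximize
completeness, then minimize contamination, then maximize relative abundance,
with a deterministic lexicographic tie-break. OTU relative abundance per
depth is the sum of member read fractions at that depth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np


class ClusteringInputError(ValueError):
    """Raised when MAGs and the ANI matrix are inconsistent."""


@dataclass(frozen=True)
class MagRecord:
    """One metagenome-assembled genome and its per-depth read fraction."""

    mag_id: str
    depth_cm: float
    completeness_pct: float
    contamination_pct: float
    read_fraction_pct: float  # % of mapped reads at this MAG's source depth
    markers: frozenset = frozenset()
    taxonomy: str = ""

    def __post_init__(self) -> None:
        if not 0.0 <= self.completeness_pct <= 100.0:
            raise ClusteringInputError(f"{self.mag_id}: completeness outside [0, 100]")
        if self.contamination_pct < 0:
            raise ClusteringInputError(f"{self.mag_id}: contamination negative")
        if not 0.0 <= self.read_fraction_pct <= 100.0:
            raise ClusteringInputError(f"{self.mag_id}: read fraction outside [0, 100]")


@dataclass
class AniMatrix:
    """Pairwise ANI percentages, possibly asymmetric, NaN where missing."""

    mag_ids: list
    values: np.ndarray  # square, diagonal 100

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.mag_ids)
        if self.values.shape != (n, n):
            raise ClusteringInputError("ANI matrix shape does not match mag_ids")
        finite = self.values[np.isfinite(self.values)]
        if finite.size and (finite.min() < 0 or finite.max() > 100):
            raise ClusteringInputError("ANI values outside [0, 100]")
        if not np.allclose(np.diag(self.values)[np.isfinite(np.diag(self.values))], 100.0):
            raise ClusteringInputError("ANI diagonal must be 100")
        self._index = {m: i for i, m in enumerate(self.mag_ids)}

    @classmethod
    def from_pairs(cls, pairs, mag_ids=None) -> "AniMatrix":
        """Build from (query, reference, ani) triples (fastANI long format).
        Missing pairs stay NaN; the diagonal is set to 100."""
        if mag_ids is None:
            seen = []
            for q, r, _ in pairs:
                for m in (q, r):
                    if m not in seen:
                        seen.append(m)
            mag_ids = seen
        idx = {m: i for i, m in enumerate(mag_ids)}
        n = len(mag_ids)
        vals = np.full((n, n), np.nan)
        np.fill_diagonal(vals, 100.0)
        for q, r, ani in pairs:
            if q not in idx or r not in idx:
                raise ClusteringInputError(f"ANI pair references unknown MAG {q!r}/{r!r}")
            vals[idx[q], idx[r]] = float(ani)
        return cls(mag_ids=list(mag_ids), values=vals)

    def symmetrized(self, method: str = "mean") -> np.ndarray:
        """Combine the two directed values per pair ({mean, max, min});
        where only one direction is present, use it."""
        v = self.values
        vt = v.T
        both = np.isfinite(v) & np.isfinite(vt)
        if method == "mean":
            combined = (v + vt) / 2.0
        elif method == "max":
            combined = np.maximum(v, vt)
        elif method == "min":
            combined = np.minimum(v, vt)
        else:
            raise ClusteringInputError(f"unknown symmetrize method {method!r}")
        out = np.where(both, combined, np.where(np.isfinite(v), v, vt))
        return out


@dataclass
class OtuCluster:
    """A >threshold-ANI group of MAGs with a representative and abundances."""

    otu_id: str
    member_mag_ids: frozenset
    representative_mag_id: str
    abundance_by_depth: dict = field(default_factory=dict)  # depth_cm -> %


def qc_filter(mags, min_completeness: float = 50.0, max_contamination: float = 10.0):
    """Split MAGs into (retained, rejected) by strict quality thresholds:
    retained iff completeness > min AND contamination < max."""
    if not (0 <= min_completeness <= 100 and 0 <= max_contamination <= 100):
        raise ClusteringInputError("thresholds must be in [0, 100]")
    retained, rejected = [], []
    for mag in mags:
        ok = (
            mag.completeness_pct > min_completeness
            and mag.contamination_pct < max_contamination
        )
        (retained if ok else rejected).append(mag)
    return retained, rejected


def select_representative(member_mag_ids, mags_by_id) -> str:
    """Representative: maximize completeness, then minimize contamination,
    then maximize read fraction; final ties broken by smallest mag_id."""
    members = sorted(member_mag_ids)
    if not members:
        raise ClusteringInputError("cannot select a representative for an empty OTU")

    def key(mag_id):
        m = mags_by_id[mag_id]
        return (-m.completeness_pct, m.contamination_pct, -m.read_fraction_pct, m.mag_id)

    return min(members, key=key)


def otu_abundance(member_mag_ids, mags_by_id, depths=None) -> dict:
    """Per-depth OTU abundance: sum of member read fractions at each depth;
    depths with no member map to 0 when ``depths`` enumerates them."""
    out = {float(d): 0.0 for d in (depths or ())}
    for mag_id in member_mag_ids:
        m = mags_by_id[mag_id]
        d = float(m.depth_cm)
        out[d] = out.get(d, 0.0) + m.read_fraction_pct
    return out


def cluster_otus(
    ani: AniMatrix,
    mags,
    threshold_pct: float = 95.0,
    symmetrize: str = "mean",
    depths=None,
) -> list:
    """Collapse MAGs into OTUs by single-linkage on symmetrized ANI strictly
    above ``threshold_pct``.

    Two MAGs share an OTU iff connected by a chain of pairs with symmetrized
    ANI > threshold. OTU ids are assigned deterministically: clusters sorted
    by their smallest member id and numbered OTU_01, OTU_02, ...
    """
    mags = list(mags)
    mags_by_id = {m.mag_id: m for m in mags}
    missing = [m.mag_id for m in mags if m.mag_id not in ani._index]
    if missing:
        raise ClusteringInputError(f"MAG(s) absent from ANI matrix: {missing}")

    sym = ani.symmetrized(symmetrize)
    graph = nx.Graph()
    graph.add_nodes_from(mags_by_id)
    keep = set(mags_by_id)
    for i, a in enumerate(ani.mag_ids):
        if a not in keep:
            continue
        for j in range(i + 1, len(ani.mag_ids)):
            b = ani.mag_ids[j]
            if b not in keep:
                continue
            v = sym[i, j]
            if np.isfinite(v) and v > threshold_pct:
                graph.add_edge(a, b)

    components = sorted(nx.connected_components(graph), key=lambda c: min(c))
    width = max(2, len(str(len(components))))
    clusters = []
    for k, comp in enumerate(components, start=1):
        members = frozenset(comp)
        clusters.append(
            OtuCluster(
                otu_id=f"OTU_{k:0{width}d}",
                member_mag_ids=members,
                representative_mag_id=select_representative(members, mags_by_id),
                abundance_by_depth=otu_abundance(members, mags_by_id, depths=depths),
            )
        )
    return clusters
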