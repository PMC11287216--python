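"""Depth-resolved community profiles: guild and pathway fractions per depth,
with the display/analysis abundance filters.

An OTU's contribution at a depth is its summed member read fraction there.
Guild fractions are keyed by (oxygen_class, carbon_class); pathway fractions
sum the abundances of OTUs whose call includes each pathway (an OTU with two
pathways contributes its full abundance to both). By default fractions are
renormalized over classified, retained OTUs so they sum to 100 at each depth;
``normalize=False`` keeps raw % of all mapped reads and reports the
unclassified remainder.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

logger = logging.getLogger(__name__)


@dataclass
class DepthProfile:
    """Community composition at one depth horizon."""

    depth_cm: float
    guild_fractions: dict = field(default_factory=dict)  # (oxygen, carbon) -> %
    pathway_fractions: dict = field(default_factory=dict)  # pathway_id -> %
    other_fraction: float = 0.0  # OTUs below the display threshold
    unclassified_fraction: float = 0.0

    def oxygen_fraction(self, oxygen_class: str) -> float:
        return sum(v for (ox, _), v in self.guild_fractions.items() if ox == oxygen_class)

    def carbon_fraction(self, *carbon_classes) -> float:
        return sum(v for (_, cc), v in self.guild_fractions.items() if cc in carbon_classes)


def abundance_filter(otus, min_pct: float = 2.0, scope: str = "any_depth"):
    """Split OTUs into (kept, other) by a strict relative-abundance cutoff.

    ``any_depth``: kept iff abundance strictly exceeds ``min_pct`` at at
    least one depth (the display convention; the analysis convention uses
    min_pct=5). ``per_depth`` returns {depth: (kept, other)} applying the
    cutoff within each depth independently.
    """
    otus = list(otus)
    if not 0.0 <= min_pct <= 100.0:
        raise ValueError("min_pct must be in [0, 100]")
    if scope == "any_depth":
        kept = [o for o in otus if any(v > min_pct for v in o.abundance_by_depth.values())]
        kept_ids = {o.otu_id for o in kept}
        return kept, [o for o in otus if o.otu_id not in kept_ids]
    if scope == "per_depth":
        depths = sorted({d for o in otus for d in o.abundance_by_depth})
        out = {}
        for d in depths:
            kept = [o for o in otus if o.abundance_by_depth.get(d, 0.0) > min_pct]
            kept_ids = {o.otu_id for o in kept}
            out[d] = (kept, [o for o in otus if o.otu_id not in kept_ids])
        return out
    raise ValueError(f"unknown scope {scope!r}")


def guild_profile(otus, calls: dict, depth: float, normalize: bool = True) -> DepthProfile:
    """Aggregate OTU calls into guild and pathway fractions at one depth.

    ``calls`` maps otu_id -> GuildCall. OTUs without a call are counted as
    unclassified (with a warning when abundant) and excluded from the
    renormalization basis.
    """
    depth = float(depth)
    guild_raw: dict = {}
    pathway_raw: dict = {}
    classified_total = 0.0
    unclassified = 0.0
    for otu in sorted(otus, key=lambda o: o.otu_id):
        ab = otu.abundance_by_depth.get(depth, 0.0)
        if ab <= 0:
            continue
        call = calls.get(otu.otu_id)
        if call is None:
            if ab > 1.0:
                logger.warning(
                    "OTU %s (%.1f%% at %g cm) has no guild call; counted unclassified",
                    otu.otu_id, ab, depth,
                )
            unclassified += ab
            continue
        classified_total += ab
        key = (call.oxygen_class, call.carbon_class)
        guild_raw[key] = guild_raw.get(key, 0.0) + ab
        for pid in call.pathways:
            pathway_raw[pid] = pathway_raw.get(pid, 0.0) + ab

    if normalize and classified_total > 0:
        scale = 100.0 / classified_total
    else:
        scale = 1.0
    return DepthProfile(
        depth_cm=depth,
        guild_fractions={k: v * scale for k, v in guild_raw.items()},
        pathway_fractions={k: v * scale for k, v in pathway_raw.items()},
        unclassified_fraction=unclassified,
    )


def profile_table(otus, calls: dict, depths=None, normalize: bool = True) -> pd.DataFrame:
    """Long-format profile across depths: columns depth_cm, kind, category,
    fraction_pct. ``kind`` is guild | pathway | unclassified."""
    if depths is None:
        depths = sorted({d for o in otus for d in o.abundance_by_depth})
    rows = []
    for d in depths:
        prof = guild_profile(otus, calls, d, normalize=normalize)
        for (ox, cc), v in sorted(prof.guild_fractions.items()):
            rows.append(
                {"depth_cm": d, "kind": "guild", "category": f"{ox}/{cc}", "fraction_pct": v}
            )
        for pid, v in sorted(prof.pathway_fractions.items()):
            rows.append(
                {"depth_cm": d, "kind": "pathway", "category": pid, "fraction_pct": v}
            )
        rows.append(
            {
                "depth_cm": d,
                "kind": "unclassified",
                "category": "unclassified",
                "fraction_pct": prof.unclassified_fraction,
            }
        )
    return pd.DataFrame(rows, columns=["depth_cm", "kind", "category", "fraction_pct"])


def plot_profiles(profiles, path=None):
    """Stacked-bar guild composition by depth; returns the matplotlib figure.

    Optional convenience output — styling is deliberately plain.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    profiles = sorted(profiles, key=lambda p: p.depth_cm)
    categories = sorted({k for p in profiles for k in p.guild_fractions})
    fig, ax = plt.subplots(figsize=(6, 4))
    bottoms = [0.0] * len(profiles)
    for cat in categories:
        vals = [p.guild_fractions.get(cat, 0.0) for p in profiles]
        ax.bar(
            [str(p.depth_cm) for p in profiles],
            vals,
            bottom=bottoms,
            label="/".join(cat),
        )
        bottoms = [b + v for b, v in zip(bottoms, vals)]
    ax.set_xlabel("depth (cm)")
    ax.set_ylabel("fraction of classified community (%)")
    ax.legend(fontsize=7, loc="center left", bbox_to_anchor=(1.0, 0.5))
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
    return fig
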