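"""Synthetic sediment-community generator with planted ground truth.

Emits every input the pipeline consumes — MAG metadata, a pairwise ANI
matrix, a long-format marker table and a porewater chemistry table —
together with the ground truth planted into them, so each pipeline stage is
testable end to end without any external data.

What is emulated:

* **Depth-structured guild composition.** Each OTU is assigned one of six
  guild archetypes (marker templates drawn from the kinds of populations
  described in hypersaline sediment cores: aerobic halophilic heterotrophs,
  sulfur-oxidizing CBB facultative autotrophs, anaerobic WL acetogens,
  hydrogenotrophic sulfate reducers, fermenters, rTCA autotrophs). Expected
  guild mixtures per depth follow the canonical redox gradient: aerobes
  decline and anaerobic autotrophs (especially WL) rise with depth.
* **Abundances.** Per depth, OTU read fractions are a Dirichlet draw whose
  concentration is proportional to the depth's guild mixture; fractions sum
  to exactly 100.
* **MAG incompleteness.** Each marker of the template is retained with
  probability completeness/100 (Bernoulli); contamination adds foreign
  markers drawn from other archetypes at a rate proportional to the
  contamination estimate.
* **ANI block structure.** Within-OTU pairs draw from a high-ANI
  distribution, between-OTU pairs from a well-separated low one; small
  directional jitter makes the matrix asymmetric like real fastANI output.
* **Porewater chemistry.** Smooth parametric depth gradients for pH,
  dissolved CO2 and tracer DPM rates.

All randomness flows from one root seed via ``numpy.random.default_rng``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .clustering import AniMatrix, MagRecord


class ScenarioConfigError(ValueError):
    """Raised for infeasible scenario configurations."""


#: marker templates and planted truth per guild archetype
GUILD_TEMPLATES = {
    "aerobic_heterotroph": {
        "markers": frozenset(
            {"pfk", "gapdh", "pyk", "glta", "sdh", "mdh", "zwf", "tkt", "rpi", "cox"}
        ),
        "truth": {
            "oxygen_class": "aerobe",
            "carbon_class": "heterotroph",
            "pathways": frozenset(),
            "donors": frozenset(),
            "acceptors": frozenset({"O2"}),
        },
    },
    "sulfur_oxidizing_cbb_autotroph": {
        "markers": frozenset({"rubisco", "prk", "sox", "sqo", "sreabc", "nife_1a", "cox"}),
        "truth": {
            "oxygen_class": "aerobe",
            "carbon_class": "autotroph",
            "pathways": frozenset({"CBB"}),
            "donors": frozenset({"H2", "sulfide", "thiosulfate"}),
            "acceptors": frozenset({"O2", "S0_polysulfide"}),
        },
    },
    "wl_acetogen": {
        "markers": frozenset(
            {
                "codh_acs", "fhs",
                "nife_1a", "nife_3b", "nife_3c", "nife_4g",
                "pfk", "gapdh", "pyk", "glta", "sdh", "mdh", "zwf", "tkt", "rpi",
            }
        ),
        "truth": {
            "oxygen_class": "anaerobe",
            "carbon_class": "facultative_autotroph",
            "pathways": frozenset({"WL"}),
            "donors": frozenset({"H2"}),
            "acceptors": frozenset(),
        },
    },
    "hydrogenotrophic_sulfate_reducer": {
        "markers": frozenset(
            {"nife_1c", "sat", "aprab", "dsrab", "cyd", "pfk", "gapdh", "pyk", "glta", "mdh"}
        ),
        "truth": {
            "oxygen_class": "aerotolerant_anaerobe",
            "carbon_class": "heterotroph",
            "pathways": frozenset(),
            "donors": frozenset({"H2"}),
            "acceptors": frozenset({"sulfate"}),
        },
    },
    "fermenter": {
        "markers": frozenset({"pfk", "gapdh", "pyk", "fefe", "zwf", "tkt"}),
        "truth": {
            "oxygen_class": "anaerobe",
            "carbon_class": "fermenter",
            "pathways": frozenset(),
            "donors": frozenset(),
            "acceptors": frozenset(),
        },
    },
    "rtca_autotroph": {
        "markers": frozenset({"acly", "ccs", "ccl", "por", "nife_3b", "phsa"}),
        "truth": {
            "oxygen_class": "anaerobe",
            "carbon_class": "autotroph",
            "pathways": frozenset({"rTCA"}),
            "donors": frozenset({"H2"}),
            "acceptors": frozenset({"thiosulfate"}),
        },
    },
}

#: expected guild mixture per depth: aerobes decline, WL autotrophs rise
DEFAULT_MIXTURES = {
    0.0: {
        "aerobic_heterotroph": 0.45,
        "sulfur_oxidizing_cbb_autotroph": 0.20,
        "wl_acetogen": 0.08,
        "hydrogenotrophic_sulfate_reducer": 0.10,
        "fermenter": 0.15,
        "rtca_autotroph": 0.02,
    },
    5.0: {
        "aerobic_heterotroph": 0.28,
        "sulfur_oxidizing_cbb_autotroph": 0.20,
        "wl_acetogen": 0.18,
        "hydrogenotrophic_sulfate_reducer": 0.15,
        "fermenter": 0.15,
        "rtca_autotroph": 0.04,
    },
    30.0: {
        "aerobic_heterotroph": 0.08,
        "sulfur_oxidizing_cbb_autotroph": 0.12,
        "wl_acetogen": 0.33,
        "hydrogenotrophic_sulfate_reducer": 0.20,
        "fermenter": 0.15,
        "rtca_autotroph": 0.12,
    },
}


@dataclass(frozen=True)
class PorewaterGradients:
    """Linear depth gradients for the emitted porewater table: brine pH
    drifting slightly acid with depth, dissolved CO2 accumulating, tracer
    uptake rising as the anaerobic autotroph fraction grows."""

    ph_surface: float = 7.3
    ph_slope_per_cm: float = -0.015
    co2_surface_uM: float = 15.0
    co2_slope_uM_per_cm: float = 1.0
    dpm_surface: float = 4.0e5
    dpm_slope_per_cm: float = 1.0e4


@dataclass(frozen=True)
class ScenarioConfig:
    """Default synthetic scenario; see module docstring for what each knob
    emulates. Defaults satisfy the ANI-separation feasibility check
    (mean_within − 2·sd > threshold > mean_between + 2·sd)."""

    n_otus: int = 12
    depths_cm: tuple = (0.0, 5.0, 30.0)
    guild_mixture_by_depth: dict = field(
        default_factory=lambda: {d: dict(m) for d, m in DEFAULT_MIXTURES.items()}
    )
    completeness_mean: float = 85.0
    completeness_sd: float = 8.0
    contamination_mean: float = 2.5
    contamination_sd: float = 2.0
    ani_within_mean: float = 98.0
    ani_within_sd: float = 0.7
    ani_between_mean: float = 80.0
    ani_between_sd: float = 3.0
    ani_threshold_pct: float = 95.0
    ani_direction_jitter_sd: float = 0.15
    contaminant_markers_per_pct: float = 0.02
    dirichlet_concentration: float = 500.0
    gradients: PorewaterGradients = PorewaterGradients()
    seed: int = 0

    def validate(self) -> "ScenarioConfig":
        if self.n_otus < len(GUILD_TEMPLATES):
            raise ScenarioConfigError(
                f"n_otus must be >= {len(GUILD_TEMPLATES)} so every archetype is planted"
            )
        for d, mix in self.guild_mixture_by_depth.items():
            if abs(sum(mix.values()) - 1.0) > 1e-9:
                raise ScenarioConfigError(f"guild mixture at depth {d} does not sum to 1")
            unknown = set(mix) - set(GUILD_TEMPLATES)
            if unknown:
                raise ScenarioConfigError(f"unknown guild(s) in mixture: {sorted(unknown)}")
        if set(map(float, self.depths_cm)) != set(map(float, self.guild_mixture_by_depth)):
            raise ScenarioConfigError("depths_cm and guild_mixture_by_depth disagree")
        if not (
            self.ani_within_mean - 2 * self.ani_within_sd
            > self.ani_threshold_pct
            > self.ani_between_mean + 2 * self.ani_between_sd
        ):
            raise ScenarioConfigError(
                "within/between ANI distributions not separated around the threshold"
            )
        return self


@dataclass
class GroundTruth:
    """Everything planted: OTU membership, per-OTU guild truth, fractions."""

    otu_members: dict  # planted otu label -> list of mag_ids
    otu_guild: dict  # planted otu label -> truth dict (incl. archetype)
    expected_fractions: dict  # depth -> guild archetype -> expected fraction
    realized_fractions: dict  # depth -> guild archetype -> realized fraction

    @property
    def partition(self) -> frozenset:
        return frozenset(frozenset(m) for m in self.otu_members.values())


@dataclass
class SyntheticDataset:
    """Bundle of generated inputs plus their ground truth."""

    mags: list
    ani: AniMatrix
    marker_table: pd.DataFrame  # columns mag_id, marker_id
    porewater: pd.DataFrame
    truth: GroundTruth
    config: ScenarioConfig


def _truncated_normal(rng, mean, sd, low, high, size):
    """Rejection-sampled truncated normal (narrow tails here, cheap)."""
    out = np.empty(size)
    todo = np.arange(size)
    while todo.size:
        draw = rng.normal(mean, sd, todo.size)
        ok = (draw > low) & (draw <= high)
        out[todo[ok]] = draw[ok]
        todo = todo[~ok]
    return out


def make_porewater(
    depths, gradients: PorewaterGradients = PorewaterGradients()
) -> pd.DataFrame:
    """Deterministic porewater table from linear depth gradients."""
    rows = []
    for d in depths:
        d = float(d)
        rows.append(
            {
                "depth_cm": d,
                "ph": gradients.ph_surface + gradients.ph_slope_per_cm * d,
                "co2_uM": gradients.co2_surface_uM + gradients.co2_slope_uM_per_cm * d,
                "dpm_rate": gradients.dpm_surface + gradients.dpm_slope_per_cm * d,
            }
        )
    return pd.DataFrame(rows)


def generate(config: ScenarioConfig | None = None, seed: int | None = None) -> SyntheticDataset:
    """Generate one synthetic dataset; reproducible given the seed."""
    if config is None:
        config = ScenarioConfig()
    if seed is not None:
        config = replace(config, seed=int(seed))
    config.validate()
    rng = np.random.default_rng(config.seed)
    guild_names = sorted(GUILD_TEMPLATES)
    depths = [float(d) for d in config.depths_cm]

    # round-robin archetype assignment: every archetype planted >= once
    otu_labels = [f"TRUE_OTU_{k + 1:02d}" for k in range(config.n_otus)]
    otu_guilds = {lab: guild_names[k % len(guild_names)] for k, lab in enumerate(otu_labels)}
    members_by_guild: dict = {}
    for lab, g in otu_guilds.items():
        members_by_guild.setdefault(g, []).append(lab)

    # per-depth Dirichlet abundances with concentration following the mixture
    abundances: dict = {}  # depth -> otu label -> %
    realized: dict = {}
    for d in depths:
        mix = {g: config.guild_mixture_by_depth[d][g] for g in guild_names}
        alphas = np.array(
            [
                config.dirichlet_concentration * mix[otu_guilds[lab]]
                / len(members_by_guild[otu_guilds[lab]])
                for lab in otu_labels
            ]
        )
        draw = rng.dirichlet(alphas) * 100.0
        draw[-1] = 100.0 - draw[:-1].sum()  # sums to exactly 100
        abundances[d] = dict(zip(otu_labels, draw))
        realized[d] = {
            g: float(sum(abundances[d][lab] for lab in members_by_guild[g]))
            for g in guild_names
        }

    # one MAG per OTU per depth
    n_mags = config.n_otus * len(depths)
    completeness = _truncated_normal(
        rng, config.completeness_mean, config.completeness_sd, 50.0, 100.0, n_mags
    )
    contamination = _truncated_normal(
        rng, config.contamination_mean, config.contamination_sd, -1e-12, 10.0 - 1e-9, n_mags
    )
    contamination = np.clip(contamination, 0.0, None)

    mags, marker_rows = [], []
    otu_members: dict = {lab: [] for lab in otu_labels}
    i = 0
    for lab in otu_labels:
        template = GUILD_TEMPLATES[otu_guilds[lab]]["markers"]
        foreign_pool = sorted(
            set().union(
                *(
                    GUILD_TEMPLATES[g]["markers"]
                    for g in guild_names
                    if g != otu_guilds[lab]
                )
            )
            - template
        )
        for d in depths:
            mag_id = f"MAG_{lab.removeprefix('TRUE_OTU_')}_{int(d):02d}cm"
            comp, cont = completeness[i], contamination[i]
            i += 1
            retained = {m for m in sorted(template) if rng.random() < comp / 100.0}
            n_foreign = rng.poisson(config.contaminant_markers_per_pct * cont)
            if n_foreign and foreign_pool:
                retained |= set(
                    rng.choice(foreign_pool, size=min(n_foreign, len(foreign_pool)), replace=False)
                )
            mags.append(
                MagRecord(
                    mag_id=mag_id,
                    depth_cm=d,
                    completeness_pct=float(comp),
                    contamination_pct=float(cont),
                    read_fraction_pct=float(abundances[d][lab]),
                    markers=frozenset(retained),
                    taxonomy=otu_guilds[lab],
                )
            )
            otu_members[lab].append(mag_id)
            marker_rows.extend({"mag_id": mag_id, "marker_id": m} for m in sorted(retained))

    # ANI block structure, asymmetric via directional jitter
    mag_ids = [m.mag_id for m in mags]
    otu_of = {m: lab for lab, ms in otu_members.items() for m in ms}
    n = len(mag_ids)
    vals = np.full((n, n), np.nan)
    np.fill_diagonal(vals, 100.0)
    for a in range(n):
        for b in range(a + 1, n):
            same = otu_of[mag_ids[a]] == otu_of[mag_ids[b]]
            base = rng.normal(
                config.ani_within_mean if same else config.ani_between_mean,
                config.ani_within_sd if same else config.ani_between_sd,
            )
            jit = rng.normal(0.0, config.ani_direction_jitter_sd, 2)
            vals[a, b] = np.clip(base + jit[0], 0.0, 100.0)
            vals[b, a] = np.clip(base + jit[1], 0.0, 100.0)
    ani = AniMatrix(mag_ids=mag_ids, values=vals)

    truth = GroundTruth(
        otu_members=otu_members,
        otu_guild={
            lab: {"archetype": otu_guilds[lab], **GUILD_TEMPLATES[otu_guilds[lab]]["truth"]}
            for lab in otu_labels
        },
        expected_fractions={
            d: dict(config.guild_mixture_by_depth[d]) for d in depths
        },
        realized_fractions=realized,
    )
    return SyntheticDataset(
        mags=mags,
        ani=ani,
        marker_table=pd.DataFrame(marker_rows, columns=["mag_id", "marker_id"]),
        porewater=make_porewater(depths, config.gradients),
        truth=truth,
        config=config,
    )
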