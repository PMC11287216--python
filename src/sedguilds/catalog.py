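"""Marker catalog: the configurable rulebook mapping gene-marker presence to
carbon-fixation pathways, electron donors/acceptors, terminal oxidases and
central carbon metabolism.

A :class:`MarkerCatalog` holds marker definitions (name, EC number, functional
role) plus the decision rules the guild classifier applies. The built-in
default catalog encodes the diagnostic-marker scheme used for hypersaline
sediment MAG communities: six autotrophic pathways (CBB, rTCA, WL, 3HP,
3HP/4HB, DC/4-HB), donor/acceptor couples for sulfur, nitrogen, arsenic,
methane and H2 cycling, and the Cox/Cyd oxygen-relationship markers.
Catalogs round-trip through a YAML config so users can edit the rules.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import yaml

logger = logging.getLogger(__name__)

ROLES = frozenset(
    {"autotrophy", "glycolysis", "tca", "ppp", "donor", "acceptor", "oxidase", "hydrogenase"}
)

PATHWAY_IDS = ("CBB", "rTCA", "WL", "HP3", "HP3HB4", "DC4HB")

#: hydrogenase functional capabilities recognised by the rules
HYDROGENASE_CAPABILITIES = frozenset({"uptake", "evolving"})


class CatalogError(ValueError):
    """Raised when a catalog config is internally inconsistent."""


@dataclass(frozen=True)
class Marker:
    """One screened gene/protein marker.

    ``hydrogenase_group`` must be set iff ``role == "hydrogenase"`` (e.g.
    ``"NiFe-1a"``, ``"FeFe"``); groups map to uptake/evolving capabilities
    at the catalog level.
    """

    marker_id: str
    display_name: str
    ec_number: str = ""
    role: str = "autotrophy"
    hydrogenase_group: Optional[str] = None

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise CatalogError(f"marker {self.marker_id!r}: unknown role {self.role!r}")
        has_group = bool(self.hydrogenase_group)
        if has_group != (self.role == "hydrogenase"):
            raise CatalogError(
                f"marker {self.marker_id!r}: hydrogenase_group must be set "
                "iff role is 'hydrogenase'"
            )


@dataclass(frozen=True)
class PathwayRule:
    """Decision rule for one autotrophic CO2-fixation pathway.

    Fires when every marker in ``required_all`` is present and, if
    ``required_any`` is non-empty, at least one alternative set is fully
    present. ``excluded_if_complete`` names another pathway whose
    ``required_all`` set, when fully present, suppresses this rule (used to
    differentiate DC/4-HB from 3HP/4HB); such rules carry a low confidence
    flag because the discrimination is indirect.
    """

    pathway_id: str
    required_all: frozenset = frozenset()
    required_any: tuple = ()  # tuple of frozensets, alternatives
    atp_cost_per_pyruvate: Optional[float] = None
    confidence: str = "high"
    excluded_if_complete: Optional[str] = None

    def referenced_markers(self) -> frozenset:
        out = set(self.required_all)
        for alt in self.required_any:
            out |= set(alt)
        return frozenset(out)


@dataclass(frozen=True)
class CompoundRule:
    """Rule mapping marker presence to one electron donor or acceptor.

    Fires when any alternative marker set is fully present, or — if
    ``hydrogenase_capability`` is set — when any hydrogenase marker whose
    group has that capability is present.
    """

    compound: str
    alternatives: tuple = ()  # tuple of frozensets
    hydrogenase_capability: Optional[str] = None

    def referenced_markers(self) -> frozenset:
        out = set()
        for alt in self.alternatives:
            out |= set(alt)
        return frozenset(out)


@dataclass
class MarkerCatalog:
    """Validated rulebook: markers plus pathway/donor/acceptor/guild rules."""

    markers: dict = field(default_factory=dict)  # marker_id -> Marker
    pathway_rules: dict = field(default_factory=dict)  # pathway_id -> PathwayRule
    donor_rules: dict = field(default_factory=dict)  # compound -> CompoundRule
    acceptor_rules: dict = field(default_factory=dict)
    central_pathways: dict = field(default_factory=dict)  # name -> frozenset of marker_ids
    aerobe_markers: frozenset = frozenset()  # Cox: respiratory O2 reduction
    aerotolerant_markers: frozenset = frozenset()  # Cyd: O2 detoxification
    hydrogenase_capabilities: dict = field(default_factory=dict)  # group -> frozenset
    allow_missing_central: int = 0
    ani_symmetrize: str = "mean"

    # -- queries -------------------------------------------------------------

    @property
    def terminal_oxidases(self) -> frozenset:
        return self.aerobe_markers | self.aerotolerant_markers

    def hydrogenases_with(self, capability: str) -> frozenset:
        """Marker ids of hydrogenases whose group grants ``capability``."""
        return frozenset(
            m.marker_id
            for m in self.markers.values()
            if m.role == "hydrogenase"
            and capability in self.hydrogenase_capabilities.get(m.hydrogenase_group, ())
        )

    def known(self, markers) -> frozenset:
        """Subset of ``markers`` present in the catalog vocabulary; unknown
        markers are logged and ignored by the rule engine."""
        markers = set(markers)
        unknown = markers - self.markers.keys()
        if unknown:
            logger.debug("ignoring unknown markers: %s", sorted(unknown))
        return frozenset(markers & self.markers.keys())

    # -- validation ----------------------------------------------------------

    def validate(self) -> "MarkerCatalog":
        vocab = set(self.markers)
        for rule in self.pathway_rules.values():
            missing = rule.referenced_markers() - vocab
            if missing:
                raise CatalogError(
                    f"pathway rule {rule.pathway_id!r} references unknown "
                    f"marker(s): {sorted(missing)}"
                )
            if rule.excluded_if_complete is not None and (
                rule.excluded_if_complete not in self.pathway_rules
            ):
                raise CatalogError(
                    f"pathway rule {rule.pathway_id!r}: excluded_if_complete "
                    f"references unknown pathway {rule.excluded_if_complete!r}"
                )
        for kind, rules in (("donor", self.donor_rules), ("acceptor", self.acceptor_rules)):
            for rule in rules.values():
                missing = rule.referenced_markers() - vocab
                if missing:
                    raise CatalogError(
                        f"{kind} rule {rule.compound!r} references unknown "
                        f"marker(s): {sorted(missing)}"
                    )
                if (
                    rule.hydrogenase_capability is not None
                    and rule.hydrogenase_capability not in HYDROGENASE_CAPABILITIES
                ):
                    raise CatalogError(
                        f"{kind} rule {rule.compound!r}: unknown hydrogenase "
                        f"capability {rule.hydrogenase_capability!r}"
                    )
        for name, members in self.central_pathways.items():
            missing = set(members) - vocab
            if missing:
                raise CatalogError(
                    f"central pathway {name!r} references unknown marker(s): {sorted(missing)}"
                )
        for group_set in (self.aerobe_markers, self.aerotolerant_markers):
            missing = set(group_set) - vocab
            if missing:
                raise CatalogError(f"oxidase list references unknown marker(s): {sorted(missing)}")
        for cap_set in self.hydrogenase_capabilities.values():
            bad = set(cap_set) - HYDROGENASE_CAPABILITIES
            if bad:
                raise CatalogError(f"unknown hydrogenase capabilities: {sorted(bad)}")
        return self

    # -- (de)serialisation ---------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "markers": [
                {
                    "id": m.marker_id,
                    "name": m.display_name,
                    "ec": m.ec_number,
                    "role": m.role,
                    **(
                        {"hydrogenase_group": m.hydrogenase_group}
                        if m.hydrogenase_group
                        else {}
                    ),
                }
                for m in sorted(self.markers.values(), key=lambda m: m.marker_id)
            ],
            "hydrogenase_capabilities": {
                g: sorted(caps) for g, caps in sorted(self.hydrogenase_capabilities.items())
            },
            "pathways": [
                {
                    "id": r.pathway_id,
                    "required_all": sorted(r.required_all),
                    "required_any": [sorted(alt) for alt in r.required_any],
                    "atp_cost_per_pyruvate": r.atp_cost_per_pyruvate,
                    "confidence": r.confidence,
                    **(
                        {"excluded_if_complete": r.excluded_if_complete}
                        if r.excluded_if_complete
                        else {}
                    ),
                }
                for r in self.pathway_rules.values()
            ],
            "donors": {
                c: {
                    "alternatives": [sorted(alt) for alt in r.alternatives],
                    **(
                        {"hydrogenase_capability": r.hydrogenase_capability}
                        if r.hydrogenase_capability
                        else {}
                    ),
                }
                for c, r in sorted(self.donor_rules.items())
            },
            "acceptors": {
                c: {
                    "alternatives": [sorted(alt) for alt in r.alternatives],
                    **(
                        {"hydrogenase_capability": r.hydrogenase_capability}
                        if r.hydrogenase_capability
                        else {}
                    ),
                }
                for c, r in sorted(self.acceptor_rules.items())
            },
            "central_pathways": {
                n: sorted(m) for n, m in sorted(self.central_pathways.items())
            },
            "aerobe_markers": sorted(self.aerobe_markers),
            "aerotolerant_markers": sorted(self.aerotolerant_markers),
            "allow_missing_central": self.allow_missing_central,
            "ani_symmetrize": self.ani_symmetrize,
        }

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)

    @classmethod
    def from_dict(cls, data: dict) -> "MarkerCatalog":
        markers = {}
        for entry in data.get("markers", []):
            m = Marker(
                marker_id=str(entry["id"]),
                display_name=str(entry.get("name", entry["id"])),
                ec_number=str(entry.get("ec", "") or ""),
                role=str(entry.get("role", "autotrophy")),
                hydrogenase_group=entry.get("hydrogenase_group"),
            )
            if m.marker_id in markers:
                raise CatalogError(f"duplicate marker id {m.marker_id!r}")
            markers[m.marker_id] = m

        pathway_rules = {}
        for entry in data.get("pathways", []):
            rule = PathwayRule(
                pathway_id=str(entry["id"]),
                required_all=frozenset(entry.get("required_all", ())),
                required_any=tuple(
                    frozenset(alt) for alt in entry.get("required_any", ())
                ),
                atp_cost_per_pyruvate=entry.get("atp_cost_per_pyruvate"),
                confidence=str(entry.get("confidence", "high")),
                excluded_if_complete=entry.get("excluded_if_complete"),
            )
            pathway_rules[rule.pathway_id] = rule

        def _compound_rules(section: dict) -> dict:
            out = {}
            for compound, body in (section or {}).items():
                out[compound] = CompoundRule(
                    compound=str(compound),
                    alternatives=tuple(
                        frozenset(alt) for alt in body.get("alternatives", ())
                    ),
                    hydrogenase_capability=body.get("hydrogenase_capability"),
                )
            return out

        cat = cls(
            markers=markers,
            pathway_rules=pathway_rules,
            donor_rules=_compound_rules(data.get("donors", {})),
            acceptor_rules=_compound_rules(data.get("acceptors", {})),
            central_pathways={
                n: frozenset(m) for n, m in (data.get("central_pathways") or {}).items()
            },
            aerobe_markers=frozenset(data.get("aerobe_markers", ())),
            aerotolerant_markers=frozenset(data.get("aerotolerant_markers", ())),
            hydrogenase_capabilities={
                g: frozenset(c)
                for g, c in (data.get("hydrogenase_capabilities") or {}).items()
            },
            allow_missing_central=int(data.get("allow_missing_central", 0)),
            ani_symmetrize=str(data.get("ani_symmetrize", "mean")),
        )
        return cat.validate()


def load_catalog(config_source: Optional[str] = None) -> MarkerCatalog:
    """Load a catalog from YAML text; with no argument return the built-in
    default rulebook.

    Raises :class:`CatalogError` naming the offending rule when a rule
    references a marker absent from the marker list.
    """
    if config_source is None:
        return default_catalog()
    data = yaml.safe_load(config_source)
    if not isinstance(data, dict):
        raise CatalogError("catalog config must be a mapping")
    return MarkerCatalog.from_dict(data)


def default_atp_costs() -> dict:
    """ATP demand per pyruvate synthesised from CO2, by pathway.

    WL is the cheapest route (~1 ATP); rTCA is reported as a 2–3 range and
    stored as the 2.5 midpoint; no consensus figure exists for the 3HP
    bicycle, reported as None (printed "n/a").
    """
    cat = default_catalog()
    return {pid: rule.atp_cost_per_pyruvate for pid, rule in cat.pathway_rules.items()}


# --------------------------------------------------------------------------
# default rulebook
# --------------------------------------------------------------------------

_M = [
    # autotrophy markers
    ("rubisco", "RuBisCO (RbcL)", "4.1.1.39", "autotrophy"),
    ("prk", "phosphoribulokinase (PRK)", "2.7.1.19", "autotrophy"),
    ("ccs", "citryl-CoA synthetase (Ccs)", "6.2.1.18", "autotrophy"),
    ("ccl", "citryl-CoA lyase (Ccl)", "4.1.3.34", "autotrophy"),
    ("acly", "ATP-citrate lyase (ACLY/AclA)", "2.3.3.8", "autotrophy"),
    ("codh_acs", "CO dehydrogenase/acetyl-CoA synthase (CODH/ACS)", "1.2.7.4", "autotrophy"),
    ("fhs", "formate-tetrahydrofolate ligase (FHS)", "6.3.4.3", "autotrophy"),
    ("pcc", "propionyl-CoA carboxylase (PCC)", "6.4.1.3", "autotrophy"),
    ("mcr", "malonyl-CoA reductase (MCR)", "1.2.1.75", "autotrophy"),
    ("mcl", "malyl-CoA lyase (MCL)", "4.1.3.24", "autotrophy"),
    ("acc", "acetyl-CoA carboxylase (ACC)", "6.4.1.2", "autotrophy"),
    ("budh4", "4-hydroxybutyryl-CoA dehydratase (4-BUDH)", "4.2.1.120", "autotrophy"),
    ("por", "pyruvate synthase (POR)", "1.2.7.1", "autotrophy"),
    # electron-donor markers
    ("aioa", "arsenite oxidase (AioA)", "1.20.9.1", "donor"),
    ("sqo", "sulfide:quinone oxidoreductase (Sqo/Sqr)", "1.8.5.8", "donor"),
    ("sox", "thiosulfate oxidation complex (SoxAB)", "2.8.5.2", "donor"),
    ("mmox", "soluble methane monooxygenase (MmoX)", "1.14.13.25", "donor"),
    # electron-acceptor markers
    ("narabg", "dissimilatory nitrate reductase (NarABG)", "1.7.5.1", "acceptor"),
    ("napab", "periplasmic nitrate reductase (NapAB)", "1.9.6.1", "acceptor"),
    ("sat", "sulfate adenylyltransferase (Sat)", "2.7.7.4", "acceptor"),
    ("aprab", "adenylylsulfate reductase (AprAB)", "1.8.99.2", "acceptor"),
    ("dsrab", "dissimilatory sulfite reductase (DsrAB)", "1.8.99.5", "acceptor"),
    ("dmso_red", "DMSO-family S0 reductase", "1.8.5.3", "acceptor"),
    ("sreabc", "sulfur reductase (SreABC)", "", "acceptor"),
    ("asr", "anaerobic sulfite reductase (Asr)", "", "acceptor"),
    ("phsa", "thiosulfate reductase (PhsA)", "1.8.5.5", "acceptor"),
    ("arra", "arsenate reductase (ArrA)", "1.20.99.1", "acceptor"),
    ("mcra", "methyl-CoM reductase (McrA)", "2.8.4.1", "acceptor"),
    # terminal oxidases
    ("cox", "cytochrome c oxidase (CoxI/II)", "7.1.1.9", "oxidase"),
    ("cyd", "cytochrome bd complex (CydABX)", "7.1.1.7", "oxidase"),
    # central carbon metabolism (compact representative sets)
    ("pfk", "6-phosphofructokinase (PfkA)", "2.7.1.11", "glycolysis"),
    ("gapdh", "glyceraldehyde-3-P dehydrogenase (GapA)", "1.2.1.12", "glycolysis"),
    ("pyk", "pyruvate kinase (PykF)", "2.7.1.40", "glycolysis"),
    ("glta", "citrate synthase (GltA)", "2.3.3.1", "tca"),
    ("sdh", "succinate dehydrogenase (SdhA)", "1.3.5.1", "tca"),
    ("mdh", "malate dehydrogenase (Mdh)", "1.1.1.37", "tca"),
    ("zwf", "glucose-6-P dehydrogenase (Zwf)", "1.1.1.49", "ppp"),
    ("tkt", "transketolase (TktA)", "2.2.1.1", "ppp"),
    ("rpi", "ribose-5-P isomerase (RpiA)", "5.3.1.6", "ppp"),
]

_HYDROGENASES = [
    ("nife_1a", "[NiFe]-hydrogenase group 1a (HysAB)", "NiFe-1a"),
    ("nife_1c", "[NiFe]-hydrogenase group 1c", "NiFe-1c"),
    ("nife_3b", "[NiFe]-hydrogenase group 3b (HyhBGSL)", "NiFe-3b"),
    ("nife_3c", "[NiFe]-hydrogenase group 3c (MvhAGD)", "NiFe-3c"),
    ("nife_4g", "[NiFe]-hydrogenase group 4g (MahABCDGH)", "NiFe-4g"),
    ("nife_4d", "[NiFe]-hydrogenase group 4d", "NiFe-4d"),
    ("fefe", "[FeFe]-hydrogenase", "FeFe"),
]

# group 1a/1c: respiratory H2 uptake; 3b: bidirectional NAD(P)+/H2;
# 3c: electron-bifurcating H2 oxidation; group 4 and FeFe: H2 evolving.
_HYD_CAPS = {
    "NiFe-1a": ("uptake",),
    "NiFe-1c": ("uptake",),
    "NiFe-3b": ("uptake", "evolving"),
    "NiFe-3c": ("uptake",),
    "NiFe-4g": ("evolving",),
    "NiFe-4d": ("evolving",),
    "FeFe": ("evolving",),
}

_HP3_SET = ("pcc", "mcr", "mcl", "acc")

_DEFAULT_DICT = {
    "markers": (
        [
            {"id": i, "name": n, "ec": e, "role": r}
            for i, n, e, r in _M
        ]
        + [
            {
                "id": i,
                "name": n,
                "ec": "1.12.1.2" if g == "FeFe" else "1.12.99.6",
                "role": "hydrogenase",
                "hydrogenase_group": g,
            }
            for i, n, g in _HYDROGENASES
        ]
    ),
    "hydrogenase_capabilities": {g: list(c) for g, c in _HYD_CAPS.items()},
    "pathways": [
        {
            "id": "CBB",
            "required_all": ["rubisco", "prk"],
            "required_any": [],
            "atp_cost_per_pyruvate": 7,
            "confidence": "high",
        },
        {
            # ATP-citrate lyase and the Ccs/Ccl couple are alternative
            # citrate-cleavage systems; either suffices.
            "id": "rTCA",
            "required_all": [],
            "required_any": [["acly"], ["ccs", "ccl"]],
            "atp_cost_per_pyruvate": 2.5,
            "confidence": "high",
        },
        {
            "id": "WL",
            "required_all": ["codh_acs", "fhs"],
            "required_any": [],
            "atp_cost_per_pyruvate": 1,
            "confidence": "high",
        },
        {
            "id": "HP3",
            "required_all": list(_HP3_SET),
            "required_any": [],
            "atp_cost_per_pyruvate": None,
            "confidence": "high",
        },
        {
            "id": "HP3HB4",
            "required_all": list(_HP3_SET) + ["budh4"],
            "required_any": [],
            "atp_cost_per_pyruvate": 9,
            "confidence": "high",
        },
        {
            # no homolog is uniquely diagnostic; differentiated from 3HP/4HB
            # via pyruvate synthase when the 3HP marker set is incomplete
            "id": "DC4HB",
            "required_all": ["budh4", "por"],
            "required_any": [],
            "atp_cost_per_pyruvate": 5,
            "confidence": "low",
            "excluded_if_complete": "HP3",
        },
    ],
    "donors": {
        "H2": {"alternatives": [], "hydrogenase_capability": "uptake"},
        "sulfide": {"alternatives": [["sqo"]]},
        "thiosulfate": {"alternatives": [["sox"]]},
        "arsenite": {"alternatives": [["aioa"]]},
        "methane": {"alternatives": [["mmox"]]},
    },
    "acceptors": {
        "O2": {"alternatives": [["cox"]]},
        "nitrate": {"alternatives": [["narabg"], ["napab"]]},
        "sulfate": {"alternatives": [["sat", "aprab", "dsrab"]]},
        "S0_polysulfide": {"alternatives": [["dmso_red"], ["sreabc"]]},
        "sulfite_tetrathionate": {"alternatives": [["asr"]]},
        "thiosulfate": {"alternatives": [["phsa"]]},
        "arsenate": {"alternatives": [["arra"]]},
        "CO2_methanogenesis": {"alternatives": [["mcra"]]},
    },
    "central_pathways": {
        "glycolysis": ["pfk", "gapdh", "pyk"],
        "tca": ["glta", "sdh", "mdh"],
        "ppp": ["zwf", "tkt", "rpi"],
    },
    "aerobe_markers": ["cox"],
    "aerotolerant_markers": ["cyd"],
    "allow_missing_central": 0,
    "ani_symmetrize": "mean",
}


def default_catalog() -> MarkerCatalog:
    """The built-in rulebook (see module docstring)."""
    return MarkerCatalog.from_dict(_DEFAULT_DICT)
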