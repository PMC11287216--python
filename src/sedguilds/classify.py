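"""Rule engine assigning carbon-fixation pathways, oxygen relationship,
electron donor/acceptor repertoires and trophic guilds from marker presence.

Classification logic, applied to a MAG's (or OTU's pooled) marker set:

* **Pathways** — a pathway is called when its rule fires (all ``required_all``
  markers present and, where alternatives exist, at least one alternative set
  complete). The DC/4-HB call is low-confidence and suppressed once the full
  3HP marker set is present (the 3HP/4HB rule then covers the evidence).
* **Oxygen** — cytochrome c oxidase (Cox) ⇒ aerobe; else cytochrome bd
  (Cyd, O2 detoxification) ⇒ aerotolerant anaerobe; neither ⇒ anaerobe.
* **Carbon** — any pathway plus complete glycolysis, TCA and pentose
  phosphate sets ⇒ facultative autotroph; any pathway otherwise ⇒ autotroph;
  no pathway, no terminal oxidase, complete glycolysis and an H2-evolving
  hydrogenase ⇒ fermenter; otherwise heterotroph.
* **Donors/acceptors** — each compound is listed when its marker rule fires;
  H2 as donor requires an uptake-capable hydrogenase group.

Because MAGs are incomplete, absence of a marker is weak evidence: OTU-level
calls pool the marker union across member MAGs and re-run every classifier
on the union, recording which member contributed each marker.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .catalog import MarkerCatalog

OXYGEN_CLASSES = ("aerobe", "aerotolerant_anaerobe", "anaerobe")
CARBON_CLASSES = ("autotroph", "facultative_autotroph", "heterotroph", "fermenter")


@dataclass
class GuildCall:
    """Functional-guild assignment for one OTU (or single MAG)."""

    otu_id: str
    pathways: dict = field(default_factory=dict)  # pathway_id -> confidence
    oxygen_class: str = "anaerobe"
    carbon_class: str = "heterotroph"
    donors: frozenset = frozenset()
    acceptors: frozenset = frozenset()
    evidence: dict = field(default_factory=dict)  # rule -> sorted fired markers

    @property
    def guild(self) -> tuple:
        return (self.oxygen_class, self.carbon_class)


def _rule_fires(markers, required_all, required_any):
    """(fires, fired_markers) for an all-of + any-of-alternatives rule."""
    if not required_all <= markers:
        return False, frozenset()
    fired = set(required_all)
    if required_any:
        for alt in required_any:
            if alt <= markers:
                fired |= alt
                return True, frozenset(fired)
        return False, frozenset()
    return True, frozenset(fired)


def detect_pathways(markers, catalog: MarkerCatalog, evidence: dict | None = None) -> dict:
    """Autotrophic pathways whose rules fire: {pathway_id: confidence}."""
    markers = catalog.known(markers)
    out = {}
    for pid, rule in catalog.pathway_rules.items():
        fires, fired = _rule_fires(markers, rule.required_all, rule.required_any)
        if fires and rule.excluded_if_complete is not None:
            blocker = catalog.pathway_rules[rule.excluded_if_complete]
            if blocker.required_all <= markers:
                fires = False
        if fires:
            out[pid] = rule.confidence
            if evidence is not None:
                evidence[f"pathway:{pid}"] = sorted(fired)
    return out


def classify_oxygen(markers, catalog: MarkerCatalog, evidence: dict | None = None) -> str:
    """Cox ⇒ aerobe; else Cyd ⇒ aerotolerant_anaerobe; else anaerobe."""
    markers = catalog.known(markers)
    aerobic = markers & catalog.aerobe_markers
    if aerobic:
        if evidence is not None:
            evidence["oxygen:aerobe"] = sorted(aerobic)
        return "aerobe"
    detox = markers & catalog.aerotolerant_markers
    if detox:
        if evidence is not None:
            evidence["oxygen:aerotolerant_anaerobe"] = sorted(detox)
        return "aerotolerant_anaerobe"
    return "anaerobe"


def central_complete(
    markers, catalog: MarkerCatalog, name: str, allow_missing: int | None = None
) -> bool:
    """Is central pathway ``name`` (glycolysis/tca/ppp) complete?

    'Complete' = all members present, minus up to ``allow_missing`` (catalog
    default 0; 1 accommodates 'nearly complete' annotations)."""
    if allow_missing is None:
        allow_missing = catalog.allow_missing_central
    members = catalog.central_pathways[name]
    return len(members - set(markers)) <= allow_missing


def classify_carbon(
    markers,
    pathways: dict,
    catalog: MarkerCatalog,
    evidence: dict | None = None,
) -> str:
    """Trophic class from pathway calls plus central metabolism (see module
    docstring). ``pathways`` must come from :func:`detect_pathways` on the
    same marker set."""
    markers = catalog.known(markers)
    heterotrophic_core = all(
        central_complete(markers, catalog, n) for n in ("glycolysis", "tca", "ppp")
    )
    if pathways:
        if heterotrophic_core:
            if evidence is not None:
                evidence["carbon:facultative_autotroph"] = sorted(
                    markers
                    & (
                        catalog.central_pathways["glycolysis"]
                        | catalog.central_pathways["tca"]
                        | catalog.central_pathways["ppp"]
                    )
                )
            return "facultative_autotroph"
        return "autotroph"
    no_oxidase = not (markers & catalog.terminal_oxidases)
    evolving = markers & catalog.hydrogenases_with("evolving")
    if no_oxidase and evolving and central_complete(markers, catalog, "glycolysis"):
        if evidence is not None:
            evidence["carbon:fermenter"] = sorted(evolving)
        return "fermenter"
    return "heterotroph"


def donor_acceptor_profile(
    markers, catalog: MarkerCatalog, evidence: dict | None = None
):
    """(donors, acceptors) whose compound rules fire on ``markers``."""
    markers = catalog.known(markers)

    def apply(rules, tag):
        hits = set()
        for compound, rule in rules.items():
            fired = set()
            ok = False
            for alt in rule.alternatives:
                if alt <= markers:
                    ok = True
                    fired |= alt
            if rule.hydrogenase_capability is not None:
                capable = markers & catalog.hydrogenases_with(rule.hydrogenase_capability)
                if capable:
                    ok = True
                    fired |= capable
            if ok:
                hits.add(compound)
                if evidence is not None:
                    evidence[f"{tag}:{compound}"] = sorted(fired)
        return frozenset(hits)

    return apply(catalog.donor_rules, "donor"), apply(catalog.acceptor_rules, "acceptor")


def classify_markers(markers, catalog: MarkerCatalog, otu_id: str = "") -> GuildCall:
    """Run every classifier on one marker set and assemble a GuildCall."""
    evidence: dict = {}
    pathways = detect_pathways(markers, catalog, evidence)
    oxygen = classify_oxygen(markers, catalog, evidence)
    carbon = classify_carbon(markers, pathways, catalog, evidence)
    donors, acceptors = donor_acceptor_profile(markers, catalog, evidence)
    return GuildCall(
        otu_id=otu_id,
        pathways=pathways,
        oxygen_class=oxygen,
        carbon_class=carbon,
        donors=donors,
        acceptors=acceptors,
        evidence=evidence,
    )


def call_otu_guild(otu, member_markers: dict, catalog: MarkerCatalog) -> GuildCall:
    """OTU-level cross-checked call: classifiers re-run on the union of
    member MAG marker sets.

    ``member_markers`` maps member mag_id -> marker set; at least one member
    is required. Evidence additionally records, per marker, which members
    contributed it (presence in any member counts; incompleteness makes
    absence weak evidence).
    """
    members = {m: frozenset(v) for m, v in member_markers.items() if m in otu.member_mag_ids}
    if not members:
        raise ValueError(f"OTU {otu.otu_id}: no member marker sets supplied")
    union = frozenset().union(*members.values())
    call = classify_markers(union, catalog, otu_id=otu.otu_id)
    contributors = {}
    for marker in sorted(catalog.known(union)):
        contributors[marker] = sorted(m for m, s in members.items() if marker in s)
    call.evidence["members"] = contributors
    return call


def apply_overrides(calls: dict, overrides) -> dict:
    """Apply a manual-override table (literature-based adjustments) after the
    rule engine.

    ``overrides`` is an iterable of mappings with keys otu_id, field
    (oxygen_class | carbon_class), value. Returns the updated calls dict;
    each applied override is logged in the call's evidence under
    ``override:<field>``.
    """
    for row in overrides:
        otu_id, fld, value = row["otu_id"], row["field"], row["value"]
        if otu_id not in calls:
            continue
        call = calls[otu_id]
        if fld == "oxygen_class" and value in OXYGEN_CLASSES:
            call.oxygen_class = value
        elif fld == "carbon_class" and value in CARBON_CLASSES:
            call.carbon_class = value
        else:
            raise ValueError(f"invalid override {fld}={value!r} for {otu_id}")
        call.evidence[f"override:{fld}"] = [value]
    return calls
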