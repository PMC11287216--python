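# Methods

## Carbonate speciation and rate normalization

Porewater DIC is modeled as a two-species system: measured dissolved CO2 in
equilibrium with bicarbonate at pKa = 6.3, so
[HCO3⁻] = [CO2]·10^(pH−pKa) and DIC = [CO2] + [HCO3⁻]. No carbonate ion,
activity coefficients, or salinity-corrected constants are included: in the
pH range of these sediments (≈6–8) the two-species Henderson–Hasselbalch
treatment captures the pool the tracer equilibrates with, and keeping the
closed form makes every downstream number auditable by hand.

Tracer uptake in DPM gdws⁻¹ h⁻¹ converts to a label-specific molar rate via
the specific activity (default 52 µCi µmol⁻¹) and the definitional constant
2.22×10⁶ DPM µCi⁻¹ (exposed as a parameter, since counters sometimes report
corrected units). The result is multiplied by the isotope-dilution factor —
total DIC amount over labeled amount added (default 1 µmol) — and scaled
µmol→nmol. Two deliberate choices:

* **Dilution direction.** A ratio written as "label added / total DIC"
  would shrink rates as the ambient pool grows, the opposite of isotope
  dilution; the factor used here is total/label, which reproduces rate
  magnitudes of order 10 nmol C gdws⁻¹ h⁻¹ from realistic inputs. The
  operation takes a caller-supplied dimensionless factor, so either
  convention can be exercised.
* **Amount basis.** Converting a µM DIC concentration to an amount needs
  the incubated porewater volume, which assay tables rarely carry; the
  helper `dilution_factor(dic_uM, porewater_volume_mL, label_added_umol)`
  makes the assumption explicit (default 10 mL) and includes the added
  label in the total pool.

Volumetric literature rates convert as
nmol gdws⁻¹ h⁻¹ = µmol cm⁻³ day⁻¹ × 1000 / (ρ × 24) with ρ = 2.0 g cm⁻³ by
default (sand-rich sediment, typical range 1.7–2.3). Report output rounds to
2 significant figures.

## QC, OTU clustering and representatives

QC keeps MAGs with completeness strictly above 50% and contamination
strictly below 10%. Clustering is single-linkage: connected components of
the graph whose edges are MAG pairs with symmetrized ANI strictly above 95%.
Single linkage is the common dereplication reading of "collapse at a
threshold" and is independent of input order; the strictness convention
(">95%", so exactly 95.0 does not link) matters only on ties. ANI tools
report two directed values per pair; these are combined by arithmetic mean
by default (`max`/`min` available), and a missing direction falls back to
the present one. OTU ids are assigned deterministically by sorting clusters
on their smallest member id. Representatives maximize completeness, then
minimize contamination, then maximize read fraction, with a final
lexicographic tie-break so reruns are bit-identical.

## The rule engine

The rulebook is data, not code: markers (with EC numbers and roles),
pathway rules, donor/acceptor rules, central-metabolism marker sets,
oxidase lists and hydrogenase-group capabilities all live in a YAML-round-
trippable catalog; the engine only evaluates it. Decisions embedded in the
default catalog:

* **CBB** requires RuBisCO *and* PRK — the conjunction guards against
  RuBisCO-like false positives.
* **rTCA** fires on ATP-citrate lyase *or* the citryl-CoA
  synthetase + lyase couple: the two are alternative citrate-cleavage
  systems, and demanding all three markers would punish genomes using only
  one system. This disjunction makes rTCA the one single-marker-triggerable
  pathway (ACLY alone), hence the most dropout/contamination-sensitive call.
* **3HP** requires PCC, MCR, MCL and ACC; **3HP/4HB** adds 4-BUDH.
* **DC/4-HB** has no uniquely diagnostic homolog; it is called when 4-BUDH
  and pyruvate synthase (POR) are present while the 3HP set is incomplete,
  and is flagged low-confidence. When the full 3HP set appears, the same
  evidence is read as 3HP/4HB instead. This is the one deliberate exception
  to rule-engine monotonicity: adding markers can *refine* a low-confidence
  DC/4-HB call into 3HP + 3HP/4HB, but can never erase pathway evidence
  outright, and donors/acceptors/all other pathways are strictly monotone
  in marker presence.
* **ATP costs per pyruvate**: WL ≈ 1, rTCA 2.5 (midpoint of the reported
  2–3 range), DC/4-HB 5, CBB 7, 3HP/4HB 9. No consensus figure exists for
  the 3HP bicycle; it is stored as absent and printed "n/a" rather than
  invented.
* **Oxygen**: Cox ⇒ aerobe; else Cyd (O2 detoxification, not conserved
  respiration — so it does not add O2 to the acceptor list) ⇒ aerotolerant
  anaerobe; neither ⇒ anaerobe.
* **Carbon**: pathway + complete glycolysis, TCA and pentose-phosphate sets
  ⇒ facultative autotroph; pathway otherwise ⇒ autotroph; no pathway, no
  terminal oxidase, complete glycolysis and an H2-evolving hydrogenase ⇒
  fermenter; else heterotroph. "Complete" means every marker of the
  (configurable, deliberately compact three-marker) set present; the
  `allow_missing_central` knob (default 0) relaxes this by n markers to
  accommodate "nearly complete" annotations.
* **Hydrogenase groups**: 1a and 1c are uptake; 3b is bidirectional
  (counts as both); 3c bifurcates electrons from H2 oxidation (uptake);
  group 4 (4g, 4d) and FeFe count as H2-evolving. H2 appears as a donor iff
  an uptake-capable group is present; the fermenter rule keys on an
  evolving-capable group.

OTU-level calls use the union of member MAG marker sets, then re-run every
classifier on the union, recording which member contributed each marker.
Rationale: completeness of these genomes is 50–100%, so absence in one MAG
is weak evidence, while presence anywhere in the cluster is strong.
Literature-based adjustments are not automatable; a manual-override table
can be applied after the engine, and every override is logged in the
evidence record.

## Depth profiles

An OTU contributes its summed member read fraction at each depth. Guild
fractions are keyed (oxygen class × carbon class) and by default
renormalized over classified, retained OTUs so each depth sums to 100;
`normalize=False` keeps raw percent-of-mapped-reads and reports the
unclassified remainder. Pathway fractions are computed on the same basis;
an OTU with several pathways contributes its full abundance to each (the
overlap is documented in output rather than split arbitrarily). Abundance
filters are strict: the display convention keeps OTUs exceeding 2% at any
depth, the analysis convention 5%.

## Synthetic communities

The generator emulates the *statistical* structure of annotation-level
inputs from a depth-stratified hypersaline sediment core; it emits no
sequences and no reads. Six guild archetypes carry canonical marker
templates (aerobic halophilic heterotroph; sulfur-oxidizing CBB facultative
autotroph; anaerobic WL acetogen with group 1a/3b/3c/4g hydrogenases;
aerotolerant hydrogenotrophic sulfate reducer; fermenter with an FeFe
hydrogenase; anaerobic rTCA autotroph), chosen so the synthetic data
exercises every rule path of the default catalog. Defaults, chosen once:

* 12 OTUs (2 per archetype), depths 0/5/30 cm, every OTU present at every
  depth with one MAG per depth — matching how per-depth assemblies yield
  one bin per population per depth, and guaranteeing each archetype is
  observable at each depth.
* Expected guild mixtures follow the canonical redox gradient (aerobes
  0.65 → 0.48 → 0.20 of the community; WL acetogens 0.08 → 0.18 → 0.33),
  with between-depth margins ≥ 0.09 so the qualitative ordering survives
  sampling noise. Realized abundances are Dirichlet draws with total
  concentration 500 around those mixtures, scaled to sum to exactly 100
  per depth.
* MAG completeness ~ N(85, 8) truncated to (50, 100]; contamination ~
  N(2.5, 2) truncated to [0, 10) — the moderate-to-high-quality band the
  QC gate admits. Each template marker is retained with probability
  completeness/100 (independent Bernoulli), the dropout mechanism that
  makes OTU-level pooling necessary.
* Contaminant markers are Poisson with mean 0.02 × contamination% per MAG,
  drawn from other archetypes' templates. The low rate reflects what the
  tables emulate: *verified* marker calls (KEGG hits confirmed by manual
  BLASTp), where a contaminant contig rarely contributes a full,
  verification-passing marker gene. Spurious single markers can still
  occasionally flip a call (the single-marker rTCA rule is the fragile
  one); at the default rate this perturbs the qualitative depth pattern in
  well under 1% of runs.
* ANI: within-OTU pairs ~ N(98.0, 0.7), between ~ N(80, 3), with N(0, 0.15)
  directional jitter for fastANI-like asymmetry. The config validator
  enforces mean_within − 2σ > 95 > mean_between + 2σ, making partition
  misassignment improbable by construction (0 failures in 400 runs).
* Porewater gradients are linear and deterministic: pH 7.3 − 0.015·z,
  CO2 15 + 1.0·z µM, DPM 4×10⁵ + 10⁴·z (z in cm) — yielding normalized
  rates of ~9–18 nmol C gdws⁻¹ h⁻¹, the magnitude reported for aquatic
  sediments.

All draws derive from a single `numpy.random.default_rng` root seed; the
generator algorithm (truncated-normal rejection sampling, Dirichlet
abundances, Bernoulli dropout in sorted marker order) is fixed, so a
reimplementation can match distributions even where byte streams differ.

What passing on synthetic data does **not** show: real communities have
uneven taxon richness, OTUs absent from some depths, correlated (not
independent-Bernoulli) marker dropout along contigs, contamination from
coherent foreign bins, and ANI distributions with fuzzy species boundaries.
Recovery here demonstrates the pipeline's correctness and determinism, not
field performance.

## Validation experiments and problem sizes

The test suite and `scripts/acceptance.py` recompute, from scratch:
published unit conversions (0.18 → 3.8 and 0.1 → 2.1 nmol C gdws⁻¹ h⁻¹ at
2 s.f.); species equality at pH = pKa; rulebook content; clustering vs an
independent brute-force transitive-closure oracle on 120 random matrices of
up to 12 MAGs; noise-free planted-guild recovery (12 OTUs, complete
genomes) which must be exact; a 20-seed sweep of the default scenario
(36 MAGs per run) checking exact partition recovery and the qualitative
depth pattern; and 300 random monotonicity trials. These sizes keep the
whole validation under a few seconds while leaving the recovery experiments
statistically meaningful; the generator scales to larger scenarios by
config.

## Known limitations

* Marker presence is trusted as given; there is no re-annotation, homology
  search, or hydrogenase motif inspection — group labels are inputs.
* The strict-conjunction pathway rules may be more conservative than manual
  curation practice (a curator might accept RuBisCO without PRK given
  phylogenetic context); conversely the disjunctive rTCA rule accepts a
  single marker.
* The two-species carbonate model under-counts DIC above pH ≈ 9 where
  carbonate ion becomes significant — outside these sediments' range.
* Guild renormalization over classified OTUs assumes unclassified
  abundance is missing at random with respect to guild.
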