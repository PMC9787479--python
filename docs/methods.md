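# Methods

## Model

A reaction network is grown by iterated graph rewriting. Molecules are
labeled graphs (atoms/bonds) restricted to {C, H, N, O, Fe}; every species is
keyed by its canonical SMILES with explicit charges, so chemically identical
products deduplicate wherever they arise. Stereochemistry is ignored (no rule
in the libraries is stereospecific) and tautomers are distinct species
connected by explicit migration rules.

A reaction rule is an atom-mapped reaction SMARTS — the practical equivalent
of an L/K/R double-pushout rewrite: reactant patterns are L (with SMARTS
queries standing in for wildcard atoms and context constraints), mapped atoms
form K, and the product patterns are R. Pattern matching and the rewrite are
delegated to RDKit (`RunReactants`); the engine adds the semantics the
expansion needs:

* **Hydrogen renormalization.** After a rewrite, hydrogen counts on C/N/O are
  recomputed from valence (C 4, N 3, O 2, adjusted for charge). Rules
  therefore only state skeleton, bond-order and charge edits; hydrogen
  migration is implicit and exactly balanced. All library species are
  closed-shell, so this is lossless.
* **Valence guard.** Applications whose products cannot be sanitized are
  rejected as no-matches, as are the rare applications that would break atom
  or charge conservation (in practice: intramolecular matches of bimolecular
  retro patterns on ring bonds, where breaking the bond does not fragment the
  molecule). Every recorded event conserves atoms and elementary charge; the
  test suite re-verifies this event-by-event on every run.
* **Automorphism deduplication.** An embedding is represented by its outcome
  (reactant multiset, product multiset); matches related by a pattern
  symmetry collapse to one embedding, and events are unique per (rule,
  reactant multiset, product multiset).
* **Reactant budget.** At most two non-ubiquitous reactants per event; water,
  H⁺, OH⁻, Fe²⁺ and Fe³⁺ are "ubiquitous" — available in any multiplicity as
  co-participants, excluded from product-diversity counts, but full
  participants in events and degree metrics. This mirrors a modeling regime
  that does not track mass balance: a reaction happens whenever its
  mechanistic requirements are met.

## Expansion semantics

Seeds are generation 0. Each iteration applies every rule to the cumulative
pool; an event's generation is `max(first_generation of reactants) + 1`,
which makes labels independent of enumeration order. The engine enumerates
only reactant tuples containing at least one previous-generation ("frontier")
species — an exact optimization, since all-older tuples were tried before —
and is verified field-by-field against a brute-force oracle that re-derives
the expansion with no frontier logic or caching on all toy systems.

The nominal-mass cap (integer masses: H=1, C=12, N=14, O=16, Fe=56) gates
whole events: if **any** product exceeds the cap the event is discarded, so a
compound requiring a heavier precursor is never reached. Expansion stops at
the generation limit or at saturation (a generation adding neither species
nor events — a fixed point, since the pool is then unchanged). There is no
randomness anywhere; runs are bit-reproducible and independent of seed or
rule input order. A configurable species-count guard (default 10⁶) aborts
runaway configurations cleanly.

## Rule libraries

The CHO core (31 rules) covers aldol/retro-aldol chemistry, the Cannizzaro
disproportionations, keto–enol migrations, 5/6/7-membered O,O ring closures
and hemiacetal equilibria with their inverses, benzilic-type rearrangement,
four decarboxylations, hydrations and eliminations. The formose library adds
plain keto–enol tautomerization (32 rules); tautomers must exist as species
because several core rules consume enols. The Maillard library adds the four
Strecker-degradation variants and amide formation; its nitrogen chemistry is
deliberately partial (only the named mechanisms are encoded). Iron chemistry
is seven rules coupling organic redox steps to the Fe²⁺/Fe³⁺ pair — e.g. a
two-electron aldehyde oxidation consumes two Fe³⁺ and releases two protons,
so charge balances event-by-event; one catalytic-iron rule (Fe³⁺ mapped
unchanged through an isomerization) ships with the toy fixtures.

Encoding conventions that were genuinely open and how they were resolved:

* Only rule *names* and two worked diagrams of the original rule set are
  public, so these encodings are functional reconstructions: they reproduce
  the qualitative chemistry and the direction of the iron effect, not any
  reported absolute network size.
* The three Cannizzaro entries partition the chemistry — the plain rule
  handles substituted aldehydes; formaldehyde participates only through the
  two crossed rules (one per redox role). This both avoids double counting
  and reflects that the entries are separate rules with separate frequencies.
* "Knoevenagel H" is encoded as the carbonyl-C–H (formoin/benzoin-type)
  coupling and "Knoevenagel C" as the sp³ α-C–H condensation: the H/C suffix
  is read as the position of the active hydrogen. The H variant is what lets
  a formaldehyde-only seed form its first C–C bond; without it the formose
  network cannot bootstrap, which fixes the interpretation.
* Ring-closure and hemiacetal chain atoms are restricted to acyclic sp³
  carbons to keep products at the sugar scale.
* Masses are nominal integers rather than average molecular weights: the cap
  is a modeling device, and integer comparisons are deterministic.

## Toy systems and what a green test establishes

The fixtures are real molecules so the full canonicalization path is
exercised. `chain_growth`: formaldehyde extends an aldehyde by one CH₂O unit,
so the saturated network has exactly ⌊cap/30⌋ species (one per mass) —
closed-form size, novelty counts and saturation generation.
`reversible_pair`: two mutually inverse triose migrations; the network closes
after the back-reaction event. `iron_shortcut`: lactic acid is three
iron-free steps from glyceraldehyde but one catalytic-Fe³⁺ step, so it is
catalyzed by construction (gen 3 vs gen 1; 25 % catalysis). The toys pin the
engine's semantics (generation labels, dedup, cap gating, saturation,
catalysis detection) — they say nothing about the realism of the preset
libraries, which is qualitative by design.

## Reporting conventions

* Percent change of a rule frequency is 100·(f_iron − f_free)/f_free rounded
  to the nearest integer; a rule that never fires without iron reports "-".
* Percent catalysis is computed exactly and formatted to one decimal below
  2 %, nearest integer otherwise.
* Growth fits are unweighted least squares on log₁₀(count) vs generation,
  requiring ≥ 2 strictly positive counts; projections are flagged as
  extrapolations and are upper bounds once a cap-limited network approaches
  saturation (demonstrated on the chain-growth toy).
* Desk-scale runs use mass cap 100 AMU for formose and pyruvic; glucose and
  the Maillard seeds weigh up to 180 AMU, so their runs use the smallest
  admissible cap of 180. Generation counts (4/4/3/3) keep the whole suite in
  minutes on one CPU.

## Known limitations

No kinetics, thermodynamics, yields or concentrations — reachability only.
No Fenton/radical or iron–sulfur chemistry. Maillard nitrogen coverage is
partial. Rule encodings are reconstructions from mechanism names; absolute
network magnitudes are not comparable to any reported run. Polymer growth
beyond the mass cap is out of scope.
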