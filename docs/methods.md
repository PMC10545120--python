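# Methods

This note documents the models and procedures implemented in `suberflux`,
the assumptions behind them, and the choices made where the design was
genuinely open.

## Constraint-based core

All simulation results are steady-state flux distributions of a
stoichiometric network: `S v = 0`, `lb <= v <= ub`, with fluxes in
mmol·gDW⁻¹·h⁻¹ (biomass flux in h⁻¹).

* **FBA** maximizes or minimizes one reaction flux (GLPK via optlang).
* **pFBA** fixes the objective at its optimum (or a supplied value),
  splits every flux into nonnegative forward/reverse parts and minimizes
  their sum. We use flux-level parsimony only; no gene-level pruning.
  pFBA is used wherever a *unique, reproducible* flux vector matters
  (trajectory recording, wild-type references), because plain FBA optima
  are degenerate.
* **FVA** computes per-reaction flux minima/maxima, optionally after
  constraining the objective to a fraction of its optimum. Reactions are
  processed in sorted-id order so output is deterministic.
* **Blocked reactions** are those whose FVA interval is within `1e-9` of
  zero. By default every boundary reaction is first opened to
  (−1000, 1000) so blockage reflects network structure rather than the
  current medium; a flag uses the model's own bounds instead, since the
  appropriate regime depends on the question being asked.
* **MOMA** minimizes the squared Euclidean distance to a reference flux
  vector subject to the current constraints — a convex QP solved with
  OSQP (absolute/relative tolerance `1e-9`, polishing on). An L1 variant
  behind a flag solves an LP instead; it is *not* the canonical MOMA and
  is labelled as such.
* **Ratio constraints** couple two fluxes as `v_a·b − v_b·a = 0`. They
  are stored on the model and injected into every program built from it,
  which is how the Rubisco carboxylation:oxygenation (Vc:Vo) ratio and
  the nitrate light:dark = 3:2 coupling are enforced.

Numerical conventions: solver tolerance `1e-9`, assertion tolerance on
returned solutions `1e-6`. Mass-balance audits flag per-element
imbalances above `1e-6` atoms; reactions containing formula-less species
(photons, e-Metabolites) are reported as *unchecked*, never guessed at.

## Biomass formulation (e-Metabolites)

Tissue dry weight is decomposed into macromolecular classes, each
represented by a pseudo-metabolite ("e-Metabolite") standing for 1 g of
that class, produced from its monomers by a dedicated reaction. A
monomer with mass fraction `w` (g/g) and molar mass `M` (g/mol) enters
with coefficient `1000·w/M` mmol per gram; condensation-incorporated
monomers release the same mmol of water. The biomass reaction consumes
the tissue's gram-fractions of e-Metabolites plus GAM ATP and produces
1 gDW; NGAM is a separate lower-bounded ATP hydrolysis.

Notes and caveats:

* With monomer fractions summing to 1, the consumed monomer mass is
  exactly 1 g; when condensation water is released the net polymer mass
  is smaller by `18·Σ(condensation·coefficient)/1000` g. The mass audit
  therefore reports consumed-minus-water; tables intended to satisfy a
  strict 1 g ± 2% audit should supply *residue* masses with
  `condensation = 0` (the miniplant tables do).
* GAM/NGAM default to 50 mmol ATP/gDW and 1.0 mmol·gDW⁻¹·h⁻¹ — standard
  placeholder magnitudes, supplied via config in any real use.
* Suberin is accepted only in inner-bark and phellogen compositions;
  a leaf composition containing suberin is rejected unless explicitly
  overridden.
* Tannins are not modelled.

## Tissue extraction

Reactions are scored from a tissue's normalized expression through their
GPR rules: AND → min, OR → max. A gene absent from the dataset is
ignored inside OR (isoenzymes still count) and poisons AND (a complex
with an unmeasured subunit scores unknown). An alternative sum-rule for
OR nodes is available behind a flag.

The core set is every reaction scoring at or above the dataset median
(computed over gene values, zeros included; both choices are flags),
plus a configurable protected list that always contains the biomass
reaction. Reactions without genes are never core — they may enter the
extracted model only as consistency fillers, mirroring the near-constant
orphan counts across real tissue models.

Extraction follows the FASTCORE scheme: alternate an LP that maximizes
how many core reactions reach a minimum activity `eps = 1e-4` with an
L1-minimization over non-core reactions, flipping reversible core
reactions that resist activation, until the core is fully serviced. One
deliberate deviation: the support of each sparse mode is taken at a
small numerical tolerance (`1e-9`) rather than at `0.99·eps`, because
stoichiometric couplings (biomass precursor coefficients ≪ 1) force
required reactions to carry fluxes far below `eps`; cutting them off
would return an inconsistent submodel. A consistency pre-pass removes
blocked reactions first; core reactions blocked in the parent are
excluded with a warning at the pipeline level (the lower-level
`fastcore_extract` treats them as a hard error). Growth feasibility is
verified before a submodel is returned, with a biomass-precursor gap
report on failure.

Extraction guarantees consistency only under the bounds it was run with.
The convenience workflow therefore extracts each tissue under its
applicable medium — leaf photoautotrophic; inner bark and phellogen
heterotrophic with unit sucrose and amino-acid uptake — and protects the
leaf's dark-operable machinery (respiration, sucrose/amino-acid
exporters), the analogue of protecting a dark-operable pathway branch in
a real leaf model. Parent exchanges can be retained (closed) in the
output so named presets stay applicable afterwards.

## Diel and multi-tissue assembly

`duplicate_diel` copies every reaction and metabolite into light- and
dark-tagged namespaces and adds one storage linker per storable
metabolite (defaults: starch, sucrose, amino acids, nitrate; the
18-amino-acid linker list is the 20 proteinogenic minus asparagine and
glutamine, fully configurable). Linkers are reversible by default
(storage in either phase) with a flag to restrict direction. Counts are
exact: `2R + s` reactions, `2M` metabolites. Growth is tied across
phases by a combined drain taking equal (configurable) light and dark
contributions; no explicit day/night duration weighting is modelled.

`merge_multitissue` namespaces each tissue (`<name>__`), then builds
common pools (leaf–inner bark; inner bark–phellogen). For each shared
metabolite and phase the member tissues' boundary reactions are deleted
and replaced by pool transfers: free diffusion (one reversible
reaction), or proton symport on import with one plasma-membrane ATPase
per tissue/phase interface pumping the proton back at the cost of one
ATP. Steady state on the pool species then forces pools to be strictly
pass-through and the proton ledger to balance exactly. All remaining
boundary reactions are closed at merge; `apply_diel_constraints`
reopens the environment — photons only in the leaf's light phase, O2 and
CO2 only in the leaf (both phases), minerals and water only in the inner
bark (no root is modelled) — and installs the nitrate 3:2 light:dark
ratio. Environment exchanges that were deleted as shared-pool
metabolites are recreated on the whitelisted tissue. O2 and CO2 are
included in the shared-pool list (diffusion mode) so non-leaf tissues
can respire while their own gas exchanges stay closed; how inner tissues
obtain O2 is not specified by the modelling conventions this follows,
and pool diffusion is this package's choice.

## Simulation protocols

Named presets define trophic regimes by the uptakes they open:
photoautotrophic (photons + CO2 + water/minerals), heterotrophic
(sucrose, unit uptake, plus O2 and minerals), photorespiratory
(photoautotrophic plus Vc:Vo = 3:1). The canonical phototrophic
protocol fixes biomass at 0.11 h⁻¹ and minimizes photon uptake; the
alternative fixes photon uptake at 100 mmol·gDW⁻¹·h⁻¹ and maximizes
growth. Both are pFBA-resolved. Quantum yield is net CO2 uptake per
photon absorbed; assimilation quotient is net CO2 uptake per O2 evolved,
both read from exchange fluxes; zero denominators yield *undefined*
rather than zero.

The validation battery checks, side-effect-free: no biomass and no ATP
hydrolysis with all uptakes closed (the ATP probe is the
energy-generating-cycle detector; full loop enumeration is out of
scope); growth abolished by removing any single elemental source; and
growth present/absent per preset as expected.

## FSEOF target ranking

Suberin is removed from the biomass reaction and given a dedicated
drain; its theoretical maximum production is computed by FBA; production
is then enforced at 10 evenly spaced levels from 5% to 95% of that
maximum while growth is maximized (pFBA-resolved). Candidates are
reactions whose flux magnitude strictly increases across levels (slack
`1e-6`) without changing sign; the biomass and drain reactions are
excluded. An FVA filter at the 95% enforcement level keeps only
candidates whose interval excludes zero (`vmin·vmax > 0`).

Overexpression of each survivor is simulated at 1.2× its wild-type flux
by MOMA against the wild-type pFBA reference, and ranked by the
phenotypic fraction
`f_ph = (v_suberin,OE / v_suberin,WT) · (v_biomass,OE / v_biomass,WT)`,
ties broken by reaction id. The ranking stage runs on the *original*
model (suberin still in biomass, drain open), and `v_suberin` is
measured as the production flux of the suberin species (biomass demand
plus drain): a growing wild type then always has `v_suberin,WT > 0`,
keeping `f_ph` well-defined, and the `oe_factor = 1` control scores
exactly 1. Candidates with zero wild-type flux are skipped (scaling
zero is not an overexpression); an infeasible MOMA records `f_ph = 0`
with a flag. The number of enforcement levels and the filter condition
are configurable since candidate counts are sensitive to both.

## The miniplant generator

The test substrate is a ~48-reaction, 5-compartment plant network with
photon-driven carbon fixation (distinct Rubisco carboxylation and
oxygenation sharing RuBP, so the Vc:Vo protocol applies verbatim), a
photorespiratory salvage that re-releases fixed CO2, starch and sucrose
metabolism, respiration, nitrate/sulfate assimilation, and a
suberin-precursor branch (glycerol-3-phosphate, ferulate, ω-hydroxy
fatty acid). All sugars are `(CH2O)n` and the ATP currency uses a
zero-mass pseudo-element with hydrated phosphate, so every enzymatic
reaction is elementally balanced by construction; photons are massless.

Anchors the tests rely on:

* one photon yields one ATP and fixing one CO2 costs exactly
  `photons_per_co2` ATP (default 8), with sucrose synthesis ATP-neutral
  — so the stoichiometric maximum quantum yield is exactly
  `1/photons_per_co2`, attained by minimizing photons at fixed sucrose
  export;
* maximum growth per preset follows from closed-form photon/sucrose
  budgets per gram of biomass — plain arithmetic, no LP — so the
  optimizer is checked against an independent prediction;
* the respiratory ATP yield is capped strictly below the photon cost of
  fixing a triose, so no fixation/respiration energy amplification
  exists for any configuration;
* miniplant biomass uses GAM = NGAM = 0 so these anchors are exact; the
  biomass builder's own defaults are unchanged;
* optional flags plant a three-reaction dead branch (the blocked-set
  ground truth) or a spurious ATP-generating cycle (which the validation
  battery must flag);
* tissue compositions mirror the real contrasts (leaf: protein 43.7% /
  carbohydrate 40.7%; inner bark: carbohydrate 46.9% / lignin 38.2%;
  phellogen: suberin 36.2%, carbohydrate 17.6%, lignin 25.2%);
  the toy e-Lipid is glycerolipid-only so the fatty-acid chain is
  genuinely suberin-exclusive, which the extraction-recovery tests rely
  on.

Synthetic expression profiles draw active genes log-normal(μ=2, σ=1)
and silenced gene groups at zero; the construction guarantees silenced
genes fall below the dataset median (an error is raised in the
degenerate case where zeros dominate). All randomness flows through one
seeded generator.

What the miniplant does *not* emulate: genome scale (thousands of
reactions), pathway redundancy and promiscuous isoenzymes, realistic
maintenance energies, thermodynamic (loopless) constraints, kinetics,
and measurement noise in expression beyond log-normal scatter. Passing
tests demonstrate the correctness of the algorithms and conservation
laws on a fully specified network, not predictive accuracy on a real
transcriptome.

## Problem sizes

The default test-and-acceptance workload uses the ~48-reaction
miniplant, three extracted tissue models (~35–42 reactions each), and a
~300-reaction diel multi-tissue assembly; extraction-recovery sweeps use
20 expression seeds. These sizes give exact, reproducible optima while
exercising every code path; all quantities scale to larger SBML inputs
through the same interfaces.

## Known limitations

* GLPK's simplex can mislabel an unbounded LP as optimal with a
  non-finite objective; the wrapper detects and reclassifies this.
* FVA-based blocked detection is O(2·R) LPs — fine at these scales,
  no FASTCC-style batching is implemented.
* The multi-tissue objective couples tissue biomasses with fixed weights
  (default equal, split evenly over phases); per-tissue growth-ratio
  coupling is not modelled.
* MOMA uniqueness holds in flux space up to solver tolerance; OSQP's
  ADMM can leave ~1e-6 residuals on badly scaled problems.
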