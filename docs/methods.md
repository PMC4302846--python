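# Methods

## The whole-plant constraint-based model

`multigem` assembles a whole-plant flux balance model from a single base
reconstruction by replicating it per tissue and per diurnal period and
linking the replicas through two kinds of pools:

* **Common pools (CP)** couple tissues in space within one period.  A pool
  has no storage: for every translocatable species s and period p there is
  one balance row, and each member tissue contributes one irreversible
  export and one irreversible import column.  The export column for tissue
  t removes one mole per gram of tissue (−1 on the tissue's metabolite row)
  and delivers ω_t moles to the pool row, where ω_t is the tissue's mass
  fraction.  Mass fractions convert intrinsic fluxes (mmol·gDW⁻¹·h⁻¹) into
  extrinsic whole-plant flows so that tissues of different size balance
  correctly; only the ratios of the ω_t matter, which the test suite checks
  as a scale-invariance property.

* **Storage pools (SP)** couple periods in time.  For a stored species there
  is one accumulation column per period (coefficient −1 on the tissue row,
  +ω_p on the storage row, ω_p the period's time fraction) and a single
  balance row Σ_p ω_p·a_p = 0: whatever is stored in one period is retrieved
  in the others.  Sign constraints (accumulate by day, release by night for
  leaf starch) are plain flux bounds.

Trophic mode is imposed with bounds: the photon uptake replica is closed in
non-phototrophic tissues and in dark periods, and carbon fixation (RuBisCO)
is closed in heterotrophic tissues via the scenario's disabled-reaction
lists.  Growth is a per-tissue biomass flux fixed (equality by default,
configurable) to the same rate in every period — the plant grows through the
night, which is what makes the starch pool obligatory.  Choosing a nitrogen
source closes the uptake replica of the alternative source everywhere.

**Active translocation** charges a penalty weight pw — moles of ATP
hydrolyzed per mole of species moved — against the paying tissue:
pw·(ATP + H₂O → ADP + orthophosphate) is folded into the transporter
column.  pw = 0 produces a column touching only the species rows (passive
diffusion); the penalty attaches to the exporting side by default and is
configurable per translocation entry, which is also how directional
("valve") transport is expressed: taxing only the direction a species does
not physiologically take prunes free export/import cycles without touching
the optimum.

## Optimization

The objective is photon minimization at fixed growth: min f·v subject to
S·v = 0 and bounds, where f selects the photon uptake replicas weighted by
their period time fractions.  All LPs go through SciPy's HiGHS dual-simplex
backend behind a small problem container; feasibility and dual tolerances of
1e-9 are requested, and tests assert at 1e-6.  A duality audit (primal
objective versus b·y + lb·μ_lb + ub·μ_ub) is part of the test suite.

Because FBA optima are degenerate, a representative flux distribution is
computed by minimizing the L1 norm at the fixed optimum via the standard
splitting v = v⁺ − v⁻ (v± ≥ 0, bounds arranged so v⁺ − v⁻ spans exactly
[lb, ub]); an independent epigraph encoding (min Σt, t ≥ ±v) serves as the
oracle in tests.  Flux variability analysis solves min/max per flux with
f·v = γ·Z_opt imposed as an equality (γ = 1 by default); a flux is blocked
when both extrema fall below 1e-9 in magnitude, and blocked columns can be
removed without changing the polytope.  Whether the pre-sampling reduction
fixes the objective at its optimum or uses only the scenario bounds is a
caller decision; the bundled pipeline fixes the optimum.

## Sampling and coupled modules

Uniform samples of the (bounded) feasible polytope come from an artificially
centered hit-and-run chain: warmup vertices from optimizing random
directions (all ±coordinate objectives when the warmup budget allows,
Gaussian mixtures otherwise), directions taken from a stored point through
the running center, and a uniform step within the feasible chord.
Directions are differences of feasible points and therefore stay in the
constraint null space; floating-point drift is removed by projecting back
onto the affine space (dense pseudo-inverse — adequate at toy scale) every
50 steps and at every recorded sample, and each recorded sample is verified
against the balances (1e-6) and bounds (1e-9).  Defaults: warmup
min(2·n_fluxes, 2000), thinning 100, seed mandatory.  The chain can sample
either the full scenario polytope or the photon-optimal face
(`fix_objective_at=`); the bundled analyses use the optimal face.

Pearson correlations are computed across samples for every flux pair;
fluxes with variance below 1e-12 are excluded and reported rather than
propagating undefined correlations.  The coupling graph has an edge where
|ρ| exceeds the cutoff (0.95 by default); maximal cliques are enumerated
with our own Bron–Kerbosch recursion using pivoting and a degeneracy outer
order, cross-checked in tests against exhaustive subset enumeration (≤ 15
vertices) and networkx.  Cliques are reported in a deterministic
lexicographic order, singletons omitted by default, and annotated with the
tissues, periods and base-model compartments of their members; transporters
inside a module spanning several tissues are flagged as tissue linkers.
Edge signs are kept in the annotation so positively and negatively coupled
members remain distinguishable.

## The synthetic toy plant

The bundled generator emulates the pathway content a whole-plant analysis
exercises — photon-driven carbon fixation, nitrate reduction
(NR → NiR, 8 electrons per nitrogen), GS/GOGAT ammonium assimilation, a
diurnal starch cycle, per-tissue biomass, and sucrose/glutamate/nitrate
translocation — with lumped single-reaction pathways and integer/rational
stoichiometry so every optimum is hand-checkable (docs/toyplant.md).  Key
parameters: 5 photons per fixed carbon (3 ATP + 2 NADPH, the Calvin-cycle
bill), 4 NADPH per nitrate reduced, respiratory yield 4 ATP (or NADPH) per
sugar, growth 0.1 per tissue per period, mass fractions 0.5/0.25/0.25 and a
12 h/12 h cycle.  The respiratory yield is deliberately below the
5-photon sugar price so leaves prefer light while sink tissues respire —
the division of labor the framework is meant to expose.

What the toy does **not** emulate: elemental mass balance (carbon counts are
lumped), thylakoid electron transport, organelle transport (compartment
labels are annotations, currency metabolites are shared), isoenzymes, and
maintenance ATP.  Passing tests on the toy therefore demonstrate the
correctness of the assembly/optimization/sampling machinery and the
qualitative physiology encoded in its energy accounting — not quantitative
agreement with any real reconstruction, whose optima depend on the curated
stoichiometry and constraint tables of that reconstruction.

The `nitrate_coupling` preset adds directional valves (see above) and drops
water from the common pools.  Water exchange is free in every tissue
replica, so pooled water adds only unidentifiable degrees of freedom; and
without directionality, every transporter pair admits a free
export/import cycle whose huge chord (bounds ±1000 versus flows of order
0.1) both drowns the correlation signal and slows chain mixing.  The valves
tax only counter-physiological directions (nitrate downward, sugars upward),
leave the optimum bit-identical to the passive preset, and make the
cross-tissue couplings between sink assimilation and source export visible
to the sampler.

## Problem sizes and numerical choices

Bundled analyses run at toy scale: 174 columns assembled (78 after blocked
removal under the coupling preset), FVA at 2 LPs per flux, 10⁴ samples with
thinning 25–50 for the shipped pipeline and calibration checks.  Default
bounds are ±1000 mmol·gDW⁻¹·h⁻¹ (0 lower for irreversible reactions);
blocked threshold 1e-9; correlation variance floor 1e-12.  Ids use a
reserved double-underscore separator (`{base}__{tissue}__{period}`,
`{species}__CP_{pool}__{period}`, `{species}__SP__{tissue}`), which the
readers reject in base ids so the mapping stays reversible; storage rows
carry the tissue suffix so two tissues may store the same species.

## Known limitations

* No gene–protein–reaction evaluation, thermodynamic loop-law constraints,
  or MILP formulations; free cycles are handled by L1 minimization and, for
  sampling, by directional penalties, not by loop-law cuts.
* More than two periods assemble correctly, but no circadian kinetics are
  modeled; senescence-driven remobilization of C and N is out of scope.
* The ACHR chain has no formal convergence diagnostic beyond the split-half
  guard in the tests; badly conditioned polytopes (very long free chords)
  mix slowly.
* SBML support targets Level 3 + fbc (with a kinetic-law bound fallback on
  read); groups/layout packages are ignored.
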