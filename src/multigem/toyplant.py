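"""A hand-checkable synthetic plant reconstruction and scenario presets.

The toy network lumps whole pathways into single reactions with small
integer/rational stoichiometry so that every photon optimum of the assembled
whole-plant model can be derived by hand (see ``docs/toyplant.md`` for the
full derivation).  It contains:

* a lumped light reaction pair (1 photon -> 1 ATP, 1 photon -> 1 NADPH),
* carbon fixation via RuBisCO (1 CO2 + 3 ATP + 2 NADPH -> 1 sugar unit),
* respiration (1 sugar -> 4 ATP or 4 NADPH), deliberately lossier than
  direct photon capture so leaves prefer light and roots burn sugar,
* nitrate assimilation: nitrate reductase (2 e-) then plastidic nitrite
  reductase (6 e-), i.e. 8 electrons = 4 NADPH per nitrogen, followed by
  the GS/GOGAT cycle (1 ATP + 1 NADPH + 1 carbon skeleton per glutamate),
* the direct ammonium route (GS/GOGAT only), which skips the 4-NADPH
  reduction cost and is therefore cheaper — the nitrate-vs-ammonium photon
  contrast of the whole-plant analysis,
* a starch synthesis/degradation cycle (storage costs 1 ATP per sugar) that
  carries carbon across the night,
* sucrose/glutamate/nitrate/water as translocatable species and a per-tissue
  biomass drain (2 sugar + 1 glutamate + 2 ATP per unit growth).

It is an energy-accounting cartoon, not a thylakoid or TCA model.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

from .core import BaseGEM, Metabolite, ModelError, Reaction
from .scenario import (
    CommonPoolSpec,
    Period,
    PlantScenario,
    StoragePoolSpec,
    TissueSpec,
    TranslocationSpec,
)

__all__ = [
    "ToySpec",
    "make_toy_plant",
    "make_scenario",
    "make_preset_scenarios",
    "HAND_DERIVED_PHOTON_OPTIMA",
    "HAND_DERIVED_STARCH_ACCUMULATION",
    "REDUCTION_SCENARIO_OPTIMUM",
]

#: photons needed per mole of ATP in the single-tissue reduction scenario is
#: 1, so these photon optima are in units of the (time-fraction-weighted)
#: photon uptake flux.  Values are exact rationals derived by hand in
#: docs/toyplant.md for the default ToySpec and the four scenario presets
#: (mass fractions 0.5/0.25/0.25, 12h/12h periods, growth 0.1, active pw=1).
HAND_DERIVED_PHOTON_OPTIMA: dict[str, float] = {
    "nitrate_passive": float(Fraction(213, 40)),    # 5.325
    "ammonium_passive": float(Fraction(35, 8)),     # 4.375
    "nitrate_active": float(Fraction(4363, 640)),   # 6.8171875
    "ammonium_active": float(Fraction(40095, 6400)),  # 6.26484375
}

#: intrinsic day starch accumulation (per g leaf) at the photon optimum
HAND_DERIVED_STARCH_ACCUMULATION: dict[str, float] = {
    "nitrate_passive": 1.0,
    "ammonium_passive": 0.8,
}

#: single-tissue, day-only, nitrate-only scenario (the degenerate-reduction
#: check): 0.1*(2*5) sugar + 0.1*11 glutamate + 0.2*1 ATP photons
REDUCTION_SCENARIO_OPTIMUM = 2.3


@dataclass
class ToySpec:
    include_nitrate_path: bool = True
    include_ammonium_path: bool = True
    starch_cycle: bool = True
    photon_per_co2: float = 5.0   # total quanta per fixed carbon (3 ATP + rest NADPH)
    nadph_per_nitrate: float = 4.0  # 8 electrons: nitrate -> nitrite -> ammonium
    respiratory_yield: float = 4.0  # ATP (or NADPH) per sugar unit respired

    def __post_init__(self) -> None:
        if self.photon_per_co2 <= 3:
            raise ModelError("photon_per_co2 must exceed the 3 ATP floor")
        if self.nadph_per_nitrate <= 1:
            raise ModelError("nadph_per_nitrate must exceed 1 (nitrite step)")
        if self.respiratory_yield <= 0:
            raise ModelError("respiratory_yield must be positive")
        if not (self.include_nitrate_path or self.include_ammonium_path):
            raise ModelError(
                "biomass contains nitrogen: at least one N path is required"
            )


def make_toy_plant(spec: ToySpec | None = None) -> BaseGEM:
    """Build the toy reconstruction (16 metabolites, up to 18 reactions)."""
    spec = spec or ToySpec()
    mets = [
        Metabolite("hv_p", "photon", "plastid"),
        Metabolite("co2_c", "carbon dioxide", "cytosol"),
        Metabolite("h2o_c", "water", "cytosol"),
        Metabolite("atp_c", "ATP", "cytosol"),
        Metabolite("adp_c", "ADP", "cytosol"),
        Metabolite("pi_c", "orthophosphate", "cytosol"),
        Metabolite("nadph_c", "NADPH", "cytosol"),
        Metabolite("nadp_c", "NADP+", "cytosol"),
        Metabolite("suc_c", "sucrose (lumped hexose unit)", "cytosol"),
        Metabolite("akg_m", "2-oxoglutarate", "mitochondrion"),
        Metabolite("glu_c", "glutamate", "cytosol"),
        Metabolite("gln_c", "glutamine", "cytosol"),
        Metabolite("no3_c", "nitrate", "cytosol"),
        Metabolite("no2_c", "nitrite", "cytosol"),
        Metabolite("nh4_c", "ammonium", "cytosol"),
        Metabolite("starch_p", "starch (glucose unit)", "plastid"),
    ]
    B = 1000.0
    nadph_fix = spec.photon_per_co2 - 3.0
    nadph_nir = spec.nadph_per_nitrate - 1.0
    y = spec.respiratory_yield
    rxns = [
        Reaction("EX_hv", {"hv_p": 1.0}, 0, B, "photon uptake", is_exchange=True),
        Reaction("EX_co2", {"co2_c": 1.0}, -B, B, "CO2 exchange", is_exchange=True),
        Reaction("EX_h2o", {"h2o_c": 1.0}, -B, B, "water exchange", is_exchange=True),
        Reaction(
            "LIGHT_ATP",
            {"hv_p": -1.0, "adp_c": -1.0, "pi_c": -1.0, "atp_c": 1.0, "h2o_c": 1.0},
            0, B, "photophosphorylation (lumped)",
        ),
        Reaction(
            "LIGHT_NADPH",
            {"hv_p": -1.0, "nadp_c": -1.0, "nadph_c": 1.0},
            0, B, "photosynthetic electron transport (lumped)",
        ),
        Reaction(
            "RUBISCO",
            {
                "co2_c": -1.0, "atp_c": -3.0, "nadph_c": -nadph_fix,
                "h2o_c": -3.0, "suc_c": 1.0, "adp_c": 3.0, "pi_c": 3.0,
                "nadp_c": nadph_fix,
            },
            0, B, "carbon fixation (RuBisCO + Calvin cycle, lumped)",
        ),
        Reaction(
            "RESP_ATP",
            {"suc_c": -1.0, "adp_c": -y, "pi_c": -y, "atp_c": y,
             "h2o_c": y, "co2_c": 1.0},
            0, B, "respiration to ATP (lumped)",
        ),
        Reaction(
            "RESP_NADPH",
            {"suc_c": -1.0, "nadp_c": -y, "nadph_c": y, "co2_c": 1.0},
            0, B, "oxidative pentose phosphate pathway (lumped)",
        ),
        Reaction(
            "GS",
            {"glu_c": -1.0, "nh4_c": -1.0, "atp_c": -1.0, "gln_c": 1.0,
             "adp_c": 1.0, "pi_c": 1.0},
            0, B, "glutamine synthetase",
        ),
        Reaction(
            "GOGAT",
            {"gln_c": -1.0, "akg_m": -1.0, "nadph_c": -1.0, "glu_c": 2.0,
             "nadp_c": 1.0},
            0, B, "glutamate synthase",
        ),
        Reaction(
            "AKG_SYNTH",
            {"suc_c": -1.0, "akg_m": 1.0},
            0, B, "carbon-skeleton supply (lumped TCA entry)",
        ),
        Reaction(
            "BIOMASS",
            {"suc_c": -2.0, "glu_c": -1.0, "atp_c": -2.0, "h2o_c": -2.0,
             "adp_c": 2.0, "pi_c": 2.0},
            0, B, "biomass drain",
        ),
    ]
    if spec.include_nitrate_path:
        rxns += [
            Reaction("EX_no3", {"no3_c": 1.0}, 0, B, "nitrate uptake",
                     is_exchange=True),
            Reaction(
                "NR",
                {"no3_c": -1.0, "nadph_c": -1.0, "no2_c": 1.0, "nadp_c": 1.0,
                 "h2o_c": 1.0},
                0, B, "cytosolic nitrate reductase",
            ),
            Reaction(
                "NiR",
                {"no2_c": -1.0, "nadph_c": -nadph_nir, "nh4_c": 1.0,
                 "nadp_c": nadph_nir, "h2o_c": 2.0},
                0, B, "plastidic nitrite reductase",
            ),
        ]
    if spec.include_ammonium_path:
        rxns.append(
            Reaction("EX_nh4", {"nh4_c": 1.0}, 0, B, "ammonium uptake",
                     is_exchange=True)
        )
    if spec.starch_cycle:
        rxns += [
            Reaction(
                "STARCH_SYN",
                {"suc_c": -1.0, "atp_c": -1.0, "starch_p": 1.0, "adp_c": 1.0,
                 "pi_c": 1.0, "h2o_c": 1.0},
                0, B, "starch synthesis (branching enzyme, lumped)",
            ),
            Reaction(
                "STARCH_DEG",
                {"starch_p": -1.0, "suc_c": 1.0},
                0, B, "starch degradation (beta-amylase, lumped)",
            ),
        ]
    return BaseGEM(mets, rxns, {"model_id": "toy_plant"})


# ---------------------------------------------------------------------------
# scenario presets
# ---------------------------------------------------------------------------

TRANSLOCATED_SPECIES = ("suc_c", "glu_c", "no3_c")
GROWTH_RATE = 0.1
MASS_FRACTIONS = {"leaf": 0.5, "stem": 0.25, "root": 0.25}


def make_scenario(
    nitrogen_source: str,
    pw: float = 0.0,
    name: str | None = None,
    growth_rate: float = GROWTH_RATE,
) -> PlantScenario:
    """Three-tissue diurnal scenario over the toy plant.

    Leaf is phototrophic; RuBisCO and the N uptakes are closed in the
    heterotrophic tissues (uptake happens in the root).  ``pw`` is the ATP
    penalty per mole of sucrose/glutamate/nitrate exported to a common pool
    (water stays passive); 0 gives the passive variant.
    """
    uptake_closed = ["EX_no3", "EX_nh4"]
    tissues = [
        TissueSpec("leaf", MASS_FRACTIONS["leaf"], phototrophic=True,
                   biomass_reaction="BIOMASS", growth_rate=growth_rate,
                   disabled_reactions=list(uptake_closed)),
        TissueSpec("stem", MASS_FRACTIONS["stem"],
                   biomass_reaction="BIOMASS", growth_rate=growth_rate,
                   disabled_reactions=["RUBISCO", *uptake_closed]),
        TissueSpec("root", MASS_FRACTIONS["root"],
                   biomass_reaction="BIOMASS", growth_rate=growth_rate,
                   disabled_reactions=["RUBISCO"]),
    ]
    pools = [
        CommonPoolSpec("leaf_stem", ("leaf", "stem"),
                       species=[*TRANSLOCATED_SPECIES, "h2o_c"]),
        CommonPoolSpec("stem_root", ("stem", "root"),
                       species=[*TRANSLOCATED_SPECIES, "h2o_c"]),
    ]
    translocations = [
        TranslocationSpec(species, tissue, pool, penalty_weight=pw)
        for species in TRANSLOCATED_SPECIES
        for tissue, pool in (
            ("leaf", "leaf_stem"), ("stem", "leaf_stem"),
            ("stem", "stem_root"), ("root", "stem_root"),
        )
    ]
    mode = "passive" if pw == 0 else "active"
    return PlantScenario(
        tissues=tissues,
        periods=[Period("day", 0.5, light=True),
                 Period("night", 0.5, light=False)],
        common_pools=pools,
        storage_pools=[
            StoragePoolSpec("starch_p", "leaf",
                            {"day": "accumulate", "night": "release"})
        ],
        translocations=translocations,
        nitrogen_source=nitrogen_source,
        photon_reaction="EX_hv",
        nitrate_uptake_reaction="EX_no3",
        ammonium_uptake_reaction="EX_nh4",
        name=name or f"{nitrogen_source}_{mode}",
    )


ACTIVE_PW = 1.0


def make_preset_scenarios() -> list[PlantScenario]:
    """The 2x2 design: {nitrate, ammonium} x {passive, active} translocation."""
    return [
        make_scenario("nitrate", pw=0.0, name="nitrate_passive"),
        make_scenario("nitrate", pw=ACTIVE_PW, name="nitrate_active"),
        make_scenario("ammonium", pw=0.0, name="ammonium_passive"),
        make_scenario("ammonium", pw=ACTIVE_PW, name="ammonium_active"),
    ]


def make_coupling_scenario(valve_pw: float = 1.0) -> PlantScenario:
    """Nitrate scenario with directional transport, for coupling analysis.

    Net translocation in the plant is directional: nitrate moves rootward
    tissues -> leaf (xylem) and sucrose leaf -> sink tissues (phloem).  This
    preset encodes that directionality by penalizing only the counter-flow
    transporter directions (nitrate down, sucrose up, and re-export into the
    pool a species came from).  Those directions carry zero flux at the
    passive optimum, so the photon optimum is identical to
    ``nitrate_passive``; what changes is the optimal-face geometry: the free
    export/import cycles disappear, so net translocation fluxes become
    perfectly coupled to the assimilation machinery of the tissues they
    feed, which is what makes cross-tissue coupled modules (with transporter
    "tissue linkers") detectable by sampling.
    """
    scenario = make_scenario("nitrate", pw=0.0, name="nitrate_coupling")
    # water exchange is free in every tissue replica, so pooled water
    # transport is redundant here and only adds unidentifiable degrees of
    # freedom; keep the pools to the three informative species
    for pool in scenario.common_pools:
        pool.species = list(TRANSLOCATED_SPECIES)
    valves = [
        # nitrate flows root -> stem -> leaf; tax the reverse directions
        ("no3_c", "root", "stem_root", "import"),
        ("no3_c", "stem", "stem_root", "export"),
        ("no3_c", "stem", "leaf_stem", "import"),
        ("no3_c", "leaf", "leaf_stem", "export"),
        # sucrose and glutamate flow leaf -> stem -> root (source to sink);
        # tax the reverse directions
        *(
            (species, tissue, pool, direction)
            for species in ("suc_c", "glu_c")
            for tissue, pool, direction in (
                ("leaf", "leaf_stem", "import"),
                ("stem", "leaf_stem", "export"),
                ("stem", "stem_root", "import"),
                ("root", "stem_root", "export"),
            )
        ),
    ]
    translocations = [
        tr for tr in scenario.translocations
        if not any((tr.species, tr.from_tissue, tr.to_pool) == v[:3]
                   for v in valves)
    ]
    translocations += [
        TranslocationSpec(species, tissue, pool, penalty_weight=valve_pw,
                          direction=direction)
        for species, tissue, pool, direction in valves
    ]
    scenario.translocations = translocations
    return scenario


def make_reduction_scenario() -> PlantScenario:
    """Single tissue, single (light) period, no pools: plain FBA territory."""
    return PlantScenario(
        tissues=[
            TissueSpec("plant", 1.0, phototrophic=True,
                       biomass_reaction="BIOMASS", growth_rate=GROWTH_RATE)
        ],
        periods=[Period("always", 1.0, light=True)],
        nitrogen_source="nitrate",
        photon_reaction="EX_hv",
        nitrate_uptake_reaction="EX_no3",
        ammonium_uptake_reaction="EX_nh4",
        name="reduction",
    )
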