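"""Assembly of the whole-plant stoichiometric system.

The assembled matrix has the nested block structure

* one internal/exchange block (S | E) per tissue per period, with bounds
  specialized by trophic mode, disabled reactions and fixed growth;
* one pair of irreversible transport columns (T) per translocatable species,
  member tissue, common pool and period, whose common-pool row entries are
  scaled by the tissue mass fractions so that intrinsic per-gram fluxes
  balance as whole-plant flows;
* one accumulation column (A) per storage pool and period, whose storage-pool
  row entries are scaled by the period time fractions so that what is stored
  in one period is retrieved in the others.

Active translocation is charged as pw moles of ATP hydrolyzed (ATP + H2O ->
ADP + orthophosphate in the paying tissue) per mole of species moved.
"""

from __future__ import annotations

from .core import (
    DEFAULT_BOUND,
    SEP,
    BaseGEM,
    FluxInfo,
    ModelError,
    RowInfo,
    ROW_COMMON_POOL,
    ROW_STORAGE_POOL,
    ROW_TISSUE,
    WholePlantModel,
)
from .scenario import (
    CommonPoolSpec,
    Period,
    PlantScenario,
    StoragePoolSpec,
    TissueSpec,
    TranslocationSpec,
)

__all__ = [
    "assemble",
    "replicate_tissue",
    "add_common_pool",
    "add_storage_pool",
    "classify_entries",
    "DEFAULT_ENERGY_SPECIES",
]

#: base-GEM ids of the species charged by translocation penalties; override
#: via PlantScenario.energy_species when the reconstruction names them
#: differently.
DEFAULT_ENERGY_SPECIES = {"atp": "atp_c", "adp": "adp_c", "pi": "pi_c",
                          "h2o": "h2o_c"}


def tissue_row(met_id: str, tissue: str, period: str) -> str:
    return f"{met_id}{SEP}{tissue}{SEP}{period}"


def tissue_col(rxn_id: str, tissue: str, period: str) -> str:
    return f"{rxn_id}{SEP}{tissue}{SEP}{period}"


def pool_row(species: str, pool: str, period: str) -> str:
    return f"{species}{SEP}CP_{pool}{SEP}{period}"


def storage_row(species: str, tissue: str) -> str:
    return f"{species}{SEP}SP{SEP}{tissue}"


def replicate_tissue(
    model: WholePlantModel,
    base: BaseGEM,
    spec: TissueSpec,
    period: Period,
    scenario: PlantScenario,
    growth_equality: bool = True,
) -> None:
    """Copy every base metabolite and reaction into one (tissue, period) block.

    Disabled reactions are pinned to zero flux, the biomass reaction is fixed
    to the tissue growth rate in every period (growth continues at night),
    and the photon reaction is closed in non-phototrophic tissues and in dark
    periods.
    """
    for rid in spec.disabled_reactions:
        if not base.has_reaction(rid):
            raise ModelError(
                f"tissue {spec.name!r}: unknown disabled reaction {rid!r}"
            )
    disabled = set(spec.disabled_reactions)
    for met in base.metabolites:
        model.add_row(
            tissue_row(met.id, spec.name, period.name),
            RowInfo(ROW_TISSUE, species=met.id, tissue=spec.name,
                    period=period.name),
        )
    time_fraction = period.time_fraction
    for rxn in base.reactions:
        lb, ub = rxn.lower_bound, rxn.upper_bound
        objective = 0.0
        if rxn.id in disabled:
            lb = ub = 0.0
        if rxn.id == scenario.photon_reaction:
            if not (spec.phototrophic and period.light):
                lb = ub = 0.0
            objective = time_fraction
        if scenario.nitrogen_source == "nitrate" and \
                rxn.id == scenario.ammonium_uptake_reaction:
            lb = ub = 0.0
        if scenario.nitrogen_source == "ammonium" and \
                rxn.id == scenario.nitrate_uptake_reaction:
            lb = ub = 0.0
        if rxn.id == spec.biomass_reaction:
            if growth_equality:
                lb = ub = spec.growth_rate
            else:
                lb, ub = spec.growth_rate, max(ub, spec.growth_rate)
        stoich = {
            tissue_row(met, spec.name, period.name): coef
            for met, coef in rxn.stoichiometry.items()
        }
        model.add_column(
            tissue_col(rxn.id, spec.name, period.name),
            stoich,
            lb,
            ub,
            FluxInfo(
                kind="exchange" if rxn.is_exchange else "reaction",
                base_reaction=rxn.id,
                tissue=spec.name,
                period=period.name,
            ),
            objective=objective,
        )


def _penalty_terms(
    model: WholePlantModel,
    scenario: PlantScenario,
    tissue: str,
    period: str,
    pw: float,
) -> dict[str, float]:
    """Stoichiometry of pw mol ATP hydrolysis in the paying tissue replica."""
    energy = dict(DEFAULT_ENERGY_SPECIES)
    energy.update(getattr(scenario, "energy_species", None) or {})
    terms: dict[str, float] = {}
    for key, sign in (("atp", -1.0), ("h2o", -1.0), ("adp", +1.0), ("pi", +1.0)):
        met = energy[key]
        if not model.base.has_metabolite(met):
            raise ModelError(
                f"translocation penalty needs metabolite {met!r} ({key}) "
                f"in the base model"
            )
        terms[tissue_row(met, tissue, period)] = sign * pw
    return terms


def add_common_pool(
    model: WholePlantModel,
    pool: CommonPoolSpec,
    scenario: PlantScenario,
    period: Period,
) -> None:
    """Add one balance row per species and paired export/import transporters.

    The export column for species s from tissue t removes one mole per gram
    of tissue (-1 on the tissue row) and delivers the extrinsic amount
    (+mass_fraction on the pool row); imports mirror it.  With a positive
    penalty weight the exporting (by default) column additionally hydrolyzes
    pw ATP in the paying tissue.
    """
    for species in pool.species:
        if not model.base.has_metabolite(species):
            raise ModelError(
                f"common pool {pool.name!r}: species {species!r} not in base model"
            )
        row = pool_row(species, pool.name, period.name)
        model.add_row(
            row,
            RowInfo(ROW_COMMON_POOL, species=species, period=period.name,
                    pool=pool.name),
        )
        for tissue_name in pool.members:
            spec = scenario.tissue(tissue_name)
            trow = tissue_row(species, tissue_name, period.name)
            tr = scenario.penalty(species, tissue_name, pool.name)
            pw = tr.penalty_weight if tr else 0.0
            direction = tr.direction if tr else "export"

            export_stoich = {trow: -1.0, row: +spec.mass_fraction}
            if pw > 0 and direction in ("export", "both"):
                for met_row, coef in _penalty_terms(
                    model, scenario, tissue_name, period.name, pw
                ).items():
                    export_stoich[met_row] = export_stoich.get(met_row, 0.0) + coef
            model.add_column(
                f"TX{SEP}{species}{SEP}{tissue_name}{SEP}{pool.name}"
                f"{SEP}export{SEP}{period.name}",
                export_stoich,
                0.0,
                DEFAULT_BOUND,
                FluxInfo(kind="transport", species=species, tissue=tissue_name,
                         pool=pool.name, direction="export", period=period.name),
            )

            import_stoich = {row: -spec.mass_fraction, trow: +1.0}
            if pw > 0 and direction in ("import", "both"):
                for met_row, coef in _penalty_terms(
                    model, scenario, tissue_name, period.name, pw
                ).items():
                    import_stoich[met_row] = import_stoich.get(met_row, 0.0) + coef
            model.add_column(
                f"TX{SEP}{species}{SEP}{tissue_name}{SEP}{pool.name}"
                f"{SEP}import{SEP}{period.name}",
                import_stoich,
                0.0,
                DEFAULT_BOUND,
                FluxInfo(kind="transport", species=species, tissue=tissue_name,
                         pool=pool.name, direction="import", period=period.name),
            )


def add_storage_pool(
    model: WholePlantModel,
    spec: StoragePoolSpec,
    scenario: PlantScenario,
) -> None:
    """Add the storage balance row and one accumulation column per period.

    The balance row sum_p time_fraction_p * a_p = 0 enforces that whatever is
    stored in one period is retrieved in the others; sign constraints become
    flux bounds (accumulate: a >= 0, release: a <= 0).
    """
    missing = {p.name for p in scenario.periods} - set(spec.sign_constraints)
    if missing:
        raise ModelError(
            f"storage pool {spec.species!r}: sign constraints missing periods "
            f"{sorted(missing)}"
        )
    row = storage_row(spec.species, spec.tissue)
    model.add_row(
        row, RowInfo(ROW_STORAGE_POOL, species=spec.species, tissue=spec.tissue)
    )
    for period in scenario.periods:
        sign = spec.sign_constraints[period.name]
        lb, ub = -DEFAULT_BOUND, DEFAULT_BOUND
        if sign == "accumulate":
            lb = 0.0
        elif sign == "release":
            ub = 0.0
        model.add_column(
            f"AC{SEP}{spec.species}{SEP}{spec.tissue}{SEP}{period.name}",
            {
                tissue_row(spec.species, spec.tissue, period.name): -1.0,
                row: +period.time_fraction,
            },
            lb,
            ub,
            FluxInfo(kind="accumulation", species=spec.species,
                     tissue=spec.tissue, pool="SP", period=period.name),
        )


def assemble(
    base: BaseGEM,
    scenario: PlantScenario,
    growth_equality: bool = True,
) -> WholePlantModel:
    """Build the full whole-plant system for a scenario.

    The per-period tissue/pool block is instantiated once per period; storage
    pools link the periods.  The objective vector selects the photon uptake
    replicas weighted by the period time fractions (photon minimization).
    """
    scenario.validate_against(base)
    model = WholePlantModel(base)
    for period in scenario.periods:
        for tissue in scenario.tissues:
            replicate_tissue(model, base, tissue, period, scenario,
                             growth_equality=growth_equality)
        for pool in scenario.common_pools:
            add_common_pool(model, pool, scenario, period)
    for sp in scenario.storage_pools:
        add_storage_pool(model, sp, scenario)
    return model


_ENTRY_LABELS = {
    ("reaction", ROW_TISSUE): "S",
    ("exchange", ROW_TISSUE): "E",
    ("transport", ROW_TISSUE): "T",
    ("transport", ROW_COMMON_POOL): "CP",
    ("accumulation", ROW_TISSUE): "A",
    ("accumulation", ROW_STORAGE_POOL): "SP",
}


def classify_entries(model: WholePlantModel) -> dict[tuple[str, str], str | None]:
    """Label every nonzero of the assembled matrix by its block of origin.

    Returns (row id, column id) -> one of S/E/T/A/CP/SP, or None for a
    nonzero that fits no block — the audit invariant is that None never
    occurs and that S/E entries stay within their own (tissue, period).
    """
    labels: dict[tuple[str, str], str | None] = {}
    for col in model.columns:
        for row_id in col.stoich:
            rinfo = model.row_info[row_id]
            label = _ENTRY_LABELS.get((col.info.kind, rinfo.kind))
            if label in ("S", "E") and (
                rinfo.tissue != col.info.tissue or rinfo.period != col.info.period
            ):
                label = None
            if label == "A" and rinfo.tissue != col.info.tissue:
                label = None
            labels[(row_id, col.id)] = label
    return labels
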