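"""Assembly: replication, pool weighting, block structure, reductions."""

from __future__ import annotations

import numpy as np
import pytest

from multigem import (
    BaseGEM,
    CommonPoolSpec,
    Metabolite,
    ModelError,
    Period,
    PlantScenario,
    Reaction,
    StoragePoolSpec,
    TissueSpec,
    TranslocationSpec,
    assemble,
    classify_entries,
    fba_min_photon,
    make_scenario,
    make_toy_plant,
)
from multigem.optimize import LPProblem
from multigem.toyplant import make_reduction_scenario


def _count(model, **sel):
    return len(model.find_columns(**sel))


def test_replica_and_transporter_counts(preset_models, toy_gem):
    """3 tissues x 2 periods over an 18-reaction base gives 108 replicated
    columns, plus 2 pools x 4 species x 2 tissues x 2 directions x 2 periods
    transporters and one accumulation column per period."""
    model = preset_models["nitrate_passive"]
    n_base = len(toy_gem.reactions)
    replicated = [
        c for c in model.columns if c.info.kind in ("reaction", "exchange")
    ]
    assert len(replicated) == n_base * 3 * 2 == 108
    assert _count(model, kind="transport") == 2 * 4 * 2 * 2 * 2
    assert _count(model, kind="accumulation") == 2
    assert model.n_cols == 108 + 64 + 2


def test_heterotrophic_and_diurnal_closures(preset_models):
    model = preset_models["nitrate_passive"]
    # carbon fixation closed in heterotrophic tissues
    for tissue in ("stem", "root"):
        for period in ("day", "night"):
            col = model.column(f"RUBISCO__{tissue}__{period}")
            assert (col.lb, col.ub) == (0.0, 0.0)
    # photons unavailable at night even in the leaf, and never in stem/root
    assert model.column("EX_hv__leaf__night").ub == 0.0
    assert model.column("EX_hv__stem__day").ub == 0.0
    assert model.column("EX_hv__leaf__day").ub > 0.0
    # growth is imposed in both periods
    for period in ("day", "night"):
        col = model.column(f"BIOMASS__leaf__{period}")
        assert col.lb == col.ub == pytest.approx(0.1)


def test_nitrogen_source_constraint(preset_models):
    nit = preset_models["nitrate_passive"]
    amm = preset_models["ammonium_passive"]
    assert (nit.column("EX_nh4__root__day").lb,
            nit.column("EX_nh4__root__day").ub) == (0.0, 0.0)
    assert (amm.column("EX_no3__root__day").lb,
            amm.column("EX_no3__root__day").ub) == (0.0, 0.0)
    assert amm.column("EX_nh4__root__day").ub > 0.0


# ---------------------------------------------------------------------------
# pool weighting
# ---------------------------------------------------------------------------


def _two_tissue_fragment():
    """Producer/consumer pair sharing species X through one pool, with mass
    fractions 0.6 / 0.3 (third tissue holds the rest of the mass)."""
    gem = BaseGEM(
        [Metabolite("X", compartment="c")],
        [
            Reaction("MAKE", {"X": 1.0}, 0, 1000),
            Reaction("USE", {"X": -1.0}, 0, 1000),
        ],
    )
    scenario = PlantScenario(
        tissues=[
            TissueSpec("leaf", 0.6, phototrophic=True,
                       disabled_reactions=["USE"]),
            TissueSpec("stem", 0.3, disabled_reactions=["MAKE"]),
            TissueSpec("idle", 0.1, disabled_reactions=["MAKE", "USE"]),
        ],
        periods=[Period("day", 1.0)],
        common_pools=[CommonPoolSpec("ls", ("leaf", "stem"), species=["X"])],
        photon_reaction="MAKE",
    )
    return assemble(gem, scenario)


def test_common_pool_row_carries_mass_fractions():
    model = _two_tissue_fragment()
    row = "X__CP_ls__day"
    exp = model.column("TX__X__leaf__ls__export__day")
    imp = model.column("TX__X__stem__ls__import__day")
    assert exp.stoich[row] == pytest.approx(0.6)
    assert imp.stoich[row] == pytest.approx(-0.3)
    assert exp.stoich["X__leaf__day"] == -1.0
    assert imp.stoich["X__stem__day"] == +1.0


def test_common_pool_balance_forces_extrinsic_flux_match():
    """With mass fractions 0.6/0.3, one intrinsic unit exported by the large
    tissue must be imported as two intrinsic units by the small one
    (0.6 * export = 0.3 * import at steady state)."""
    model = _two_tissue_fragment()
    model.set_bounds("TX__X__leaf__ls__export__day", 1.0, 1.0)
    # close the reverse directions so the exported amount cannot cycle back
    model.set_bounds("TX__X__leaf__ls__import__day", 0.0, 0.0)
    model.set_bounds("TX__X__stem__ls__export__day", 0.0, 0.0)
    lb, ub = model.bounds()
    j = model.column_index("TX__X__stem__ls__import__day")
    for sense, expected in ((1, 2.0), (-1, 2.0)):
        c = np.zeros(model.n_cols)
        c[j] = 1.0
        res = LPProblem(c, model.matrix().tocsc(),
                        np.zeros(model.n_rows), lb, ub).solve(sense=sense)
        assert res.status == "optimal"
        assert res.objective == pytest.approx(expected, abs=1e-9)


def test_storage_pool_time_fraction_balance():
    """With time fractions 2/3 day, 1/3 night, feasibility forces
    a_night = -2 a_day."""
    gem = BaseGEM(
        [Metabolite("S", compartment="p")],
        [
            Reaction("MAKE", {"S": 1.0}, 0, 1000),
            Reaction("USE", {"S": -1.0}, 0, 1000),
        ],
    )
    scenario = PlantScenario(
        tissues=[TissueSpec("leaf", 1.0, phototrophic=True)],
        periods=[Period("day", 2 / 3), Period("night", 1 / 3, light=False)],
        storage_pools=[
            StoragePoolSpec("S", "leaf",
                            {"day": "accumulate", "night": "release"})
        ],
        photon_reaction="MAKE",
    )
    model = assemble(gem, scenario)
    model.set_bounds("AC__S__leaf__day", 1.0, 1.0)
    lb, ub = model.bounds()
    j = model.column_index("AC__S__leaf__night")
    c = np.zeros(model.n_cols)
    c[j] = 1.0
    for sense in (1, -1):
        res = LPProblem(c, model.matrix().tocsc(),
                        np.zeros(model.n_rows), lb, ub).solve(sense=sense)
        assert res.status == "optimal"
        assert res.objective == pytest.approx(-2.0, abs=1e-9)


def test_storage_sign_constraints(preset_models):
    model = preset_models["nitrate_passive"]
    day = model.column("AC__starch_p__leaf__day")
    night = model.column("AC__starch_p__leaf__night")
    assert day.lb == 0.0 and day.ub > 0
    assert night.ub == 0.0 and night.lb < 0


# ---------------------------------------------------------------------------
# block-pattern audit and reductions
# ---------------------------------------------------------------------------


@pytest.mark.parametrize("preset", ["nitrate_passive", "nitrate_active"])
def test_block_pattern_exhaustive(preset_models, preset):
    """Every nonzero of the assembled matrix is classified into exactly one
    of the S/E/T/A/CP/SP blocks."""
    labels = classify_entries(preset_models[preset])
    assert labels, "matrix has no entries?"
    unclassified = [k for k, v in labels.items() if v is None]
    assert unclassified == []
    assert set(labels.values()) == {"S", "E", "T", "A", "CP", "SP"}


def test_degenerate_reduction_matches_base_fba(toy_gem, reduction_model):
    """One tissue, one period, no pools: the assembly is base S plus E and
    min-photon FBA matches an LP built directly from the base matrices."""
    # matrix equality up to the id suffixing
    S = toy_gem.stoichiometric_matrix().toarray()
    W = reduction_model.matrix().toarray()
    met_order = [r.split("__")[0] for r in reduction_model.row_ids]
    col_order = [c.id.split("__")[0] for c in reduction_model.columns]
    assert met_order == toy_gem.metabolite_ids
    assert col_order == toy_gem.reaction_ids
    assert np.array_equal(S, W)

    sol = fba_min_photon(reduction_model)

    # independent direct LP on the base reconstruction
    lb, ub = [], []
    scenario = make_reduction_scenario()
    for r in toy_gem.reactions:
        lo, hi = r.lower_bound, r.upper_bound
        if r.id == "BIOMASS":
            lo = hi = 0.1
        if r.id == "EX_nh4":
            lo = hi = 0.0
        lb.append(lo)
        ub.append(hi)
    c = np.array([1.0 if r.id == "EX_hv" else 0.0 for r in toy_gem.reactions])
    res = LPProblem(c, toy_gem.stoichiometric_matrix().tocsc(),
                    np.zeros(len(toy_gem.metabolites)),
                    np.array(lb), np.array(ub)).solve()
    assert res.status == "optimal"
    assert abs(sol.objective_value - res.objective) < 1e-9


def test_reduction_matches_cobra_oracle(toy_gem, reduction_model):
    """Cross-check the same reduction against cobrapy/GLPK as an independent
    FBA implementation."""
    cobra = pytest.importorskip("cobra")
    m = cobra.Model("toy")
    mets = {
        mt.id: cobra.Metabolite(mt.id, compartment=mt.compartment)
        for mt in toy_gem.metabolites
    }
    for r in toy_gem.reactions:
        rxn = cobra.Reaction(r.id)
        m.add_reactions([rxn])
        rxn.add_metabolites({mets[k]: v for k, v in r.stoichiometry.items()})
        rxn.bounds = (r.lower_bound, r.upper_bound)
    m.reactions.get_by_id("BIOMASS").bounds = (0.1, 0.1)
    m.reactions.get_by_id("EX_nh4").bounds = (0.0, 0.0)
    m.objective = m.reactions.get_by_id("EX_hv")
    m.objective_direction = "min"
    sol = m.optimize()
    assert sol.status == "optimal"
    ours = fba_min_photon(reduction_model)
    assert ours.objective_value == pytest.approx(sol.objective_value, abs=1e-6)


def test_penalty_zero_equals_penalty_free_build(toy_gem):
    """pw=0 through the penalty machinery produces the same matrix and the
    same optimum as a build with no penalty terms at all."""
    passive = assemble(toy_gem, make_scenario("nitrate", 0.0))
    no_terms = assemble(
        toy_gem,
        make_scenario("nitrate", 0.0, name="explicitly_penalty_free"),
    )
    assert passive.column_ids == no_terms.column_ids
    for a, b in zip(passive.columns, no_terms.columns):
        assert a.stoich == b.stoich and (a.lb, a.ub) == (b.lb, b.ub)
    za = fba_min_photon(passive).objective_value
    zb = fba_min_photon(no_terms).objective_value
    assert za == zb


def test_penalty_monotonicity(toy_gem):
    """An ATP tax on translocation can never reduce the photon demand."""
    optima = []
    for pw in (0.0, 0.5, 1.0, 2.0):
        model = assemble(toy_gem, make_scenario("nitrate", pw))
        optima.append(fba_min_photon(model).objective_value)
    assert all(b >= a - 1e-9 for a, b in zip(optima, optima[1:]))
    assert optima[-1] > optima[0]  # the tax binds on this network


def test_mass_fraction_scale_invariance(toy_gem):
    """Only the ratios of the tissue weights matter: fractions derived from
    proportional weight vectors give identical optimal intrinsic fluxes."""
    from multigem import fba_l1_representative

    weights = np.array([2.0, 1.0, 1.0])
    solutions = []
    for scale in (1.0, 3.0):
        w = weights * scale
        fractions = w / w.sum()
        sc = make_scenario("nitrate", 0.0)
        for t, f in zip(sc.tissues, fractions):
            t.mass_fraction = f
        model = assemble(toy_gem, sc)
        solutions.append(fba_l1_representative(model))
    assert solutions[0].objective_value == pytest.approx(
        solutions[1].objective_value, abs=1e-9
    )
    for fid, v in solutions[0].fluxes.items():
        assert solutions[1].fluxes[fid] == pytest.approx(v, abs=1e-6)


def test_unknown_disabled_reaction_rejected(toy_gem):
    sc = make_scenario("nitrate", 0.0)
    sc.tissues[0].disabled_reactions.append("NOT_A_REACTION")
    with pytest.raises(ModelError, match="NOT_A_REACTION"):
        assemble(toy_gem, sc)


def test_translocation_penalty_stoichiometry(toy_gem):
    """An active export column realizes pw [ATP + H2O] + species(tissue) ->
    pw [ADP + Pi](tissue) + species(pool)."""
    model = assemble(toy_gem, make_scenario("nitrate", 1.5))
    col = model.column("TX__suc_c__leaf__leaf_stem__export__day")
    assert col.stoich["suc_c__leaf__day"] == -1.0
    assert col.stoich["suc_c__CP_leaf_stem__day"] == pytest.approx(0.5)
    assert col.stoich["atp_c__leaf__day"] == pytest.approx(-1.5)
    assert col.stoich["h2o_c__leaf__day"] == pytest.approx(-1.5)
    assert col.stoich["adp_c__leaf__day"] == pytest.approx(1.5)
    assert col.stoich["pi_c__leaf__day"] == pytest.approx(1.5)
    # passive water transporter touches only the species rows
    water = model.column("TX__h2o_c__leaf__leaf_stem__export__day")
    assert set(water.stoich) == {"h2o_c__leaf__day", "h2o_c__CP_leaf_stem__day"}
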