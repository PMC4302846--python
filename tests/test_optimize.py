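"""Photon FBA, L1 representative, FVA and blocked-reaction removal."""

from __future__ import annotations

import numpy as np
import pytest
from scipy import sparse
from scipy.optimize import linprog

from multigem import (
    BaseGEM,
    Metabolite,
    PlantScenario,
    Period,
    Reaction,
    TissueSpec,
    assemble,
    fba_l1_representative,
    fba_min_photon,
    fva,
    make_toy_plant,
    remove_blocked,
)
from multigem.optimize import LPProblem, OptimizationError, model_lp
from multigem.toyplant import REDUCTION_SCENARIO_OPTIMUM, ToySpec, make_reduction_scenario


def test_reduction_scenario_photon_optimum(reduction_model):
    """Single-tissue day-only nitrate growth at 0.1 costs
    0.1*10 (sugar) + 0.1*11 (glutamate) + 0.2 (ATP) photons."""
    sol = fba_min_photon(reduction_model)
    assert sol.status == "optimal"
    assert sol.objective_value == pytest.approx(REDUCTION_SCENARIO_OPTIMUM,
                                                abs=1e-9)


def test_zero_growth_needs_no_photons(toy_gem):
    sc = make_reduction_scenario()
    sc.tissues[0].growth_rate = 0.0
    sol = fba_min_photon(assemble(toy_gem, sc))
    assert sol.status == "optimal"
    assert sol.objective_value == pytest.approx(0.0, abs=1e-9)


def test_growth_without_nitrogen_is_infeasible(toy_gem):
    sc = make_reduction_scenario()
    sc.tissues[0].disabled_reactions = ["EX_no3", "EX_nh4"]
    sol = fba_min_photon(assemble(toy_gem, sc))
    assert sol.status == "infeasible"
    assert sol.fluxes == {}


# ---------------------------------------------------------------------------
# L1 representative
# ---------------------------------------------------------------------------


def _cycle_model():
    """Photon-fed biomass plus a free reversible 3-cycle a->b->c->a that is
    not coupled to the objective."""
    gem = BaseGEM(
        [Metabolite(x, compartment="c") for x in ("p", "a", "b", "c")],
        [
            Reaction("EX_p", {"p": 1.0}, 0, 1000, is_exchange=True),
            Reaction("GROW", {"p": -1.0}, 0, 1000),
            Reaction("R_ab", {"a": -1.0, "b": 1.0}, -1000, 1000),
            Reaction("R_bc", {"b": -1.0, "c": 1.0}, -1000, 1000),
            Reaction("R_ca", {"c": -1.0, "a": 1.0}, -1000, 1000),
        ],
    )
    scenario = PlantScenario(
        tissues=[TissueSpec("t", 1.0, phototrophic=True,
                            biomass_reaction="GROW", growth_rate=1.0)],
        periods=[Period("day", 1.0)],
        photon_reaction="EX_p",
    )
    return assemble(gem, scenario)


def test_l1_zeroes_free_cycles():
    model = _cycle_model()
    sol = fba_l1_representative(model)
    assert sol.status == "optimal"
    assert sol.objective_value == pytest.approx(1.0)
    for rid in ("R_ab__t__day", "R_bc__t__day", "R_ca__t__day"):
        assert sol.fluxes[rid] == pytest.approx(0.0, abs=1e-9)
    # photon uptake and growth both carry exactly the demanded unit
    assert sol.l1_norm == pytest.approx(2.0, abs=1e-9)


def test_l1_matches_epigraph_encoding(preset_models, preset_optima):
    """Independent oracle: minimize sum(t) with t >= v, t >= -v gives the
    same minimal L1 norm as the flux-splitting encoding."""
    model = preset_models["nitrate_passive"]
    z = preset_optima["nitrate_passive"]
    sol = fba_l1_representative(model, z)
    assert sol.objective_value == pytest.approx(z, abs=1e-9)

    lp = model_lp(model)
    n = len(lp.c)
    A_eq = sparse.hstack([lp.A, sparse.csr_matrix((lp.A.shape[0], n))])
    A_eq = sparse.vstack(
        [A_eq, sparse.hstack([sparse.csr_matrix(lp.c), sparse.csr_matrix((1, n))])]
    )
    b_eq = np.append(np.zeros(lp.A.shape[0]), z)
    eye = sparse.identity(n)
    A_ub = sparse.vstack(
        [sparse.hstack([eye, -eye]), sparse.hstack([-eye, -eye])]
    )
    res = linprog(
        np.concatenate([np.zeros(n), np.ones(n)]),
        A_ub=A_ub.tocsc(),
        b_ub=np.zeros(2 * n),
        A_eq=A_eq.tocsc(),
        b_eq=b_eq,
        bounds=[(lo, hi) for lo, hi in zip(lp.lb, lp.ub)]
        + [(0, None)] * n,
        method="highs",
    )
    assert res.status == 0
    assert sol.l1_norm == pytest.approx(res.fun, abs=1e-6)


def test_l1_infeasible_optimum_reports_clearly(preset_models, preset_optima):
    model = preset_models["nitrate_passive"]
    with pytest.raises(OptimizationError, match="infeasible"):
        fba_l1_representative(model, preset_optima["nitrate_passive"] * 0.5)


# ---------------------------------------------------------------------------
# FVA
# ---------------------------------------------------------------------------


def test_fva_pins_constrained_fluxes(preset_models, preset_optima,
                                     nitrate_passive_fva):
    result = nitrate_passive_fva
    for period in ("day", "night"):
        lo, hi = result.range(f"BIOMASS__leaf__{period}")
        assert lo == pytest.approx(0.1, abs=1e-9)
        assert hi == pytest.approx(0.1, abs=1e-9)
    for fid in result.minimum:
        assert result.minimum[fid] <= result.maximum[fid] + 1e-9


def test_fva_brackets_l1_solution(preset_models, preset_optima,
                                  nitrate_passive_fva):
    sol = fba_l1_representative(
        preset_models["nitrate_passive"], preset_optima["nitrate_passive"]
    )
    for fid, v in sol.fluxes.items():
        lo, hi = nitrate_passive_fva.range(fid)
        assert lo - 1e-6 <= v <= hi + 1e-6


def test_fva_classification_matches_feasibility_oracle(
    preset_models, preset_optima, nitrate_passive_fva
):
    """Brute-force oracle: for each flux, probe with feasibility LPs whether
    it can be pushed away from zero (sign tests) and away from its
    representative value (fixedness), with the photon objective pinned."""
    model = preset_models["nitrate_passive"]
    z = preset_optima["nitrate_passive"]
    rep = fba_l1_representative(model, z)
    lp = model_lp(model)
    A = sparse.vstack([lp.A, sparse.csr_matrix(lp.c)]).tocsc()
    b = np.append(lp.b, z)
    tau = 1e-6

    def feasible(j, lo, hi):
        lb, ub = lp.lb.copy(), lp.ub.copy()
        lb[j], ub[j] = max(lp.lb[j], lo), min(lp.ub[j], hi)
        if lb[j] > ub[j]:
            return False
        res = LPProblem(np.zeros(len(lb)), A, b, lb, ub).solve()
        return res.status == "optimal"

    classes = nitrate_passive_fva.classify()
    rng = np.random.default_rng(0)
    # exhaustive over a deterministic subsample to keep the LP count sane
    indices = rng.choice(model.n_cols, size=60, replace=False)
    for j in sorted(indices):
        fid = model.column_ids[j]
        can_pos = feasible(j, tau, np.inf)
        can_neg = feasible(j, -np.inf, -tau)
        v = rep.fluxes[fid]
        can_move = (
            feasible(j, v + tau, np.inf) or feasible(j, -np.inf, v - tau)
        )
        if not can_pos and not can_neg:
            expected = "blocked"
        elif can_move:
            expected = "variable"
        else:
            expected = "fixed"
        assert classes[fid] == expected, fid


def test_remove_blocked_preserves_polytope(preset_models, preset_optima,
                                           nitrate_passive_fva):
    model = preset_models["nitrate_passive"]
    reduced = remove_blocked(model, nitrate_passive_fva)
    assert reduced.n_cols == model.n_cols - len(nitrate_passive_fva.blocked)
    z = fba_min_photon(reduced).objective_value
    assert z == pytest.approx(preset_optima["nitrate_passive"], abs=1e-9)
    again = remove_blocked(reduced, nitrate_passive_fva)
    assert again.column_ids == reduced.column_ids


def test_dead_end_metabolite_is_blocked(toy_gem):
    """A reaction feeding a metabolite with no consumer can never run."""
    gem = BaseGEM(
        list(toy_gem.metabolites) + [Metabolite("orphan_c", compartment="c")],
        list(toy_gem.reactions)
        + [Reaction("DEAD", {"suc_c": -1.0, "orphan_c": 1.0}, 0, 1000)],
    )
    model = assemble(gem, make_reduction_scenario())
    result = fva(model)
    assert "DEAD__plant__always" in result.blocked
    reduced = remove_blocked(model, result)
    assert "DEAD__plant__always" not in reduced.column_ids


# ---------------------------------------------------------------------------
# numerics
# ---------------------------------------------------------------------------


def test_lp_duality_gap(preset_models):
    for name, model in preset_models.items():
        lp = model_lp(model)
        res = lp.solve()
        assert res.status == "optimal"
        assert lp.duality_gap(res) < 1e-6, name


def test_deterministic_resolves(preset_models):
    model = preset_models["nitrate_active"]
    z1 = fba_min_photon(model).objective_value
    z2 = fba_min_photon(model).objective_value
    assert abs(z1 - z2) < 1e-9


def test_fva_gamma_relaxation_widens_ranges(preset_models, preset_optima):
    model = preset_models["nitrate_passive"]
    z = preset_optima["nitrate_passive"]
    tight = fva(model, z, gamma=1.0)
    # photon uptake above the optimum admits strictly more starch cycling
    fid = "STARCH_SYN__leaf__day"
    assert tight.maximum[fid] <= 1000.0
    with pytest.raises(Exception):
        fva(model, z, gamma=0.0)
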