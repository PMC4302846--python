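"""Shared fixtures: the toy reconstruction, assembled scenario presets and
one sampled chain, all session-scoped since assembly and LP solves are pure
functions of their inputs."""

from __future__ import annotations

import numpy as np
import pytest

from multigem import (
    assemble,
    achr_sample,
    correlate,
    fba_min_photon,
    fva,
    make_coupling_scenario,
    make_preset_scenarios,
    make_reduction_scenario,
    make_toy_plant,
    remove_blocked,
)

SAMPLE_SEED = 20260
N_SAMPLES = 10_000
THINNING = 50


@pytest.fixture(scope="session")
def toy_gem():
    return make_toy_plant()


@pytest.fixture(scope="session")
def preset_scenarios():
    return {sc.name: sc for sc in make_preset_scenarios()}


@pytest.fixture(scope="session")
def preset_models(toy_gem, preset_scenarios):
    return {
        name: assemble(toy_gem, sc) for name, sc in preset_scenarios.items()
    }


@pytest.fixture(scope="session")
def preset_optima(preset_models):
    out = {}
    for name, model in preset_models.items():
        sol = fba_min_photon(model)
        assert sol.status == "optimal", f"{name}: {sol.status}"
        out[name] = sol.objective_value
    return out


@pytest.fixture(scope="session")
def reduction_model(toy_gem):
    return assemble(toy_gem, make_reduction_scenario())


@pytest.fixture(scope="session")
def nitrate_passive_fva(preset_models, preset_optima):
    return fva(preset_models["nitrate_passive"], preset_optima["nitrate_passive"])


@pytest.fixture(scope="session")
def coupling_chain(toy_gem):
    """The analysis chain on the directional (coupling) scenario: assembled
    model, optimum, reduced model, samples and correlation matrix."""
    model = assemble(toy_gem, make_coupling_scenario())
    z = fba_min_photon(model).objective_value
    result = fva(model, z)
    reduced = remove_blocked(model, result)
    samples = achr_sample(
        reduced, N_SAMPLES, seed=SAMPLE_SEED, thinning=THINNING,
        fix_objective_at=z,
    )
    corr = correlate(samples)
    return {
        "model": model,
        "z_opt": z,
        "fva": result,
        "reduced": reduced,
        "samples": samples,
        "corr": corr,
    }
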