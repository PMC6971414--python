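"""Shared fixtures: geometries, simulated maneuvers and cached studies."""

from __future__ import annotations

import numpy as np
import pytest

from fenodyn.airway import (
    ConcentrationSeries,
    DEFAULT_GEOMETRY,
    Maneuver,
    NOSourceParams,
    PDESolveConfig,
    constant_flow_series,
    solve_pde,
)
from fenodyn.inference import MCMCConfig
from fenodyn.simulate import build_scenario_dataset
from fenodyn.study import replicate_abs_diff, run_simulation_study


@pytest.fixture(scope="session")
def geometry():
    return DEFAULT_GEOMETRY


@pytest.fixture(scope="session")
def median_truth():
    """Population-median individual: caw = 58 ppb, ca = 2.05 ppb."""
    return NOSourceParams(58.0, 2.05)


def make_battery(truth, geometry, noise_sd=5.0, seed=0):
    """Nine ramped constant-flow maneuvers (2/3/2/2 at 30/50/100/300 ml/s)."""
    rng = np.random.default_rng(seed)
    maneuvers = []
    for q, dur in [(30, 12), (30, 12), (50, 10), (50, 10), (50, 10),
                   (100, 8), (100, 8), (300, 6), (300, 6)]:
        fl = constant_flow_series(q, dur)
        clean = solve_pde(truth, geometry, fl)
        no = clean.no_ppb + rng.normal(0.0, noise_sd, clean.no_ppb.size)
        maneuvers.append(
            Maneuver(flow=fl, concentration=ConcentrationSeries(fl.times_s, no))
        )
    return maneuvers


@pytest.fixture(scope="session")
def battery(median_truth, geometry):
    return make_battery(median_truth, geometry, seed=202)


@pytest.fixture(scope="session")
def quick_mcmc():
    """Short chains for structural (non-statistical) assertions."""
    return MCMCConfig(n_iter=600, max_extra_iter=600, seed=31)


# --- the desk-scale simulation study shared by the acceptance tests -------

N_STUDY_INDIVIDUALS = 10
STUDY_SEED = 20260920


@pytest.fixture(scope="session")
def study_dataset():
    return build_scenario_dataset(N_STUDY_INDIVIDUALS, seed=STUDY_SEED)


@pytest.fixture(scope="session")
def study_result(study_dataset):
    """10 individuals x 7 scenarios, 3 chains x 5,000 iterations, sigma = 5."""
    return run_simulation_study(
        study_dataset, mcmc_config=MCMCConfig(seed=STUDY_SEED)
    )


N_REPLICATE_INDIVIDUALS = 40


@pytest.fixture(scope="session")
def replicate_table():
    """Replicate-stability run: 40 individuals, two fits per target flow."""
    dataset = build_scenario_dataset(N_REPLICATE_INDIVIDUALS, seed=STUDY_SEED + 1)
    return replicate_abs_diff(dataset, mcmc_config=MCMCConfig(seed=STUDY_SEED + 1))
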