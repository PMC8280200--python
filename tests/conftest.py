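"""Shared fixtures: a desk-scale synthetic plate and the staged fit run on it.

The expensive pipeline stages are session-scoped so the fitting, analysis
and acceptance tests all reuse one deterministic run (fixed seeds
throughout).  Scales are reduced relative to reporting scale -- fewer
stage-1 repeats, hundreds instead of thousands of cells -- which keeps the
whole suite within minutes while leaving every qualitative property intact.
"""

import numpy as np
import pytest

import zfclock as z
from zfclock.trace import Trace


@pytest.fixture(scope="session")
def control_params():
    return z.CONTROL_PARAMS


@pytest.fixture(scope="session")
def stage1_pop():
    cfg = z.FitStageConfig(n_runs=4, popsize=24, maxiter=60, seed=3)
    return z.stage1_fit(cfg)


@pytest.fixture(scope="session")
def desk_plate():
    return z.fig2a_fixture(rng_seed=11, n_wells=8, n_cells=800, measurement_noise_rel=0.02)


@pytest.fixture(scope="session")
def desk_data(desk_plate):
    plate, _, _ = desk_plate
    times = plate["time_h"].to_numpy()
    zs = [z.zscore(Trace(times, plate[c].to_numpy())).values for c in plate.columns[1:]]
    return Trace(times, np.mean(zs, axis=0))


@pytest.fixture(scope="session")
def stage2_pop(stage1_pop, desk_data):
    cfg = z.FitStageConfig(n_cells=250, maxiter=8, popsize=6, seed=3)
    return z.stage2_estimate_noise(stage1_pop, desk_data, cfg)


@pytest.fixture(scope="session")
def stage3_result(stage2_pop, desk_data):
    cfg = z.FitStageConfig(n_cells=300, popsize=12, maxiter=12, seed=3)
    return z.stage3_fit(stage2_pop, desk_data, z.FIG_PROTOCOL, cfg)


@pytest.fixture(scope="session")
def entrained_x0(control_params):
    return z.burn_in_initial_state(control_params, dt=0.02)
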