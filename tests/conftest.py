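"""Shared fixtures.

The expensive simulations and experiments are session-scoped so the
property tests and the acceptance tests reuse a single computation.
"""

from __future__ import annotations

import numpy as np
import pytest

from burncontract import experiments as ex
from burncontract import fem2d
from burncontract import parameters as par
from burncontract import radial_solver as rs

# reference parameter set of the contraction figure: small burn, low
# initial fill, slow myofibroblast apoptosis, mid-range collagen secretion
FIG_PARAMS = dict(c_I=3.57, I_w=0.1, delta_M=2e-2, k_rho=1.75e-8)


@pytest.fixture
def table1() -> par.DimensionalParameters:
    return par.DimensionalParameters()


@pytest.fixture
def fig_params() -> par.DimensionalParameters:
    return par.DimensionalParameters(**FIG_PARAMS)


@pytest.fixture(scope="session")
def fig_radial_run():
    p = par.DimensionalParameters(**FIG_PARAMS)
    return rs.run_simulation(p, t_end=42.0,
                             output_times=[0, 7, 14, 21, 28, 35, 42])


@pytest.fixture(scope="session")
def equilibrium_run():
    """Unwounded tissue: the uniform state must be stationary."""
    p = par.DimensionalParameters(I_w=1.0, c_w=0.0)
    return rs.run_simulation(p, t_end=42.0, output_times=[0, 21, 42])


@pytest.fixture(scope="session")
def longtime_run():
    # default (range-midpoint) parameters: the canonical healing trajectory
    p = par.DimensionalParameters()
    return rs.run_simulation(p, t_end=300.0,
                             output_times=np.arange(0.0, 301.0, 5.0))


@pytest.fixture(scope="session")
def disk2d_run():
    p = par.DimensionalParameters(**FIG_PARAMS)
    return fem2d.run_simulation_2d(p, t_end=42.0, output_times=[0.0, 42.0],
                                   shape="disk")


@pytest.fixture(scope="session")
def disk_radial_run():
    p = par.DimensionalParameters(**FIG_PARAMS)
    return rs.run_simulation(p, t_end=42.0, output_times=[0.0, 42.0])


@pytest.fixture(scope="session")
def base_mesh_185():
    return fem2d.generate_base_mesh(half_width=12.0, target_edge=1.85)


@pytest.fixture(scope="session")
def factorial_run():
    return ex.run_factorial_experiment(engine="radial")


@pytest.fixture(scope="session")
def mc_seed1():
    return ex.run_probabilistic_experiment(
        engine="radial", cfg=ex.MonteCarloConfig(seed=1))


@pytest.fixture(scope="session")
def mc_seed2():
    return ex.run_probabilistic_experiment(
        engine="radial", cfg=ex.MonteCarloConfig(seed=2))
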