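"""Shared fixtures: small CPM runs reused across the physics tests.

The simulations are deliberately small (64 cells, a few thousand sweeps) so
the whole suite runs in minutes on one core; parameter values follow the
monolayer regime the theory targets (A0=40, P0=26 on the square lattice).
"""

import numpy as np
import pytest

from epishape.cpm import CPMConfig, run_simulation, single_cell_mode


FIG2C_PARAMS = dict(A0=40.0, P0=26.0, lambda_P=0.5, temperature=12.5)


def _confluent(seed, **kw):
    base = dict(
        lattice="square",
        size=(64, 40),
        n_cells=64,
        lambda_A=1.0,
        lambda_P=0.5,
        A0=40.0,
        P0=26.0,
        temperature=25.0,
        equilibration_sweeps=1500,
        production_sweeps=2000,
        sampling_interval=10,
        seed=seed,
    )
    base.update(kw)
    return run_simulation(CPMConfig(**base))


@pytest.fixture(scope="session")
def lam_a_runs():
    """lambda_A in {1, 4} at fixed perimeter parameters and T (area-term test)."""
    return {
        lam: _confluent(seed=101, lambda_A=lam, **FIG2C_PARAMS)
        for lam in (1.0, 4.0)
    }


@pytest.fixture(scope="session")
def lam_p_runs():
    """lambda_P sweep at fixed T = 25 (alpha-linearity and collapse tests)."""
    return {
        lp: _confluent(seed=202, lambda_P=lp, temperature=25.0)
        for lp in (0.25, 0.5, 0.75, 1.0)
    }


@pytest.fixture(scope="session")
def temperature_runs():
    """T sweep at fixed lambda_P = 0.5 (alpha linear in 1/T)."""
    return {
        t: _confluent(seed=303, lambda_P=0.5, temperature=t)
        for t in (12.5, 16.67, 25.0, 50.0)
    }


@pytest.fixture(scope="session")
def p0_runs():
    """P0 sweep at lambda_P = 0.5, T = 16.67 (alpha decreasing in P0)."""
    return {
        p0: _confluent(seed=404, P0=p0, temperature=16.67)
        for p0 in (24.0, 26.0, 28.0)
    }


@pytest.fixture(scope="session")
def single_vs_confluent():
    """Matched single-cell and confluent runs at identical parameters."""
    common = dict(lambda_A=1.0, lambda_P=0.5, A0=90.0, P0=38.0, temperature=16.67)
    conf = run_simulation(
        CPMConfig(size=(45, 50), n_cells=25, seed=505, equilibration_sweeps=1200,
                  production_sweeps=1600, sampling_interval=10, **common)
    )
    single = single_cell_mode(
        CPMConfig(size=(32, 32), n_cells=1, seed=506, equilibration_sweeps=1200,
                  production_sweeps=16000, sampling_interval=10, **common)
    )
    return conf, single
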