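"""Shared fixtures.

The pulse-wave solve is the expensive stage and is independent of all BM
parameters, so a single session-scoped haemodynamic solution backs every
coupled test.  It uses the full vessel geometry at a test-scale resolution
(Δt = 2.5e−5 s, 5 cardiac cycles) — coarse enough to run in about a minute,
fine enough that the final cycle is settled to well below the 1% periodicity
criterion.
"""

import numpy as np
import pytest

import ipadflow as ipf


@pytest.fixture(scope="session")
def test_config() -> ipf.RunConfig:
    return ipf.RunConfig(n_cycles=5, dt=2.5e-5, store_every=40, seed=0)


@pytest.fixture(scope="session")
def hemo(test_config):
    """Settled pulse-wave solution of the MCA bifurcation (shared)."""
    return ipf.solve_hemodynamics(test_config)


@pytest.fixture(scope="session")
def short_config() -> ipf.RunConfig:
    """Tiny network (short vessels, 1 cycle) for solver-behaviour tests."""
    return ipf.RunConfig(
        n_cycles=1, dt=2.5e-5, store_every=40,
        segments={
            # short vessels keep the step count down; the daughters' taper
            # is kept at the physiological slope rather than compressed
            # into the shorter length
            "mca": {"L": 1.5},
            "left": {"L": 1.3, "R_d": 0.12},
            "right": {"L": 1.2, "R_d": 0.12},
        },
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
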