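import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import parpflow as pf

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def wt():
    return pf.get_preset("WT")


@pytest.fixture(scope="session")
def dwgr():
    return pf.get_preset("dWGR")


@pytest.fixture
def fast_assoc_instrument():
    """Small association acquisition for quick unit tests."""
    return pf.association_instrument(seed=0, n_points=80)


@pytest.fixture
def fast_dissoc_instrument():
    """Small dissociation acquisition for quick unit tests."""
    return pf.dissociation_instrument(seed=0, n_points=120)


@pytest.fixture
def wt_dissociation_start(wt):
    """Pre-equilibrated 37/25 nM protein-probe mix."""
    return pf.pre_equilibrate(37.0, 25.0, wt.k1, wt.k_m1)


def exchange_phase(params):
    """Ternary-mechanism rate constants for the post-mixing exchange phase:
    binary complexes do not dissociate directly."""
    return params.evolve(k_m1=0.0)


@pytest.fixture(scope="session")
def wt_exchange(wt):
    return exchange_phase(wt)


def max_conservation_drift(traj: np.ndarray, init) -> float:
    """Largest absolute drift of any conserved total along a trajectory (nM)."""
    t0 = init.totals()
    p = traj[:, 0] + traj[:, 3] + traj[:, 4] + traj[:, 5]
    ds = traj[:, 1] + traj[:, 3] + traj[:, 5]
    d = traj[:, 2] + traj[:, 4] + traj[:, 5]
    return max(
        np.abs(p - t0.totalP).max(),
        np.abs(ds - t0.totalDstar).max(),
        np.abs(d - t0.totalD).max(),
    )
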