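"""Shared fixtures: generated model bundles reused across the suite.

All model inputs are generated programmatically (synthetic ellipsoid organ);
session scope keeps the expensive space colonization runs to one per suite.
"""

import numpy as np
import pytest

from hepavasc.config import RunConfig
from hepavasc import pipeline


@pytest.fixture(scope="session")
def bundle10():
    """10-super-lobule model in the 1.6 L ellipsoid (modest cloud for speed)."""
    cfg = RunConfig.from_dict(
        {"seed": 3, "geometry": {"n_super_lobules": 10, "min_cloud": 3000}}
    )
    return pipeline.generate_model(cfg)


@pytest.fixture(scope="session")
def solution10(bundle10):
    return pipeline.solve_bundle(bundle10)


@pytest.fixture(scope="session")
def loading10(bundle10, solution10):
    from hepavasc.perfusion import simulate_loading

    return simulate_loading(
        bundle10.network, solution10, dt=0.01, snapshot_stride=100
    )


@pytest.fixture(scope="session")
def bundle100():
    """100-super-lobule model used for the time-step convergence protocol."""
    cfg = RunConfig.from_dict(
        {"seed": 11, "geometry": {"n_super_lobules": 100, "min_cloud": 8000}}
    )
    return pipeline.generate_model(cfg)


@pytest.fixture(scope="session")
def solution100(bundle100):
    return pipeline.solve_bundle(bundle100)


@pytest.fixture(scope="session")
def small_ellipsoid():
    """A small (0.2 L) ellipsoid for fast growth tests."""
    from hepavasc.geometry import synthetic_ellipsoid

    return synthetic_ellipsoid(target_volume=2.0e5)


def make_path_network(volumes, Q, n_sl_at=None):
    """Chain of unit-radius vessels with prescribed volumes and a uniform
    flow, as a FlowNetwork + hand-built FlowSolution (test helper)."""
    from hepavasc.hemodynamics import FlowNetwork, FlowSolution, VESSEL

    m = len(volumes)
    L = np.asarray(volumes, dtype=float) / np.pi  # r = 1
    net = FlowNetwork(
        prox=np.arange(m),
        dist=np.arange(1, m + 1),
        kind=np.full(m, VESSEL),
        L=L,
        r=np.ones(m),
        R=np.ones(m),
        n_nodes=m + 1,
        inlet_node=0,
        outlet_node=m,
        sl_volume=1.0,
    )
    sol = FlowSolution(
        Q=np.full(m, float(Q)), P=np.zeros(m + 1), network=net, R_SL=0.0
    )
    return net, sol
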