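"""Shared fixtures: small geometries, networks, and the replicated
2D diffusion-rate runs reused by the pattern-trend and acceptance tests.
"""

import numpy as np
import pytest

from svbsim import geometry, network
from svbsim.config import BASE_HB_PARAMS
from svbsim.network import Reaction, ReactionNetwork, Species


@pytest.fixture(scope="session")
def disc10():
    return geometry.build_disc(10)


@pytest.fixture(scope="session")
def cyl_small():
    return geometry.build_cylinder(4, 8)


@pytest.fixture(scope="session")
def hb_params():
    return dict(BASE_HB_PARAMS)


@pytest.fixture(scope="session")
def hb_network(hb_params):
    return network.make_model("HB", hb_params)


@pytest.fixture(scope="session")
def diffusion_only_network():
    """One diffusing species, no reactions: hops conserve molecules."""
    return ReactionNetwork((Species("H", 1.0),), ())


@pytest.fixture(scope="session")
def birth_death_network():
    """0 -> H at k4, H -> 0 at k5: stationary law Poisson(k4/k5)."""
    return ReactionNetwork(
        (Species("H", 0.0),),
        (Reaction("X4", {}, {"H": 1}, 50.0),
         Reaction("X5", {"H": 1}, {}, 1.0)),
    )


@pytest.fixture(scope="session")
def fig5_runs():
    """Replicated 2D runs over the diffusion grid used for the spot
    density/size trends: D_H in {0.016, 0.05} x ratio in {10, 1000},
    3 replicates, spots thresholded at 400 molecules/voxel.

    Session-scoped because these are the slowest runs in the suite; the
    trend, acceptance, and dispersion-consistency tests all read from
    the same table.
    """
    from svbsim.patterns import sweep

    return sweep(BASE_HB_PARAMS, [0.016, 0.05], [10.0, 1000.0],
                 replicates=3, radius=30, seed=7, max_time=25.0,
                 threshold=400.0)
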