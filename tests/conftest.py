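"""Shared fixtures.

The expensive branch-barrier measurements are computed once per session and
shared between the acceptance tests that consume them.
"""

import numpy as np
import pytest


@pytest.fixture(scope="session")
def icosphere3():
    from phagosim.engine import reference_icosphere

    return reference_icosphere(3)


@pytest.fixture(scope="session")
def t2_barrier():
    """Tube-to-disk barrier H1 at v = 0.577 (shared across tests)."""
    from phagosim.branches import tube_disk_barrier

    return tube_disk_barrier(3, seed=1, n_seeds=2)


@pytest.fixture(scope="session")
def t3_barrier():
    """Disk-to-cup barrier H2 at v = 0.577 (deterministic)."""
    from phagosim.branches import disk_cup_barrier

    return disk_cup_barrier(da_grid=(1.00, 0.96, 0.92, 0.88))


@pytest.fixture(scope="session")
def t9_barrier():
    """Tube-to-disk barrier H1 at v = 0.5 (four fused vesicles).

    Both the tube minimum and the barrier top are minima over warm seeds
    and converge slowly: the refined anchor energy scatters ~0.015 across
    seeds, with a deeper tube basin appearing in roughly one seed in
    five. This fixture uses the largest sampling the suite budget allows
    at a pinned seed; the acceptance script spends more.
    """
    from phagosim.branches import tube_disk_barrier

    return tube_disk_barrier(4, seed=1, n_seeds=3, n_anchor_seeds=2)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
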