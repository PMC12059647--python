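import numpy as np
import pytest
from hypothesis import settings

import hritools as h

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20250921)


@pytest.fixture(scope="session")
def table1_predictions():
    """Published comparison grid: (L, gamma0) -> (predicted B, predicted B')."""
    return {
        (1_000, 0.02): (1.000, 0.978),
        (10_000, 0.02): (0.996, 0.976),
        (100_000, 0.02): (0.966, 0.960),
        (1_000_000, 0.02): (0.815, 0.873),
        (1_000, 2.0): (0.483, 0.646),
        (10_000, 2.0): (0.285, 0.438),
        (100_000, 2.0): (0.158, 0.270),
        (1_000_000, 2.0): (0.081, 0.155),
        (1_000, 200.0): (0.741, 0.741),
        (10_000, 200.0): (0.050, 0.070),
        (100_000, 200.0): (0.009, 0.021),
        (1_000_000, 200.0): (0.004, 0.011),
    }


@pytest.fixture(scope="session")
def table2_solutions():
    """Native-grid solutions, reused across tests (solves are cheap but the
    coalescence quadratures are not)."""
    out = {}
    for L in (2500, 10000, 40000):
        for s in (1e-3, 1e-2):
            p = h.table2_preset(L, s)
            out[(L, s)] = (p, h.solve_fixation_B(p))
    return out


@pytest.fixture(scope="session")
def warm_simulator():
    """Compile the simulator kernel once for the whole session."""
    p = h.ModelParams(N0=50, s=0.0, u=1e-5, kappa=1.0, L=64)
    h.run_replicate(p, 50, 10, seed=1)
    return True
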