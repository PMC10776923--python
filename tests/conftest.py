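import numpy as np
import pytest

from stabsel import SimulationConfig, generate_cohort


@pytest.fixture(scope="session")
def solver_fixture_8x3():
    """Fixed small design with one forced covariate, for solver oracles."""
    rng = np.random.default_rng(7)
    X = rng.standard_normal((8, 3))
    y = np.array([0, 1, 0, 1, 1, 0, 1, 0], dtype=float)
    pf = np.array([0.0, 1.0, 1.0])
    return X, y, pf


@pytest.fixture(scope="session")
def solver_fixture_20x10():
    """Larger fixed design with one strong feature (forced covariate first)."""
    rng = np.random.default_rng(11)
    X = rng.standard_normal((20, 10))
    beta = np.zeros(10)
    beta[1] = 1.5
    y = (rng.random(20) < 1.0 / (1.0 + np.exp(-(X @ beta)))).astype(float)
    pf = np.ones(10)
    pf[0] = 0.0
    return X, y, pf


@pytest.fixture(scope="session")
def small_signal_cohort():
    """Session-scoped synthetic cohort with 5 strong causal proteins."""
    config = SimulationConfig(
        n_participants=300, n_proteins=60, n_causal=5,
        effect_sizes=np.full(5, 1.2), n_blocks=12, rho=0.3,
        missing_rate=0.0, seed=5,
    )
    return config, generate_cohort(config)
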