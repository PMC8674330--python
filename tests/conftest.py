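import numpy as np
import pytest

from triomics import ModelParams, SimConfig, simulate_study_dataset


@pytest.fixture()
def make_rng():
    """Factory for order-independent seeded generators."""
    def _make(seed: int = 0) -> np.random.Generator:
        return np.random.default_rng(seed)
    return _make


def draw_params(rng: np.random.Generator, n_cov: int = 2) -> ModelParams:
    """A random but well-conditioned parameter vector."""
    u = lambda lo, hi: float(rng.uniform(lo, hi))
    return ModelParams(
        beta0=u(-1.0, 1.0), beta_x=rng.uniform(-0.5, 0.5, size=n_cov),
        beta_g=u(-1.0, 1.0), beta_m=u(-1.0, 1.0), beta_e=u(-1.0, 1.0),
        alpha0=u(-1.5, 1.5), alpha_g=u(-1.5, 1.5), gamma0=u(-1.5, 1.5),
        gamma_g=u(-1.5, 1.5), gamma_m=u(-1.5, 1.5),
        sigma1_sq=u(0.3, 2.5), sigma2_sq=u(0.3, 2.5), p=u(0.05, 0.95))


@pytest.fixture()
def mixed_dataset():
    """A small dataset exercising all four missingness patterns."""
    cfg = SimConfig(n_case=60, n_control=60, m_both=0.2, m_meth_only=0.1,
                    m_expr_only=0.1, seed=7)
    return simulate_study_dataset(cfg)


@pytest.fixture()
def complete_dataset():
    cfg = SimConfig(n_case=80, n_control=80, seed=11)
    return simulate_study_dataset(cfg)
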