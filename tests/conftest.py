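import numpy as np
import pytest

from paneldml.design_prep import PrepConfig
from paneldml.synthetic_panel import DGPConfig, generate_panel


@pytest.fixture(scope="session")
def small_cfg() -> DGPConfig:
    """A small linear-nuisance panel config used across unit tests."""
    return DGPConfig(
        n_cities=40,
        n_years=8,
        start_year=2007,
        theta_true=0.15,
        adoption_waves=((2009, 0.15), (2011, 0.15)),
        confounder_dim=5,
        nonlinear_nuisance=False,
        fe_sd_city=0.0,
        mediator_paths={"EEQ": (0.3, 0.5)},
        mediator_noise_sd={"EEQ": 0.5},
        seed=11,
    )


@pytest.fixture(scope="session")
def small_panel(small_cfg):
    return generate_panel(small_cfg)


@pytest.fixture(scope="session")
def lean_prep() -> PrepConfig:
    """Design without city dummies, matching the no-city-effect test DGPs."""
    return PrepConfig(fe_city=False)


def ols_fit(y: np.ndarray, Z: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Independent OLS oracle: coefficients and classical standard errors."""
    beta, *_ = np.linalg.lstsq(Z, y, rcond=None)
    resid = y - Z @ beta
    n, k = Z.shape
    sigma2 = resid @ resid / (n - k)
    cov = sigma2 * np.linalg.pinv(Z.T @ Z)
    return beta, np.sqrt(np.diag(cov))
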