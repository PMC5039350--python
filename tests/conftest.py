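import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import bzipreg as bz

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=40,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def study_data() -> bz.BivariateCountDataset:
    """One realized study-like dataset (n = 864)."""
    return bz.make_study_like(seed=11)


def intercept_only_dataset(
    n: int = 864, p0: float = 0.45, lam1: float = 2.5, lam2: float = 0.4,
    lam3: float = 0.1, seed: int = 7,
) -> bz.BivariateCountDataset:
    """IID BZIP pairs wrapped as an intercept-only regression dataset."""
    params = bz.BZIPParamsCore(p0, bz.BPRates(lam1, lam2, lam3))
    y = bz.sample_bzip(n, params, seed=seed)
    return bz.BivariateCountDataset(
        y1=y[:, 0], y2=y[:, 1], X=np.ones((n, 1)), covariate_names=["intercept"]
    )


@pytest.fixture(scope="session")
def intercept_fit():
    """Converged intercept-only BZIP fit at the study's scale, shared across
    diagnostic and recovery tests.  Truth: p0=0.45, lam1=2.5, lam2=0.4,
    lam3=0.1, n=864."""
    data = intercept_only_dataset()
    model = bz.restrict_model(data, "bzip")
    config = bz.ChainConfig(n_chains=2, burn_in=1000, n_iter=8000, thin=8, seed=2)
    samples = bz.run_chains(model, config)
    return data, model, samples
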