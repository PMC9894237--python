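import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from colimit import CarbonateParams, CellParams, Environment

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def chem() -> CarbonateParams:
    return CarbonateParams()


@pytest.fixture(scope="session")
def ambient() -> Environment:
    return Environment(pCO2=0.0004)


@pytest.fixture(scope="session")
def default_cell() -> CellParams:
    return CellParams()


@pytest.fixture(scope="session")
def random_cells(chem):
    """100 log-uniform random parameter sets over the stated ranges (fixed seed)."""
    rng = np.random.default_rng(20240521)

    def lu(lo, hi, n=100):
        return np.exp(rng.uniform(np.log(lo), np.log(hi), n))

    alpha = lu(1e2, 1e5)
    beta = lu(1e-3, 1.0)
    cells = [
        CellParams(
            P_C=a / 3.3e4,
            P_H=b / 3.3e4,
            sa_v=3.3e4,
            gamma=g,
            delta=d,
            chi=x,
            phi=p,
        )
        for a, b, g, d, x, p in zip(
            alpha,
            beta,
            lu(1.0, 1e3),
            lu(1e-2, 1e4),
            lu(1e-2, 1e2),
            lu(1e-2, 10.0),
        )
    ]
    return cells
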