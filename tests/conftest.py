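import numpy as np
import pytest

from pdcycle import Pools, RateParams, fixture


def random_basic_set(rng: np.random.Generator) -> tuple[RateParams, Pools]:
    """One random basic-cycle parameterization, log-uniform over moderate
    physiological ranges (rates 0.1-10, pools 0.1-100 uM)."""
    def lu(lo, hi):
        return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))

    params = RateParams(
        lambda1=lu(0.1, 10), lambda_m1=lu(0.1, 10), k1=lu(0.1, 10),
        lambda2=lu(0.1, 10), lambda_m2=lu(0.1, 10), k2=lu(0.1, 10),
    )
    pools = Pools(Kt=lu(0.01, 100), Pt=lu(0.1, 100), St=lu(0.1, 100))
    return params, pools


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)


@pytest.fixture
def fig3b():
    return fixture("fig3b")


@pytest.fixture
def fig6a():
    return fixture("fig6a")
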