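import warnings

import numpy as np
import pytest

from psmforge import fixtures as fx
from psmforge.km_reconstruct import IPDSet


@pytest.fixture()
def toy_exp_ipd():
    """Times 1..4, all events: exponential MLE rate = 4/10 = 0.4."""
    return IPDSet(time=np.array([1.0, 2.0, 3.0, 4.0]),
                  event=np.array([1, 1, 1, 1]))


@pytest.fixture(scope="session")
def weibull_arm():
    """n=500 Weibull(1.3, 20) arm with administrative censoring at 30."""
    return fx.simulate_arm("weibull", [1.3, 20.0], 500, 1.0, 30.0, rng=5,
                           arm="control", endpoint="OS")


@pytest.fixture(scope="session")
def base_inputs():
    """Small but complete ModelInputs from a seeded synthetic trial."""
    return fx.build_inputs(fx.TrialSpec(seed=3, n_per_arm=300))


@pytest.fixture(autouse=True)
def _quiet_ph_warnings():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        yield


def random_censored_arm(n, rate=1 / 20.0, dropout_rate=1 / 60.0,
                        admin=30.0, seed=7, arm="control", endpoint="OS"):
    """Exponential events + independent exponential dropout + admin cutoff."""
    rng = np.random.default_rng(seed)
    t_ev = rng.exponential(1.0 / rate, n)
    t_cn = rng.exponential(1.0 / dropout_rate, n)
    t = np.minimum(np.minimum(t_ev, t_cn), admin)
    e = ((t_ev <= t_cn) & (t_ev <= admin)).astype(int)
    return IPDSet(time=t, event=e, arm=arm, endpoint=endpoint)
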