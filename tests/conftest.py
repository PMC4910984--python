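import numpy as np
import pytest

from tumordecay.kinetics import closed_form_power_decay
from tumordecay.series import LysisSeries


@pytest.fixture
def rng():
    return np.random.default_rng(20160616)


def make_parabolic_series(d=2.0, nu=0.5, T0=9100.0, dt=1.0, noise=0.0, rng=None):
    """Synthetic power-law decay sampled hourly until extinction."""
    t_star = T0 ** (1.0 - nu) / (d * (1.0 - nu))
    t = np.arange(0.0, t_star + dt, dt)
    T = closed_form_power_decay(d, nu, T0, t)
    if noise > 0:
        T = T * (1.0 + noise * rng.standard_normal(len(T)))
        T = np.maximum.accumulate(T[::-1])[::-1]  # keep it non-increasing
        T = np.maximum(T, 0.0)
    return LysisSeries(t, T)


@pytest.fixture
def parabolic_series():
    return make_parabolic_series()
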