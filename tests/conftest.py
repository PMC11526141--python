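import numpy as np
import pandas as pd
import pytest

from dielpredict import EnvSeries


def make_series(x, dt=600.0, variable="temperature", start="2021-01-01", site="test"):
    unit = "degC" if variable == "temperature" else "% air saturation"
    t = pd.date_range(start, periods=len(x), freq=pd.Timedelta(seconds=dt))
    return EnvSeries(site_id=site, variable=variable, unit=unit, t=t, x=np.asarray(x, float))


def diel_cosine(days, amplitude=5.0, mean=20.0, dt=600.0, phase=0.0, period_h=24.0, **kw):
    n = int(days * 86400 / dt)
    ts = np.arange(n) * dt
    x = mean + amplitude * np.cos(2 * np.pi * (ts - phase) / (period_h * 3600.0))
    return make_series(x, dt=dt, **kw)


def ar1_series(n, phi, sd=1.0, seed=0, dt=600.0, **kw):
    rng = np.random.default_rng(seed)
    x = np.empty(n)
    x[0] = rng.normal(0, sd)
    e = rng.normal(0, sd * np.sqrt(1 - phi**2), n - 1)
    for i in range(1, n):
        x[i] = phi * x[i - 1] + e[i - 1]
    return make_series(x, dt=dt, **kw)


@pytest.fixture
def tone_30d():
    return diel_cosine(30)
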