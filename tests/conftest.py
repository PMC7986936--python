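import numpy as np
import pytest

from hdprog.models import StateModelSpec
from hdprog.synthetic import CohortConfig, generate_cohort
from hdprog.vl import PriorSpec, fit_subject


@pytest.fixture(scope="session")
def small_cohort():
    """A 6+6 default-calibrated cohort, shared across tests."""
    config = CohortConfig(seed=1234, n_hd=6, n_control=6)
    subjects, series = generate_cohort(config)
    return config, subjects, series


@pytest.fixture(scope="session")
def dynamic_spec():
    return StateModelSpec(form="dynamic")


@pytest.fixture(scope="session")
def dynamic_priors(dynamic_spec):
    return PriorSpec.default(dynamic_spec)


@pytest.fixture(scope="session")
def fitted_small_cohort(small_cohort, dynamic_spec, dynamic_priors):
    """Subject-level dynamic-model posteriors for the shared cohort."""
    _, subjects, series = small_cohort
    posteriors = [fit_subject(ts, dynamic_spec, dynamic_priors)
                  for ts in series]
    return subjects, series, posteriors


def rk4_states(deriv, x0, times, step=0.01):
    """Independent fixed-step RK4 oracle, integrating outward from t=0."""
    times = np.asarray(times, float)
    out = np.empty((len(times), len(x0)))
    order = np.argsort(times)
    for direction in (+1, -1):
        sel = times[order] >= 0 if direction > 0 else times[order] < 0
        targets = times[order][sel] if direction > 0 else times[order][sel][::-1]
        x = np.array(x0, float)
        t = 0.0
        rows = []
        for tt in targets:
            span = tt - t
            n = max(1, int(np.ceil(abs(span) / step))) if span else 0
            h = span / n if n else 0.0
            for _ in range(n):
                k1 = deriv(t, x)
                k2 = deriv(t + h / 2, x + h / 2 * k1)
                k3 = deriv(t + h / 2, x + h / 2 * k2)
                k4 = deriv(t + h, x + h * k3)
                x = x + h / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
                t += h
            rows.append(x.copy())
        idx = np.where(sel)[0] if direction > 0 else np.where(sel)[0][::-1]
        for i, row in zip(idx, rows):
            out[order[i]] = row
    return out
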