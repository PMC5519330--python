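"""Shared fixtures: models, relaxed states and one full-length Poisson run.

The expensive 100 s pre-run + 300 s / 10 Hz Poisson simulation of the
gh = 0 model is computed once per session and shared by the acceptance
tests and by the steady-state charge-balance property test.
"""

import numpy as np
import pytest

from axodelay import cable_sim as cs
from axodelay import spike_metrics as sm
from axodelay import stimuli as st

TEST_SEED = 42


@pytest.fixture(scope="session")
def gh0_model():
    return cs.make_model("Ih_block")


@pytest.fixture(scope="session")
def gh0_rest(gh0_model):
    """Relaxed resting state of the gh = 0 model (shorter pre-run: the
    clamped pre-run settles in a few seconds)."""
    return cs.relax_to_rest(gh0_model, duration_s=30.0)


@pytest.fixture(scope="session")
def single_spike(gh0_model, gh0_rest):
    """One pulse from rest: (train, trace) with a single propagated spike."""
    state = gh0_rest.copy()
    train = st.StimulusTrain(np.array([20.0]))
    trace = cs.integrate(gh0_model, state, train, t_end_ms=120.0)
    return train, trace


@pytest.fixture(scope="session")
def gh0_full_run():
    """Full study protocol: 100 s pre-run, 300 s / 10 Hz Poisson.

    Returns (model, train, trace, series); the trace carries the total
    membrane conductance at site 1 for the velocity-equation analyses.
    """
    model = cs.make_model("Ih_block")
    state = cs.relax_to_rest(model, duration_s=100.0)
    train = st.poisson_train(10.0, 300.0, seed=TEST_SEED)
    trace = cs.integrate(model, state, train, t_end_ms=300_500.0,
                         record_gtot=True)
    series = sm.build_spike_series(trace, train)
    series = sm.gate_rate_features(series, model)
    return model, train, trace, series


def pump_epoch_means(trace):
    """Mean dynamic pump current over minute 1 and minute 5 of a run."""
    p = trace.pump
    t = trace.pump_times - trace.t0_ms
    ok = np.isfinite(p)
    p, t = p[ok], t[ok]
    m1 = float(np.mean(p[(t >= 0) & (t < 60_000)]))
    m5 = float(np.mean(p[(t >= 240_000) & (t < 300_000)]))
    return m1, m5
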