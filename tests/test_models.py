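"""State-model trajectories, observation mapping and their exactness."""

import numpy as np
import pytest

from hdprog.models import (
    InvalidModelError,
    StateModelSpec,
    SubjectParams,
    build_A,
    edge_preset,
    integrate_states,
    observe,
    predict_and_jacobian,
    predict_decade_loss,
    sigmoid_input,
)
from hdprog.regions import N_REGIONS, N_STATES, REGION_STATE_INDEX
from conftest import rk4_states

TIMES = np.array([-6.0, -3.5, 0.0, 2.0, 5.0])


def _params(form, rng=None, **kw):
    rng = rng or np.random.default_rng(0)
    base = dict(x0=100 + rng.normal(0, 3, N_STATES))
    if form in ("constant_rate", "quadratic_rate"):
        base["rate_c0"] = rng.normal(0, 0.5, N_STATES)
    if form == "quadratic_rate":
        base["accel_c1"] = rng.normal(0, 0.1, N_STATES)
    if form in ("dynamic", "dynamic_sigmoid"):
        base["log_decay"] = np.log(0.02) + rng.normal(0, 0.3, N_STATES)
    if form == "dynamic_sigmoid":
        base.update(csens=rng.normal(0, 0.5, N_STATES), input_t0=0.5,
                    input_log_tau=0.0)
    base.update(kw)
    return SubjectParams(**base)


# ---------------------------------------------------------------------------
# sigmoid input
# ---------------------------------------------------------------------------

def test_sigmoid_midpoint_saturation_and_value():
    assert sigmoid_input(0.0, 0.0, 1.0) == pytest.approx(0.5)
    assert sigmoid_input(-1e3, 0.0, 1.0) == pytest.approx(0.0, abs=1e-12)
    assert sigmoid_input(1e3, 0.0, 1.0) == pytest.approx(1.0)
    assert sigmoid_input(2.0, 0.0, 1.0) == pytest.approx(1 / (1 + np.exp(-2)))


def test_sigmoid_monotone_and_tau_positive():
    t = np.linspace(-10, 10, 200)
    u = sigmoid_input(t, 1.0, 0.7)
    assert np.all(np.diff(u) > 0)
    with pytest.raises(InvalidModelError):
        sigmoid_input(0.0, 0.0, -1.0)


# ---------------------------------------------------------------------------
# trajectories vs independent RK4 oracles
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("form", ["constant_rate", "quadratic_rate",
                                  "dynamic", "dynamic_sigmoid"])
def test_trajectories_match_rk4_oracle(form):
    spec = StateModelSpec(form=form)
    params = _params(form)
    traj = integrate_states(spec, params, TIMES)

    x0 = params.x0
    if form == "constant_rate":
        deriv = lambda t, x: params.rate_c0
    elif form == "quadratic_rate":
        deriv = lambda t, x: params.rate_c0 + params.accel_c1 * t
    elif form == "dynamic":
        deriv = lambda t, x: params.decay * x
    else:
        tau = np.exp(params.input_log_tau)
        deriv = lambda t, x: params.decay * x + params.csens * sigmoid_input(
            t, params.input_t0, tau)
    oracle = rk4_states(deriv, x0, TIMES, step=0.005)
    np.testing.assert_allclose(traj.states, oracle, rtol=2e-7, atol=1e-6)


@pytest.mark.parametrize("form", ["constant_rate", "quadratic_rate",
                                  "dynamic", "dynamic_sigmoid"])
def test_time_zero_anchors_x0(form):
    spec = StateModelSpec(form=form)
    params = _params(form)
    traj = integrate_states(spec, params, [0.0])
    np.testing.assert_allclose(traj.states[0], params.x0, rtol=1e-12)


def test_quadratic_polynomial_exact():
    spec = StateModelSpec(form="quadratic_rate")
    params = SubjectParams(x0=np.zeros(N_STATES),
                           rate_c0=np.ones(N_STATES),
                           accel_c1=np.full(N_STATES, 2.0))
    t = np.array([-2.0, 1.5, 4.0])
    traj = integrate_states(spec, params, t)
    expected = t + t**2
    for i in range(N_STATES):
        np.testing.assert_allclose(traj.states[:, i], expected, rtol=1e-12)


def test_dynamic_closed_form_value():
    spec = StateModelSpec(form="dynamic")
    params = SubjectParams(x0=np.full(N_STATES, 100.0),
                           log_decay=np.full(N_STATES, np.log(0.05)))
    traj = integrate_states(spec, params, [5.0])
    assert traj.states[0, 0] == pytest.approx(100 * np.exp(-0.25), rel=1e-12)


def test_zero_decay_limit_is_constant():
    spec = StateModelSpec(form="dynamic")
    params = SubjectParams(x0=np.full(N_STATES, 97.0),
                           log_decay=np.full(N_STATES, -30.0))
    traj = integrate_states(spec, params, TIMES)
    np.testing.assert_allclose(traj.states, 97.0, rtol=1e-8)


def test_zero_edge_weights_equal_diagonal_model():
    edges = edge_preset("striatal_cortical")
    espec = StateModelSpec(form="dynamic", connectivity_edges=edges)
    dspec = StateModelSpec(form="dynamic")
    params = _params("dynamic", edge_weights=np.zeros(len(edges)))
    e = integrate_states(espec, params, TIMES)
    d = integrate_states(dspec, params, TIMES)
    np.testing.assert_allclose(e.states, d.states, rtol=1e-9, atol=1e-9)


def test_edged_dynamics_match_rk4_oracle():
    edges = edge_preset("cortical_cortical")
    spec = StateModelSpec(form="dynamic", connectivity_edges=edges)
    rng = np.random.default_rng(7)
    params = _params("dynamic", rng=rng,
                     edge_weights=rng.normal(0, 0.02, len(edges)))
    A = build_A(spec, params.log_decay, params.edge_weights)
    traj = integrate_states(spec, params, TIMES)
    oracle = rk4_states(lambda t, x: A @ x, params.x0, TIMES, step=0.005)
    np.testing.assert_allclose(traj.states, oracle, rtol=1e-6, atol=1e-6)


def test_sigmoid_with_zero_input_reduces_to_dynamic():
    sspec = StateModelSpec(form="dynamic_sigmoid")
    dspec = StateModelSpec(form="dynamic")
    params = _params("dynamic_sigmoid", csens=np.zeros(N_STATES))
    s = integrate_states(sspec, params, TIMES)
    d = integrate_states(dspec, params, TIMES)
    np.testing.assert_allclose(s.states, d.states, rtol=1e-9, atol=1e-9)


# ---------------------------------------------------------------------------
# observation model
# ---------------------------------------------------------------------------

def test_bilateral_pairs_share_their_state():
    spec = StateModelSpec(form="dynamic")
    params = _params("dynamic")
    traj = integrate_states(spec, params, TIMES)
    obs = observe(traj, spec, params)
    assert obs.shape == (len(TIMES), N_REGIONS)
    for col, state in enumerate(REGION_STATE_INDEX):
        np.testing.assert_array_equal(obs[:, col], traj.states[:, state])


def test_behavior_readout_is_hand_computed_dot_product():
    spec = StateModelSpec(form="dynamic", n_behavior=2)
    W = np.zeros((2, N_STATES))
    W[0, [25, 26]] = [-1.5, -2.0]  # caudate, putamen
    W[1, 0] = 0.5
    params = _params("dynamic", behavior_weights=W,
                     behavior_intercepts=np.array([40.0, 60.0]))
    traj = integrate_states(spec, params, TIMES)
    obs = observe(traj, spec, params)
    expected0 = -1.5 * traj.states[:, 25] - 2.0 * traj.states[:, 26] + 40.0
    np.testing.assert_allclose(obs[:, N_REGIONS], expected0, rtol=1e-12)
    np.testing.assert_allclose(obs[:, N_REGIONS + 1],
                               0.5 * traj.states[:, 0] + 60.0, rtol=1e-12)


def test_zero_weights_constant_behavior():
    spec = StateModelSpec(form="dynamic", n_behavior=1)
    params = _params("dynamic",
                     behavior_weights=np.zeros((1, N_STATES)),
                     behavior_intercepts=np.array([40.0]))
    obs = observe(integrate_states(spec, params, TIMES), spec, params)
    np.testing.assert_allclose(obs[:, N_REGIONS], 40.0)


def test_behavior_requested_without_weights_rejected():
    spec = StateModelSpec(form="dynamic", n_behavior=1)
    params = _params("dynamic")
    traj = integrate_states(spec, params, TIMES)
    with pytest.raises(InvalidModelError):
        observe(traj, spec, params)


# ---------------------------------------------------------------------------
# decade loss
# ---------------------------------------------------------------------------

def test_decade_loss_values_and_monotonicity():
    p0 = _params("dynamic", log_decay=np.full(N_STATES, -30.0))
    assert predict_decade_loss(p0, 0) == pytest.approx(0.0, abs=1e-10)
    p1 = _params("dynamic", log_decay=np.full(N_STATES, np.log(0.0207)))
    assert predict_decade_loss(p1, 26) == pytest.approx(18.7, abs=0.1)
    lams = np.linspace(-8, -2, 10)
    losses = [predict_decade_loss(
        _params("dynamic", log_decay=np.full(N_STATES, lam)), 0)
        for lam in lams]
    assert np.all(np.diff(losses) > 0)


def test_decade_loss_requires_dynamic_form():
    with pytest.raises(InvalidModelError):
        predict_decade_loss(_params("constant_rate"), 0)


# ---------------------------------------------------------------------------
# spec validation and jacobian consistency
# ---------------------------------------------------------------------------

def test_invalid_specs_rejected():
    with pytest.raises(InvalidModelError):
        StateModelSpec(form="cubic")
    with pytest.raises(InvalidModelError):
        StateModelSpec(form="dynamic", connectivity_edges=((3, 3),))
    with pytest.raises(InvalidModelError):
        StateModelSpec(form="constant_rate", connectivity_edges=((0, 1),))


@pytest.mark.parametrize("form", ["constant_rate", "quadratic_rate",
                                  "dynamic", "dynamic_sigmoid"])
def test_analytic_jacobian_matches_finite_differences(form):
    spec = StateModelSpec(form=form, n_behavior=1)
    rng = np.random.default_rng(11)
    theta = rng.normal(0, 0.1, spec.n_params)
    sl = spec.slices()
    theta[sl["x0"]] = 100 + rng.normal(0, 3, N_STATES)
    if "lam" in sl:
        theta[sl["lam"]] = np.log(0.02) + rng.normal(0, 0.2, N_STATES)
    pred, jac = predict_and_jacobian(spec, theta, TIMES)
    for k in rng.choice(spec.n_params, size=12, replace=False):
        h = 1e-6 * max(1.0, abs(theta[k]))
        tp = theta.copy()
        tp[k] += h
        fd = (predict_and_jacobian(spec, tp, TIMES)[0] - pred) / h
        np.testing.assert_allclose(jac[:, :, k], fd, atol=2e-4)
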