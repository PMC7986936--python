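"""Generative state models of regional atrophy progression.

A subject's regional volumes are driven by a latent linear dynamical system

    dx/dt = A x(t) + C u(t, theta_u),        y(t) = g(x(t), theta_g) + eps

with 28 latent states read out onto 55 observed region columns (bilateral
pairs share their state).  Four candidate forms of the state equation are
supported:

``constant_rate``
    A = 0, u = c0: a constant rate of volume change, x(t) = x0 + c0 t.
``quadratic_rate``
    A = 0, u = c0 + c1 t: linearly accelerating change,
    x(t) = x0 + c0 t + (c1/2) t^2.
``dynamic``
    A != 0, C = 0: negatively self-connected states giving region-specific
    exponential decay x_i(t) = x0_i exp(a_i t) with a_i = -exp(lambda_i);
    optional directed between-region connections make A non-diagonal and the
    trajectory a matrix-exponential solution.
``dynamic_sigmoid``
    dynamic self-connections plus a sigmoidal input u(t) = logistic((t-t0)/tau)
    scaled per state by a sensitivity vector c; solved numerically (RK4).

Time t is measured in years relative to motor conversion (t = 0), which
anchors the initial condition x0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .regions import (
    BEHAVIOR_CHANNELS,
    CORTICAL_STATE_INDICES,
    N_REGIONS,
    N_STATES,
    REGION_STATE_INDEX,
    STATE_NAMES,
    states_in_lobe,
)

FORMS = ("constant_rate", "quadratic_rate", "dynamic", "dynamic_sigmoid")

#: fixed step (years) for RK4 integration of the sigmoid-input model
RK4_STEP = 0.05
#: coarser step used inside iterative fitting (error is O(h^4), far below
#: measurement noise at these decay scales)
RK4_STEP_FIT = 0.1


class InvalidModelError(ValueError):
    """Raised for inconsistent model specifications or parameters."""


# ---------------------------------------------------------------------------
# specifications and parameters
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StateModelSpec:
    """Structure of one candidate generative model.

    Parameters
    ----------
    form:
        One of :data:`FORMS`.
    connectivity_edges:
        Directed ``(source_state, target_state)`` pairs adding off-diagonal
        entries to A (``dynamic`` form only).  Self-pairs are rejected:
        self-connections are always present in dynamic forms.
    n_behavior:
        Number of behavioral readout channels (0, 1 or 2) appended to the
        55 volume columns.
    """

    form: str
    connectivity_edges: tuple[tuple[int, int], ...] = ()
    n_behavior: int = 0
    n_states: int = N_STATES
    state_to_region: tuple[int, ...] = tuple(REGION_STATE_INDEX)

    def __post_init__(self):
        if self.form not in FORMS:
            raise InvalidModelError(f"unknown model form {self.form!r}")
        if len(self.state_to_region) != N_REGIONS:
            raise InvalidModelError("state_to_region must map all 55 regions")
        if set(self.state_to_region) != set(range(self.n_states)):
            raise InvalidModelError("every state must drive at least one region")
        for s, t in self.connectivity_edges:
            if s == t:
                raise InvalidModelError(
                    "self-pairs are not connectivity edges (self-connections "
                    "are always present in dynamic forms)")
            if not (0 <= s < self.n_states and 0 <= t < self.n_states):
                raise InvalidModelError(f"edge ({s},{t}) out of range")
        if self.connectivity_edges and self.form != "dynamic":
            raise InvalidModelError(
                "connectivity edges are only supported by the dynamic form")
        if not 0 <= self.n_behavior <= len(BEHAVIOR_CHANNELS):
            raise InvalidModelError("n_behavior must be 0, 1 or 2")

    # ---- flat parameter layout -------------------------------------------
    @property
    def param_names(self) -> list[str]:
        """Ordered names of the flat parameter vector for this spec."""
        names = [f"x0:{s}" for s in STATE_NAMES]
        if self.form in ("constant_rate", "quadratic_rate"):
            names += [f"c0:{s}" for s in STATE_NAMES]
        if self.form == "quadratic_rate":
            names += [f"c1:{s}" for s in STATE_NAMES]
        if self.form in ("dynamic", "dynamic_sigmoid"):
            names += [f"lam:{s}" for s in STATE_NAMES]
        if self.form == "dynamic":
            names += [
                f"edge:{STATE_NAMES[s]}->{STATE_NAMES[t]}"
                for s, t in self.connectivity_edges
            ]
        if self.form == "dynamic_sigmoid":
            names += [f"csens:{s}" for s in STATE_NAMES] + ["t0", "log_tau"]
        for ch in BEHAVIOR_CHANNELS[: self.n_behavior]:
            names += [f"w:{ch}:{s}" for s in STATE_NAMES]
        names += [f"intercept:{ch}" for ch in BEHAVIOR_CHANNELS[: self.n_behavior]]
        names += ["log_prec_vol"]
        if self.n_behavior:
            names += ["log_prec_beh"]
        return names

    @property
    def n_params(self) -> int:
        return len(self.param_names)

    def slices(self) -> dict[str, slice]:
        """Slices of the flat vector for each parameter block."""
        names = self.param_names
        blocks: dict[str, slice] = {}
        i = 0
        while i < len(names):
            key = names[i].split(":")[0]
            j = i
            while j < len(names) and names[j].split(":")[0] == key:
                j += 1
            blocks[key] = slice(i, j)
            i = j
        return blocks


@dataclass
class SubjectParams:
    """Subject-level parameters of one :class:`StateModelSpec`.

    Self-connections are parameterized as ``a_i = -exp(log_decay_i)`` so the
    states are negatively self-connected by construction; the sigmoid time
    constant is carried as ``log(tau)`` so tau > 0.
    """

    x0: np.ndarray
    log_decay: np.ndarray | None = None
    rate_c0: np.ndarray | None = None
    accel_c1: np.ndarray | None = None
    input_t0: float | None = None
    input_log_tau: float | None = None
    csens: np.ndarray | None = None
    edge_weights: np.ndarray = field(default_factory=lambda: np.zeros(0))
    behavior_weights: np.ndarray | None = None  # [n_channels, n_states]
    behavior_intercepts: np.ndarray | None = None
    log_noise_precision: float = 0.0
    log_behavior_precision: float = 0.0

    @property
    def decay(self) -> np.ndarray:
        """Self-connection values a_i = -exp(log_decay_i) (always negative)."""
        if self.log_decay is None:
            raise InvalidModelError("model form carries no decay parameters")
        return -np.exp(np.asarray(self.log_decay, float))

    # ---- flat-vector round trip ------------------------------------------
    def to_vector(self, spec: StateModelSpec) -> np.ndarray:
        sl = spec.slices()
        theta = np.zeros(spec.n_params)
        theta[sl["x0"]] = self.x0
        if "c0" in sl:
            theta[sl["c0"]] = 0.0 if self.rate_c0 is None else self.rate_c0
        if "c1" in sl:
            theta[sl["c1"]] = 0.0 if self.accel_c1 is None else self.accel_c1
        if "lam" in sl:
            if self.log_decay is None:
                raise InvalidModelError("log_decay required for dynamic forms")
            theta[sl["lam"]] = self.log_decay
        if "edge" in sl:
            theta[sl["edge"]] = self.edge_weights
        if "csens" in sl:
            theta[sl["csens"]] = 0.0 if self.csens is None else self.csens
            theta[sl["t0"]] = 0.0 if self.input_t0 is None else self.input_t0
            theta[sl["log_tau"]] = (
                0.0 if self.input_log_tau is None else self.input_log_tau)
        if "w" in sl:
            if self.behavior_weights is None or self.behavior_intercepts is None:
                raise InvalidModelError("behavior channels require weights")
            theta[sl["w"]] = np.asarray(self.behavior_weights).ravel()
            theta[sl["intercept"]] = self.behavior_intercepts
        theta[sl["log_prec_vol"]] = self.log_noise_precision
        if "log_prec_beh" in sl:
            theta[sl["log_prec_beh"]] = self.log_behavior_precision
        return theta

    @classmethod
    def from_vector(cls, spec: StateModelSpec, theta: np.ndarray) -> "SubjectParams":
        theta = np.asarray(theta, float)
        if theta.shape != (spec.n_params,):
            raise InvalidModelError(
                f"expected {spec.n_params} parameters, got {theta.shape}")
        sl = spec.slices()
        p = cls(x0=theta[sl["x0"]].copy())
        if "c0" in sl:
            p.rate_c0 = theta[sl["c0"]].copy()
        if "c1" in sl:
            p.accel_c1 = theta[sl["c1"]].copy()
        if "lam" in sl:
            p.log_decay = theta[sl["lam"]].copy()
        if "edge" in sl:
            p.edge_weights = theta[sl["edge"]].copy()
        if "csens" in sl:
            p.csens = theta[sl["csens"]].copy()
            p.input_t0 = float(theta[sl["t0"]][0])
            p.input_log_tau = float(theta[sl["log_tau"]][0])
        if "w" in sl:
            nb = spec.n_behavior
            p.behavior_weights = theta[sl["w"]].reshape(nb, spec.n_states).copy()
            p.behavior_intercepts = theta[sl["intercept"]].copy()
        p.log_noise_precision = float(theta[sl["log_prec_vol"]][0])
        if "log_prec_beh" in sl:
            p.log_behavior_precision = float(theta[sl["log_prec_beh"]][0])
        return p


@dataclass
class StateTrajectory:
    times: np.ndarray
    states: np.ndarray  # [time x n_states]


# ---------------------------------------------------------------------------
# inputs
# ---------------------------------------------------------------------------

def sigmoid_input(t, t0: float, tau: float):
    """Logistic input u(t) = 1 / (1 + exp(-(t - t0)/tau)), tau > 0."""
    if tau <= 0:
        raise InvalidModelError("sigmoid time constant tau must be positive")
    z = (np.asarray(t, float) - t0) / tau
    with np.errstate(over="ignore"):  # saturates cleanly at 0 and 1
        return 1.0 / (1.0 + np.exp(-z))


# ---------------------------------------------------------------------------
# trajectories (closed forms + RK4) and their Jacobians
# ---------------------------------------------------------------------------

def _eig_traj(A: np.ndarray, x0: np.ndarray, times: np.ndarray):
    """Matrix-exponential trajectory x(t) = expm(A t) x0 via eigendecomposition.

    Returns (states [T x n], eig data) or None if A is too ill-conditioned to
    diagonalize, in which case the caller falls back to scipy's expm.
    """
    mu, V = np.linalg.eig(A)
    if np.linalg.cond(V) > 1e10:
        return None
    M = np.linalg.inv(V)
    z = M @ x0.astype(complex)
    E = np.exp(np.outer(times, mu))  # [T x n]
    states = np.real(E * z[None, :] @ V.T)
    return states, (mu, V, M, z, E)


def _expm_traj(A: np.ndarray, x0: np.ndarray, times: np.ndarray) -> np.ndarray:
    from scipy.linalg import expm

    return np.stack([expm(A * t) @ x0 for t in times])


def build_A(spec: StateModelSpec, log_decay: np.ndarray,
            edge_weights: np.ndarray) -> np.ndarray:
    """Connectivity matrix: negative self-connections plus directed edges."""
    A = np.diag(-np.exp(np.asarray(log_decay, float)))
    for w, (s, t) in zip(np.atleast_1d(edge_weights), spec.connectivity_edges):
        A[t, s] += w
    return A


def _rk4_sigmoid(a, c, t0, tau, x0, times, with_sens=False, step=RK4_STEP):
    """RK4 integration of dx/dt = a*x + c*u(t) from t=0 outward.

    ``times`` need not be sorted; integration runs forward and backward from
    the anchor t = 0 with fixed step <= ``step``, landing exactly on each
    requested time.  With ``with_sens`` the forward sensitivities wrt a, c,
    t0 and tau are integrated alongside (they share the linear part).
    """
    n = len(a)
    ncols = 5 if with_sens else 1
    a_col = a[:, None]

    order = np.argsort(times)
    t_sorted = np.asarray(times, float)[order]
    results = np.empty((len(times), n, ncols))

    for direction in (+1, -1):
        sel = t_sorted >= 0 if direction > 0 else t_sorted < 0
        targets = t_sorted[sel] if direction > 0 else t_sorted[sel][::-1]
        # fixed-step plan landing exactly on every requested time
        steps: list[tuple[float, float]] = []  # (t_start, h)
        marks: list[int] = []  # index into steps after which each target is hit
        t = 0.0
        for tt in targets:
            span = tt - t
            nstep = max(1, int(np.ceil(abs(span) / step))) if span != 0 else 0
            h = span / nstep if nstep else 0.0
            for _ in range(nstep):
                steps.append((t, h))
                t += h
            marks.append(len(steps))

        # forcing term at all RK4 nodes, vectorized across steps
        ts = np.array([s[0] for s in steps])
        hs = np.array([s[1] for s in steps])
        nodes = np.stack([ts, ts + hs / 2, ts + hs], axis=1)  # [steps x 3]
        u = 1.0 / (1.0 + np.exp(-(nodes - t0) / tau))
        if with_sens:
            g0 = -u * (1 - u) / tau
            gt = -(nodes - t0) / tau**2 * u * (1 - u)
            # forcing[s, node] is the (n x 5) additive term of dY/dt
            F = np.zeros((len(steps), 3, n, ncols))
            F[:, :, :, 0] = u[:, :, None] * c[None, None, :]
            F[:, :, :, 2] = u[:, :, None]
            F[:, :, :, 3] = g0[:, :, None] * c[None, None, :]
            F[:, :, :, 4] = gt[:, :, None] * c[None, None, :]
        else:
            F = (u[:, :, None] * c[None, None, :])[:, :, :, None]

        if with_sens:
            def deriv(Y, Fn):
                out = a_col * Y + Fn
                out[:, 1] += Y[:, 0]
                return out
        else:
            def deriv(Y, Fn):
                return a_col * Y + Fn

        Y = np.zeros((n, ncols))
        Y[:, 0] = x0
        out_rows = []
        mark_iter = iter(marks)
        next_mark = next(mark_iter, None)
        while next_mark == 0:
            out_rows.append(Y.copy())
            next_mark = next(mark_iter, None)
        for si, h in enumerate(hs):
            Fn = F[si]
            k1 = deriv(Y, Fn[0])
            k2 = deriv(Y + (h / 2) * k1, Fn[1])
            k3 = deriv(Y + (h / 2) * k2, Fn[1])
            k4 = deriv(Y + h * k3, Fn[2])
            Y = Y + (h / 6) * (k1 + 2 * k2 + 2 * k3 + k4)
            while next_mark == si + 1:
                out_rows.append(Y.copy())
                next_mark = next(mark_iter, None)
        idx = np.where(sel)[0] if direction > 0 else np.where(sel)[0][::-1]
        for i, row in zip(idx, out_rows):
            results[order[i]] = row
    return results


def integrate_states(spec: StateModelSpec, params: SubjectParams,
                     times) -> StateTrajectory:
    """Exact (or RK4, for the sigmoid form) latent trajectories at ``times``.

    t = 0 anchors the initial condition: all forms return x0 exactly at t = 0.
    """
    times = np.atleast_1d(np.asarray(times, float))
    x0 = np.asarray(params.x0, float)
    if x0.shape != (spec.n_states,):
        raise InvalidModelError("x0 must have one value per state")
    if not np.all(np.isfinite(x0)):
        raise InvalidModelError("non-finite parameters")

    if spec.form == "constant_rate":
        c0 = np.asarray(params.rate_c0, float)
        states = x0[None, :] + np.outer(times, c0)
    elif spec.form == "quadratic_rate":
        c0 = np.asarray(params.rate_c0, float)
        c1 = np.asarray(params.accel_c1, float)
        states = x0[None, :] + np.outer(times, c0) + np.outer(times**2 / 2, c1)
    elif spec.form == "dynamic":
        a = params.decay
        if len(spec.connectivity_edges) == 0:
            states = x0[None, :] * np.exp(np.outer(times, a))
        else:
            A = build_A(spec, params.log_decay, params.edge_weights)
            res = _eig_traj(A, x0, times)
            states = res[0] if res is not None else _expm_traj(A, x0, times)
    elif spec.form == "dynamic_sigmoid":
        tau = float(np.exp(params.input_log_tau))
        a = params.decay
        c = np.asarray(params.csens, float)
        states = _rk4_sigmoid(a, c, params.input_t0, tau, x0, times)[:, :, 0]
    else:  # pragma: no cover - guarded in __post_init__
        raise InvalidModelError(f"unknown form {spec.form!r}")

    if not np.all(np.isfinite(states)):
        raise InvalidModelError("non-finite trajectory values")
    return StateTrajectory(times=times, states=states)


def observe(traj: StateTrajectory, spec: StateModelSpec,
            params: SubjectParams) -> np.ndarray:
    """Noise-free predicted observations [time x (55 + n_behavior)].

    Both hemisphere columns of a bilateral pair read the shared state value;
    behavioral channels are weighted state sums plus an intercept.  Noise
    belongs to the likelihood, not to this mapping.
    """
    x = traj.states
    cols = [x[:, list(spec.state_to_region)]]
    if spec.n_behavior:
        if params.behavior_weights is None or params.behavior_intercepts is None:
            raise InvalidModelError("behavior channels requested without weights")
        W = np.asarray(params.behavior_weights, float)
        b = np.asarray(params.behavior_intercepts, float)
        cols.append(x @ W.T + b[None, :])
    return np.concatenate(cols, axis=1)


def predict_decade_loss(params: SubjectParams, state: int) -> float:
    """Percent volume lost over a 10-year span, 100 (1 - exp(10 a_state)).

    Only meaningful for the dynamic forms (exponential decay).
    """
    a = params.decay[state]
    return float(100.0 * (1.0 - np.exp(10.0 * a)))


# ---------------------------------------------------------------------------
# predictions with analytic Jacobians (used by variational Laplace)
# ---------------------------------------------------------------------------

def predict_observations(spec: StateModelSpec, theta: np.ndarray, times,
                         rk4_step: float = RK4_STEP) -> np.ndarray:
    """Predicted observations f(theta) only (fast path, no Jacobian)."""
    times = np.atleast_1d(np.asarray(times, float))
    params = SubjectParams.from_vector(spec, theta)
    if spec.form == "dynamic_sigmoid":
        tau = float(np.exp(params.input_log_tau))
        x = _rk4_sigmoid(params.decay, np.asarray(params.csens, float),
                         params.input_t0, tau, params.x0, times,
                         step=rk4_step)[:, :, 0]
        traj = StateTrajectory(times=times, states=x)
    else:
        traj = integrate_states(spec, params, times)
    return observe(traj, spec, params)


def predict_and_jacobian(spec: StateModelSpec, theta: np.ndarray, times,
                         rk4_step: float = RK4_STEP):
    """Predicted observations f(theta) and Jacobian df/dtheta.

    Returns ``(pred [T x n_obs_cols], jac [T x n_obs_cols x n_params])`` where
    the observation columns are the 55 regions followed by any behavioral
    channels.  Noise-precision parameters have zero derivative rows.
    """
    times = np.atleast_1d(np.asarray(times, float))
    T = len(times)
    sl = spec.slices()
    n = spec.n_states
    params = SubjectParams.from_vector(spec, theta)

    # latent states and their jacobian wrt structural state parameters
    dx = np.zeros((T, n, spec.n_params))
    x0 = params.x0

    if spec.form == "constant_rate":
        x = x0[None, :] + np.outer(times, params.rate_c0)
        eye = np.eye(n)
        dx[:, :, sl["x0"]] = eye[None, :, :]
        dx[:, :, sl["c0"]] = times[:, None, None] * eye[None, :, :]
    elif spec.form == "quadratic_rate":
        x = (x0[None, :] + np.outer(times, params.rate_c0)
             + np.outer(times**2 / 2, params.accel_c1))
        eye = np.eye(n)
        dx[:, :, sl["x0"]] = eye[None, :, :]
        dx[:, :, sl["c0"]] = times[:, None, None] * eye[None, :, :]
        dx[:, :, sl["c1"]] = (times**2 / 2)[:, None, None] * eye[None, :, :]
    elif spec.form == "dynamic" and not spec.connectivity_edges:
        a = params.decay
        G = np.exp(np.outer(times, a))            # [T x n]
        x = x0[None, :] * G
        for i in range(n):
            dx[:, i, sl["x0"].start + i] = G[:, i]
            # d x_i / d lam_i = a_i * t * x_i(t)
            dx[:, i, sl["lam"].start + i] = a[i] * times * x[:, i]
    elif spec.form == "dynamic":
        x, dx = _dynamic_edged_jac(spec, params, times, dx, sl)
    elif spec.form == "dynamic_sigmoid":
        tau = float(np.exp(params.input_log_tau))
        a = params.decay
        res = _rk4_sigmoid(a, np.asarray(params.csens, float), params.input_t0,
                           tau, x0, times, with_sens=True, step=rk4_step)
        x = res[:, :, 0]
        S_a, S_c, S_t0, S_tau = res[:, :, 1], res[:, :, 2], res[:, :, 3], res[:, :, 4]
        Gx0 = np.exp(np.outer(times, a))
        for i in range(n):
            dx[:, i, sl["x0"].start + i] = Gx0[:, i]
            dx[:, i, sl["lam"].start + i] = S_a[:, i] * a[i]
            dx[:, i, sl["csens"].start + i] = S_c[:, i]
        dx[:, :, sl["t0"].start] = S_t0
        dx[:, :, sl["log_tau"].start] = S_tau * tau
    else:  # pragma: no cover
        raise InvalidModelError(spec.form)

    # observation mapping
    idx = list(spec.state_to_region)
    n_obs = N_REGIONS + spec.n_behavior
    pred = np.empty((T, n_obs))
    jac = np.zeros((T, n_obs, spec.n_params))
    pred[:, :N_REGIONS] = x[:, idx]
    jac[:, :N_REGIONS, :] = dx[:, idx, :]

    if spec.n_behavior:
        W = params.behavior_weights
        b = params.behavior_intercepts
        pred[:, N_REGIONS:] = x @ W.T + b[None, :]
        for ch in range(spec.n_behavior):
            jac[:, N_REGIONS + ch, :] = np.einsum("s,tsp->tp", W[ch], dx)
            w_sl = slice(sl["w"].start + ch * n, sl["w"].start + (ch + 1) * n)
            jac[:, N_REGIONS + ch, w_sl] = x
            jac[:, N_REGIONS + ch, sl["intercept"].start + ch] = 1.0
    return pred, jac


def _dynamic_edged_jac(spec, params, times, dx, sl):
    """States and Jacobian for the dynamic form with connectivity edges.

    Uses the eigendecomposition A = V diag(mu) V^-1 and the first-order
    perturbation of the matrix exponential: for a direction D,
    d/de expm((A + e D) t) x0 = V [Phi(t) o (V^-1 D V)] V^-1 x0 with
    Phi_ij = (exp(mu_i t) - exp(mu_j t)) / (mu_i - mu_j).
    """
    x0 = params.x0
    A = build_A(spec, params.log_decay, params.edge_weights)
    res = _eig_traj(A, x0, times)
    if res is None:  # rare ill-conditioned case: finite differences
        return _edged_jac_fd(spec, params, times, dx, sl)
    x, (mu, V, M, z, E) = res

    # directions: diagonal entries (for lam) then edges
    a = params.decay
    ks = [i for i in range(spec.n_states)] + [t for _, t in spec.connectivity_edges]
    ls = [i for i in range(spec.n_states)] + [s for s, _ in spec.connectivity_edges]
    scales = np.concatenate([a, np.ones(len(spec.connectivity_edges))])
    cols = ([sl["lam"].start + i for i in range(spec.n_states)]
            + [sl["edge"].start + e for e in range(len(spec.connectivity_edges))])

    diff = mu[:, None] - mu[None, :]
    tiny = np.abs(diff) < 1e-12
    safe = np.where(tiny, 1.0, diff)
    Vl_z = V[ls, :].T * z[:, None]          # [n x ndir]
    Mk = M[:, ks]                            # [n x ndir]
    for t_i, t in enumerate(times):
        Et = E[t_i]
        Phi = np.where(tiny, t * Et[:, None], (Et[:, None] - Et[None, :]) / safe)
        G = Phi @ Vl_z                       # [n x ndir]
        terms = np.real(V @ (Mk * G)) * scales[None, :]
        for j, col in enumerate(cols):
            dx[t_i, :, col] = terms[:, j]
        dx[t_i, :, sl["x0"]] = np.real(V @ (Et[:, None] * M))
    return x, dx


def _edged_jac_fd(spec, params, times, dx, sl, step=1e-6):
    """Finite-difference fallback Jacobian for non-diagonalizable A."""
    theta = params.to_vector(spec)

    def states_of(th):
        p = SubjectParams.from_vector(spec, th)
        A = build_A(spec, p.log_decay, p.edge_weights)
        return _expm_traj(A, p.x0, times)

    x = states_of(theta)
    cols = list(range(sl["x0"].start, sl["x0"].stop)) + \
        list(range(sl["lam"].start, sl["lam"].stop)) + \
        list(range(sl["edge"].start, sl["edge"].stop))
    for c in cols:
        th = theta.copy()
        h = step * max(1.0, abs(th[c]))
        th[c] += h
        dx[:, :, c] = (states_of(th) - x) / h
    return x, dx


# ---------------------------------------------------------------------------
# connectivity-edge presets
# ---------------------------------------------------------------------------

def edge_preset(name: str) -> tuple[tuple[int, int], ...]:
    """Shipped between-region connection sets.

    ``striatal_cortical``: caudate and putamen states project to every
    cortical state (atrophy spreading out of the striatum).
    ``cortical_cortical``: bidirectional connections between consecutive
    cortical states within each lobe (local cortical spread).
    """
    from .regions import STRIATAL_STATE_INDICES

    if name == "striatal_cortical":
        return tuple(
            (s, t) for s in STRIATAL_STATE_INDICES for t in CORTICAL_STATE_INDICES
        )
    if name == "cortical_cortical":
        edges: list[tuple[int, int]] = []
        for lobe in ("frontal", "parietal", "occipital", "temporal", "limbic"):
            members = [i for i in states_in_lobe(lobe) if i in CORTICAL_STATE_INDICES]
            for u, v in zip(members[:-1], members[1:]):
                edges += [(u, v), (v, u)]
        return tuple(edges)
    raise InvalidModelError(f"unknown edge preset {name!r}")
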