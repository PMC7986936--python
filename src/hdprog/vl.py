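"""Subject-level model inversion by variational Laplace.

Given a generative :class:`~hdprog.models.StateModelSpec`, a Gaussian prior
over its flat parameter vector and one subject's observed time series, this
module maximizes the variational free energy

    F = log p(y | theta) + log p(theta) + (1/2) log |2 pi Sigma|

over a Gaussian posterior q(theta) = N(m, Sigma), using Gauss-Newton ascent
with Levenberg-Marquardt damping.  Sigma is the inverse curvature at m, so F
is the Laplace bound on log model evidence; in the linear-Gaussian
(fixed-noise) case it is the exact log evidence and q the exact posterior.

The observation likelihood is Gaussian with one shared precision
exp(log_prec_vol) across the 55 volume columns and, when behavioral channels
are present, a second shared precision exp(log_prec_beh) for the score
columns (scores and volumes live on different scales).  Noise precisions are
parameters with their own priors; a prior variance of exactly 0 fixes a
parameter at its prior mean (used both for frozen noise and for switching
parameters off).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.linalg import cho_factor, cho_solve

from .cohort import RegionalTimeSeries
from .models import (
    RK4_STEP_FIT,
    StateModelSpec,
    predict_and_jacobian,
)
from .regions import N_REGIONS

LOG2PI = float(np.log(2.0 * np.pi))


class InversionError(ValueError):
    pass


# ---------------------------------------------------------------------------
# priors
# ---------------------------------------------------------------------------

#: weakly informative default prior (mean, variance) per parameter block,
#: on the % volume scale with decade-plausible decay magnitudes
DEFAULT_BLOCK_PRIORS: dict[str, tuple[float, float]] = {
    "x0": (100.0, 100.0),
    # decay magnitudes from ~0.1% to ~60% per decade within 2 prior sd: wide
    # enough to cover both manifest striatal atrophy and healthy aging
    "lam": (float(np.log(0.005)), 2.25),
    "c0": (0.0, 1.0),
    "c1": (0.0, 0.25),
    "t0": (0.0, 4.0),
    "log_tau": (0.0, 0.25),
    "edge": (0.0, 0.01),
    "csens": (0.0, 1.0),
    "w": (0.0, 1.0),
    "intercept": (50.0, 900.0),
    "log_prec_vol": (0.0, 1.0),
    "log_prec_beh": (0.0, 1.0),
}


@dataclass
class PriorSpec:
    """Diagonal Gaussian prior over a spec's flat parameter vector.

    ``noise_prior`` mirrors the entries at the noise-precision indices and is
    kept as an explicit attribute because it is the one prior most analyses
    touch (fix it to freeze the noise level).
    """

    mean: np.ndarray
    variance: np.ndarray
    noise_prior: tuple[float, float] = (0.0, 1.0)

    def __post_init__(self):
        self.mean = np.asarray(self.mean, float)
        self.variance = np.asarray(self.variance, float)
        if self.mean.shape != self.variance.shape:
            raise InversionError("prior mean and variance shapes differ")
        if np.any(self.variance < 0):
            raise InversionError("prior variances must be >= 0")

    @classmethod
    def default(cls, spec: StateModelSpec,
                overrides: dict[str, tuple[float, float]] | None = None,
                noise_prior: tuple[float, float] = (0.0, 1.0)) -> "PriorSpec":
        blocks = dict(DEFAULT_BLOCK_PRIORS)
        blocks["log_prec_vol"] = noise_prior
        if overrides:
            blocks.update(overrides)
        mean = np.empty(spec.n_params)
        var = np.empty(spec.n_params)
        for key, sl in spec.slices().items():
            m, v = blocks[key]
            mean[sl], var[sl] = m, v
        return cls(mean=mean, variance=var, noise_prior=noise_prior)

    def with_fixed_noise(self, log_precision: float) -> "PriorSpec":
        """Freeze all noise precisions at a known value (variance 0)."""
        mean = self.mean.copy()
        var = self.variance.copy()
        # noise precision params are the trailing log_prec entries
        return replace(self, mean=mean, variance=var,
                       noise_prior=(log_precision, 0.0))


@dataclass
class SubjectPosterior:
    """Gaussian posterior and free energy from one subject-level inversion."""

    mean: np.ndarray
    covariance: np.ndarray
    free_energy: float
    n_iterations: int
    converged: bool
    free_mask: np.ndarray | None = None  # True where the prior was not fixed

    def sd(self) -> np.ndarray:
        return np.sqrt(np.clip(np.diag(self.covariance), 0.0, None))


@dataclass
class VLSettings:
    tol: float = 1e-3
    streak: int = 4
    max_iter: int = 128
    init_damping: float = 1e-6
    rk4_step: float = RK4_STEP_FIT
    data_init: bool = True


# ---------------------------------------------------------------------------
# internals
# ---------------------------------------------------------------------------

def _channel_layout(spec: StateModelSpec):
    """(observation column indices, log-precision parameter index) pairs."""
    sl = spec.slices()
    layout = [(np.arange(N_REGIONS), sl["log_prec_vol"].start)]
    if spec.n_behavior:
        layout.append((np.arange(N_REGIONS, N_REGIONS + spec.n_behavior),
                       sl["log_prec_beh"].start))
    return layout


def _apply_fixed(theta: np.ndarray, priors: PriorSpec) -> np.ndarray:
    fixed = priors.variance == 0
    out = theta.copy()
    out[fixed] = priors.mean[fixed]
    return out


def _noise_indices(spec: StateModelSpec) -> list[int]:
    sl = spec.slices()
    idx = [sl["log_prec_vol"].start]
    if "log_prec_beh" in sl:
        idx.append(sl["log_prec_beh"].start)
    return idx


def _resolve_noise_prior(spec: StateModelSpec, priors: PriorSpec) -> PriorSpec:
    """Reflect PriorSpec.noise_prior into the flat mean/variance entries."""
    mean = priors.mean.copy()
    var = priors.variance.copy()
    m, v = priors.noise_prior
    for i in _noise_indices(spec):
        mean[i], var[i] = m, v
    return replace(priors, mean=mean, variance=var)


def _data_init(spec: StateModelSpec, data: RegionalTimeSeries,
               priors: PriorSpec) -> np.ndarray:
    """Cheap least-squares initialization of the structural parameters."""
    theta = priors.mean.copy()
    sl = spec.slices()
    t = data.times
    X = np.column_stack([np.ones_like(t), t])
    # per-state hemispheric mean volumes
    n = spec.n_states
    sums = np.zeros((len(t), n))
    counts = np.zeros(n)
    for col, s in enumerate(spec.state_to_region):
        sums[:, s] += data.volumes[:, col]
        counts[s] += 1
    xbar = sums / counts[None, :]
    coef, *_ = np.linalg.lstsq(X, xbar, rcond=None)
    intercept, slope = coef[0], coef[1]
    intercept = np.clip(intercept, 1.0, None)
    theta[sl["x0"]] = intercept
    if "c0" in sl:
        theta[sl["c0"]] = slope
    if "lam" in sl:
        a_est = slope / intercept
        theta[sl["lam"]] = np.log(np.clip(-a_est, 1e-4, 0.5))
    if "w" in sl and data.behavior is not None:
        means = np.nanmean(data.behavior[:, : spec.n_behavior], axis=0)
        means = np.where(np.isfinite(means), means, 50.0)
        theta[sl["intercept"]] = means
    return theta


class _Objective:
    """Log joint, gradient, curvature and free energy at a parameter point."""

    def __init__(self, spec, data, priors, settings):
        self.spec = spec
        self.priors = priors
        self.settings = settings
        y = data.volumes
        if spec.n_behavior:
            if data.behavior is None:
                beh = np.full((len(data.times), spec.n_behavior), np.nan)
            else:
                beh = data.behavior[:, : spec.n_behavior]
            y = np.concatenate([y, beh], axis=1)
        if not np.all(np.isfinite(data.volumes)):
            raise InversionError("non-finite volume data")
        self.y = y
        self.times = data.times
        self.free = priors.variance > 0
        self.n_free = int(self.free.sum())
        self.P0 = 1.0 / priors.variance[self.free]
        self.mu0 = priors.mean[self.free]
        self.channels = _channel_layout(spec)
        # free-vector position of each channel's noise parameter (or None)
        pos = {j: k for k, j in enumerate(np.where(self.free)[0])}
        self.chan_free_pos = [pos.get(ip) for _, ip in self.channels]
        self.log_prior_norm = -0.5 * np.sum(np.log(2 * np.pi
                                                   * priors.variance[self.free]))

    def evaluate(self, theta: np.ndarray):
        """Return (F, L, grad, H, ok) at theta (full-length vector)."""
        spec, priors = self.spec, self.priors
        pred, jac = predict_and_jacobian(spec, theta, self.times,
                                         rk4_step=self.settings.rk4_step)
        if not np.all(np.isfinite(pred)):
            return None
        free_idx = np.where(self.free)[0]
        dtheta = theta[self.free] - self.mu0
        L = -0.5 * np.sum(dtheta**2 * self.P0) + self.log_prior_norm
        g = -self.P0 * dtheta
        H = np.diag(self.P0.copy())

        for (cols, ip), kpos in zip(self.channels, self.chan_free_pos):
            yc = self.y[:, cols]
            mask = np.isfinite(yc)
            if not mask.any():
                continue
            r = (yc - pred[:, cols])[mask]
            Jc = jac[:, cols, :][mask][:, free_idx]
            lam = theta[ip]
            w = np.exp(lam)
            N = r.size
            sse = float(r @ r)
            L += 0.5 * N * lam - 0.5 * w * sse - 0.5 * N * LOG2PI
            Jr = Jc.T @ r
            g += w * Jr
            H += w * (Jc.T @ Jc)
            if kpos is not None:
                # mean-field partition between structural parameters and
                # noise log precisions: the cross curvature -w J^T r is
                # dropped, keeping H positive definite everywhere (it
                # vanishes at the mode, where w J^T r equals the small
                # prior gradient)
                g[kpos] += 0.5 * N - 0.5 * w * sse
                H[kpos, kpos] += 0.5 * w * sse
        # F needs log|H|; H must be positive definite
        try:
            cf = cho_factor(H, lower=True)
        except np.linalg.LinAlgError:
            return (None, L, g, H, False)
        logdetH = 2.0 * np.sum(np.log(np.diag(cf[0])))
        F = L + 0.5 * (self.n_free * LOG2PI - logdetH)
        return (F, L, g, H, True)


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------

def fit_subject(data: RegionalTimeSeries, spec: StateModelSpec,
                priors: PriorSpec | None = None,
                settings: VLSettings | None = None) -> SubjectPosterior:
    """Invert one subject's time series under a state-model specification.

    Returns a Gaussian posterior over the spec's flat parameter vector with
    the free energy approximation to log model evidence.  Non-convergence
    within ``settings.max_iter`` is reported via ``converged=False``, never
    silently.
    """
    if priors is None:
        priors = PriorSpec.default(spec)
    priors = _resolve_noise_prior(spec, priors)
    settings = settings or VLSettings()
    if len(data.times) < 3:
        raise InversionError("at least 3 visits are required")

    obj = _Objective(spec, data, priors, settings)
    theta = (_data_init(spec, data, priors) if settings.data_init
             else priors.mean.copy())
    theta = _apply_fixed(theta, priors)

    res = obj.evaluate(theta)
    if res is None:
        # fall back to the prior mean if the data-driven start is sick
        theta = _apply_fixed(priors.mean.copy(), priors)
        res = obj.evaluate(theta)
        if res is None:
            raise InversionError("objective not defined at the prior mean")
    # F is undefined while the curvature is indefinite (far from any mode);
    # damped ascent steps are still well defined and quickly restore it
    F, _, g, H, _ = res

    damping = settings.init_damping
    streak = 0
    n_iter = 0
    converged = False
    free_idx = np.where(obj.free)[0]

    for n_iter in range(1, settings.max_iter + 1):
        # damped Gauss-Newton proposal
        ok_step = False
        for _ in range(24):
            Hd = H + damping * np.diag(np.clip(np.diag(H), 1e-12, None))
            try:
                cf = cho_factor(Hd, lower=True)
            except np.linalg.LinAlgError:
                damping = max(damping, 1e-6) * 8
                continue
            delta = cho_solve(cf, g)
            cand = theta.copy()
            cand[free_idx] += delta
            res = obj.evaluate(cand)
            if res is not None and res[4] and (F is None or res[0] > F):
                ok_step = True
                break
            damping = max(damping, 1e-6) * 8
            if damping > 1e10:
                break
        if not ok_step:
            # no direction improves F any more: we are at a local maximum
            converged = F is not None
            break
        dF = np.inf if F is None else res[0] - F
        theta, (F, _, g, H, _) = cand, res
        damping = max(damping / 3.0, 1e-9)
        streak = streak + 1 if dF < settings.tol else 0
        if streak >= settings.streak:
            converged = True
            break

    if F is None:
        raise InversionError("no positive-definite curvature found; the "
                             "model cannot be inverted on these data")
    Sigma_free = np.linalg.inv(H)
    Sigma_free = 0.5 * (Sigma_free + Sigma_free.T)
    n = spec.n_params
    cov = np.zeros((n, n))
    cov[np.ix_(free_idx, free_idx)] = Sigma_free
    return SubjectPosterior(mean=theta, covariance=cov, free_energy=float(F),
                            n_iterations=n_iter, converged=converged,
                            free_mask=obj.free.copy())


def free_energy(posterior_candidate, data: RegionalTimeSeries,
                spec: StateModelSpec, priors: PriorSpec,
                settings: VLSettings | None = None) -> float:
    """Free energy of a candidate Gaussian posterior.

    ``posterior_candidate`` is a :class:`SubjectPosterior` or a
    ``(mean, covariance)`` pair.  ``F = log p(y | m) + log p(m) +
    (1/2) log |2 pi Sigma|`` over the free parameters; equals the exact log
    marginal likelihood in the linear-Gaussian case when (m, Sigma) is the
    exact posterior.
    """
    if hasattr(posterior_candidate, "mean"):
        posterior_mean = posterior_candidate.mean
        posterior_cov = posterior_candidate.covariance
    else:
        posterior_mean, posterior_cov = posterior_candidate
    priors = _resolve_noise_prior(spec, priors)
    obj = _Objective(spec, data, priors, settings or VLSettings())
    theta = _apply_fixed(np.asarray(posterior_mean, float), priors)
    res = obj.evaluate(theta)
    if res is None:
        raise InversionError("non-finite prediction at the candidate mean")
    _, L, _, _, _ = res
    free_idx = np.where(obj.free)[0]
    S = np.asarray(posterior_cov, float)[np.ix_(free_idx, free_idx)]
    sign, logdet = np.linalg.slogdet(S)
    if sign <= 0:
        raise InversionError("candidate covariance is singular or indefinite")
    return float(L + 0.5 * (obj.n_free * LOG2PI + logdet))
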