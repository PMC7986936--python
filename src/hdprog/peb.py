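"""Second-level (group) model: parametric empirical Bayes over subject posteriors.

Subject-level posteriors are embedded in a group-level linear model

    theta_i = B x_i + eps_i,      eps_i ~ N(0, Sigma_b)

where x_i is the subject's row of the design matrix (overall mean, diagnostic
group, CAG-repeat length, gender, age orthogonalized with respect to CAG,
total intracranial volume, site), B is the [parameters x covariates] effect
matrix and Sigma_b the between-subject covariance (diagonal, with one
empirically estimated log-precision multiplier per parameter block).

Each subject's data enter through the Gaussian likelihood summary extracted
from their first-level posterior: the data-information precision
Lambda_i = Sigma_i^-1 - Sigma0^-1 and canonical mean h_i = Sigma_i^-1 m_i -
Sigma0^-1 mu0.  Replacing the first-level prior by the group-conditional
prior N(B x_i, Sigma_b) and integrating over B (Gaussian prior) and the
between-subject log precision (Laplace) yields the hierarchical free energy
used for model comparison.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar

from .cohort import Subject
from .vl import PriorSpec, SubjectPosterior

logger = logging.getLogger(__name__)


class PEBError(ValueError):
    pass


# ---------------------------------------------------------------------------
# design matrix
# ---------------------------------------------------------------------------

def orthogonalize(v: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Residual of v after removing its projection onto w (both centered).

    Equals the residual of the least-squares regression of centered v on
    centered w.
    """
    v = np.asarray(v, float)
    w = np.asarray(w, float)
    if v.shape != w.shape:
        raise PEBError("vectors must have equal length")
    vc = v - v.mean()
    wc = w - w.mean()
    denom = wc @ wc
    if denom <= 0:
        raise PEBError("cannot orthogonalize against a constant vector")
    return vc - (vc @ wc) / denom * wc


@dataclass
class DesignMatrix:
    values: np.ndarray  # [subjects x columns]
    column_labels: list[str]

    def __post_init__(self):
        self.values = np.asarray(self.values, float)
        if self.values.shape[1] != len(self.column_labels):
            raise PEBError("labels do not match design columns")
        if not np.allclose(self.values[:, 0], 1.0):
            raise PEBError("first design column must be the constant 1")
        if np.linalg.matrix_rank(self.values) < self.values.shape[1]:
            raise PEBError("design matrix is rank deficient")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    def column(self, label: str) -> np.ndarray:
        return self.values[:, self.column_labels.index(label)]


def prune_design_columns(values: np.ndarray, labels: list[str],
                         n_mandatory: int = 3):
    """Drop trailing nuisance columns that are constant or collinear.

    The first ``n_mandatory`` columns (mean, group, CAG) are always kept.
    Returns (values, labels, kept column indices of the input).
    """
    keep = list(range(n_mandatory))
    for j in range(n_mandatory, values.shape[1]):
        cand = values[:, keep + [j]]
        if values[:, j].std() == 0 or \
                np.linalg.matrix_rank(cand) < cand.shape[1]:
            continue
        keep.append(j)
    return values[:, keep], [labels[j] for j in keep], keep


def _zscore(v: np.ndarray) -> np.ndarray:
    sd = v.std()
    if sd == 0:
        raise PEBError("cannot scale a constant covariate")
    return (v - v.mean()) / sd


def build_design_matrix(subjects: list[Subject], center: bool = True,
                        include_site: bool = True) -> DesignMatrix:
    """Fixed-order design: mean, group, CAG, gender, age_orth, TIV, site dummies.

    Continuous covariates are mean-centered and unit-scaled; group is coded
    +1 (HD) / -1 (control); gender +1 (F) / -1 (M), centered; site is one-hot
    with the reference (most frequent) level dropped and columns centered.
    Controls carry no CAG and enter the CAG column at the centered value 0.
    Age is orthogonalized with respect to CAG (their correlation is strong by
    design of the cohort).
    """
    if len(subjects) < 2:
        raise PEBError("need at least 2 subjects")
    groups = np.array([+1.0 if s.group == "HD" else -1.0 for s in subjects])
    if len(set(groups)) < 2:
        raise PEBError("both groups must be represented")

    cag = np.array([np.nan if s.cag is None else float(s.cag) for s in subjects])
    hd = np.isfinite(cag)
    if not hd.any():
        raise PEBError("no subject carries a CAG value")
    cag_z = np.zeros(len(subjects))
    sd = cag[hd].std()
    if sd > 0:
        cag_z[hd] = (cag[hd] - cag[hd].mean()) / sd

    gender = np.array([+1.0 if s.gender == "F" else -1.0 for s in subjects])
    gender = gender - gender.mean() if center else gender

    age = np.array([s.age_at_alignment for s in subjects])
    age_orth = orthogonalize(_zscore(age), cag_z)
    if age_orth.std() > 0:
        age_orth = age_orth / age_orth.std()

    tiv = np.array([s.tiv for s in subjects])
    tiv = _zscore(tiv) if tiv.std() > 0 else np.zeros_like(tiv)

    optional = [("gender", gender), ("age_orth", age_orth), ("TIV", tiv)]
    if include_site:
        sites = [s.site for s in subjects]
        levels = sorted(set(sites))
        if len(levels) < 2:
            logger.info("single site: site column dropped from the design")
        else:
            ref = max(levels, key=sites.count)
            for lv in levels:
                if lv == ref:
                    continue
                d = np.array([1.0 if s == lv else 0.0 for s in sites])
                optional.append((f"site_{lv}", d - d.mean() if center else d))

    # the mean, group and CAG columns are mandatory; nuisance columns that
    # are constant or collinear in a small sample are dropped with a notice
    cols = [np.ones(len(subjects)), groups, cag_z]
    labels = ["mean", "group", "CAG"]
    for name, col in optional:
        cand = np.column_stack(cols + [col])
        if col.std() == 0 or np.linalg.matrix_rank(cand) < cand.shape[1]:
            logger.info("covariate %s dropped from the design (constant or "
                        "collinear in this sample)", name)
            continue
        cols.append(col)
        labels.append(name)

    return DesignMatrix(values=np.column_stack(cols), column_labels=labels)


# ---------------------------------------------------------------------------
# PEB machinery
# ---------------------------------------------------------------------------

@dataclass
class PEBSettings:
    #: between-subject variance prior expectation = first-level prior
    #: variance / re_variance_divisor
    re_variance_divisor: float = 16.0
    #: prior N(0, 1) on each between-subject log precision multiplier g
    g_prior_var: float = 1.0
    g_bounds: tuple[float, float] = (-8.0, 8.0)
    #: optimizer budget for the per-block log precisions
    g_maxfev: int = 60
    #: line-search tolerance on each log precision
    g_xatol: float = 0.1
    #: coordinate-descent sweeps over the block log precisions
    g_max_sweeps: int = 3
    #: reuse previously estimated log precisions instead of optimizing
    #: (used by leave-one-out refits, where g barely moves)
    fixed_g: dict | None = None


#: parameter-name prefix -> random-effects block.  One between-subject log
#: precision is estimated per block: initial states, dynamics, behavioral
#: readout and noise hyperparameters have very different scales and
#: different amounts of residual heterogeneity.
_RE_BLOCKS = {
    "x0": "x0",
    "lam": "dyn", "c0": "dyn", "c1": "dyn", "edge": "dyn", "csens": "dyn",
    "t0": "dyn", "log_tau": "dyn",
    "w": "readout", "intercept": "readout",
    "log_prec_vol": "noise", "log_prec_beh": "noise",
}


@dataclass
class PEBResult:
    beta: np.ndarray  # [parameters x covariates]
    beta_covariance: np.ndarray  # joint posterior covariance of vec-by-column beta
    random_effects_precision: dict  # block -> multiplier exp(g*) on base precision
    free_energy: float  # total hierarchical free energy (for model comparison)
    param_names: list[str] = field(default_factory=list)
    column_labels: list[str] = field(default_factory=list)
    # internals reused by model reduction, LOO prediction and shrinkage
    beta_prior_mean: np.ndarray = field(default_factory=lambda: np.zeros(0))
    beta_prior_variance: np.ndarray = field(default_factory=lambda: np.zeros(0))
    sigma_b: np.ndarray = field(default_factory=lambda: np.zeros(0))
    second_level_evidence: float = 0.0
    null_evidence: float = 0.0
    sum_subject_f: float = 0.0

    @property
    def n_params(self) -> int:
        return self.beta.shape[0]

    @property
    def n_cols(self) -> int:
        return self.beta.shape[1]

    def entry_index(self, param: int | str, col: int | str) -> int:
        """Flat index of (parameter, covariate) in the vec-by-column layout."""
        if isinstance(param, str):
            param = self.param_names.index(param)
        if isinstance(col, str):
            col = self.column_labels.index(col)
        return col * self.n_params + param


def _likelihood_summaries(posteriors: list[SubjectPosterior],
                          priors: PriorSpec):
    """(h_i, Lambda_i) per subject over the free parameters; Lambda clipped
    to PSD (the Gauss-Newton cross-curvature can carry tiny negative
    directions)."""
    free = posteriors[0].free_mask
    for p in posteriors:
        if p.free_mask is None or not np.array_equal(p.free_mask, free):
            raise PEBError("subject posteriors are over different parameters")
    idx = np.where(free)[0]
    P0 = np.diag(1.0 / priors.variance[idx])
    mu0 = priors.mean[idx]
    hs, lams = [], []
    for p in posteriors:
        S = p.covariance[np.ix_(idx, idx)]
        P = np.linalg.inv(S)
        P = 0.5 * (P + P.T)
        lam = P - P0
        evals, evecs = np.linalg.eigh(lam)
        lam = (evecs * np.clip(evals, 0.0, None)) @ evecs.T
        # summary-statistic convention: the pseudo-likelihood is centered at
        # the posterior mean with the data-information precision.  Centering
        # at the extrapolated maximum-likelihood point (P m - P0 mu0) is
        # exact for linear models but unstable along weakly identified
        # nonlinear ridges, where the quadratic extrapolation leaves the
        # region in which the Laplace approximation holds.
        h = lam @ p.mean[idx]
        hs.append(h)
        lams.append(lam)
    return idx, hs, lams, mu0, priors.variance[idx]


def _logz(h, lam, nu, s_diag):
    """log int exp(-theta' Lam theta / 2 + h' theta) N(theta; nu, diag(s)) dtheta."""
    p = len(h)
    Sinv = 1.0 / s_diag
    Q = lam + np.diag(Sinv)
    cf = np.linalg.cholesky(Q)
    b = h + Sinv * nu
    half = np.linalg.solve(cf, b)
    return float(-0.5 * np.sum(np.log(s_diag)) - np.sum(np.log(np.diag(cf)))
                 - 0.5 * np.sum(nu**2 * Sinv) + 0.5 * half @ half)


def _marginal_terms(h, lam, s_diag):
    """Quadratic form of logZ as a function of the prior mean nu:
    logZ(nu) = -nu' R nu / 2 + s' nu + c."""
    Sinv = 1.0 / s_diag
    Q = lam + np.diag(Sinv)
    Qinv = np.linalg.inv(Q)
    R = np.diag(Sinv) - Sinv[:, None] * Qinv * Sinv[None, :]
    s = Sinv * (Qinv @ h)
    cf = np.linalg.cholesky(Q)
    c = (-0.5 * np.sum(np.log(s_diag)) - np.sum(np.log(np.diag(cf)))
         + 0.5 * h @ Qinv @ h)
    return R, s, float(c)


def fit_peb(posteriors: list[SubjectPosterior], X: DesignMatrix,
            priors: PriorSpec, settings: PEBSettings | None = None,
            param_names: list[str] | None = None) -> PEBResult:
    """Empirical-Bayes estimate of group effects B and between-subject
    precision, with the hierarchical free energy.

    First-level posterior uncertainty propagates: subjects with fewer visits
    (wider posteriors) carry flatter likelihood summaries and weigh less.
    """
    settings = settings or PEBSettings()
    if X.n_subjects != len(posteriors):
        raise PEBError("design rows do not match the number of posteriors")
    idx, hs, lams, mu0, prior_var = _likelihood_summaries(posteriors, priors)
    n, c = X.values.shape
    p = len(idx)

    base_bvar = prior_var / settings.re_variance_divisor
    w_prior_var = np.tile(prior_var, c)  # beta prior: rows inherit first-level
    # the group-mean column's prior expectation is the first-level prior mean;
    # covariate effects are a priori zero
    w_prior_mean = np.zeros(c * p)
    w_prior_mean[:p] = mu0
    Xv = X.values

    names = (param_names if param_names is not None
             else [f"p{j}" for j in range(posteriors[0].mean.size)])
    free_names = [names[j] for j in idx]
    block_labels = sorted({_RE_BLOCKS[nm.split(":")[0]] for nm in free_names})
    block_of = np.array([block_labels.index(_RE_BLOCKS[nm.split(":")[0]])
                         for nm in free_names])
    nb = len(block_labels)

    null_ev = sum(_logz(h, lam, mu0, prior_var) for h, lam in zip(hs, lams))

    def evidence(g: np.ndarray):
        s_b = np.exp(-g[block_of]) * base_bvar
        Rs = np.empty((n, p, p))
        ss = np.empty((n, p))
        c_sum = 0.0
        for i in range(n):
            R, s, cc = _marginal_terms(hs[i], lams[i], s_b)
            Rs[i], ss[i] = R, s
            c_sum += cc
        # vec-by-column layout: w = [B[:,0]; B[:,1]; ...]
        Qw = np.einsum("ij,ik,iab->jakb", Xv, Xv, Rs).reshape(c * p, c * p)
        Qw = Qw + np.diag(1.0 / w_prior_var)
        bw = (Xv.T @ ss).reshape(c * p) + w_prior_mean / w_prior_var
        cf = np.linalg.cholesky(0.5 * (Qw + Qw.T))
        half = np.linalg.solve(cf, bw)
        logev = (c_sum - 0.5 * np.sum(np.log(w_prior_var))
                 - np.sum(np.log(np.diag(cf)))
                 - 0.5 * np.sum(w_prior_mean**2 / w_prior_var)
                 + 0.5 * half @ half)
        return float(logev), Qw, bw, s_b

    def neg_f2(g):
        g = np.clip(np.asarray(g, float), *settings.g_bounds)
        logev = evidence(g)[0]
        return -(logev - 0.5 * np.sum(g**2) / settings.g_prior_var
                 - 0.5 * nb * np.log(2 * np.pi * settings.g_prior_var))

    if settings.fixed_g is not None:
        g_star = np.array([settings.fixed_g[lab] for lab in block_labels])
        f2_mode = -neg_f2(g_star)
    else:
        # coordinate descent with bounded line searches per block
        g_star = np.zeros(nb)
        f2_mode = -neg_f2(g_star)
        for sweep in range(settings.g_max_sweeps):
            moved = 0.0
            for k in range(nb):
                def along(gk, k=k):
                    g = g_star.copy()
                    g[k] = gk
                    return neg_f2(g)
                res = minimize_scalar(along, bounds=settings.g_bounds,
                                      method="bounded",
                                      options={"xatol": settings.g_xatol})
                if -res.fun > f2_mode:
                    moved = max(moved, abs(res.x - g_star[k]))
                    g_star[k] = float(res.x)
                    f2_mode = -float(res.fun)
            if moved < 0.1:
                break

    # Laplace correction over the log precisions (diagonal curvature)
    eps = 0.05
    log_vg = 0.0
    for k in range(nb):
        e = np.zeros(nb)
        e[k] = eps
        curv = (neg_f2(g_star + e) + neg_f2(g_star - e) - 2 * (-f2_mode)) / eps**2
        log_vg += np.log(1.0 / max(curv, 1e-6))
    f2 = f2_mode + 0.5 * (nb * np.log(2 * np.pi) + log_vg)

    logev, Qw, bw, s_b = evidence(g_star)
    Sw = np.linalg.inv(Qw)
    Sw = 0.5 * (Sw + Sw.T)
    mw = Sw @ bw
    beta = mw.reshape(c, p).T  # [p x c]

    sum_f = sum(float(p_.free_energy) for p_ in posteriors)
    return PEBResult(
        beta=beta, beta_covariance=Sw,
        random_effects_precision={
            lab: float(np.exp(g_star[k])) for k, lab in enumerate(block_labels)},
        free_energy=float(sum_f + f2 - null_ev),
        param_names=free_names,
        column_labels=list(X.column_labels),
        beta_prior_mean=w_prior_mean, beta_prior_variance=w_prior_var,
        sigma_b=s_b,
        second_level_evidence=float(f2), null_evidence=float(null_ev),
        sum_subject_f=float(sum_f))


def subject_level_updates(peb: PEBResult, posteriors: list[SubjectPosterior],
                          X: DesignMatrix, priors: PriorSpec) -> np.ndarray:
    """Empirical-Bayes updated subject parameter estimates [subjects x p].

    Each update is the posterior mean of theta_i under the group-conditional
    prior N(B x_i, Sigma_b) and the subject's likelihood summary; it shrinks
    the first-level estimate toward the group prediction.
    """
    idx, hs, lams, _, _ = _likelihood_summaries(posteriors, priors)
    out = np.empty((len(posteriors), len(idx)))
    Binv = np.diag(1.0 / peb.sigma_b)
    for i, (h, lam) in enumerate(zip(hs, lams)):
        nu = peb.beta @ X.values[i]
        out[i] = np.linalg.solve(lam + Binv, h + Binv @ nu)
    return out


def eb_updated_posteriors(peb: PEBResult, posteriors: list[SubjectPosterior],
                          X: DesignMatrix,
                          priors: PriorSpec) -> list[SubjectPosterior]:
    """Posteriors whose means are replaced by their empirical-Bayes updates.

    Pooling across subjects through the group model counteracts the
    subject-level shrinkage toward the first-level prior, so trajectories
    derived from these means are the hierarchical point estimates.
    """
    from dataclasses import replace as _replace

    updates = subject_level_updates(peb, posteriors, X, priors)
    out = []
    for post, upd in zip(posteriors, updates):
        mean = post.mean.copy()
        mean[post.free_mask] = upd
        out.append(_replace(post, mean=mean))
    return out


def subject_group_logz(peb: PEBResult, posterior: SubjectPosterior,
                       priors: PriorSpec, x_row: np.ndarray,
                       include_beta_uncertainty: bool = True) -> float:
    """Evidence contribution of one subject under the group prior B x_row.

    Used for out-of-sample covariate prediction: the subject's likelihood
    summary is re-evaluated under the group-conditional prior implied by a
    candidate design row.
    """
    idx, hs, lams, _, _ = _likelihood_summaries([posterior], priors)
    h, lam = hs[0], lams[0]
    nu = peb.beta @ x_row
    s = peb.sigma_b.copy()
    if include_beta_uncertainty:
        p = peb.n_params
        c = peb.n_cols
        # diagonal of (x' kron I) Sw (x kron I)
        Sw = peb.beta_covariance.reshape(c, p, c, p)
        s = s + np.einsum("j,jakb,k->ab", x_row, Sw, x_row).diagonal()
    return _logz(h, lam, nu, s)
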