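"""Bayesian model selection, reduction and averaging at the group level.

Model selection compares the four candidate state-model forms (constant rate,
quadratic rate, dynamic, dynamic with sigmoidal input) by their total
hierarchical free energy; free-energy differences are log Bayes factors and
are mapped to posterior model probabilities under equal model priors.

Bayesian model reduction (BMR) scores reduced versions of the group-level
effect matrix analytically: switching a (parameter, covariate) entry off
collapses its prior variance toward zero, and the evidence and posterior of
the reduced model follow from the full posterior without refitting.  Each
entry's posterior probability of being "on" is the softmax of the on/off
evidence pair; entries are thresholded at Pp > 0.95.  Averaged estimates come
from an evidence-weighted average over the greedily searched model family.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .models import StateModelSpec, edge_preset
from .peb import DesignMatrix, PEBResult, PEBSettings, build_design_matrix, fit_peb
from .vl import PriorSpec, SubjectPosterior, VLSettings, fit_subject

#: prior variance representing a switched-off parameter (exactly zero would
#: make the linear algebra singular)
OFF_VARIANCE = 1e-8

#: posterior-probability threshold for retaining group-level effects
PP_THRESHOLD = 0.95


class SelectionError(ValueError):
    pass


@dataclass
class ModelComparison:
    model_ids: list[str]
    free_energies: list[float]
    posterior_probs: np.ndarray
    notes: list[str] = field(default_factory=list)

    @property
    def winner(self) -> str:
        return self.model_ids[int(np.argmax(self.free_energies))]


@dataclass
class BMAResult:
    estimates: np.ndarray  # [parameters x covariates], model-averaged
    sds: np.ndarray
    posterior_probs: np.ndarray  # Pp per entry
    surviving: np.ndarray  # Pp > threshold
    threshold: float
    param_names: list[str]
    column_labels: list[str]
    n_models_visited: int


def posterior_model_probs(free_energies) -> np.ndarray:
    """Softmax of free energies under equal prior model probabilities."""
    F = np.asarray(free_energies, float)
    if F.size < 2:
        raise SelectionError("need at least two models to compare")
    if not np.all(np.isfinite(F)):
        raise SelectionError("non-finite free energy")
    z = F - F.max()
    w = np.exp(z)
    return w / w.sum()


# ---------------------------------------------------------------------------
# Bayesian model reduction
# ---------------------------------------------------------------------------

def _reduced_log_evidence(mu, Sigma, mu0, var0, mu0_r, var0_r):
    """Change in log evidence and reduced posterior when the (diagonal)
    prior (mu0, var0) is replaced by (mu0_r, var0_r), holding the likelihood
    summary fixed.  Exact for Gaussian posteriors."""
    P = np.linalg.inv(Sigma)
    P = 0.5 * (P + P.T)
    P0 = np.diag(1.0 / var0)
    P0r = np.diag(1.0 / var0_r)
    Pr = P + P0r - P0
    c = P @ mu - P0 @ mu0 + P0r @ mu0_r
    Sr = np.linalg.inv(Pr)
    Sr = 0.5 * (Sr + Sr.T)
    mur = Sr @ c

    sign, logdet_P = np.linalg.slogdet(P)
    sign_r, logdet_Pr = np.linalg.slogdet(Pr)
    if sign <= 0 or sign_r <= 0:
        raise SelectionError("indefinite precision in model reduction")
    dF = 0.5 * (
        (np.sum(np.log(var0)) - np.sum(np.log(var0_r)))
        - (logdet_Pr - logdet_P)
        + (mur @ Pr @ mur - mu @ P @ mu)
        + (mu0 @ P0 @ mu0 - mu0_r @ P0r @ mu0_r)
    )
    return float(dF), mur, Sr


def bayesian_model_reduction(peb: PEBResult, off_mask) -> tuple[float, np.ndarray, np.ndarray]:
    """Evidence change and reduced posterior with the given group-level
    entries switched off (prior variance collapsed to OFF_VARIANCE, prior
    expectation 0).

    ``off_mask`` is an iterable of (parameter, covariate) pairs, by index or
    by name.  Returns ``(delta_F, reduced_mean, reduced_covariance)`` over
    the vec-by-column beta; ``delta_F = F_reduced - F_full``.
    """
    entries = [peb.entry_index(p, c) for p, c in off_mask]
    mean_col = [e for e in entries
                if e < peb.n_params]  # column 0 is the group mean
    if len(mean_col) == peb.n_params:
        raise SelectionError("cannot switch off the entire mean column")
    mu = peb.beta.T.reshape(-1)  # vec-by-column
    if not entries:
        return 0.0, mu.copy(), peb.beta_covariance.copy()
    var0_r = peb.beta_prior_variance.copy()
    mu0_r = peb.beta_prior_mean.copy()
    var0_r[entries] = OFF_VARIANCE
    mu0_r[entries] = 0.0
    dF, mur, Sr = _reduced_log_evidence(
        mu, peb.beta_covariance, peb.beta_prior_mean,
        peb.beta_prior_variance, mu0_r, var0_r)
    return dF, mur, Sr


def _rank_one_dF(mu, Sigma, e, v0):
    """Evidence change of switching off one zero-prior-mean entry, via
    Sherman-Morrison on the current reduced posterior."""
    delta = 1.0 / OFF_VARIANCE - 1.0 / v0
    see = Sigma[e, e]
    denom = 1.0 + delta * see
    return 0.5 * (np.log(v0 / OFF_VARIANCE) - np.log(denom)
                  - delta * mu[e] ** 2 / denom)


def _rank_one_apply(mu, Sigma, e, v0):
    delta = 1.0 / OFF_VARIANCE - 1.0 / v0
    denom = 1.0 + delta * Sigma[e, e]
    mu_new = mu - (delta * mu[e] / denom) * Sigma[:, e]
    Sigma_new = Sigma - (delta / denom) * np.outer(Sigma[:, e], Sigma[:, e])
    return mu_new, Sigma_new


def bma_average(peb: PEBResult, search: str = "greedy") -> BMAResult:
    """Model reduction and averaging over the group-level effect matrix.

    Per-entry posterior probabilities come from the on/off Bayesian model
    comparison of each switchable entry (softmax of the evidence pair, the
    off model collapsing that entry's prior).  Averaged estimates are the
    evidence-weighted mean over the searched reduced-model family (greedy:
    the visited pruning path; exhaustive: all on/off combinations, refused
    beyond 20 switchable entries).
    """
    p, c = peb.n_params, peb.n_cols
    switchable = [(a, j) for j in range(1, c) for a in range(p)]
    mu_full = peb.beta.T.reshape(-1)
    S_full = peb.beta_covariance
    var0 = peb.beta_prior_variance

    # per-entry on/off posterior probability on the full model
    Pp = np.ones((p, c))
    for a, j in switchable:
        e = j * p + a
        dF = _rank_one_dF(mu_full, S_full, e, var0[e])
        Pp[a, j] = 1.0 / (1.0 + np.exp(min(dF, 500.0)))

    if search == "exhaustive":
        if len(switchable) > 20:
            raise SelectionError(
                "exhaustive search refused beyond 20 switchable entries; "
                "use greedy")
        models = []
        for bits in range(2 ** len(switchable)):
            off = [sw for k, sw in enumerate(switchable) if bits >> k & 1]
            dF, mur, Sr = bayesian_model_reduction(peb, off)
            models.append((dF, mur, np.diag(Sr).copy()))
    elif search == "greedy":
        mu, Sigma = mu_full.copy(), S_full.copy()
        models = [(0.0, mu.copy(), np.diag(Sigma).copy())]
        remaining = {(a, j): j * p + a for a, j in switchable}
        total_dF = 0.0
        while remaining:
            keys = list(remaining)
            es = np.array([remaining[k] for k in keys])
            delta = 1.0 / OFF_VARIANCE - 1.0 / var0[es]
            denom = 1.0 + delta * Sigma[es, es]
            dFs = 0.5 * (np.log(var0[es] / OFF_VARIANCE) - np.log(denom)
                         - delta * mu[es] ** 2 / denom)
            k = int(np.argmax(dFs))
            if dFs[k] <= 0.0:
                break
            best = keys[k]
            e = remaining.pop(best)
            mu, Sigma = _rank_one_apply(mu, Sigma, e, var0[e])
            total_dF += float(dFs[k])
            models.append((total_dF, mu, np.diag(Sigma).copy()))
    else:
        raise SelectionError(f"unknown search {search!r}")

    Fs = np.array([m[0] for m in models])
    w = np.exp(Fs - Fs.max())
    w /= w.sum()
    est = np.zeros(p * c)
    second = np.zeros(p * c)
    for wk, (dF, mur, var_r) in zip(w, models):
        est += wk * mur
        second += wk * (var_r + mur**2)
    sds = np.sqrt(np.clip(second - est**2, 0.0, None))

    return BMAResult(
        estimates=est.reshape(c, p).T, sds=sds.reshape(c, p).T,
        posterior_probs=Pp, surviving=Pp > PP_THRESHOLD,
        threshold=PP_THRESHOLD, param_names=list(peb.param_names),
        column_labels=list(peb.column_labels), n_models_visited=len(models))


# ---------------------------------------------------------------------------
# hierarchical model comparison
# ---------------------------------------------------------------------------

def select_state_model(subjects, series, forms=None,
                       priors_by_form: dict | None = None,
                       vl_settings: VLSettings | None = None,
                       peb_settings: PEBSettings | None = None,
                       X: DesignMatrix | None = None) -> ModelComparison:
    """Fit all candidate state-model forms hierarchically and compare their
    total group-level free energies.

    Subjects whose inversion fails to converge under any form are excluded
    from every comparison (noted in the result), so all models see the same
    data.
    """
    forms = list(forms or ("constant_rate", "quadratic_rate", "dynamic",
                           "dynamic_sigmoid"))
    X = X or build_design_matrix(subjects)
    fits: dict[str, list[SubjectPosterior]] = {}
    priors: dict[str, PriorSpec] = {}
    for form in forms:
        spec = StateModelSpec(form=form)
        pr = (priors_by_form or {}).get(form) or PriorSpec.default(spec)
        fits[form] = [fit_subject(ts, spec, pr, vl_settings) for ts in series]
        priors[form] = pr

    notes = []
    bad = set()
    for form in forms:
        for i, post in enumerate(fits[form]):
            if not post.converged:
                bad.add(i)
                notes.append(f"subject {series[i].subject_id} excluded: "
                             f"no convergence under {form}")
    keep = [i for i in range(len(series)) if i not in bad]
    if len(keep) < 2:
        raise SelectionError("too few converged subjects for comparison")
    Xk = (X if not bad else
          build_design_matrix([subjects[i] for i in keep]))

    Fs = []
    for form in forms:
        spec = StateModelSpec(form=form)
        peb = fit_peb([fits[form][i] for i in keep], Xk, priors[form],
                      peb_settings, param_names=spec.param_names)
        Fs.append(peb.free_energy)
    return ModelComparison(model_ids=forms, free_energies=Fs,
                           posterior_probs=posterior_model_probs(Fs),
                           notes=notes)


def compare_connectivity_models(subjects, series,
                                edge_presets=("striatal_cortical",
                                              "cortical_cortical"),
                                priors_by_model: dict | None = None,
                                vl_settings: VLSettings | None = None,
                                peb_settings: PEBSettings | None = None,
                                X: DesignMatrix | None = None) -> ModelComparison:
    """Compare the diagonal dynamic model against dynamic models with
    interregional connection presets by group free energy."""
    X = X or build_design_matrix(subjects)
    model_specs = {"diagonal": StateModelSpec(form="dynamic")}
    for name in edge_presets:
        model_specs[name] = StateModelSpec(
            form="dynamic", connectivity_edges=edge_preset(name))

    fits = {}
    priors = {}
    for name, spec in model_specs.items():
        pr = (priors_by_model or {}).get(name) or PriorSpec.default(spec)
        fits[name] = [fit_subject(ts, spec, pr, vl_settings) for ts in series]
        priors[name] = pr

    notes = []
    bad = set()
    for name, posts in fits.items():
        for i, post in enumerate(posts):
            if not post.converged:
                bad.add(i)
                notes.append(f"subject {series[i].subject_id} excluded: "
                             f"no convergence under {name}")
    keep = [i for i in range(len(series)) if i not in bad]
    Xk = (X if not bad else build_design_matrix([subjects[i] for i in keep]))

    ids, Fs = [], []
    for name, spec in model_specs.items():
        peb = fit_peb([fits[name][i] for i in keep], Xk, priors[name],
                      peb_settings, param_names=spec.param_names)
        ids.append(name)
        Fs.append(peb.free_energy)
    return ModelComparison(model_ids=ids, free_energies=Fs,
                           posterior_probs=posterior_model_probs(Fs),
                           notes=notes)
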