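"""Validation and summary analyses.

Covers the model's predictive-validity checks and descriptive summaries:
leave-one-out covariate prediction (group membership and CAG-repeat length),
the nonhierarchical per-decade volume-loss summary, variance of volume
explained by CAG over progression time, and brain-behavior fit metrics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .cohort import RegionalTimeSeries, Subject
from .models import StateModelSpec, SubjectParams, integrate_states
from .peb import DesignMatrix, PEBSettings, build_design_matrix, fit_peb, \
    prune_design_columns, subject_group_logz
from .regions import BEHAVIOR_CHANNELS, N_STATES, REGION_COLUMNS, STATE_NAMES
from .vl import PriorSpec, SubjectPosterior, VLSettings, fit_subject

logger = logging.getLogger(__name__)


class ValidationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# nonhierarchical decade-loss summary
# ---------------------------------------------------------------------------

def decade_loss_summary(subjects: list[Subject],
                        series: list[RegionalTimeSeries],
                        window_start: float = -6.0) -> pd.DataFrame:
    """Median percent volume loss per decade, per region and group.

    Per subject and region an ordinary least-squares line is fitted to
    volume against time; the loss is the slope over 10 years expressed as a
    percentage of the fitted volume at the window start (t = -6), and the
    group summary is the median across subjects.  This is deliberately
    nonhierarchical: no priors touch the rates.
    """
    per_group: dict[str, list[np.ndarray]] = {}
    for subj, ts in zip(subjects, series):
        t = ts.times
        if len(np.unique(t)) < 2:
            logger.info("subject %s skipped in decade-loss summary: fewer "
                        "than 2 distinct visit times", subj.id)
            continue
        A = np.column_stack([np.ones_like(t), t])
        coef, *_ = np.linalg.lstsq(A, ts.volumes, rcond=None)
        fitted_start = coef[0] + coef[1] * window_start
        with np.errstate(divide="ignore", invalid="ignore"):
            loss = -coef[1] * 10.0 / fitted_start * 100.0
        per_group.setdefault(subj.group, []).append(loss)
    out = {g: np.median(np.stack(v), axis=0) for g, v in per_group.items()}
    return pd.DataFrame(out, index=REGION_COLUMNS)


def state_decade_loss(summary: pd.DataFrame, state: str, group: str) -> float:
    """Average the hemisphere columns of a state in a decade-loss summary."""
    cols = [c for c in summary.index if c == state or c.startswith(state + "_")]
    return float(summary.loc[cols, group].mean())


# ---------------------------------------------------------------------------
# CAG variance explained over progression time
# ---------------------------------------------------------------------------

def variance_explained_over_time(subjects: list[Subject],
                                 posteriors: list[SubjectPosterior],
                                 spec: StateModelSpec,
                                 states=("caudate", "putamen", "white_matter"),
                                 times=None,
                                 min_subjects: int = 3) -> pd.DataFrame:
    """R^2 of model-predicted volume regressed on CAG, at each time point.

    Predictions are the denoised model trajectories (posterior means), so the
    curves show how much of the modelled volume variance CAG explains as the
    disease progresses; only HD gene carriers enter.
    """
    times = np.arange(-6, 6, dtype=float) if times is None else np.asarray(times, float)
    hd = [(s, p) for s, p in zip(subjects, posteriors)
          if s.group == "HD" and s.cag is not None]
    if len(hd) < min_subjects:
        raise ValidationError("too few HD subjects with CAG")
    cags = np.array([s.cag for s, _ in hd], float)
    state_idx = [STATE_NAMES.index(nm) for nm in states]

    preds = np.empty((len(hd), len(times), len(state_idx)))
    for i, (_, post) in enumerate(hd):
        params = SubjectParams.from_vector(spec, post.mean)
        traj = integrate_states(spec, params, times)
        preds[i] = traj.states[:, state_idx]

    A = np.column_stack([np.ones_like(cags), cags])
    out = np.empty((len(times), len(state_idx)))
    for ti in range(len(times)):
        for si in range(len(state_idx)):
            y = preds[:, ti, si]
            coef, *_ = np.linalg.lstsq(A, y, rcond=None)
            resid = y - A @ coef
            sst = np.sum((y - y.mean()) ** 2)
            out[ti, si] = 0.0 if sst == 0 else 1.0 - np.sum(resid**2) / sst
    return pd.DataFrame(out, index=times, columns=list(states))


# ---------------------------------------------------------------------------
# brain-behavior metrics
# ---------------------------------------------------------------------------

@dataclass
class BehaviorFit:
    r2: dict[str, float]
    decade_change: dict[str, float]  # model-implied change over 10 years
    weights: dict[str, np.ndarray]  # per-state readout weights
    intercepts: dict[str, float]
    noise_sd: dict[str, float]


def _bayes_ridge(A: np.ndarray, y: np.ndarray, prior_mean: np.ndarray,
                 prior_var: np.ndarray):
    """Bayesian linear regression with scalar noise precision estimated by
    evidence maximization (type-II maximum likelihood)."""
    P0 = np.diag(1.0 / prior_var)
    h0 = prior_mean / prior_var
    AtA = A.T @ A
    Aty = A.T @ y
    n = len(y)

    def neg_ev(log_prec):
        w = np.exp(log_prec)
        P = P0 + w * AtA
        cf = np.linalg.cholesky(P)
        b = h0 + w * Aty
        half = np.linalg.solve(cf, b)
        ev = (0.5 * n * (log_prec - np.log(2 * np.pi)) - 0.5 * w * y @ y
              - 0.5 * np.sum(np.log(2 * np.pi * prior_var))
              - 0.5 * np.sum(prior_mean**2 / prior_var)
              + 0.5 * len(b) * np.log(2 * np.pi) - np.sum(np.log(np.diag(cf)))
              + 0.5 * half @ half)
        return -ev

    res = minimize_scalar(neg_ev, bounds=(-10, 10), method="bounded",
                          options={"xatol": 1e-3})
    w = np.exp(res.x)
    P = P0 + w * AtA
    S = np.linalg.inv(P)
    m = S @ (h0 + w * Aty)
    return m, S, float(res.x)


def behavior_fit_metrics(subjects: list[Subject],
                         series: list[RegionalTimeSeries],
                         posteriors: list[SubjectPosterior],
                         spec: StateModelSpec,
                         decade_window: tuple[float, float] = (-6.0, 4.0),
                         weight_prior_var: float = 1.0) -> BehaviorFit:
    """Fit the brain-behavior readout and report R^2 and decade change.

    A single readout weight vector per channel (shared across HD subjects,
    plus an intercept) is estimated by Bayesian linear regression of the
    pooled observed scores on the subjects' model-predicted latent states;
    R^2 is computed on the pooled subject-visits and the decade change is
    the mean model-implied score change over ``decade_window`` (a 10-year
    span on the rescaled [0, 100] scale).
    """
    rows = []
    targets = {ch: [] for ch in BEHAVIOR_CHANNELS}
    deltas = []
    any_behavior = False
    for subj, ts, post in zip(subjects, series, posteriors):
        if subj.group != "HD" or ts.behavior is None:
            continue
        any_behavior = True
        params = SubjectParams.from_vector(spec, post.mean)
        traj = integrate_states(spec, params, ts.times)
        rows.append(traj.states)
        for j, ch in enumerate(BEHAVIOR_CHANNELS):
            targets[ch].append(ts.behavior[:, j])
        ends = integrate_states(spec, params, np.array(decade_window))
        deltas.append(ends.states[1] - ends.states[0])
    if not any_behavior:
        raise ValidationError("cohort carries no behavioral scores")

    Xs = np.vstack(rows)
    A = np.column_stack([Xs, np.ones(len(Xs))])
    prior_mean = np.concatenate([np.zeros(N_STATES), [50.0]])
    prior_var = np.concatenate([np.full(N_STATES, weight_prior_var), [900.0]])
    deltas = np.stack(deltas)

    r2, change, weights, intercepts, noise = {}, {}, {}, {}, {}
    for ch in BEHAVIOR_CHANNELS:
        y = np.concatenate(targets[ch])
        mask = np.isfinite(y)
        m, S, logprec = _bayes_ridge(A[mask], y[mask], prior_mean, prior_var)
        pred = A[mask] @ m
        sst = np.sum((y[mask] - y[mask].mean()) ** 2)
        r2[ch] = float(1.0 - np.sum((y[mask] - pred) ** 2) / sst)
        weights[ch] = m[:N_STATES]
        intercepts[ch] = float(m[-1])
        noise[ch] = float(np.exp(-logprec / 2.0))
        change[ch] = float(np.mean(deltas @ m[:N_STATES]))
    return BehaviorFit(r2=r2, decade_change=change, weights=weights,
                       intercepts=intercepts, noise_sd=noise)


# ---------------------------------------------------------------------------
# leave-one-out covariate prediction
# ---------------------------------------------------------------------------

@dataclass
class LooResult:
    covariate: str
    subject_ids: list[str]
    true_values: np.ndarray
    predicted: np.ndarray
    uncertainty: np.ndarray  # posterior probability (group) or posterior sd
    accuracy: float | None
    r: float
    notes: list[str] = field(default_factory=list)


def loo_predict(subjects: list[Subject], series: list[RegionalTimeSeries],
                covariate: str = "group",
                spec: StateModelSpec | None = None,
                priors: PriorSpec | None = None,
                vl_settings: VLSettings | None = None,
                peb_settings: PEBSettings | None = None,
                posteriors: list[SubjectPosterior] | None = None) -> LooResult:
    """Leave-one-out prediction of a covariate from brain data.

    The winning (dynamic) hierarchical model is fitted to all but one
    subject; the left-out subject's covariate is then inferred from how well
    the group-conditional priors for each candidate value explain their
    (already inverted) data summary.  For ``group``, the posterior
    probability of HD assigns the label; for ``CAG``, a posterior mean over
    the integer support is reported.  The left-out subject never enters the
    group stage.
    """
    n = len(subjects)
    if n < 10:
        raise ValidationError("leave-one-out refused below 10 subjects")
    if covariate not in ("group", "CAG"):
        raise ValidationError("covariate must be 'group' or 'CAG'")
    spec = spec or StateModelSpec(form="dynamic")
    priors = priors or PriorSpec.default(spec)

    if posteriors is None:
        posteriors = [fit_subject(ts, spec, priors, vl_settings)
                      for ts in series]
    X = build_design_matrix(subjects)

    # between-subject precisions from the full fit, reused in each refit
    full = fit_peb(posteriors, X, priors, peb_settings,
                   param_names=spec.param_names)
    fixed_g = {k: float(np.log(v))
               for k, v in full.random_effects_precision.items()}
    refit_settings = PEBSettings(**{
        **(peb_settings.__dict__ if peb_settings else {}), "fixed_g": fixed_g})

    hd_cags = np.array([s.cag for s in subjects if s.cag is not None], float)
    cag_mean, cag_sd = hd_cags.mean(), hd_cags.std()
    cag_grid = np.arange(39, 51, dtype=float)

    ids, truth, pred, unc = [], [], [], []
    for i in range(n):
        rest = [j for j in range(n) if j != i]
        # a fold can make a nuisance column collinear; prune per fold
        vals, labels, kept = prune_design_columns(
            X.values[rest], X.column_labels)
        X_rest = DesignMatrix(values=vals, column_labels=labels)
        jcov = labels.index(covariate if covariate == "CAG" else "group")
        peb = fit_peb([posteriors[j] for j in rest], X_rest, priors,
                      refit_settings, param_names=spec.param_names)
        row = X.values[i][kept].copy()
        if covariate == "group":
            logz = []
            for gval in (+1.0, -1.0):
                r = row.copy()
                r[jcov] = gval
                if gval < 0:  # a control carries no CAG burden
                    r[labels.index("CAG")] = 0.0
                logz.append(subject_group_logz(peb, posteriors[i], priors, r))
            p_hd = float(np.exp(logz[0] - np.logaddexp(*logz)))
            ids.append(subjects[i].id)
            truth.append(+1.0 if subjects[i].group == "HD" else -1.0)
            pred.append(2.0 * p_hd - 1.0)
            unc.append(p_hd)
        else:
            if subjects[i].cag is None:
                continue
            logzs = []
            for cag in cag_grid:
                r = row.copy()
                r[jcov] = (cag - cag_mean) / cag_sd
                logzs.append(subject_group_logz(peb, posteriors[i], priors, r))
            logzs = np.array(logzs)
            wts = np.exp(logzs - logzs.max())
            wts /= wts.sum()
            mean_cag = float(wts @ cag_grid)
            ids.append(subjects[i].id)
            truth.append(float(subjects[i].cag))
            pred.append(mean_cag)
            unc.append(float(np.sqrt(wts @ (cag_grid - mean_cag) ** 2)))

    truth = np.asarray(truth)
    pred = np.asarray(pred)
    acc = None
    if covariate == "group":
        acc = float(np.mean(np.sign(pred) == truth))
    r = float(np.corrcoef(pred, truth)[0, 1]) if len(truth) > 2 else np.nan
    return LooResult(covariate=covariate, subject_ids=ids, true_values=truth,
                     predicted=pred, uncertainty=np.asarray(unc),
                     accuracy=acc, r=r)
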