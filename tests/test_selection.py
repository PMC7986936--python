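"""Model comparison, Bayesian model reduction and averaging."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from hdprog.cohort import RegionalTimeSeries
from hdprog.models import (
    StateModelSpec,
    SubjectParams,
    edge_preset,
    integrate_states,
)
from hdprog.peb import PEBResult, build_design_matrix, fit_peb
from hdprog.regions import N_STATES, REGION_STATE_INDEX
from hdprog.selection import (
    OFF_VARIANCE,
    SelectionError,
    _rank_one_apply,
    _rank_one_dF,
    bayesian_model_reduction,
    bma_average,
    compare_connectivity_models,
    posterior_model_probs,
    select_state_model,
)
from hdprog.synthetic import CohortConfig, generate_cohort, _decay_a
from hdprog.vl import PriorSpec, fit_subject


# ---------------------------------------------------------------------------
# posterior model probabilities
# ---------------------------------------------------------------------------

def test_equal_free_energies_give_uniform_probs():
    p = posterior_model_probs([5.0, 5.0, 5.0, 5.0])
    np.testing.assert_allclose(p, 0.25)


def test_delta_f_three_gives_sigmoid_probability():
    p = posterior_model_probs([3.0, 0.0])
    np.testing.assert_allclose(p, [1 / (1 + np.exp(-3)), 1 / (1 + np.exp(3))],
                               rtol=1e-9)


@settings(max_examples=40, deadline=None)
@given(st.lists(st.floats(-100, 100), min_size=2, max_size=6),
       st.floats(-1000, 1000))
def test_probs_sum_to_one_and_shift_invariant(fs, shift):
    p = posterior_model_probs(fs)
    assert p.sum() == pytest.approx(1.0, abs=1e-12)
    np.testing.assert_allclose(p, posterior_model_probs(np.array(fs) + shift),
                               atol=1e-9)


def test_non_finite_free_energy_rejected():
    with pytest.raises(SelectionError):
        posterior_model_probs([1.0, np.nan])


# ---------------------------------------------------------------------------
# Bayesian model reduction
# ---------------------------------------------------------------------------

def _toy_peb(seed=3, p=2, c=3):
    """A PEBResult backed by an exact conjugate linear-Gaussian posterior."""
    rng = np.random.default_rng(seed)
    d = p * c
    A = rng.normal(0, 1, (4 * d, d))
    w_true = rng.normal(0, 1, d)
    y = A @ w_true + rng.normal(0, 0.5, len(A))
    var0 = np.full(d, 1.0)
    mu0 = np.zeros(d)
    prec = 4.0
    P = np.diag(1 / var0) + prec * A.T @ A
    S = np.linalg.inv(P)
    m = S @ (prec * A.T @ y)
    peb = PEBResult(
        beta=m.reshape(c, p).T, beta_covariance=S,
        random_effects_precision={}, free_energy=0.0,
        param_names=[f"x0:s{a}" for a in range(p)],
        column_labels=["mean"] + [f"cov{j}" for j in range(1, c)],
        beta_prior_mean=mu0, beta_prior_variance=var0)
    return peb, A, y, var0, prec


def _direct_evidence(A, y, var0, prec):
    C = A @ np.diag(var0) @ A.T + np.eye(len(y)) / prec
    return stats.multivariate_normal.logpdf(y, np.zeros(len(y)), C)


def test_empty_mask_is_evidence_neutral():
    peb, *_ = _toy_peb()
    dF, mur, Sr = bayesian_model_reduction(peb, [])
    assert dF == 0.0
    np.testing.assert_allclose(mur, peb.beta.T.reshape(-1))


def test_reduction_matches_direct_refit():
    """Analytic BMR equals refitting under the collapsed prior to <1e-6."""
    peb, A, y, var0, prec = _toy_peb()
    off = [(1, 1), (0, 2)]
    dF, mur, Sr = bayesian_model_reduction(peb, off)
    var_r = var0.copy()
    for pa, j in off:
        var_r[j * peb.n_params + pa] = OFF_VARIANCE
    dF_direct = (_direct_evidence(A, y, var_r, prec)
                 - _direct_evidence(A, y, var0, prec))
    assert dF == pytest.approx(dF_direct, abs=1e-6)


def test_rank_one_matches_dense_reduction():
    peb, *_ = _toy_peb(seed=9)
    mu = peb.beta.T.reshape(-1)
    e = peb.entry_index(0, 1)
    dF_dense, mur, Sr = bayesian_model_reduction(peb, [(0, 1)])
    dF_r1 = _rank_one_dF(mu, peb.beta_covariance, e,
                         peb.beta_prior_variance[e])
    mu_r1, S_r1 = _rank_one_apply(mu, peb.beta_covariance, e,
                                  peb.beta_prior_variance[e])
    assert dF_r1 == pytest.approx(dF_dense, abs=1e-8)
    np.testing.assert_allclose(mu_r1, mur, atol=1e-8)
    np.testing.assert_allclose(S_r1, Sr, atol=1e-8)


def test_masking_strong_effect_disfavored(fitted_small_cohort, dynamic_spec,
                                          dynamic_priors):
    subjects, _, posts = fitted_small_cohort
    X = build_design_matrix(subjects)
    peb = fit_peb(posts, X, dynamic_priors,
                  param_names=dynamic_spec.param_names)
    dF, *_ = bayesian_model_reduction(peb, [("x0:putamen", "group")])
    assert dF < 0


def test_masking_whole_mean_column_rejected():
    peb, *_ = _toy_peb()
    with pytest.raises(SelectionError):
        bayesian_model_reduction(peb, [(a, 0) for a in range(peb.n_params)])


# ---------------------------------------------------------------------------
# model averaging
# ---------------------------------------------------------------------------

def test_equal_evidence_entry_has_pp_half():
    peb, *_ = _toy_peb(seed=5)
    e = peb.entry_index(0, 1)
    # engineer the posterior mean so the on/off comparison is exactly even
    mu = peb.beta.T.reshape(-1)
    S = peb.beta_covariance
    v0 = peb.beta_prior_variance[e]
    delta = 1 / OFF_VARIANCE - 1 / v0
    denom = 1 + delta * S[e, e]
    mu_e = np.sqrt((np.log(v0 / OFF_VARIANCE) - np.log(denom)) * denom / delta)
    mu[e] = mu_e
    peb.beta = mu.reshape(peb.n_cols, peb.n_params).T
    bma = bma_average(peb)
    assert bma.posterior_probs[0, 1] == pytest.approx(0.5, abs=1e-6)


def test_greedy_and_exhaustive_agree_on_toy():
    peb, *_ = _toy_peb(seed=13, p=2, c=3)  # 4 switchable entries
    g = bma_average(peb, search="greedy")
    x = bma_average(peb, search="exhaustive")
    np.testing.assert_array_equal(g.surviving, x.surviving)
    np.testing.assert_allclose(g.estimates, x.estimates, atol=0.15)


def test_exhaustive_refused_beyond_twenty_entries():
    peb, *_ = _toy_peb(seed=1, p=8, c=4)  # 24 switchable
    with pytest.raises(SelectionError):
        bma_average(peb, search="exhaustive")


def test_strong_group_effect_survives_null_covariate_pruned(
        fitted_small_cohort, dynamic_spec, dynamic_priors):
    subjects, _, posts = fitted_small_cohort
    X = build_design_matrix(subjects)
    peb = fit_peb(posts, X, dynamic_priors,
                  param_names=dynamic_spec.param_names)
    bma = bma_average(peb)
    a = bma.param_names.index("x0:putamen")
    jg = bma.column_labels.index("group")
    jgen = bma.column_labels.index("gender")
    assert bma.posterior_probs[a, jg] > 0.95
    assert bma.posterior_probs[a, jgen] < 0.95


# ---------------------------------------------------------------------------
# hierarchical model comparison
# ---------------------------------------------------------------------------

def _cohort_from_constant_model(seed, n_per_group=8):
    """Cohort whose volumes follow a constant-rate (linear) model.

    Rates are steepened so that linear and exponential trajectories are
    distinguishable above the measurement noise within the visit window.
    """
    rng = np.random.default_rng(seed)
    from hdprog.regions import STATE_LOBES, STATE_NAMES
    steep = {name: (0.05 if STATE_LOBES[name] == "striatal" else 0.02)
             for name in STATE_NAMES}
    config = CohortConfig(seed=seed, n_hd=n_per_group, n_control=n_per_group,
                          true_decay={"HD": steep,
                                      "control": {n: 0.01 for n in STATE_NAMES}},
                          cag_slope={n: 0.0 for n in STATE_NAMES})
    subjects, series = generate_cohort(config)
    spec = StateModelSpec(form="constant_rate")
    out = []
    for subj, ts in zip(subjects, series):
        a = _decay_a(config, subj.group, subj.cag)
        x0 = config.x0_for_subject(subj.group)
        params = SubjectParams(x0=x0, rate_c0=a * x0)  # matched linear slope
        traj = integrate_states(spec, params, ts.times)
        vols = traj.states[:, REGION_STATE_INDEX] \
            + rng.normal(0, config.noise_sd, ts.volumes.shape)
        out.append(RegionalTimeSeries(subject_id=ts.subject_id,
                                      times=ts.times,
                                      volumes=np.maximum(vols, 1e-3)))
    return subjects, out


def test_constant_rate_recovered_when_generating():
    from hdprog.peb import PEBSettings
    from hdprog.vl import VLSettings
    wins = 0
    for seed in range(3):
        subjects, series = _cohort_from_constant_model(700 + seed)
        cmp = select_state_model(
            subjects, series,
            vl_settings=VLSettings(streak=2),
            peb_settings=PEBSettings(g_xatol=0.3, g_max_sweeps=2))
        wins += cmp.winner == "constant_rate"
        assert len(cmp.model_ids) == 4
        assert cmp.posterior_probs.sum() == pytest.approx(1.0, abs=1e-9)
    assert wins >= 2


def test_connectivity_detected_when_simulated():
    rng = np.random.default_rng(6)
    config = CohortConfig(seed=301, n_hd=8, n_control=8)
    subjects, series = generate_cohort(config)
    edges = edge_preset("striatal_cortical")
    espec = StateModelSpec(form="dynamic", connectivity_edges=edges)
    edged = []
    for subj, ts in zip(subjects, series):
        a = _decay_a(config, subj.group, subj.cag)
        w = rng.uniform(0.005, 0.02, len(edges)) if subj.group == "HD" \
            else np.zeros(len(edges))
        params = SubjectParams(x0=config.x0_for_subject(subj.group),
                               log_decay=np.log(np.clip(-a, 1e-8, None)),
                               edge_weights=w)
        traj = integrate_states(espec, params, ts.times)
        vols = traj.states[:, REGION_STATE_INDEX] \
            + rng.normal(0, 1.0, ts.volumes.shape)
        edged.append(RegionalTimeSeries(subject_id=ts.subject_id,
                                        times=ts.times,
                                        volumes=np.maximum(vols, 1e-3)))
    cmp = compare_connectivity_models(subjects, edged)
    assert np.all(np.isfinite(cmp.free_energies))
    assert cmp.winner != "diagonal"
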