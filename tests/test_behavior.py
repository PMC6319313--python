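"""Deconfounding, RT correlations, prototypical sequences, RT prediction."""

import numpy as np
import pytest

from tuda.behavior import (
    build_rt_design,
    deconfound,
    predict_rt_cv,
    prototypical_sequences,
    sequence_lead,
    timewise_rt_correlation,
)


# ---------------------------------------------------------------------------
# deconfounding
# ---------------------------------------------------------------------------


def test_deconfound_removes_a_perfectly_confounded_signal(rng):
    confound = rng.uniform(size=50)
    values = 2.0 * confound
    resid = deconfound(values, confound)
    np.testing.assert_allclose(resid, 0.0, atol=1e-10)


def test_deconfound_residuals_are_orthogonal_to_confound(rng):
    confound = rng.uniform(size=80)
    values = rng.normal(size=(80, 3))
    resid = deconfound(values, confound)
    for j in range(3):
        assert abs(np.corrcoef(resid[:, j], confound)[0, 1]) < 1e-10
    assert np.allclose(resid.mean(axis=0), 0.0, atol=1e-12)


def test_deconfound_matches_normal_equations_on_four_trials():
    confound = np.array([0.0, 1.0, 2.0, 3.0])
    values = np.array([1.0, 3.0, 2.0, 6.0])
    Z = np.column_stack([np.ones(4), confound])
    beta = np.linalg.solve(Z.T @ Z, Z.T @ values)
    np.testing.assert_allclose(deconfound(values, confound), values - Z @ beta, atol=1e-12)


def test_deconfound_is_idempotent(rng):
    confound = rng.uniform(size=40)
    values = rng.normal(size=40)
    once = deconfound(values, confound)
    twice = deconfound(once, confound)
    np.testing.assert_allclose(once, twice, atol=1e-12)


def test_constant_confound_mean_centers_with_warning():
    with pytest.warns(RuntimeWarning, match="constant"):
        resid = deconfound(np.array([1.0, 2.0, 3.0]), np.ones(3))
    np.testing.assert_allclose(resid, [-1.0, 0.0, 1.0])


# ---------------------------------------------------------------------------
# time-resolved RT correlation and prototypical sequences
# ---------------------------------------------------------------------------


def _shifted_gamma(n_trials, T, K, shifts, block=10):
    """One-hot K-state sequential time courses shifted per trial."""
    gamma = np.zeros((n_trials, T, K))
    for s in range(n_trials):
        bounds = np.cumsum([block] * (K - 1)) + shifts[s]
        path = np.zeros(T, dtype=int)
        for b in bounds:
            path[max(b, 0):] += 1
        path = np.minimum(path, K - 1)
        gamma[s, np.arange(T), path] = 1.0
    return gamma


def test_rt_correlation_is_null_when_rt_is_independent(rng):
    gamma = rng.dirichlet(np.ones(3), size=(40, 20))
    rt = rng.uniform(0.3, 0.8, size=40)
    out = timewise_rt_correlation(gamma, rt, n_permutations=300, seed=0)
    # no (t, k) cell should be extreme relative to its permutation null
    assert (out["p_values"] > 0.001).all()


def test_rt_correlation_detects_state_timing_link(rng):
    # later state-2 onset <-> longer RT
    shifts = rng.integers(-5, 6, size=60)
    gamma = _shifted_gamma(60, 40, 3, shifts)
    rt = 0.3 + 0.02 * shifts + rng.normal(0, 0.002, size=60)
    out = timewise_rt_correlation(gamma, rt)
    corr = out["correlation"]
    # around the state-0/1 boundary (t=10): being still in state 0 on a trial
    # means a late shift, hence positive correlation with RT
    assert corr[10, 0] > 0.5
    assert corr[10, 1] < -0.5


def test_no_press_trials_are_excluded():
    gamma = np.zeros((6, 4, 2))
    gamma[:, :, 0] = 1.0
    rt = np.array([0.5, np.nan, 0.4, 0.6, np.nan, 0.7])
    out = timewise_rt_correlation(gamma, rt)
    assert out["included"].sum() == 4
    assert out["zero_variance"].all()
    np.testing.assert_allclose(out["correlation"], 0.0)


def test_mirror_image_corr_curves_give_antisymmetric_sequences():
    t = np.linspace(0.2, 6.0, 30)
    curves = np.column_stack([np.sin(t), -np.sin(t)])
    short, long = prototypical_sequences(curves)
    informative = np.abs(np.sin(t)) > 1e-3  # exact ties resolve to state 0
    np.testing.assert_array_equal(short[informative], 1 - long[informative])


def test_prototypical_sequences_recover_the_construction_lead(rng):
    """Two trial groups whose paths differ by a known shift.

    State probabilities carry RT information only inside the transition
    windows; there the short-RT prototype shows the state the fast group has
    already reached and the long-RT prototype the state the slow group still
    occupies.  The long sequence therefore replays the short one delayed by
    the inter-boundary spacing (the intermediate state's dwell), which is
    the identifiable lead of the construction.
    """
    lag, block = 6, 15
    shifts = np.where(np.arange(80) % 2 == 0, 0, lag)
    gamma = _shifted_gamma(80, 50, 3, shifts, block=block)
    gamma = np.clip(gamma + rng.normal(0, 0.02, gamma.shape), 0, 1)
    rt = 0.3 + 0.01 * shifts + rng.normal(0, 0.001, 80)
    out = timewise_rt_correlation(gamma, rt)
    short, long = prototypical_sequences(out["correlation"])
    w = np.abs(out["correlation"]).max(axis=1)
    lead = sequence_lead(short, long, max_lag=25, weights=w)
    assert abs(lead - block) <= 1


def test_literal_convention_swaps_the_sequences(rng):
    curves = rng.normal(size=(20, 3))
    s1, l1 = prototypical_sequences(curves, convention="fast-negative")
    s2, l2 = prototypical_sequences(curves, convention="fast-positive")
    np.testing.assert_array_equal(s1, l2)
    np.testing.assert_array_equal(l1, s2)


# ---------------------------------------------------------------------------
# RT design and prediction
# ---------------------------------------------------------------------------


def test_constant_time_courses_give_all_zero_scores():
    gamma = np.ones((30, 12, 1))
    rt = np.linspace(0.3, 0.8, 30)
    design = build_rt_design(gamma, rt, n_pcs=5)
    np.testing.assert_allclose(design.features, 0.0, atol=1e-12)


def test_full_basis_pca_is_lossless_for_prediction(rng):
    T = 8
    gamma = rng.dirichlet(np.ones(2), size=(40, T))
    rt = rng.uniform(0.3, 0.8, size=40)
    design = build_rt_design(gamma, rt, n_pcs=T)
    # raw (deconfounded) curves are reconstructable from the full score basis:
    # regression of rt on scores equals regression on centered raw curves
    from tuda.behavior import deconfound as _d

    raw = gamma[:, :, 0] - gamma[:, :, 0].mean(axis=0)
    Z1 = design.features[:, :T]
    pred_scores = Z1 @ np.linalg.lstsq(Z1, rt, rcond=None)[0]
    pred_raw = raw @ np.linalg.lstsq(raw, rt, rcond=None)[0]
    np.testing.assert_allclose(pred_scores, pred_raw, atol=1e-8)


def test_truncation_error_matches_eigenvalue_tail(rng):
    gamma = rng.normal(size=(60, 10, 1))
    rt = rng.uniform(size=60)
    n_pcs = 4
    design = build_rt_design(gamma, rt, n_pcs=n_pcs)
    centered = gamma[:, :, 0] - gamma[:, :, 0].mean(axis=0)
    cov_eigs = np.sort(np.linalg.eigvalsh(centered.T @ centered))[::-1]
    # captured variance equals the sum of the leading eigenvalues
    captured = (design.features**2).sum()
    np.testing.assert_allclose(captured, cov_eigs[:n_pcs].sum(), rtol=1e-8)


def test_build_design_errors_with_too_few_trials():
    gamma = np.ones((4, 10, 1))
    rt = np.array([0.5, 0.6, np.nan, 0.7])
    with pytest.raises(ValueError, match="usable trials"):
        build_rt_design(gamma, rt, n_pcs=25)


def test_rt_prediction_recovers_planted_sparse_signal(rng):
    n, p = 200, 40
    X = rng.normal(size=(n, p))
    beta = np.zeros(p)
    beta[[3, 17, 31]] = [1.0, -0.8, 0.6]
    y = X @ beta + rng.normal(0, 0.3, size=n)
    design_subject = np.repeat(np.arange(4), 50)
    design = type("D", (), {})()
    from tuda.behavior import RtDesign

    design = RtDesign(
        features=X, rt_deconf=y, included=np.ones(n, bool), subject=design_subject, n_pcs=p
    )
    out = predict_rt_cv(design, seed=0)
    assert out["r"] > 0.8
    assert (np.asarray(out["fold"]) >= 0).all()


def test_rt_prediction_null_when_rt_is_noise(rng):
    from tuda.behavior import RtDesign

    n, p = 120, 20
    design = RtDesign(
        features=rng.normal(size=(n, p)),
        rt_deconf=rng.normal(size=n),
        included=np.ones(n, bool),
        subject=np.repeat(np.arange(3), 40),
        n_pcs=p,
    )
    out = predict_rt_cv(design, seed=1, n_permutations=60)
    assert out["p_perm"] > 0.05
    assert abs(out["r"]) < 0.4


def test_prediction_never_uses_a_trials_own_rt(rng):
    """Fold bookkeeping: each trial is predicted exactly once, from a model
    fitted without its subject's trials."""
    from tuda.behavior import RtDesign

    n, p = 90, 10
    subject = np.repeat(np.arange(3), 30)
    X = rng.normal(size=(n, p))
    y = X[:, 0] + rng.normal(0, 0.1, size=n)
    design = RtDesign(
        features=X, rt_deconf=y, included=np.ones(n, bool), subject=subject, n_pcs=p
    )
    out = predict_rt_cv(design, seed=0)
    folds = np.asarray(out["fold"])
    assert set(np.unique(folds)) == {0, 1, 2}
    for i in range(3):
        np.testing.assert_array_equal(np.unique(subject[folds == i]), [i])


def test_small_subject_folds_are_excluded_with_warning(rng):
    from tuda.behavior import RtDesign

    subject = np.array([0] * 40 + [1] * 40 + [2] * 2)
    X = rng.normal(size=(82, 5))
    y = X[:, 0] + rng.normal(0, 0.1, size=82)
    design = RtDesign(
        features=X, rt_deconf=y, included=np.ones(82, bool), subject=subject, n_pcs=5
    )
    with pytest.warns(RuntimeWarning, match="excluded"):
        out = predict_rt_cv(design, seed=0)
    assert (np.asarray(out["fold"])[subject == 2] == -1).all()
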