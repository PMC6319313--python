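"""The decoding-state model: initialization, EM, VB and recovery properties."""

import itertools

import numpy as np
import pytest

from tuda.datasets import EpochedDataset
from tuda.model import (
    TUDA,
    cluster_initialize,
    dwell_and_occupancy_stats,
    em_refine_synchronous,
    infer_state_dynamics,
    match_states,
    oracle_decoding_weights,
    predict_stimulus,
    state_log_likelihoods,
)
from tuda.simulate import LinearStateSimSpec, simulate_linear_states
from tuda.standard import divergence_matrix, error_matrix, fit_pointwise_decoders


def _dataset(X, Y, fs=100.0):
    return EpochedDataset(X=np.asarray(X, float), Y=np.asarray(Y, float), sampling_rate=fs)


# ---------------------------------------------------------------------------
# clustering initialization
# ---------------------------------------------------------------------------


def test_cluster_init_splits_two_regimes_at_the_true_changepoint(synchronous_two_state):
    _, data, truth = synchronous_two_state
    v = fit_pointwise_decoders(data)
    D = divergence_matrix(error_matrix(data, v))
    W, labels = cluster_initialize(data, D, 2)
    change = np.flatnonzero(np.diff(labels))
    assert len(change) == 1
    true_change = np.flatnonzero(np.diff(truth.state_path[0]))
    assert change[0] == true_change[0]


def test_cluster_init_with_K_equal_T_reproduces_pointwise_decoders(rng):
    X = rng.normal(size=(20, 6, 4))
    Y = rng.normal(size=(20, 2))
    data = _dataset(X, Y)
    v = fit_pointwise_decoders(data)
    D = divergence_matrix(error_matrix(data, v))
    W, labels = cluster_initialize(data, D, 6)
    assert len(np.unique(labels)) == 6
    np.testing.assert_allclose(W[labels], v, atol=1e-6)


@pytest.fixture(scope="module")
def sequential_recovery_fit():
    """Full-size sequential benchmark at moderate jitter, fitted once."""
    spec = LinearStateSimSpec(seed=3, dwell_dispersions=(0.02, 0.03, 0.04, 0.05, 0.06))
    data, truth = simulate_linear_states(spec)
    res = TUDA(data, K=5).fit()
    return data, truth, res


def test_cluster_init_recovers_near_contiguous_blocks_on_sequential_data(
    sequential_recovery_fit,
):
    data, _, _ = sequential_recovery_fit
    v = fit_pointwise_decoders(data)
    D = divergence_matrix(error_matrix(data, v))
    _, labels = cluster_initialize(data, D, 5)
    assert len(np.unique(labels)) == 5
    # blocks are ordered in time and contiguous up to fuzzy boundaries
    assert np.mean(labels == np.sort(labels)) >= 0.97


# ---------------------------------------------------------------------------
# synchronous EM
# ---------------------------------------------------------------------------


def test_em_at_ground_truth_on_noiseless_synchronous_data_is_a_fixed_point():
    spec = LinearStateSimSpec(
        n_trials=20,
        n_timepoints=100,
        sampling_rate=100.0,
        n_states=2,
        n_channels=10,
        active_channels_per_state=4,
        noise_sd=0.0,
        dwell_means=(0.5, 0.5),
        dwell_dispersions=(0.0, 0.0),
        seed=1,
    )
    data, truth = simulate_linear_states(spec)
    # noiseless disjoint-support data are rank-deficient: the tiny auto ridge applies
    W0 = oracle_decoding_weights(data.X, data.Y, truth.state_path, 2, ridge="auto")
    W, noise_var, assignment, sse = em_refine_synchronous(data, W0)
    assert sse[-1] < 1e-8
    np.testing.assert_array_equal(assignment, truth.state_path[0])


def test_em_sse_trace_is_monotone_non_increasing(small_sequential):
    _, data, _ = small_sequential
    v = fit_pointwise_decoders(data)
    D = divergence_matrix(error_matrix(data, v))
    W0, _ = cluster_initialize(data, D, 5)
    _, _, _, sse = em_refine_synchronous(data, W0)
    assert (np.diff(sse) <= 1e-9 * max(1.0, sse[0])).all()


def test_em_assignment_matches_exhaustive_search_on_tiny_problem(rng):
    """3 timepoints, 2 states: compare with the best of all 2^3 assignments."""
    X = rng.normal(size=(12, 3, 2))
    Y = rng.normal(size=(12, 1))
    data = _dataset(X, Y)
    W0 = np.stack([fit_pointwise_decoders(data)[t] for t in (0, 2)])
    W, _, assignment, _ = em_refine_synchronous(data, W0, ridge=None)

    def assignment_sse(assign):
        sse = 0.0
        for k in range(2):
            idx = [t for t in range(3) if assign[t] == k]
            if not idx:
                continue
            Xk = X[:, idx, :].reshape(-1, 2)
            Yk = np.tile(Y, (len(idx), 1))
            Yk = np.vstack([Y for _ in idx])
            wk = np.linalg.lstsq(Xk, Yk, rcond=None)[0]
            sse += np.sum((Xk @ wk - Yk) ** 2)
        return sse

    best = min(itertools.product(range(2), repeat=3), key=assignment_sse)
    assert assignment_sse(tuple(assignment)) <= assignment_sse(best) + 1e-9


def test_em_soft_mode_runs_and_does_not_increase_noise_variance_wildly(small_sequential):
    _, data, _ = small_sequential
    v = fit_pointwise_decoders(data)
    D = divergence_matrix(error_matrix(data, v))
    W0, _ = cluster_initialize(data, D, 5)
    _, nv_hard, _, _ = em_refine_synchronous(data, W0)
    _, nv_soft, _, _ = em_refine_synchronous(data, W0, soft=True)
    assert 0 < nv_soft < 10 * nv_hard


# ---------------------------------------------------------------------------
# state log-likelihoods
# ---------------------------------------------------------------------------


def test_loglik_peak_equals_gaussian_normalizing_constant():
    X = np.ones((2, 3, 1))
    Y = np.full((2, 2), 0.5)
    W = np.array([[[0.5, 0.5]]])  # exact prediction, zero residual
    ll = state_log_likelihoods(_dataset(X, Y), W, noise_var=0.25)
    expected = -0.5 * 2 * np.log(2 * np.pi * 0.25)
    np.testing.assert_allclose(ll, expected)


def test_loglik_matches_scipy_gaussian_density(rng):
    from scipy.stats import norm

    X = rng.normal(size=(3, 4, 2))
    Y = rng.normal(size=(3, 2))
    W = rng.normal(size=(2, 2, 2))
    nv = 0.7
    ll = state_log_likelihoods(_dataset(X, Y), W, nv)
    s, t, k = 1, 2, 1
    pred = X[s, t] @ W[k]
    expected = norm.logpdf(Y[s], loc=pred, scale=np.sqrt(nv)).sum()
    np.testing.assert_allclose(ll[s, t, k], expected, atol=1e-12)


def test_equal_residuals_give_equal_loglik(rng):
    X = rng.normal(size=(2, 3, 2))
    Y = rng.normal(size=(2, 1))
    W = np.stack([np.zeros((2, 1)), np.zeros((2, 1))])
    ll = state_log_likelihoods(_dataset(X, Y), W, 1.0)
    np.testing.assert_allclose(ll[..., 0], ll[..., 1])


# ---------------------------------------------------------------------------
# variational stage
# ---------------------------------------------------------------------------


def test_vb_free_energy_is_monotone_non_decreasing(small_sequential, rng):
    _, data, _ = small_sequential
    res = TUDA(data, K=5).fit()
    fe = res.free_energy
    assert (np.diff(fe) >= -1e-6 * np.abs(fe[0])).all()
    # also on random likelihoods
    ll = rng.normal(size=(10, 30, 3))
    vb = infer_state_dynamics(ll, max_iter=50)
    assert (np.diff(vb.free_energy) >= -1e-8 * abs(vb.free_energy[0])).all()


def test_vb_transition_posterior_concentrates_on_a_single_path():
    # all trials follow the same hard path 0,0,1,1,2,2 with near-certain evidence
    T, K = 6, 3
    path = np.array([0, 0, 1, 1, 2, 2])
    ll = np.full((20, T, K), -50.0)
    ll[:, np.arange(T), path] = 0.0
    vb = infer_state_dynamics(ll, max_iter=100)
    # row 0 counts: 20 self-transitions, 20 to state 1, Dirichlet(1) prior
    # -> posterior mean ~ (21/43, 21/43, 1/43)
    Theta = vb.Theta
    assert Theta[0, 0] > 0.45 and Theta[0, 1] > 0.45
    assert Theta[0, 2] < 0.05 and Theta[1, 0] < 0.05 and Theta[2, 0] < 0.05
    np.testing.assert_allclose(vb.gamma[:, np.arange(T), path], 1.0, atol=1e-6)


# ---------------------------------------------------------------------------
# full fit: reductions, invariances, recovery
# ---------------------------------------------------------------------------


def test_one_state_model_reduces_to_pooled_ols(rng):
    X = rng.normal(size=(15, 20, 4))
    Y = rng.normal(size=(15, 2))
    data = _dataset(X, Y)
    res = TUDA(data, K=1).fit()
    Xf = X.reshape(-1, 4)
    Yf = np.repeat(Y, 20, axis=0)
    w_pooled = np.linalg.lstsq(Xf, Yf, rcond=None)[0]
    np.testing.assert_allclose(res.W[0], w_pooled, atol=1e-6)
    np.testing.assert_allclose(res.gamma, 1.0)
    pred = res.predict()
    np.testing.assert_allclose(pred, np.einsum("stc,cf->stf", X, w_pooled), atol=1e-6)


def test_prediction_contract_one_hot_and_uniform_gamma(rng):
    X = rng.normal(size=(4, 5, 3))
    Y = rng.normal(size=(4, 2))
    data = _dataset(X, Y)
    W = rng.normal(size=(2, 3, 2))
    one_hot = np.zeros((4, 5, 2))
    one_hot[..., 1] = 1.0
    np.testing.assert_allclose(
        predict_stimulus(data, W, one_hot), np.einsum("stc,cf->stf", X, W[1]), atol=1e-12
    )
    Wsame = np.stack([W[0], W[0]])
    uniform = np.full((4, 5, 2), 0.5)
    np.testing.assert_allclose(
        predict_stimulus(data, Wsame, uniform),
        np.einsum("stc,cf->stf", X, W[0]),
        atol=1e-12,
    )
    # random mixture against hand computation at one sample
    g = np.random.default_rng(0).dirichlet(np.ones(2), size=(4, 5))
    pred = predict_stimulus(data, W, g)
    s, t = 2, 3
    np.testing.assert_allclose(
        pred[s, t], X[s, t] @ (g[s, t, 0] * W[0] + g[s, t, 1] * W[1]), atol=1e-12
    )


def test_label_permutation_consistency(small_sequential):
    _, data, _ = small_sequential
    res = TUDA(data, K=5, reorder_states=False).fit()
    perm = np.array([3, 0, 4, 1, 2])
    permuted = res.reordered(perm)
    np.testing.assert_allclose(permuted.gamma, res.gamma[:, :, perm])
    np.testing.assert_allclose(permuted.Theta, res.Theta[np.ix_(perm, perm)])
    np.testing.assert_allclose(permuted.pi, res.pi[perm])
    np.testing.assert_allclose(permuted.predict(), res.predict(), atol=1e-12)


def test_noiseless_low_jitter_fit_recovers_weights_and_paths_sharply():
    spec = LinearStateSimSpec(
        n_trials=40,
        n_timepoints=300,
        sampling_rate=150.0,
        noise_sd=0.0,
        dwell_means=(0.4, 0.5, 0.4, 0.4, 0.3),
        dwell_dispersions=(0.0,) * 5,
        seed=8,
    )
    data, truth = simulate_linear_states(spec)
    res = TUDA(data, K=5).fit()
    Wref = oracle_decoding_weights(data.X, data.Y, truth.state_path, 5, ridge="auto")
    perm = match_states(res.W, Wref)
    assert sorted(perm.tolist()) == [0, 1, 2, 3, 4]
    for k in range(5):
        assert np.abs(res.W[perm[k]] - Wref[k]).max() < 1e-5
    inv = np.empty(5, dtype=int)
    inv[perm] = np.arange(5)
    gamma_true = np.take_along_axis(
        res.gamma, inv[truth.state_path][..., None], axis=2
    )[..., 0]
    assert gamma_true.mean() > 0.99


def test_parameter_recovery_at_moderate_jitter(sequential_recovery_fit):
    """Hungarian-matched paths and weights recover the planted structure.

    The reference per state is the OLS decoder restricted to the true
    state's samples; sample-wise Viterbi agreement is checked against the
    information ceiling that moderate dwell jitter allows.
    """
    data, truth, res = sequential_recovery_fit
    Wref = oracle_decoding_weights(data.X, data.Y, truth.state_path, 5)
    perm = match_states(res.W, Wref)
    assert sorted(perm.tolist()) == [0, 1, 2, 3, 4]
    inv = np.empty(5, dtype=int)
    inv[perm] = np.arange(5)
    agreement = (inv[res.viterbi_paths()] == truth.state_path).mean()
    assert agreement >= 0.95
    for k in range(5):
        r = np.corrcoef(res.W[perm[k]].ravel(), Wref[k].ravel())[0, 1]
        assert r > 0.85


def test_fit_is_deterministic(synchronous_two_state):
    _, data, _ = synchronous_two_state
    r1 = TUDA(data, K=2).fit()
    r2 = TUDA(data, K=2).fit()
    np.testing.assert_array_equal(r1.gamma, r2.gamma)
    np.testing.assert_array_equal(r1.W, r2.W)


# ---------------------------------------------------------------------------
# dwell / occupancy statistics
# ---------------------------------------------------------------------------


def test_dwell_stats_on_synchronous_hard_paths_have_zero_onset_variance():
    paths = np.tile(np.repeat([0, 1, 2], 10), (6, 1))
    out = dwell_and_occupancy_stats(paths=paths, sampling_rate=10.0)
    onsets = out["per_trial"].query("state == 1")["first_onset_s"]
    assert onsets.var() == 0.0
    np.testing.assert_allclose(out["occupancy"].sum(axis=1), 1.0)
    np.testing.assert_allclose(
        out["per_state"]["mean_dwell_s"].to_numpy(), [1.0, 1.0, 1.0]
    )


def test_dwell_stats_counts_fragmented_visits():
    paths = np.array([[0, 1, 0, 0, 1, 1]])
    out = dwell_and_occupancy_stats(paths=paths, sampling_rate=1.0)
    visits = out["visits"]
    assert len(visits) == 4
    total0 = out["per_trial"].query("state == 0")["total_dwell_s"].iloc[0]
    assert total0 == 3.0


def test_summary_prints_states_one_based(synchronous_two_state):
    _, data, _ = synchronous_two_state
    res = TUDA(data, K=2).fit()
    text = res.summary()
    assert "states: 2" in text
    assert "\n    1  " in text and "\n    2  " in text
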