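"""Cross-validated accuracy, surrogate bias correction and encoding maps.

Cross-validating a model whose state time courses are themselves estimated
from the held-out stimulus is inherently biased: the "biased" scheme runs
forward-backward on held-out trials (using their stimulus) to pick the best
state mixture per timepoint, while the "unbiased" scheme reuses the
training-trials' mean state time course and so discards between-trial
variability.  Both raw accuracies are corrected by subtracting a baseline
obtained from label-permuted surrogate datasets evaluated through the same
pipeline; the result is the adjusted CV-R^2, which is comparable across
schemes and against the per-timepoint baseline.

Encoding weights reverse the regression (stimulus -> sensor) per state via
state-probability-weighted least squares, giving spatially interpretable
explained-variance maps.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
from sklearn.model_selection import KFold

from .datasets import EpochedDataset
from .hmm import forward_backward
from .model import TUDA, state_log_likelihoods, predict_stimulus

__all__ = [
    "CvReport",
    "EncodingModelSet",
    "crossvalidate_tuda",
    "surrogate_baseline",
    "adjusted_cvr2",
    "encoding_weights",
    "variability_vs_accuracy",
]


@dataclasses.dataclass
class CvFoldArtifacts:
    """Everything needed to re-score one fold on surrogate stimuli."""

    train: np.ndarray
    test: np.ndarray
    W: np.ndarray
    noise_var: float
    Theta: np.ndarray
    pi: np.ndarray
    gamma_train: np.ndarray  # (n_train, T, K)
    gamma_test: np.ndarray  # (n_test, T, K), estimated with the true stimulus


@dataclasses.dataclass
class CvReport:
    """Cross-validated accuracy of the decoding-state model, one scheme."""

    scheme: str
    K: int
    cvr2_pooled: float
    cvr2_timecourse: np.ndarray
    folds: int
    seed: int
    n_surrogates: int = 0
    surrogate_percentile: float = np.nan
    adjusted_cvr2: float = np.nan
    fold_artifacts: list[CvFoldArtifacts] | None = None

    def adjust(self, baseline: float) -> "CvReport":
        self.surrogate_percentile = float(baseline)
        self.adjusted_cvr2 = adjusted_cvr2(self.cvr2_pooled, baseline)
        return self


def _scheme_gamma(scheme: str, art: CvFoldArtifacts) -> np.ndarray:
    """Per-test-trial state time courses used for prediction under a scheme."""
    if scheme == "unbiased":
        gbar = art.gamma_train.mean(axis=0)  # (T, K)
        return np.broadcast_to(gbar, (len(art.test),) + gbar.shape)
    if scheme == "biased":
        return art.gamma_test
    raise ValueError(f"unknown CV scheme {scheme!r}; use 'unbiased' or 'biased'")


def _fold_sse(
    data: EpochedDataset,
    art: CvFoldArtifacts,
    scheme: str,
    W: np.ndarray | None = None,
    Y_override: np.ndarray | None = None,
) -> tuple[np.ndarray, float]:
    """Per-timepoint test SSE and the SST about the training-mean stimulus."""
    W = art.W if W is None else W
    Y = data.Y if Y_override is None else Y_override
    test_data = EpochedDataset(
        X=data.X[art.test], Y=Y[art.test], sampling_rate=data.sampling_rate
    )
    gamma = _scheme_gamma(scheme, art)
    pred = predict_stimulus(test_data, W, gamma)
    sse_t = ((pred - test_data.Y[:, None, :]) ** 2).sum(axis=(0, 2))
    sst = float(((Y[art.test] - Y[art.train].mean(axis=0)) ** 2).sum())
    return sse_t, sst


def crossvalidate_tuda(
    data: EpochedDataset,
    K: int | list[int],
    scheme: str = "unbiased",
    folds: int = 10,
    seed: int = 0,
    *,
    keep_artifacts: bool = False,
    **fit_options,
) -> CvReport | list[CvReport]:
    """Cross-validated (pre-adjustment) accuracy of the decoding-state model.

    Per fold the full three-stage model is fitted on the training trials;
    held-out prediction uses either the training-mean state time course at
    each timepoint (``scheme="unbiased"``) or trial-specific time courses
    from forward-backward on the held-out trials, which peeks at their
    stimulus (``scheme="biased"``).  CV-R^2 is ``1 - SSE/SST`` pooled over
    folds, test trials, timepoints and features, with SST about the
    training-fold stimulus mean.  ``K`` may be a list, one report per value.
    """
    if isinstance(K, (list, tuple, np.ndarray)):
        return [
            crossvalidate_tuda(
                data, int(k), scheme, folds, seed, keep_artifacts=keep_artifacts, **fit_options
            )
            for k in K
        ]
    if folds < 2:
        raise ValueError("need at least 2 folds")
    if scheme not in ("unbiased", "biased"):
        raise ValueError(f"unknown CV scheme {scheme!r}; use 'unbiased' or 'biased'")

    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    T = data.n_timepoints
    sse_t = np.zeros(T)
    sst_total = 0.0
    artifacts: list[CvFoldArtifacts] = []
    for train, test in kf.split(np.arange(data.n_trials)):
        res = TUDA(data.subset(train), K, **fit_options).fit()
        test_data = data.subset(test)
        ll = state_log_likelihoods(test_data, res.W, res.noise_var)
        stc = forward_backward(ll, res.Theta, res.pi, compute_xi=False)
        art = CvFoldArtifacts(
            train=train,
            test=test,
            W=res.W,
            noise_var=res.noise_var,
            Theta=res.Theta,
            pi=res.pi,
            gamma_train=res.gamma,
            gamma_test=stc.gamma,
        )
        artifacts.append(art)
        fold_sse_t, fold_sst = _fold_sse(data, art, scheme)
        sse_t += fold_sse_t
        sst_total += fold_sst

    # sst_total sums over test trials and features once; predictions exist at
    # every timepoint, so the pooled denominator counts it T times
    cvr2_pooled = 1.0 - sse_t.sum() / (sst_total * T)
    cvr2_timecourse = 1.0 - sse_t / sst_total
    return CvReport(
        scheme=scheme,
        K=K,
        cvr2_pooled=float(cvr2_pooled),
        cvr2_timecourse=cvr2_timecourse,
        folds=folds,
        seed=seed,
        fold_artifacts=artifacts if keep_artifacts else None,
    )


def _refit_weights_fixed_gamma(
    X: np.ndarray, Y: np.ndarray, gamma: np.ndarray, ridge_scale: float = 1e-8
) -> np.ndarray:
    """Weighted LS refit of state weights with the time courses held fixed.

    ``w_k = (sum_st g_stk x x')^-1 (sum_st g_stk x y')`` over the given
    trials; a tiny data-scaled ridge guards ill-conditioning.
    """
    K = gamma.shape[2]
    C = X.shape[2]
    Mx = np.einsum("stk,stc->skc", gamma, X, optimize=True)
    H = np.einsum("sf,skc->kcf", Y, Mx, optimize=True)
    G = np.einsum("stk,stc,std->kcd", gamma, X, X, optimize=True)
    lam = ridge_scale * np.einsum("kcc->k", G) / C
    G = G + lam[:, None, None] * np.eye(C)
    return np.linalg.solve(G, H)


def surrogate_baseline(
    data: EpochedDataset,
    report: CvReport,
    scheme: str | None = None,
    n_surrogates: int = 100,
    seed: int = 0,
    *,
    percentile: float = 5.0,
    refit_weights: bool = True,
) -> tuple[float, np.ndarray]:
    """Label-permutation baseline for the chosen cross-validation scheme.

    Each surrogate permutes the stimulus rows across trials and re-runs the
    scoring pipeline reusing the already-estimated state time courses: the
    state weights are refit per fold against the permuted stimulus with the
    time courses fixed (set ``refit_weights=False`` to freeze them), then the
    fold is scored exactly as the original run.  Returns the requested
    percentile (default the 5th) of the surrogate pooled CV-R^2 distribution
    and the full surrogate vector.
    """
    if report.fold_artifacts is None:
        raise ValueError("run crossvalidate_tuda with keep_artifacts=True first")
    if n_surrogates < 1:
        raise ValueError("n_surrogates must be >= 1")
    if n_surrogates < 20:
        warnings.warn(
            "fewer than 20 surrogates gives an unstable 5% percentile", RuntimeWarning
        )
    scheme = scheme or report.scheme
    rng = np.random.default_rng(seed)
    values = np.empty(n_surrogates)
    for i in range(n_surrogates):
        perm = rng.permutation(data.n_trials)
        Yp = data.Y[perm]
        sse = 0.0
        sst = 0.0
        for art in report.fold_artifacts:
            W = art.W
            if refit_weights:
                W = _refit_weights_fixed_gamma(
                    data.X[art.train], Yp[art.train], art.gamma_train
                )
            fold_sse_t, fold_sst = _fold_sse(data, art, scheme, W=W, Y_override=Yp)
            sse += fold_sse_t.sum()
            sst += fold_sst * data.n_timepoints
        values[i] = 1.0 - sse / sst
    return float(np.percentile(values, percentile)), values


def adjusted_cvr2(raw: float, baseline: float) -> float:
    """Bias-corrected accuracy: raw pooled CV-R^2 minus the surrogate baseline."""
    return float(raw - baseline)


# ---------------------------------------------------------------------------
# encoding models
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class EncodingModelSet:
    """Per-sensor, per-state encoding weights and explained-variance maps."""

    B: np.ndarray  # (sensors, K, features)
    ev_map: np.ndarray  # (sensors, K)
    ev_sum: np.ndarray  # (sensors,)


def encoding_weights(
    data: EpochedDataset, gamma: np.ndarray, *, ridge_scale: float = 0.0
) -> EncodingModelSet:
    """State-wise encoding models by gamma-weighted least squares.

    For sensor l and state k the encoding weights solve
    ``b_lk = (Y' diag(g_k) Y)^-1 (Y' diag(g_k) X^l)`` over the concatenated
    (trial, timepoint) samples; the stimulus is constant within trial, so the
    weighted Gram matrix reduces to per-trial sums of the time courses.
    ``ev_map`` holds the weighted R^2 of predicting each sensor from the
    stimulus under each state's weighting, ``ev_sum`` its sum over states.
    """
    X, Y = data.X, data.Y
    S, T, C = X.shape
    K = gamma.shape[2]
    if gamma.shape[:2] != (S, T):
        raise ValueError("gamma and data disagree on trials/timepoints")

    w_trial = gamma.sum(axis=1)  # (S, K): total state mass per trial
    G = np.einsum("sk,sf,sg->kfg", w_trial, Y, Y, optimize=True)  # (K, F, F)
    Mx = np.einsum("stk,stc->skc", gamma, X, optimize=True)
    H = np.einsum("sf,skc->kfc", Y, Mx, optimize=True)  # (K, F, C)
    if ridge_scale > 0:
        F = Y.shape[1]
        lam = ridge_scale * np.einsum("kff->k", G) / F
        G = G + lam[:, None, None] * np.eye(F)
    try:
        b = np.linalg.solve(G, H)  # (K, F, C)
    except np.linalg.LinAlgError:
        warnings.warn("weighted Gram matrix singular; applying ridge fallback", RuntimeWarning)
        F = Y.shape[1]
        lam = 1e-8 * np.einsum("kff->k", G) / F
        b = np.linalg.solve(G + lam[:, None, None] * np.eye(F), H)

    # weighted explained variance per (sensor, state)
    sum_w = np.maximum(w_trial.sum(axis=0), 1e-300)  # (K,)
    sum_gx = Mx.sum(axis=0)  # (K, C): sum_st g x
    sum_gx2 = np.einsum("stk,stc->kc", gamma, X**2, optimize=True)
    pred = np.einsum("sf,kfc->skc", Y, b, optimize=True)  # (S, K, C)
    sse = (
        sum_gx2
        - 2.0 * np.einsum("skc,skc->kc", pred, Mx, optimize=True)
        + np.einsum("sk,skc->kc", w_trial, pred**2, optimize=True)
    )
    ss_tot = sum_gx2 - sum_gx**2 / sum_w[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        ev = np.where(ss_tot > 0, 1.0 - sse / ss_tot, 0.0)
    ev_map = ev.T  # (sensors, K)
    return EncodingModelSet(B=b.transpose(2, 0, 1), ev_map=ev_map, ev_sum=ev_map.sum(axis=1))


def variability_vs_accuracy(
    gamma: np.ndarray,
    cvr2_timecourse: np.ndarray,
    *,
    n_permutations: int = 10_000,
    seed: int = 0,
) -> dict:
    """Across-trial state-assignment variability versus per-time accuracy.

    Per timepoint, variability is the across-trial variance of the state
    time courses summed over states; this is paired with the CV-R^2 time
    course and summarized by a Pearson correlation with a permutation
    p-value (timepoints shuffled).
    """
    T = gamma.shape[1]
    if cvr2_timecourse.shape[0] != T:
        raise ValueError("time axes of gamma and the accuracy curve differ")
    variance = gamma.var(axis=0).sum(axis=1)  # (T,)
    acc = np.asarray(cvr2_timecourse, dtype=float)
    if variance.std() == 0 or acc.std() == 0:
        return {
            "variance": variance,
            "accuracy": acc,
            "correlation": np.nan,
            "p_value": np.nan,
        }
    r = float(np.corrcoef(variance, acc)[0, 1])
    p = np.nan
    if n_permutations > 0:
        rng = np.random.default_rng(seed)
        vc = variance - variance.mean()
        ac = acc - acc.mean()
        denom = np.sqrt((vc**2).sum() * (ac**2).sum())
        null = np.empty(n_permutations)
        for i in range(n_permutations):
            null[i] = (vc[rng.permutation(T)] * ac).sum() / denom
        p = float((1 + np.sum(np.abs(null) >= abs(r))) / (1 + n_permutations))
    return {"variance": variance, "accuracy": acc, "correlation": r, "p_value": p}
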