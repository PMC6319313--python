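"""Relating trial-specific state timing to reaction time.

The state time courses carry when each decoding state becomes active on each
trial; if that timing has a neural origin it should co-vary with behavior.
This module implements the full chain: regressing the task confound (the
absolute relative angle) out of both the time courses and the reaction
times, time-resolved correlations between state probabilities and RT,
prototypical fast/slow-trial state sequences, and cross-validated RT
prediction from PCA-compressed time courses with sparse (lasso) regression
and leave-one-subject-out folds.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
from sklearn.linear_model import Lasso, LassoCV
from sklearn.model_selection import KFold

__all__ = [
    "RtDesign",
    "deconfound",
    "timewise_rt_correlation",
    "prototypical_sequences",
    "sequence_lead",
    "build_rt_design",
    "predict_rt_cv",
]


def deconfound(values: np.ndarray, confound: np.ndarray) -> np.ndarray:
    """Residualize per-trial values against a confound (intercept included).

    ``values`` may be 1-D (one value per trial) or 2-D with trials on axis 0;
    residuals are exactly uncorrelated with the confound.  A constant
    confound only removes the mean (with a warning).
    """
    values = np.asarray(values, dtype=float)
    confound = np.asarray(confound, dtype=float).ravel()
    n = confound.shape[0]
    if values.shape[0] != n:
        raise ValueError("values and confound must share the trial axis")
    flat = values.reshape(n, -1)
    if np.ptp(confound) == 0:
        warnings.warn("constant confound: returning mean-centered values", RuntimeWarning)
        resid = flat - flat.mean(axis=0)
        return resid.reshape(values.shape)
    Z = np.column_stack([np.ones(n), confound])
    beta, *_ = np.linalg.lstsq(Z, flat, rcond=None)
    resid = flat - Z @ beta
    return resid.reshape(values.shape)


def _pearson_columns(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pearson r between vector ``b`` and each column of ``a`` (zero-variance
    columns give 0)."""
    ac = a - a.mean(axis=0)
    bc = b - b.mean()
    denom = np.sqrt((ac**2).sum(axis=0) * (bc**2).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(denom > 0, (ac * bc[:, None]).sum(axis=0) / denom, 0.0)
    return r


def timewise_rt_correlation(
    gamma: np.ndarray,
    rt: np.ndarray,
    confound: np.ndarray | None = None,
    *,
    n_permutations: int = 0,
    seed: int = 0,
) -> dict:
    """Correlation between state probabilities and RT at every (time, state).

    Trials without a button press (NaN RT) are discarded; both the time
    courses and the RTs are deconfounded first when a confound is given.
    Zero-variance probability columns yield correlation 0 (flagged in the
    returned mask).  Optional permutation p-values shuffle RT across trials.
    """
    rt = np.asarray(rt, dtype=float)
    included = np.isfinite(rt)
    if included.sum() < 3:
        raise ValueError("need at least 3 button-press trials")
    g = gamma[included]
    r_rt = rt[included]
    conf = None if confound is None else np.asarray(confound, dtype=float)[included]
    if conf is not None:
        g = deconfound(g, conf)
        r_rt = deconfound(r_rt, conf)
    S, T, K = g.shape
    flat = g.reshape(S, T * K)
    corr = _pearson_columns(flat, r_rt).reshape(T, K)
    # columns with (numerically) no across-trial variation carry no RT
    # information; residual-of-a-constant artifacts would otherwise produce
    # arbitrary correlation values there
    flagged = (gamma[included].reshape(S, T * K).std(axis=0) <= 1e-10).reshape(T, K)
    corr = np.where(flagged, 0.0, corr)

    p = None
    if n_permutations > 0:
        rng = np.random.default_rng(seed)
        exceed = np.zeros((T, K))
        for _ in range(n_permutations):
            cp = _pearson_columns(flat, r_rt[rng.permutation(S)]).reshape(T, K)
            exceed += np.abs(cp) >= np.abs(corr)
        p = (1.0 + exceed) / (1.0 + n_permutations)
    return {"correlation": corr, "zero_variance": flagged, "p_values": p, "included": included}


def prototypical_sequences(
    corr_curves: np.ndarray, *, convention: str = "fast-negative"
) -> tuple[np.ndarray, np.ndarray]:
    """Prototypical short-RT and long-RT state sequences from RT correlations.

    At each timepoint the short-RT prototype picks the state most
    characteristic of fast trials and the long-RT prototype the state most
    characteristic of slow trials; ties go to the lowest state index.

    A state that is active at time t only on fast trials *anti*-correlates
    with RT there, so the default convention takes the per-time argmin of the
    correlation for the short-RT sequence and the argmax for the long-RT
    sequence.  ``convention="fast-positive"`` swaps the two readings.
    """
    corr = np.asarray(corr_curves, dtype=float)
    if corr.ndim != 2:
        raise ValueError("corr_curves must be time x states")
    lo = corr.argmin(axis=1)
    hi = corr.argmax(axis=1)
    if convention == "fast-negative":
        return lo, hi
    if convention == "fast-positive":
        return hi, lo
    raise ValueError("convention must be 'fast-negative' or 'fast-positive'")


def sequence_lead(
    short_seq: np.ndarray,
    long_seq: np.ndarray,
    max_lag: int | None = None,
    weights: np.ndarray | None = None,
) -> int:
    """Lag (in samples) by which the short-RT sequence leads the long-RT one.

    Found as the shift maximizing (optionally weighted) agreement between the
    two categorical sequences: ``argmax_d mean(short[t] == long[t + d])``
    over ``d in [0, max_lag]``.  Timepoints where neither state probability
    carries RT information produce arbitrary prototype states, so passing
    ``weights`` (e.g. the per-time maximum absolute RT correlation)
    suppresses them.
    """
    short_seq = np.asarray(short_seq)
    long_seq = np.asarray(long_seq)
    T = short_seq.shape[0]
    if max_lag is None:
        max_lag = T // 2
    w = np.ones(T) if weights is None else np.asarray(weights, dtype=float)
    agree = np.empty(max_lag + 1)
    for d in range(max_lag + 1):
        ww = w[: T - d]
        match = (short_seq[: T - d] == long_seq[d:]).astype(float)
        agree[d] = (ww * match).sum() / max(ww.sum(), 1e-300)
    return int(np.argmax(agree))


@dataclasses.dataclass
class RtDesign:
    """Design matrix for RT prediction from compressed state time courses."""

    features: np.ndarray  # (n_included, K * n_pcs)
    rt_deconf: np.ndarray  # (n_included,)
    included: np.ndarray  # (n_trials,) bool mask of button-press trials
    subject: np.ndarray | None
    n_pcs: int


def build_rt_design(
    gamma: np.ndarray,
    rt: np.ndarray,
    confound: np.ndarray | None = None,
    subject: np.ndarray | None = None,
    n_pcs: int = 25,
) -> RtDesign:
    """PCA-compress per-state time courses into RT-prediction regressors.

    Button-press trials are selected; time courses and RT are deconfounded;
    then, separately for each state, the trials x timepoints matrix of that
    state's time courses is reduced to ``n_pcs`` principal-component scores.
    The scores are concatenated across states into the feature matrix.
    """
    from sklearn.decomposition import PCA

    rt = np.asarray(rt, dtype=float)
    included = np.isfinite(rt)
    n = int(included.sum())
    S, T, K = gamma.shape
    n_pcs = int(n_pcs)
    if n < max(n_pcs, 3):
        raise ValueError(f"only {n} usable trials for n_pcs={n_pcs}")
    g = gamma[included]
    y = rt[included]
    conf = None if confound is None else np.asarray(confound, dtype=float)[included]
    if conf is not None:
        g = deconfound(g, conf)
        y = deconfound(y, conf)
    n_pcs_eff = min(n_pcs, T, n)
    blocks = []
    for k in range(K):
        gk = g[:, :, k]
        if np.allclose(gk.var(axis=0), 0):
            blocks.append(np.zeros((n, n_pcs_eff)))
            continue
        scores = PCA(n_components=n_pcs_eff, svd_solver="auto", random_state=0).fit_transform(gk)
        blocks.append(scores)
    features = np.hstack(blocks)
    return RtDesign(
        features=features,
        rt_deconf=y,
        included=included,
        subject=None if subject is None else np.asarray(subject)[included],
        n_pcs=n_pcs_eff,
    )


def _lasso_alphas(X: np.ndarray, y: np.ndarray, n_alphas: int = 20) -> np.ndarray:
    """Logarithmic penalty grid 1e-3..1e1 times the data-scaled lambda_max."""
    n = X.shape[0]
    lam_max = np.abs(X.T @ (y - y.mean())).max() / n
    lam_max = max(lam_max, 1e-12)
    return lam_max * np.logspace(-3, 1, n_alphas)


def predict_rt_cv(
    design: RtDesign,
    seed: int = 0,
    *,
    n_permutations: int = 0,
    folds_if_single_subject: int = 5,
    min_fold_trials: int = 5,
) -> dict:
    """Cross-validated sparse-regression prediction of reaction time.

    Outer folds are leave-one-subject-out when subject labels are present
    (subjects with fewer than ``min_fold_trials`` trials are excluded with a
    warning), otherwise ``folds_if_single_subject`` random trial folds.  The
    L1 penalty is selected per training set by inner 5-fold CV on a
    logarithmic grid.  Features are standardized within each training fold.

    The permutation null refits the lasso (at the penalty selected on the
    unpermuted data) on shuffled RTs through the same folds.  Returns
    held-out predictions, the Pearson r between real and predicted RT, the
    permutation p-value and bookkeeping (fold id per trial, chosen alphas).
    """
    X = design.features
    y = design.rt_deconf
    n = X.shape[0]
    rng = np.random.default_rng(seed)

    if design.subject is not None and len(np.unique(design.subject)) >= 2:
        fold_defs = []
        for subj in np.unique(design.subject):
            idx = np.flatnonzero(design.subject == subj)
            if idx.size < min_fold_trials:
                warnings.warn(
                    f"subject {subj!r} has {idx.size} trials (<{min_fold_trials}); excluded",
                    RuntimeWarning,
                )
                continue
            fold_defs.append(idx)
        if len(fold_defs) < 2:
            raise ValueError("need at least 2 usable subject folds")
    else:
        kf = KFold(n_splits=folds_if_single_subject, shuffle=True, random_state=seed)
        fold_defs = [test for _, test in kf.split(np.arange(n))]

    def run_cv(target: np.ndarray, fixed_alphas: list[float] | None = None):
        pred = np.full(n, np.nan)
        fold_id = np.full(n, -1)
        chosen = []
        for i, test in enumerate(fold_defs):
            train = np.setdiff1d(np.arange(n), test)
            mu, sd = X[train].mean(axis=0), X[train].std(axis=0)
            sd[sd == 0] = 1.0
            Xtr = (X[train] - mu) / sd
            Xte = (X[test] - mu) / sd
            ytr = target[train]
            if fixed_alphas is None:
                las = LassoCV(
                    alphas=_lasso_alphas(Xtr, ytr), cv=5, max_iter=50_000, random_state=0
                ).fit(Xtr, ytr)
                chosen.append(float(las.alpha_))
                est = las
            else:
                est = Lasso(alpha=fixed_alphas[i], max_iter=50_000).fit(Xtr, ytr)
            pred[test] = est.predict(Xte)
            fold_id[test] = i
        mask = fold_id >= 0
        r = float(np.corrcoef(target[mask], pred[mask])[0, 1])
        return pred, fold_id, r, chosen

    pred, fold_id, r, alphas = run_cv(y)

    p = np.nan
    if n_permutations > 0:
        null = np.empty(n_permutations)
        for i in range(n_permutations):
            _, _, null[i], _ = run_cv(y[rng.permutation(n)], fixed_alphas=alphas)
        p = float((1 + np.sum(null >= r)) / (1 + n_permutations))
    return {
        "predicted": pred,
        "fold": fold_id,
        "r": r,
        "p_perm": p,
        "alphas": alphas,
        "null": null if n_permutations > 0 else None,
    }
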