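"""Per-timepoint ("standard") decoding and its temporal-generalization tools.

One ordinary-least-squares regression from channels to stimulus features is
fitted at every within-trial timepoint, pooling trials — the classic decoding
baseline that assumes every trial traverses the same processing stages at the
same times.  From the fitted decoders we derive the across-time error matrix
``e`` (decoder trained at t, evaluated at j), its symmetrized divergence
``D = e + e'`` (the analogue of a temporal-generalization matrix), a
cross-validated generalization map, and correlation-based hierarchical
clustering of the decoder weights.

All across-time quantities are computed from per-timepoint sufficient
statistics (X'X, X'Y, ||Y||^2), never from materialized T x T prediction
tensors.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from sklearn.model_selection import KFold

from .datasets import EpochedDataset

__all__ = [
    "pca_reduce",
    "PcaProjection",
    "fit_pointwise_decoders",
    "error_matrix",
    "divergence_matrix",
    "generalization_cv",
    "cluster_decoders_by_correlation",
    "PointwiseDecoder",
    "PointwiseDecoderResults",
]


# ---------------------------------------------------------------------------
# PCA projection
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class PcaProjection:
    """A fitted channel-space PCA: components, mean and explained variance."""

    components: np.ndarray  # (n_components, n_channels)
    mean: np.ndarray  # (n_channels,)
    explained_variance_ratio: np.ndarray

    @property
    def variance_explained(self) -> float:
        return float(self.explained_variance_ratio.sum())

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (X - self.mean) @ self.components.T

    def inverse_transform(self, Z: np.ndarray) -> np.ndarray:
        return Z @ self.components + self.mean

    def map_to_sensors(self, values: np.ndarray) -> np.ndarray:
        """Map component-space values (…, n_components) back to sensor space."""
        return values @ self.components


def pca_reduce(
    data: EpochedDataset, n_components: int
) -> tuple[EpochedDataset, PcaProjection]:
    """Project the channel dimension onto its leading principal components.

    The PCA is fitted on the (trials*time) x channels concatenation after
    mean-centering.  Returns the projected dataset and the projection, which
    is kept so encoding-model results computed in component space can be
    mapped back to sensors.
    """
    from sklearn.decomposition import PCA

    if n_components > data.n_channels:
        raise ValueError("n_components cannot exceed the number of channels")
    flat = data.X.reshape(-1, data.n_channels)
    rank = np.linalg.matrix_rank(flat - flat.mean(axis=0))
    if n_components > rank:
        raise ValueError(f"n_components={n_components} exceeds data rank {rank}")
    pca = PCA(n_components=n_components, svd_solver="full")
    Z = pca.fit_transform(flat).reshape(data.n_trials, data.n_timepoints, n_components)
    proj = PcaProjection(
        components=pca.components_,
        mean=pca.mean_,
        explained_variance_ratio=pca.explained_variance_ratio_,
    )
    reduced = EpochedDataset(
        X=Z,
        Y=data.Y,
        sampling_rate=data.sampling_rate,
        rt=data.rt,
        subject=data.subject,
    )
    return reduced, proj


# ---------------------------------------------------------------------------
# sufficient statistics and pointwise OLS
# ---------------------------------------------------------------------------


def timepoint_suff_stats(
    X: np.ndarray, Y: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """Per-timepoint normal-equation statistics.

    Returns ``A`` (T, C, C) with ``A_t = sum_s x_st x_st'``, ``B`` (T, C, F)
    with ``B_t = sum_s x_st y_s'`` and the scalar ``sum_s ||y_s||^2`` (the
    stimulus is constant within trial, so the Y statistics do not depend on t).
    """
    A = np.einsum("stc,std->tcd", X, X, optimize=True)
    B = np.einsum("stc,sf->tcf", X, Y, optimize=True)
    yss = float(np.sum(Y**2))
    return A, B, yss


def _solve_decoders(A: np.ndarray, B: np.ndarray, ridge) -> np.ndarray:
    """Solve ``(A_t + lam I) v_t = B_t`` for every t."""
    T, C, _ = A.shape
    if ridge is None:
        ranks = np.linalg.matrix_rank(A)
        bad = np.nonzero(ranks < C)[0]
        if bad.size:
            raise np.linalg.LinAlgError(
                f"singular normal equations at timepoint(s) {bad[:5].tolist()}; "
                "enable the ridge fallback or reduce dimensionality"
            )
        lam = 0.0
    elif ridge == "auto":
        # tiny Tikhonov term scaled to the data, guards PCA-reduced rank loss
        # (absolute floor keeps an all-zero Gram matrix solvable -> zero weights)
        lam = np.maximum(1e-8 * np.einsum("tcc->t", A) / C, 1e-12)
        lam = lam[:, None]
    else:
        lam = float(ridge)
    Areg = A + np.eye(C) * (lam[..., None] if np.ndim(lam) else lam)
    return np.linalg.solve(Areg, B)


def fit_pointwise_decoders(data: EpochedDataset, ridge="auto") -> np.ndarray:
    """OLS decoding weights ``v_t = (X_t'X_t)^-1 X_t'Y`` at every timepoint.

    Returns an array of shape (T, channels, features); the prediction
    contract is ``Yhat_t = X_t v_t``.  ``ridge`` may be ``"auto"`` (tiny
    data-scaled Tikhonov term), a float, or ``None`` (raise on singular
    normal equations, naming the offending timepoints).
    """
    A, B, _ = timepoint_suff_stats(data.X, data.Y)
    return _solve_decoders(A, B, ridge)


def _error_from_stats(
    v: np.ndarray, A: np.ndarray, B: np.ndarray, yss: float, chunk: int = 64
) -> np.ndarray:
    """``e_tj = sum_s ||X_sj v_t - y_s||^2`` via the quadratic-form identity."""
    T = v.shape[0]
    Tj = A.shape[0]
    e = np.empty((T, Tj))
    cross = 2.0 * np.einsum("tcf,jcf->tj", v, B, optimize=True)
    for start in range(0, T, chunk):
        vc = v[start : start + chunk]
        Av = np.einsum("jcd,tdf->tjcf", A, vc, optimize=True)
        e[start : start + chunk] = np.einsum("tjcf,tcf->tj", Av, vc, optimize=True)
    e += yss - cross
    # guard tiny negative values from cancellation
    np.maximum(e, 0.0, out=e)
    return e


def error_matrix(data: EpochedDataset, v: np.ndarray) -> np.ndarray:
    """Across-time error matrix: decoder trained at t scored at time j.

    ``e_tj`` sums squared prediction errors over trials and stimulus
    features.  Row t is the generalization profile of decoder t.
    """
    if v.shape[0] != data.n_timepoints:
        raise ValueError("decoders were fitted on a different time axis")
    A, B, yss = timepoint_suff_stats(data.X, data.Y)
    return _error_from_stats(v, A, B, yss)


def divergence_matrix(e: np.ndarray) -> np.ndarray:
    """Symmetric between-decoder divergence ``D_tj = e_tj + e_jt``."""
    e = np.asarray(e)
    if e.ndim != 2 or e.shape[0] != e.shape[1]:
        raise ValueError("e must be a square matrix")
    return e + e.T


def generalization_cv(
    data: EpochedDataset,
    folds: int = 10,
    seed: int = 0,
    ridge="auto",
) -> np.ndarray:
    """Cross-validated temporal-generalization matrix of CV-R^2 values.

    For every fold, decoders are fitted at each timepoint on the training
    trials and scored on the held-out trials at every timepoint; R^2 is
    ``1 - SSE/SST`` with SSE and SST pooled over folds, test trials and
    stimulus features, and SST taken about the training-fold mean of Y.
    """
    if folds < 2:
        raise ValueError("need at least 2 folds")
    S, T = data.n_trials, data.n_timepoints
    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    sse = np.zeros((T, T))
    sst = 0.0
    for train, test in kf.split(np.arange(S)):
        if len(test) < 2 or len(train) < 2:
            raise ValueError("a fold has fewer than 2 trials")
        Xtr, Ytr = data.X[train], data.Y[train]
        Xte, Yte = data.X[test], data.Y[test]
        A, B, _ = timepoint_suff_stats(Xtr, Ytr)
        v = _solve_decoders(A, B, ridge)
        Ate, Bte, yss_te = timepoint_suff_stats(Xte, Yte)
        sse += _error_from_stats(v, Ate, Bte, yss_te)
        sst += float(np.sum((Yte - Ytr.mean(axis=0)) ** 2))
    return 1.0 - sse / sst


def correlation_distance(v: np.ndarray) -> np.ndarray:
    """Pairwise ``1 - Pearson r`` between vectorized decoder weights."""
    flat = v.reshape(v.shape[0], -1)
    sd = flat.std(axis=1)
    constant = sd == 0
    if constant.any():
        warnings.warn(
            "constant decoder weight vectors: correlation undefined, using distance 1",
            RuntimeWarning,
            stacklevel=2,
        )
    centered = flat - flat.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1)
    norms[norms == 0] = 1.0
    corr = (centered / norms[:, None]) @ (centered / norms[:, None]).T
    corr[constant, :] = 0.0
    corr[:, constant] = 0.0
    np.fill_diagonal(corr, 1.0)
    dist = 1.0 - np.clip(corr, -1.0, 1.0)
    np.fill_diagonal(dist, 0.0)
    return dist


def cluster_decoders_by_correlation(
    v: np.ndarray,
    *,
    n_clusters: int | None = None,
    threshold: float | None = None,
    method: str = "ward",
) -> tuple[np.ndarray, np.ndarray]:
    """Hierarchically cluster per-timepoint decoders by weight correlation.

    Distance is ``1 - Pearson r`` between vectorized weight matrices;
    linkage defaults to Ward (configurable: single/complete/average).
    Exactly one of ``n_clusters`` or ``threshold`` must be given; returns
    0-based labels over time and the scipy linkage matrix.
    """
    if v.shape[0] < 2:
        raise ValueError("need at least 2 timepoints to cluster")
    if (n_clusters is None) == (threshold is None):
        raise ValueError("give exactly one of n_clusters or threshold")
    dist = correlation_distance(v)
    Z = hierarchy.linkage(squareform(dist, checks=False), method=method)
    if n_clusters is not None:
        labels = hierarchy.fcluster(Z, t=n_clusters, criterion="maxclust")
    else:
        labels = hierarchy.fcluster(Z, t=threshold, criterion="distance")
    return labels - 1, Z


# ---------------------------------------------------------------------------
# model/results interface
# ---------------------------------------------------------------------------


class PointwiseDecoder:
    """Per-timepoint decoding model over an :class:`EpochedDataset`.

    ``fit()`` estimates one OLS decoder per timepoint and the across-time
    error and divergence matrices, returning a
    :class:`PointwiseDecoderResults`.
    """

    def __init__(self, data: EpochedDataset, ridge="auto"):
        self.data = data
        self.ridge = ridge

    def fit(self) -> "PointwiseDecoderResults":
        A, B, yss = timepoint_suff_stats(self.data.X, self.data.Y)
        v = _solve_decoders(A, B, self.ridge)
        e = _error_from_stats(v, A, B, yss)
        return PointwiseDecoderResults(model=self, v=v, e=e, D=divergence_matrix(e))


@dataclasses.dataclass
class PointwiseDecoderResults:
    """Fitted per-timepoint decoders with generalization diagnostics."""

    model: PointwiseDecoder
    v: np.ndarray  # (T, channels, features)
    e: np.ndarray  # (T, T) error matrix
    D: np.ndarray  # (T, T) divergence matrix

    def generalization_cv(self, folds: int = 10, seed: int = 0) -> np.ndarray:
        return generalization_cv(self.model.data, folds=folds, seed=seed, ridge=self.model.ridge)

    def cluster_by_correlation(self, **kwargs) -> tuple[np.ndarray, np.ndarray]:
        return cluster_decoders_by_correlation(self.v, **kwargs)

    def summary(self) -> str:
        T, C, F = self.v.shape
        lines = [
            "Per-timepoint decoding results",
            f"  timepoints: {T}, channels: {C}, stimulus features: {F}",
            f"  in-sample SSE on the diagonal: mean {np.mean(np.diag(self.e)):.4g}",
            f"  divergence matrix range: [{self.D.min():.4g}, {self.D.max():.4g}]",
        ]
        return "\n".join(lines)
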