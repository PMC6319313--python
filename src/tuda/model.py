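"""The temporally unconstrained decoding model (TUDA).

A hidden Markov model whose K states are stimulus-decoding regressions: state
k carries a (channels x features) weight matrix ``w_k``, and the observation
model at trial s, time t is ``Y_s = X_st (sum_k gamma_stk w_k) + eps`` with
shared Gaussian noise variance.  Inference is staged so the state decoders
remain comparable to the per-timepoint baseline:

1. initialization — hierarchical clustering of the T per-timepoint decoders
   using the divergence matrix ``D``; cluster representatives are refit by
   pooled OLS over member timepoints;
2. synchronous EM — timepoints (shared across trials) are reassigned to the
   state with the lowest pooled squared error and state weights refit, until
   the assignment stabilizes (pooled SSE is non-increasing);
3. variational Bayes — with the decoding weights fixed, trial-specific state
   time courses ``gamma`` and Dirichlet posteriors over the transition matrix
   and initial distribution are estimated by forward-backward under expected
   log transition parameters (free energy is non-decreasing).

The user-facing surface is statsmodels-like: ``TUDA(data, K=5).fit()``
returns a :class:`TUDAResults` holding the estimates, diagnostics, traces
and summary table.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import squareform
from scipy.special import digamma, gammaln

from .datasets import EpochedDataset
from .hmm import StateTimeCourses, forward_backward, viterbi_paths
from .standard import _solve_decoders, divergence_matrix, _error_from_stats, timepoint_suff_stats

__all__ = [
    "TUDA",
    "TUDAResults",
    "TudaModelParams",
    "cluster_initialize",
    "em_refine_synchronous",
    "state_log_likelihoods",
    "infer_state_dynamics",
    "fit_tuda",
    "predict_stimulus",
    "dwell_and_occupancy_stats",
    "match_states",
    "oracle_decoding_weights",
]


@dataclasses.dataclass
class TudaModelParams:
    """Point estimates of the decoding-state HMM.

    ``W[k]`` is the (channels x features) decoding weight matrix of state k,
    ``noise_var`` the shared residual variance, ``Theta`` the K x K
    transition matrix (rows sum to one) and ``pi`` the initial distribution.
    """

    W: np.ndarray
    noise_var: float
    Theta: np.ndarray
    pi: np.ndarray

    @property
    def K(self) -> int:
        return self.W.shape[0]

    def validate(self) -> None:
        if self.noise_var <= 0:
            raise ValueError("noise_var must be positive")
        if not np.allclose(self.Theta.sum(axis=1), 1.0, atol=1e-10) or (self.Theta < 0).any():
            raise ValueError("Theta rows must be distributions")
        if not np.isclose(self.pi.sum(), 1.0, atol=1e-10) or (self.pi < 0).any():
            raise ValueError("pi must be a distribution")

    def permute(self, perm: np.ndarray) -> "TudaModelParams":
        """Relabel states by ``perm`` (new order of old indices)."""
        perm = np.asarray(perm)
        return TudaModelParams(
            W=self.W[perm],
            noise_var=self.noise_var,
            Theta=self.Theta[np.ix_(perm, perm)],
            pi=self.pi[perm],
        )


# ---------------------------------------------------------------------------
# stage 1: clustering initialization
# ---------------------------------------------------------------------------


def cluster_initialize(
    data: EpochedDataset,
    D: np.ndarray,
    K: int,
    *,
    method: str = "ward",
    ridge="auto",
) -> tuple[np.ndarray, np.ndarray]:
    """Initialize state decoding weights by clustering the time axis.

    Timepoints are grouped into K clusters by hierarchical clustering of the
    between-decoder divergence matrix ``D``; each cluster's representative
    weight matrix is refit by OLS pooling every (trial, timepoint) sample of
    its members.  Returns (W, labels) with ``W`` of shape (K, C, F) and
    ``labels`` the synchronous time -> cluster map (0-based, ordered by
    first occurrence in time).
    """
    T = data.n_timepoints
    if K > T:
        raise ValueError("K cannot exceed the number of timepoints")
    D = np.asarray(D, dtype=float)
    D = 0.5 * (D + D.T)
    Dz = D.copy()
    np.fill_diagonal(Dz, 0.0)
    Z = hierarchy.linkage(squareform(Dz, checks=False), method=method)
    labels = hierarchy.fcluster(Z, t=K, criterion="maxclust") - 1
    n_found = labels.max() + 1
    if n_found < K:
        warnings.warn(
            f"clustering produced only {n_found} non-empty clusters (K={K} requested)",
            RuntimeWarning,
            stacklevel=2,
        )
    # relabel clusters by first appearance so state 0 is the earliest
    order = np.argsort([np.argmax(labels == c) for c in range(n_found)])
    remap = np.empty(n_found, dtype=int)
    remap[order] = np.arange(n_found)
    labels = remap[labels]

    A, B, _ = timepoint_suff_stats(data.X, data.Y)
    C, F = data.n_channels, data.n_features
    W = np.zeros((n_found, C, F))
    for k in range(n_found):
        members = labels == k
        W[k] = _solve_decoders(
            A[members].sum(axis=0)[None], B[members].sum(axis=0)[None], ridge
        )[0]
    return W, labels


# ---------------------------------------------------------------------------
# stage 2: synchronous EM refinement
# ---------------------------------------------------------------------------


def em_refine_synchronous(
    data: EpochedDataset,
    W: np.ndarray,
    *,
    max_iter: int = 100,
    tol: float = 1e-5,
    soft: bool = False,
    ridge="auto",
    trim_frac: float = 0.2,
) -> tuple[np.ndarray, float, np.ndarray, np.ndarray]:
    """Refine state weights under the between-trial synchrony restriction.

    Alternates (i) assigning every timepoint — shared by all trials — to the
    state with the smallest pooled squared error and (ii) refitting each
    state's weights by OLS over its assigned timepoints.  With ``soft=True``
    the assignment step uses Gaussian responsibilities instead of a hard
    argmin and the refit is responsibility-weighted.

    After the descent converges, each state's weights are refit once more
    excluding a ``trim_frac`` fraction of its segment at every edge that
    abuts another state's segment: near those boundaries trials genuinely
    disagree about the active state, and the pooled refit would blend
    neighboring states into the weights (``trim_frac=0`` disables this; the
    trial-start and trial-end edges are never trimmed, so a single-state
    model still reduces to pooled OLS exactly).

    Returns ``(W, noise_var, assignment, sse_trace)``; the pooled SSE trace
    of the descent is non-increasing, and ``noise_var`` is the pooled
    residual variance of the returned weights over all samples.
    """
    A, B, yss = timepoint_suff_stats(data.X, data.Y)
    S, T, F = data.n_trials, data.n_timepoints, data.n_features
    K = W.shape[0]
    W = W.copy()
    n_obs = S * T * F

    def per_state_sse() -> np.ndarray:
        # sse[k, t] = sum_s ||X_st w_k - y_s||^2
        return _error_from_stats(W, A, B, yss)

    sse_kt = per_state_sse()
    assignment = sse_kt.argmin(axis=0)
    sse_trace = [float(sse_kt[assignment, np.arange(T)].sum())]
    noise_var = sse_trace[0] / n_obs

    for _ in range(max_iter):
        if soft:
            # synchronous responsibilities per timepoint, shared over trials
            logr = -0.5 * sse_kt / noise_var
            logr -= logr.max(axis=0, keepdims=True)
            r = np.exp(logr)
            r /= r.sum(axis=0, keepdims=True)
            for k in range(K):
                wk_A = np.einsum("t,tcd->cd", r[k], A)
                wk_B = np.einsum("t,tcf->cf", r[k], B)
                if r[k].sum() > 1e-12:
                    W[k] = _solve_decoders(wk_A[None], wk_B[None], ridge)[0]
        else:
            for k in range(K):
                members = assignment == k
                if not members.any():
                    warnings.warn(
                        f"state {k} lost all timepoints; keeping previous weights",
                        RuntimeWarning,
                        stacklevel=2,
                    )
                    continue
                W[k] = _solve_decoders(
                    A[members].sum(axis=0)[None], B[members].sum(axis=0)[None], ridge
                )[0]
        sse_kt = per_state_sse()
        new_assignment = sse_kt.argmin(axis=0)
        sse = float(sse_kt[new_assignment, np.arange(T)].sum())
        noise_var = max(sse / n_obs, np.finfo(float).tiny)
        converged = (not soft) and np.array_equal(new_assignment, assignment)
        stalled = abs(sse_trace[-1] - sse) <= tol * max(abs(sse_trace[-1]), 1.0)
        assignment = new_assignment
        sse_trace.append(sse)
        if converged or stalled:
            break

    if trim_frac > 0:
        W = _trimmed_segment_refit(A, B, assignment, W, trim_frac, ridge, T)
        sse_kt = per_state_sse()
        noise_var = max(float(sse_kt[assignment, np.arange(T)].sum()) / n_obs, np.finfo(float).tiny)
    return W, noise_var, assignment, np.asarray(sse_trace)


def _trimmed_segment_refit(
    A: np.ndarray,
    B: np.ndarray,
    assignment: np.ndarray,
    W: np.ndarray,
    trim_frac: float,
    ridge,
    T: int,
) -> np.ndarray:
    """Refit each state's weights on its segment minus contaminated edges.

    An edge is trimmed only where the segment abuts another state's
    timepoints (interior boundaries); segments too short to trim are used
    whole.
    """
    W = W.copy()
    for k in range(W.shape[0]):
        idx = np.flatnonzero(assignment == k)
        if idx.size == 0:
            continue
        trim = int(trim_frac * idx.size)
        lo = trim if idx[0] > 0 else 0
        hi = idx.size - trim if idx[-1] < T - 1 else idx.size
        keep = idx[lo:hi] if hi - lo >= max(2, idx.size - 2 * trim) and hi > lo else idx
        if keep.size == 0:
            keep = idx
        W[k] = _solve_decoders(
            A[keep].sum(axis=0)[None], B[keep].sum(axis=0)[None], ridge
        )[0]
    return W


# ---------------------------------------------------------------------------
# per-state log-likelihoods
# ---------------------------------------------------------------------------


def state_log_likelihoods(data: EpochedDataset, W: np.ndarray, noise_var: float) -> np.ndarray:
    """Gaussian log-density of the stimulus under each state's decoder.

    Returns ``loglik[s, t, k] = log N(Y_s | X_st w_k, noise_var I)`` of shape
    (trials, T, K).
    """
    if noise_var <= 0:
        raise ValueError("noise_var must be positive")
    pred = np.einsum("stc,kcf->stkf", data.X, W, optimize=True)
    resid2 = ((pred - data.Y[:, None, None, :]) ** 2).sum(axis=3)
    F = data.n_features
    return -0.5 * (F * np.log(2.0 * np.pi * noise_var) + resid2 / noise_var)


# ---------------------------------------------------------------------------
# stage 3: variational inference of the state dynamics
# ---------------------------------------------------------------------------


def _dirichlet_kl(alpha: np.ndarray, alpha0: np.ndarray) -> float:
    """KL(Dir(alpha) || Dir(alpha0)) summed over the rows of a 2-D array."""
    alpha = np.atleast_2d(alpha)
    alpha0 = np.atleast_2d(alpha0)
    a_sum = alpha.sum(axis=1)
    a0_sum = alpha0.sum(axis=1)
    kl = (
        gammaln(a_sum)
        - gammaln(a0_sum)
        - (gammaln(alpha).sum(axis=1) - gammaln(alpha0).sum(axis=1))
        + ((alpha - alpha0) * (digamma(alpha) - digamma(a_sum)[:, None])).sum(axis=1)
    )
    return float(kl.sum())


@dataclasses.dataclass
class VbState:
    """Posterior state of the variational stage."""

    alpha_Theta: np.ndarray  # Dirichlet posteriors over rows of Theta
    alpha_pi: np.ndarray  # Dirichlet posterior over pi
    gamma: np.ndarray
    xi: np.ndarray | None
    free_energy: np.ndarray  # trace, one entry per iteration
    converged: bool

    @property
    def Theta(self) -> np.ndarray:
        """Posterior-mean transition matrix."""
        return self.alpha_Theta / self.alpha_Theta.sum(axis=1, keepdims=True)

    @property
    def pi(self) -> np.ndarray:
        return self.alpha_pi / self.alpha_pi.sum()


def infer_state_dynamics(
    loglik: np.ndarray,
    *,
    init_Theta_counts: np.ndarray | None = None,
    init_pi_counts: np.ndarray | None = None,
    prior_alpha: float = 1.0,
    max_iter: int = 100,
    tol: float = 1e-5,
) -> VbState:
    """Variational Bayes estimation of trial-specific state dynamics.

    With the state decoders (hence ``loglik``) fixed, iterates an E-step —
    forward-backward under the expected log transition parameters
    ``exp(E[log Theta])`` — and an M-step updating symmetric
    ``Dirichlet(prior_alpha)`` posteriors over each transition-matrix row and
    over the initial distribution from the pairwise-posterior counts.  The
    variational free energy is non-decreasing; iteration stops when its
    relative change falls below ``tol``.
    """
    S, T, K = loglik.shape
    prior_Theta = np.full((K, K), prior_alpha)
    prior_pi = np.full(K, prior_alpha)
    alpha_Theta = prior_Theta + (init_Theta_counts if init_Theta_counts is not None else 0.0)
    alpha_pi = prior_pi + (init_pi_counts if init_pi_counts is not None else 0.0)

    fe = []
    converged = False
    gamma = xi = None
    for _ in range(max_iter):
        ETheta = np.exp(digamma(alpha_Theta) - digamma(alpha_Theta.sum(axis=1))[:, None])
        Epi = np.exp(digamma(alpha_pi) - digamma(alpha_pi.sum()))
        stc = forward_backward(loglik, ETheta, Epi, allow_subnormalized=True)
        gamma, xi = stc.gamma, stc.xi
        f = (
            float(stc.log_evidence.sum())
            - _dirichlet_kl(alpha_Theta, prior_Theta)
            - _dirichlet_kl(alpha_pi, prior_pi)
        )
        if fe and abs(f - fe[-1]) <= tol * max(abs(fe[-1]), 1.0):
            fe.append(f)
            converged = True
            break
        fe.append(f)
        counts = xi.sum(axis=(0, 1)) if xi is not None else np.zeros((K, K))
        alpha_Theta = prior_Theta + counts
        alpha_pi = prior_pi + gamma[:, 0, :].sum(axis=0)
    if not converged:
        warnings.warn("variational stage did not converge within max_iter", RuntimeWarning)
    return VbState(
        alpha_Theta=alpha_Theta,
        alpha_pi=alpha_pi,
        gamma=gamma,
        xi=xi,
        free_energy=np.asarray(fe),
        converged=converged,
    )


# ---------------------------------------------------------------------------
# prediction, decoding, summary statistics
# ---------------------------------------------------------------------------


def predict_stimulus(data: EpochedDataset, W: np.ndarray, gamma: np.ndarray) -> np.ndarray:
    """Model prediction ``Yhat_st = X_st (sum_k gamma_stk w_k)``."""
    mixed = np.einsum("stk,kcf->stcf", gamma, W, optimize=True)
    return np.einsum("stc,stcf->stf", data.X, mixed, optimize=True)


def dwell_and_occupancy_stats(
    gamma: np.ndarray | None = None,
    paths: np.ndarray | None = None,
    sampling_rate: float = 1.0,
) -> dict:
    """Per-state dwell/onset/offset tables and occupancy curves.

    Hard paths are used when given, otherwise the per-sample argmax of
    ``gamma``.  Returns a dict with:

    - ``visits``: DataFrame of contiguous state visits (trial, state,
      onset/offset sample, duration in samples and seconds);
    - ``per_state``: DataFrame of per-state mean dwell, mean first onset and
      mean last offset (seconds);
    - ``occupancy``: (T, K) fraction of trials in each state per timepoint.
    """
    if paths is None:
        if gamma is None:
            raise ValueError("need gamma or hard paths")
        paths = np.argmax(gamma, axis=2)
    paths = np.asarray(paths)
    S, T = paths.shape
    K = int(paths.max()) + 1 if gamma is None else gamma.shape[2]

    rows = []
    for s in range(S):
        change = np.flatnonzero(np.diff(paths[s]) != 0)
        starts = np.concatenate([[0], change + 1])
        ends = np.concatenate([change, [T - 1]])
        for a, b in zip(starts, ends):
            rows.append((s, int(paths[s, a]), int(a), int(b), int(b - a + 1)))
    visits = pd.DataFrame(rows, columns=["trial", "state", "onset", "offset", "duration"])
    visits["onset_s"] = visits["onset"] / sampling_rate
    visits["offset_s"] = (visits["offset"] + 1) / sampling_rate
    visits["duration_s"] = visits["duration"] / sampling_rate

    # per (trial, state): first onset, last offset and total dwell
    per_trial = (
        visits.groupby(["trial", "state"])
        .agg(
            first_onset_s=("onset_s", "min"),
            last_offset_s=("offset_s", "max"),
            total_dwell_s=("duration_s", "sum"),
            n_visits=("duration_s", "size"),
        )
        .reset_index()
    )

    per_state = []
    for k in range(K):
        vk = visits[visits["state"] == k]
        pk = per_trial[per_trial["state"] == k]
        if len(vk) == 0:
            per_state.append((k, np.nan, np.nan, np.nan, np.nan, 0))
            continue
        per_state.append(
            (
                k,
                pk["total_dwell_s"].mean(),
                vk["duration_s"].mean(),
                pk["first_onset_s"].mean(),
                pk["last_offset_s"].mean(),
                len(vk),
            )
        )
    per_state = pd.DataFrame(
        per_state,
        columns=[
            "state",
            "mean_dwell_s",  # mean over trials of the total time spent in the state
            "mean_visit_s",  # mean over contiguous visits
            "mean_first_onset_s",
            "mean_last_offset_s",
            "n_visits",
        ],
    )

    occupancy = np.zeros((T, K))
    for k in range(K):
        occupancy[:, k] = (paths == k).mean(axis=0)
    return {"visits": visits, "per_trial": per_trial, "per_state": per_state, "occupancy": occupancy}


def match_states(W_est: np.ndarray, W_ref: np.ndarray) -> np.ndarray:
    """Hungarian matching of estimated to reference states by weight correlation.

    ``W_est[k]`` and ``W_ref[j]`` are weight matrices (any orientation with
    matching total size).  Returns ``perm`` such that estimated state
    ``perm[j]`` corresponds to reference state j.
    """
    a = W_est.reshape(W_est.shape[0], -1)
    b = W_ref.reshape(W_ref.shape[0], -1)
    a = a - a.mean(axis=1, keepdims=True)
    b = b - b.mean(axis=1, keepdims=True)
    a /= np.maximum(np.linalg.norm(a, axis=1, keepdims=True), 1e-300)
    b /= np.maximum(np.linalg.norm(b, axis=1, keepdims=True), 1e-300)
    corr = b @ a.T  # (ref, est)
    ref_idx, est_idx = linear_sum_assignment(-np.abs(corr))
    perm = np.empty(W_ref.shape[0], dtype=int)
    perm[ref_idx] = est_idx
    return perm


def oracle_decoding_weights(
    X: np.ndarray, Y: np.ndarray, state_path: np.ndarray, K: int, ridge="auto"
) -> np.ndarray:
    """Per-state OLS decoders fitted on the *true* state samples.

    The generative (encoding) weights of a simulation are not directly
    comparable to decoding weights; the fair reference for a recovered
    ``w_k`` is the OLS decoder restricted to the samples where ground truth
    says state k was active.  Returns (K, channels, features).
    """
    S, T, C = X.shape
    F = Y.shape[1]
    W = np.zeros((K, C, F))
    for k in range(K):
        mask = state_path == k  # (S, T)
        A = np.einsum("st,stc,std->cd", mask, X, X, optimize=True)
        B = np.einsum("st,stc,sf->cf", mask, X, Y, optimize=True)
        W[k] = _solve_decoders(A[None], B[None], ridge)[0]
    return W


def _activation_time_order(gamma: np.ndarray) -> np.ndarray:
    """States ordered by their occupancy-weighted mean activation time."""
    T = gamma.shape[1]
    t = np.arange(T)
    mass = gamma.sum(axis=0)  # (T, K)
    center = (mass * t[:, None]).sum(axis=0) / np.maximum(mass.sum(axis=0), 1e-300)
    return np.argsort(center, kind="stable")


# ---------------------------------------------------------------------------
# orchestration: model / results classes
# ---------------------------------------------------------------------------


class TUDA:
    """Temporally unconstrained decoding model for an epoched dataset.

    Parameters
    ----------
    data : EpochedDataset
    K : int
        Number of decoding states.
    em_max_iter, vb_max_iter : int
        Iteration caps for the synchronous EM and variational stages.
    tol : float
        Relative-change convergence tolerance for both stages.
    prior_alpha : float
        Symmetric Dirichlet prior on transition-matrix rows and on the
        initial distribution.
    ridge : "auto" | float | None
        Regularization policy for every internal OLS solve.
    linkage : str
        Linkage method for the initialization clustering; ``"auto"`` runs
        the EM descent from ward, complete and average initializations and
        keeps the one with the lowest pooled SSE (which initialization
        survives the divergence-matrix geometry is instance-dependent).
    trim_frac : float
        Fraction of each state's segment excluded at interior edges for the
        final weight refit (guards against between-trial boundary jitter
        blending neighboring states into the weights).
    reorder_states : bool
        Relabel states by the order in which they tend to arise in trials.

    Examples
    --------
    >>> from tuda.simulate import five_state_spec, simulate_linear_states
    >>> data, truth = simulate_linear_states(five_state_spec(seed=1))
    >>> res = TUDA(data, K=5).fit()
    >>> res.gamma.shape
    (200, 1000, 5)
    """

    def __init__(
        self,
        data: EpochedDataset,
        K: int,
        *,
        em_max_iter: int = 100,
        vb_max_iter: int = 100,
        tol: float = 1e-5,
        prior_alpha: float = 1.0,
        ridge="auto",
        linkage: str = "auto",
        soft_em: bool = False,
        trim_frac: float = 0.2,
        reorder_states: bool = True,
    ):
        if K < 1:
            raise ValueError("K must be >= 1")
        self.data = data
        self.K = K
        self.em_max_iter = em_max_iter
        self.vb_max_iter = vb_max_iter
        self.tol = tol
        self.prior_alpha = prior_alpha
        self.ridge = ridge
        self.linkage = linkage
        self.soft_em = soft_em
        self.trim_frac = trim_frac
        self.reorder_states = reorder_states

    def fit(self, seed: int | None = None) -> "TUDAResults":
        """Run the three inference stages; deterministic given the data."""
        data = self.data
        # stage 0/1: per-timepoint decoders -> divergence -> clustering init
        A, B, yss = timepoint_suff_stats(data.X, data.Y)
        v = _solve_decoders(A, B, self.ridge)
        e = _error_from_stats(v, A, B, yss)
        D = divergence_matrix(e)
        # stage 2: synchronous EM; with linkage="auto" the descent is run
        # from each linkage's initialization and the lowest pooled SSE wins
        methods = ("ward", "complete", "average") if self.linkage == "auto" else (self.linkage,)
        best = None
        for method in methods:
            W0, labels = cluster_initialize(data, D, self.K, method=method, ridge=self.ridge)
            fit = em_refine_synchronous(
                data,
                W0,
                max_iter=self.em_max_iter,
                tol=self.tol,
                soft=self.soft_em,
                ridge=self.ridge,
                trim_frac=self.trim_frac,
            )
            if best is None or fit[3][-1] < best[0][3][-1] - 1e-9 * abs(best[0][3][-1]):
                best = (fit, labels)
        (W, noise_var, assignment, sse_trace), init_labels = best
        K = W.shape[0]
        # seed the transition posteriors from the synchronous assignment
        trans_counts = np.zeros((K, K))
        for a, b in zip(assignment[:-1], assignment[1:]):
            trans_counts[a, b] += 1
        trans_counts *= data.n_trials
        pi_counts = np.zeros(K)
        pi_counts[assignment[0]] = data.n_trials
        # stage 3: variational state dynamics with W fixed
        loglik = state_log_likelihoods(data, W, noise_var)
        vb = infer_state_dynamics(
            loglik,
            init_Theta_counts=trans_counts,
            init_pi_counts=pi_counts,
            prior_alpha=self.prior_alpha,
            max_iter=self.vb_max_iter,
            tol=self.tol,
        )
        params = TudaModelParams(W=W, noise_var=noise_var, Theta=vb.Theta, pi=vb.pi)
        res = TUDAResults(
            model=self,
            params=params,
            gamma=vb.gamma,
            xi=vb.xi,
            free_energy=vb.free_energy,
            em_sse=sse_trace,
            sync_assignment=assignment,
            init_labels=init_labels,
            vb_converged=vb.converged,
        )
        if self.reorder_states:
            res = res.reordered(_activation_time_order(vb.gamma))
        res.params.validate()
        return res


@dataclasses.dataclass
class TUDAResults:
    """Fitted TUDA model: estimates, state time courses and diagnostics."""

    model: TUDA
    params: TudaModelParams
    gamma: np.ndarray  # (S, T, K)
    xi: np.ndarray | None
    free_energy: np.ndarray
    em_sse: np.ndarray
    sync_assignment: np.ndarray
    init_labels: np.ndarray
    vb_converged: bool

    # -- convenience accessors -------------------------------------------
    @property
    def W(self) -> np.ndarray:
        return self.params.W

    @property
    def Theta(self) -> np.ndarray:
        return self.params.Theta

    @property
    def pi(self) -> np.ndarray:
        return self.params.pi

    @property
    def noise_var(self) -> float:
        return self.params.noise_var

    @property
    def K(self) -> int:
        return self.params.K

    def state_time_courses(self) -> StateTimeCourses:
        return StateTimeCourses(gamma=self.gamma, xi=self.xi)

    # -- derived quantities ----------------------------------------------
    def predict(self, data: EpochedDataset | None = None, gamma: np.ndarray | None = None) -> np.ndarray:
        data = data if data is not None else self.model.data
        gamma = gamma if gamma is not None else self.gamma
        return predict_stimulus(data, self.W, gamma)

    def loglik(self, data: EpochedDataset | None = None) -> np.ndarray:
        data = data if data is not None else self.model.data
        return state_log_likelihoods(data, self.W, self.noise_var)

    def viterbi_paths(self, data: EpochedDataset | None = None) -> np.ndarray:
        return viterbi_paths(self.loglik(data), self.Theta, self.pi)

    def dwell_stats(self, use_viterbi: bool = True) -> dict:
        fs = self.model.data.sampling_rate
        if use_viterbi:
            return dwell_and_occupancy_stats(
                gamma=self.gamma, paths=self.viterbi_paths(), sampling_rate=fs
            )
        return dwell_and_occupancy_stats(gamma=self.gamma, sampling_rate=fs)

    def occupancy(self) -> np.ndarray:
        """Mean state probability per (time, state)."""
        return self.gamma.mean(axis=0)

    def reordered(self, perm: np.ndarray) -> "TUDAResults":
        """Relabel states by ``perm`` (new order of old indices)."""
        perm = np.asarray(perm)
        xi = None if self.xi is None else self.xi[:, :, perm][:, :, :, perm]
        return TUDAResults(
            model=self.model,
            params=self.params.permute(perm),
            gamma=self.gamma[:, :, perm],
            xi=xi,
            free_energy=self.free_energy,
            em_sse=self.em_sse,
            sync_assignment=np.argsort(perm)[self.sync_assignment],
            init_labels=self.init_labels,
            vb_converged=self.vb_converged,
        )

    def summary(self) -> str:
        """Human-readable fit report (1-based state labels)."""
        occ = self.occupancy().mean(axis=0)
        stats = self.dwell_stats(use_viterbi=False)["per_state"]
        lines = [
            "Temporally unconstrained decoding analysis",
            "==========================================",
            f"trials: {self.model.data.n_trials}   timepoints: {self.model.data.n_timepoints}"
            f"   channels: {self.model.data.n_channels}   states: {self.K}",
            f"noise variance: {self.noise_var:.6g}",
            f"EM iterations: {len(self.em_sse) - 1} (final pooled SSE {self.em_sse[-1]:.6g})",
            f"VB iterations: {len(self.free_energy)} "
            f"(final free energy {self.free_energy[-1]:.6g}, converged: {self.vb_converged})",
            "",
            "state  frac.occupancy  mean dwell (s)  mean onset (s)",
        ]
        for k in range(self.K):
            row = stats[stats["state"] == k]
            dwell = float(row["mean_dwell_s"].iloc[0]) if len(row) else float("nan")
            onset = float(row["mean_first_onset_s"].iloc[0]) if len(row) else float("nan")
            lines.append(f"{k + 1:>5d}  {occ[k]:>14.3f}  {dwell:>14.3f}  {onset:>14.3f}")
        return "\n".join(lines)

    def save(self, path) -> None:
        """Write the fitted model to HDF5."""
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset("W", data=self.W)
            f.create_dataset("noise_var", data=self.noise_var)
            f.create_dataset("Theta", data=self.Theta)
            f.create_dataset("pi", data=self.pi)
            f.create_dataset("gamma", data=self.gamma)
            f.create_dataset("free_energy", data=self.free_energy)
            f.create_dataset("em_sse", data=self.em_sse)
            f.attrs["K"] = self.K
            f.attrs["tol"] = self.model.tol
            f.attrs["prior_alpha"] = self.model.prior_alpha


def fit_tuda(data: EpochedDataset, K: int, **options) -> tuple[TudaModelParams, StateTimeCourses]:
    """Functional wrapper: fit the three-stage pipeline and return
    ``(params, state time courses)``."""
    res = TUDA(data, K, **options).fit()
    return res.params, res.state_time_courses()
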