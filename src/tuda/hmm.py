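"""Hidden Markov machinery shared by the decoding-state model.

Scaled forward-backward recursions and Viterbi decoding, vectorized over
trials (every trial shares the transition matrix, so the recursion loops
over time and operates on all trials at once).  Inputs are per-state
log-likelihoods; transition parameters may be sub-normalized (as produced by
variational posterior expectations ``exp(E[log theta])``), in which case the
returned log-evidence is the variational lower-bound normalizer rather than
a true marginal likelihood.
"""

from __future__ import annotations

import dataclasses

import numpy as np

__all__ = ["StateTimeCourses", "forward_backward", "viterbi_paths"]


@dataclasses.dataclass
class StateTimeCourses:
    """Posterior state probabilities per trial and timepoint.

    ``gamma[s, t, k]`` is the probability that state k is active at time t
    of trial s; ``xi[s, t, l, k]`` the joint posterior of (state l at t,
    state k at t+1).  ``log_evidence`` holds the per-trial log normalizer.
    """

    gamma: np.ndarray  # (S, T, K)
    xi: np.ndarray | None = None  # (S, T-1, K, K)
    log_evidence: np.ndarray | None = None  # (S,)

    @property
    def n_states(self) -> int:
        return self.gamma.shape[2]

    def occupancy(self) -> np.ndarray:
        """Mean state probability over trials, per (time, state)."""
        return self.gamma.mean(axis=0)


def _validate_hmm_params(Theta: np.ndarray, pi: np.ndarray, K: int, *, normalized: bool) -> None:
    if Theta.shape != (K, K) or pi.shape != (K,):
        raise ValueError("Theta/pi shapes inconsistent with the likelihood array")
    if (Theta < 0).any() or (pi < 0).any():
        raise ValueError("Theta and pi must be non-negative")
    if normalized:
        if not np.allclose(Theta.sum(axis=1), 1.0, atol=1e-8):
            raise ValueError("rows of Theta must sum to 1")
        if not np.isclose(pi.sum(), 1.0, atol=1e-8):
            raise ValueError("pi must sum to 1")


def forward_backward(
    loglik: np.ndarray,
    Theta: np.ndarray,
    pi: np.ndarray,
    *,
    compute_xi: bool = True,
    allow_subnormalized: bool = False,
) -> StateTimeCourses:
    """Exact HMM posterior marginals via scaled forward-backward.

    Parameters
    ----------
    loglik : ndarray, shape (n_trials, T, K)
        Per-state observation log-likelihoods.
    Theta, pi : ndarray
        Transition matrix (rows: from-state) and initial distribution.
    compute_xi : bool
        Also return the pairwise posteriors (needed for transition updates).
    allow_subnormalized : bool
        Accept sub-normalized parameters (variational expected-parameter
        recursions); row sums <= 1 are then not enforced.

    Returns
    -------
    StateTimeCourses with ``gamma`` (rows summing to one), optional ``xi``
    and the per-trial log-evidence from the scaling constants.
    """
    loglik = np.asarray(loglik, dtype=float)
    if loglik.ndim != 3:
        raise ValueError("loglik must be trials x time x states")
    S, T, K = loglik.shape
    Theta = np.asarray(Theta, dtype=float)
    pi = np.asarray(pi, dtype=float)
    _validate_hmm_params(Theta, pi, K, normalized=not allow_subnormalized)

    # per-(s,t) shift keeps exp() in range; folded into the log-evidence
    shift = loglik.max(axis=2)
    if not np.isfinite(shift).all():
        s, t = np.unravel_index(int(np.argmin(shift)), shift.shape)
        raise FloatingPointError(
            f"all states have zero likelihood at trial {s}, time {t}"
        )
    b = np.exp(loglik - shift[:, :, None])  # (S, T, K), max 1 per (s,t)

    alpha = np.empty((S, T, K))
    scale = np.empty((S, T))
    a = pi[None, :] * b[:, 0, :]
    scale[:, 0] = a.sum(axis=1)
    if (scale[:, 0] <= 0).any():
        raise FloatingPointError("zero forward mass at t=0")
    alpha[:, 0] = a / scale[:, 0, None]
    for t in range(1, T):
        a = (alpha[:, t - 1] @ Theta) * b[:, t]
        scale[:, t] = a.sum(axis=1)
        if (scale[:, t] <= 0).any():
            s = int(np.argmax(scale[:, t] <= 0))
            raise FloatingPointError(f"zero forward mass at trial {s}, time {t}")
        alpha[:, t] = a / scale[:, t, None]

    beta = np.empty((S, T, K))
    beta[:, T - 1] = 1.0
    for t in range(T - 2, -1, -1):
        beta[:, t] = (beta[:, t + 1] * b[:, t + 1]) @ Theta.T
        beta[:, t] /= scale[:, t + 1, None]

    gamma = alpha * beta
    gamma /= gamma.sum(axis=2, keepdims=True)

    xi = None
    if compute_xi and T > 1:
        # xi[s,t] prop alpha_t (.) Theta (.) b_{t+1} beta_{t+1}
        xi = (
            alpha[:, :-1, :, None]
            * Theta[None, None, :, :]
            * (b[:, 1:, None, :] * beta[:, 1:, None, :])
            / scale[:, 1:, None, None]
        )
        xi /= xi.sum(axis=(2, 3), keepdims=True)

    log_evidence = np.log(scale).sum(axis=1) + shift.sum(axis=1)
    return StateTimeCourses(gamma=gamma, xi=xi, log_evidence=log_evidence)


def viterbi_paths(loglik: np.ndarray, Theta: np.ndarray, pi: np.ndarray) -> np.ndarray:
    """Most probable state path per trial (ties broken to the lowest index).

    Returns an integer array of shape (n_trials, T) with 0-based states.
    """
    loglik = np.asarray(loglik, dtype=float)
    S, T, K = loglik.shape
    Theta = np.asarray(Theta, dtype=float)
    pi = np.asarray(pi, dtype=float)
    _validate_hmm_params(Theta, pi, K, normalized=False)
    with np.errstate(divide="ignore"):
        logTheta = np.log(Theta)
        logpi = np.log(pi)

    delta = logpi[None, :] + loglik[:, 0]
    back = np.empty((S, T, K), dtype=np.int64)
    for t in range(1, T):
        cand = delta[:, :, None] + logTheta[None, :, :]  # (S, from, to)
        back[:, t] = cand.argmax(axis=1)  # argmax picks lowest index on ties
        delta = cand.max(axis=1) + loglik[:, t]

    paths = np.empty((S, T), dtype=np.int64)
    paths[:, T - 1] = delta.argmax(axis=1)
    for t in range(T - 2, -1, -1):
        paths[:, t] = back[np.arange(S), t + 1, paths[:, t + 1]]
    return paths
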