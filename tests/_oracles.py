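"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own recursions: posterior marginals
and best paths are computed by exhaustive enumeration over all K**T state
sequences, and clustering by explicit greedy merging.  Only feasible for
tiny instances, which is the point.
"""

import itertools

import numpy as np


def enumerate_posteriors(loglik_trial: np.ndarray, Theta: np.ndarray, pi: np.ndarray):
    """Exact gamma, xi and log-evidence for one trial by path enumeration.

    ``loglik_trial`` is (T, K).  Returns (gamma (T,K), xi (T-1,K,K), logZ).
    """
    T, K = loglik_trial.shape
    gamma = np.zeros((T, K))
    xi = np.zeros((max(T - 1, 0), K, K))
    Z = 0.0
    with np.errstate(divide="ignore"):
        logTheta = np.log(Theta)
        logpi = np.log(pi)
    for path in itertools.product(range(K), repeat=T):
        logw = logpi[path[0]] + loglik_trial[0, path[0]]
        for t in range(1, T):
            logw += logTheta[path[t - 1], path[t]] + loglik_trial[t, path[t]]
        w = np.exp(logw)
        Z += w
        for t in range(T):
            gamma[t, path[t]] += w
        for t in range(T - 1):
            xi[t, path[t], path[t + 1]] += w
    gamma /= Z
    xi /= Z
    return gamma, xi, np.log(Z)


def enumerate_best_path(loglik_trial: np.ndarray, Theta: np.ndarray, pi: np.ndarray):
    """Most probable path by exhaustive search; ties to the lexicographically
    smallest path (matching lowest-index tie-breaking)."""
    T, K = loglik_trial.shape
    with np.errstate(divide="ignore"):
        logTheta = np.log(Theta)
        logpi = np.log(pi)
    best, best_score = None, -np.inf
    for path in itertools.product(range(K), repeat=T):
        score = logpi[path[0]] + loglik_trial[0, path[0]]
        for t in range(1, T):
            score += logTheta[path[t - 1], path[t]] + loglik_trial[t, path[t]]
        if score > best_score + 1e-12 or best is None:
            best, best_score = path, score
    return np.array(best)


def single_linkage_labels(dist: np.ndarray, n_clusters: int) -> np.ndarray:
    """Greedy single-linkage agglomeration on a full distance matrix."""
    n = dist.shape[0]
    clusters = [{i} for i in range(n)]
    while len(clusters) > n_clusters:
        best = None
        best_d = np.inf
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                d = min(dist[a, b] for a in clusters[i] for b in clusters[j])
                if d < best_d:
                    best_d, best = d, (i, j)
        i, j = best
        clusters[i] |= clusters[j]
        del clusters[j]
    labels = np.empty(n, dtype=int)
    for c, members in enumerate(clusters):
        for m in members:
            labels[m] = c
    return labels


def random_hmm_instance(rng: np.random.Generator, K: int, T: int, S: int = 1):
    """A random, well-conditioned HMM likelihood instance."""
    Theta = rng.dirichlet(np.ones(K) * 2.0, size=K)
    pi = rng.dirichlet(np.ones(K) * 2.0)
    loglik = rng.normal(0.0, 1.5, size=(S, T, K))
    return loglik, Theta, pi
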