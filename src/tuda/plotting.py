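"""Minimal diagnostic plots: occupancy curves and temporal-generalization maps."""

from __future__ import annotations

import numpy as np


def plot_occupancy(occupancy: np.ndarray, sampling_rate: float = 1.0, ax=None):
    """Stacked occupancy curves (fraction of trials per state over time)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    T, K = occupancy.shape
    t = np.arange(T) / sampling_rate
    for k in range(K):
        ax.plot(t, occupancy[:, k], label=f"state {k + 1}")
    ax.set_xlabel("time (s)")
    ax.set_ylabel("occupancy")
    ax.legend(fontsize="small")
    return ax


def plot_generalization(matrix: np.ndarray, sampling_rate: float = 1.0, ax=None, **imshow_kw):
    """Train-time x test-time map (CV-R^2 or divergence)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    T = matrix.shape[0]
    extent = [0, T / sampling_rate, T / sampling_rate, 0]
    im = ax.imshow(matrix, extent=extent, aspect="auto", **imshow_kw)
    ax.set_xlabel("test time (s)")
    ax.set_ylabel("train time (s)")
    ax.figure.colorbar(im, ax=ax)
    return ax
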