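"""Synthetic data generators.

Two generators are provided:

* :func:`simulate_linear_states` — a sequential hidden-state generative model:
  K decoding states, each a linear map from per-trial stimulus features to a
  disjoint subset of channels, visited in a fixed order with Gaussian dwell
  times sampled independently per trial.  This is the canonical test bed for
  showing how per-timepoint decoding misreads asynchronous trials.
* :func:`simulate_angle_task` — an orientation-matching task emulator: 16
  grating orientations encoded as sine/cosine covariates, state-onset jitter
  per trial, and a reaction time generated as an affine function of a chosen
  state's onset plus a relative-angle effect, for exercising the behavioral
  analyses end to end.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .datasets import EpochedDataset

__all__ = [
    "LinearStateSimSpec",
    "GroundTruth",
    "AngleTaskTruth",
    "sample_state_paths",
    "simulate_linear_states",
    "simulate_angle_task",
    "five_state_spec",
]


@dataclasses.dataclass
class LinearStateSimSpec:
    """Parameters of the sequential linear-state generative model.

    Defaults reproduce the five-state benchmark: 200 trials of 2 s at 500 Hz
    (1000 samples), 20 channels, 5 states each driving its own 4 channels,
    3 stimulus features drawn uniform on [0, 1] (an RGB color), observation
    noise sd 0.1, mean dwell times 0.2–0.6 s with per-trial Gaussian
    variability.

    ``dwell_dispersions`` are standard deviations in seconds by default; set
    ``dispersion_is_variance=True`` to read them as variances (s^2).
    """

    n_trials: int = 200
    n_timepoints: int = 1000
    sampling_rate: float = 500.0
    n_channels: int = 20
    n_states: int = 5
    n_stim_features: int = 3
    active_channels_per_state: int = 4
    noise_sd: float = 0.1
    dwell_means: tuple[float, ...] = (0.2, 0.3, 0.4, 0.5, 0.6)
    dwell_dispersions: tuple[float, ...] = (0.02, 0.05, 0.12, 0.5, 0.8)
    dispersion_is_variance: bool = False
    transition_order: tuple[int, ...] | None = None  # default 0..K-1
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "n_trials",
            "n_timepoints",
            "n_channels",
            "n_states",
            "n_stim_features",
            "active_channels_per_state",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if len(self.dwell_means) != self.n_states:
            raise ValueError("dwell_means must have one entry per state")
        if len(self.dwell_dispersions) != self.n_states:
            raise ValueError("dwell_dispersions must have one entry per state")
        if any(m <= 0 for m in self.dwell_means):
            raise ValueError("dwell_means must be positive")
        if self.transition_order is None:
            self.transition_order = tuple(range(self.n_states))
        order = tuple(self.transition_order)
        if sorted(order) != list(range(self.n_states)):
            raise ValueError("transition_order must visit every state exactly once")
        self.transition_order = order
        # minimum of one sample per state visit must fit in the trial
        if self.n_states > self.n_timepoints:
            raise ValueError("summed minimum dwells exceed n_timepoints")

    @property
    def dwell_sds(self) -> np.ndarray:
        """Per-state dwell standard deviations in seconds."""
        disp = np.asarray(self.dwell_dispersions, dtype=float)
        return np.sqrt(disp) if self.dispersion_is_variance else disp


@dataclasses.dataclass
class GroundTruth:
    """True latent structure of a simulated dataset (0-based state labels)."""

    state_path: np.ndarray  # (n_trials, n_timepoints) int
    true_weights: np.ndarray | None = None  # (n_states, n_features, n_channels)
    dwell_durations: list[list[int]] | None = None  # per-state sampled visit lengths (samples)


def sample_state_paths(spec: LinearStateSimSpec, rng: np.random.Generator | None = None) -> GroundTruth:
    """Sample per-trial state paths of the sequential dwell model.

    Every trial starts in the first state of ``transition_order`` and visits
    each state once, in order.  Each visit length is drawn from a Gaussian
    with the state's dwell mean/sd, rounded to the nearest sample and clamped
    to at least one sample; the concatenated path is truncated at
    ``n_timepoints`` (overruns) or the final state is extended (underruns).
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    K, T = spec.n_states, spec.n_timepoints
    fs = spec.sampling_rate
    means = np.asarray(spec.dwell_means, dtype=float)
    sds = spec.dwell_sds
    order = list(spec.transition_order)

    paths = np.empty((spec.n_trials, T), dtype=np.int64)
    dwell_durations: list[list[int]] = [[] for _ in range(K)]
    for s in range(spec.n_trials):
        draws = rng.normal(means[order], sds[order])  # seconds, in visit order
        samples = np.maximum(np.rint(draws * fs).astype(int), 1)
        for k, d in zip(order, samples):
            dwell_durations[k].append(int(d))
        bounds = np.cumsum(samples)
        path = np.repeat(order, samples)
        if bounds[-1] >= T:
            path = path[:T]
        else:
            path = np.concatenate([path, np.full(T - bounds[-1], order[-1])])
        paths[s] = path
    return GroundTruth(state_path=paths, dwell_durations=dwell_durations)


def _draw_state_weights(spec: LinearStateSimSpec, rng: np.random.Generator) -> np.ndarray:
    """Per-state (features x channels) weights with disjoint channel support."""
    K, a, C = spec.n_states, spec.active_channels_per_state, spec.n_channels
    if K * a > C:
        raise ValueError(
            f"cannot assign {K} disjoint supports of {a} channels with only {C} channels"
        )
    W = np.zeros((K, spec.n_stim_features, C))
    channels = rng.permutation(C)[: K * a].reshape(K, a)
    for k in range(K):
        W[k][:, channels[k]] = rng.uniform(0.0, 1.0, size=(spec.n_stim_features, a))
    return W


def simulate_linear_states(
    spec: LinearStateSimSpec,
) -> tuple[EpochedDataset, GroundTruth]:
    """Generate a dataset from the sequential linear-state model.

    Per trial, stimulus features are uniform on [0, 1] and constant over the
    trial; the observation at (trial s, time t) is the stimulus row times the
    active state's weight matrix plus isotropic Gaussian noise.
    """
    rng = np.random.default_rng(spec.seed)
    truth = sample_state_paths(spec, rng)
    truth.true_weights = _draw_state_weights(spec, rng)

    Y = rng.uniform(0.0, 1.0, size=(spec.n_trials, spec.n_stim_features))
    # signal[s, t] = Y[s] @ W[path[s, t]]
    per_state = np.einsum("sf,kfc->ksc", Y, truth.true_weights)
    signal = per_state[truth.state_path, np.arange(spec.n_trials)[:, None], :]
    noise = rng.normal(0.0, spec.noise_sd, size=signal.shape) if spec.noise_sd > 0 else 0.0
    X = signal + noise
    data = EpochedDataset(X=X, Y=Y, sampling_rate=spec.sampling_rate)
    return data, truth


def five_state_spec(seed: int = 0, **overrides) -> LinearStateSimSpec:
    """The default five-state benchmark specification (overridable)."""
    return LinearStateSimSpec(seed=seed, **overrides)


# ---------------------------------------------------------------------------
# angle-matching task emulator
# ---------------------------------------------------------------------------

ANGLE_GRID_DEG = np.arange(5.625, 175.0, 11.25)  # 16 orientations


@dataclasses.dataclass
class AngleTaskTruth:
    """Latent structure behind an angle-task simulation."""

    state_path: np.ndarray
    true_weights: np.ndarray
    angles_deg: np.ndarray  # presented orientation per trial
    rel_angle_deg: np.ndarray  # |relative angle| to the template, in [0, 90]
    onset_samples: np.ndarray  # onset of the RT-linked state per trial
    link_state: int
    rt_intercept: float
    rt_onset_slope: float  # s of RT per s of onset
    rt_angle_slope: float  # s of RT per degree of relative angle
    rt_noise_sd: float


def relative_angle_deg(angles_deg: np.ndarray, template_deg: float) -> np.ndarray:
    """Absolute angular distance to a template respecting 180-deg periodicity."""
    d = np.abs(np.asarray(angles_deg, dtype=float) - template_deg) % 180.0
    return np.minimum(d, 180.0 - d)


def simulate_angle_task(
    n_trials: int = 200,
    n_timepoints: int = 150,
    *,
    sampling_rate: float = 250.0,
    n_channels: int = 16,
    n_states: int = 3,
    active_channels_per_state: int = 4,
    noise_sd: float = 0.1,
    dwell_means: tuple[float, ...] = (0.15, 0.2, 0.25),
    dwell_dispersions: tuple[float, ...] = (0.0, 0.0, 0.0),
    onset_jitter_choices: tuple[float, ...] | None = (0.0, 0.08),
    double_angle: bool = True,
    template_deg: float = 90.0,
    link_state: int = 1,
    rt_intercept: float = 0.3,
    rt_onset_slope: float = 1.0,
    rt_angle_slope: float = 0.002,
    rt_noise_sd: float = 0.02,
    no_press_prob: float = 0.1,
    n_subjects: int = 1,
    seed: int = 0,
) -> tuple[EpochedDataset, AngleTaskTruth]:
    """Emulate an orientation-matching task with an RT-linked state onset.

    Orientations are drawn uniformly from the 16-angle grid (5.625–174.375
    deg in 11.25-deg steps) and encoded as sine/cosine covariates; gratings
    are 180-deg periodic, so by default the features are sin/cos of twice the
    angle (``double_angle=False`` gives plain sin/cos).  Data come from the
    sequential linear-state model; per-trial onset jitter is injected by
    adding a draw from ``onset_jitter_choices`` (seconds) to the first
    state's dwell, shifting every later state onset by that amount (with
    ``None``, jitter comes from the Gaussian dwell dispersions alone).
    Reaction time is affine in the onset of ``link_state`` plus a
    relative-angle effect plus Gaussian noise; a configurable fraction of
    trials is flagged as "no button press" (RT = NaN).
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    rng = np.random.default_rng(seed)
    spec = LinearStateSimSpec(
        n_trials=n_trials,
        n_timepoints=n_timepoints,
        sampling_rate=sampling_rate,
        n_channels=n_channels,
        n_states=n_states,
        n_stim_features=2,
        active_channels_per_state=active_channels_per_state,
        noise_sd=noise_sd,
        dwell_means=dwell_means,
        dwell_dispersions=dwell_dispersions,
        seed=seed,
    )
    truth = sample_state_paths(spec, rng)
    if onset_jitter_choices is not None:
        jitter_s = rng.choice(np.asarray(onset_jitter_choices, dtype=float), size=n_trials)
        shift = np.rint(jitter_s * sampling_rate).astype(int)
        for s in range(n_trials):
            if shift[s] > 0:
                first = truth.state_path[s, 0]
                shifted = np.concatenate(
                    [np.full(shift[s], first), truth.state_path[s, : n_timepoints - shift[s]]]
                )
                truth.state_path[s] = shifted

    W = _draw_state_weights(spec, rng)
    angles = rng.choice(ANGLE_GRID_DEG, size=n_trials)
    theta = np.deg2rad(angles * (2.0 if double_angle else 1.0))
    Y = np.column_stack([np.sin(theta), np.cos(theta)])

    per_state = np.einsum("sf,kfc->ksc", Y, W)
    signal = per_state[truth.state_path, np.arange(n_trials)[:, None], :]
    X = signal + (rng.normal(0.0, noise_sd, size=signal.shape) if noise_sd > 0 else 0.0)

    # onset of the RT-linked state (first sample where it is active)
    onset = np.array(
        [
            int(np.argmax(truth.state_path[s] == link_state))
            if (truth.state_path[s] == link_state).any()
            else n_timepoints
            for s in range(n_trials)
        ]
    )
    rel = relative_angle_deg(angles, template_deg)
    rt = (
        rt_intercept
        + rt_onset_slope * onset / sampling_rate
        + rt_angle_slope * rel
        + (rng.normal(0.0, rt_noise_sd, size=n_trials) if rt_noise_sd > 0 else 0.0)
    )
    rt = np.maximum(rt, 1.0 / sampling_rate)  # keep RTs positive
    if no_press_prob > 0:
        rt[rng.uniform(size=n_trials) < no_press_prob] = np.nan

    subject = None
    if n_subjects > 1:
        subject = np.repeat(np.arange(n_subjects), int(np.ceil(n_trials / n_subjects)))[:n_trials]

    data = EpochedDataset(X=X, Y=Y, sampling_rate=sampling_rate, rt=rt, subject=subject)
    task_truth = AngleTaskTruth(
        state_path=truth.state_path,
        true_weights=W,
        angles_deg=angles,
        rel_angle_deg=rel,
        onset_samples=onset,
        link_state=link_state,
        rt_intercept=rt_intercept,
        rt_onset_slope=rt_onset_slope,
        rt_angle_slope=rt_angle_slope,
        rt_noise_sd=rt_noise_sd,
    )
    return data, task_truth
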