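# Methods

## The model

`tuda` implements temporally unconstrained decoding analysis: a hidden
Markov model whose K hidden states are stimulus-decoding regression models.
For trial s and within-trial time t, with data row `x_st` (channels or PCA
components) and per-trial stimulus features `y_s` (e.g. sine/cosine of a
grating orientation),

    y_s = x_st ( Σ_k γ_stk w_k ) + ε_st,      ε_st ~ N(0, σ² I)

where `w_k` is state k's (channels × features) decoding weight matrix,
`γ_stk` the probability that state k is active at (s, t), and σ² a single
noise variance shared across states and features.  State dynamics are
first-order Markov: a K×K transition matrix Θ (rows sum to one) and an
initial distribution π.  The crucial difference from per-timepoint
("standard") decoding is that γ is *trial-specific*: two trials may occupy
different processing stages at the same within-trial time.

Assumptions worth stating explicitly: the decoder is linear and
instantaneous (no embedding, phase or power features); the stimulus is
constant within a trial; the noise is isotropic with a shared variance; and
state identity is defined purely by *how* the stimulus maps to the data, so
two states with identical decoding weights are indistinguishable.

## Inference: three stages

Estimation is deliberately staged so the state decoders remain comparable
with the per-timepoint baseline; weights and dynamics are never estimated
simultaneously.

1. **Initialization by clustering the time axis.**  One OLS decoder `v_t`
   is fitted per timepoint; the across-time error matrix
   `e_tj = Σ_s ‖x_sj v_t − y_s‖²` and its symmetrization `D = e + eᵀ`
   (a divergence between the decoders at t and j, the analogue of a
   temporal-generalization matrix) feed hierarchical clustering of the T
   timepoints into K groups.  Each group's representative weights are
   refit by pooled OLS over its member timepoints.  Which linkage survives
   the geometry of D is instance-dependent — ward/average can chain through
   heavily jittered late states while splitting early ones — so the default
   (`linkage="auto"`) runs the next stage from ward, complete and average
   initializations and keeps the solution with the lowest pooled squared
   error.

2. **Synchronous EM.**  Keeping the between-trial synchrony restriction,
   timepoints (shared by all trials) are alternately reassigned to the
   state with the smallest pooled squared error and state weights refit by
   OLS over their assigned timepoints.  This coordinate descent makes the
   pooled SSE non-increasing; it stops when the assignment is stable or the
   relative SSE change falls below `tol` (default 1e-5, `max_iter` 100).
   After convergence each state's weights are refit once more excluding
   `trim_frac` (default 0.2) of the segment at every edge that abuts
   another state's segment: near those boundaries trials genuinely disagree
   about the active state, and the pooled refit would blend neighboring
   states into the weights — on the five-state benchmark this trimming
   reduces the worst-case error of the first state's recovered dwell from
   0.034 s to 0.003 s.  Trial-start/end edges are never trimmed, so with
   K=1 the estimate reduces exactly to pooled OLS.  The shared noise
   variance is the pooled residual variance of the final weights.

3. **Variational state dynamics.**  With `w_k` and σ² fixed, trial-specific
   state time courses and the dynamics are estimated by variational Bayes:
   symmetric Dirichlet(α=1) priors on each row of Θ and on π; the E-step is
   exact forward–backward (per-timepoint scaling for stability, vectorized
   over trials) under the expected-log parameters `exp(E[log Θ])`; the
   M-step adds the pairwise-posterior counts to the Dirichlet posteriors.
   The variational free energy — the summed forward-pass log-normalizers
   minus the Dirichlet KL terms — is non-decreasing and convergence is
   declared at relative change < `tol`.  Reported Θ and π are posterior
   means.

States are relabeled for reporting by their occupancy-weighted mean
activation time, so state 1 is the earliest-arising state.  Ties anywhere
(assignments, Viterbi back-pointers) break to the lowest state index.
Hard state paths for dwell/onset statistics come from Viterbi decoding;
dwell time of a state within a trial is the total time assigned to it
(visits may occasionally fragment), and occupancy is the trial-fraction per
(time, state).

## Evaluation

Cross-validation is over trials (K-fold, shuffled, seeded).  Two schemes:
**unbiased** predicts held-out stimuli with the training trials' mean state
time course per timepoint (discarding between-trial variability);
**biased** runs forward–backward on each held-out trial — which uses that
trial's stimulus — to obtain trial-specific time courses before predicting.
Accuracy is CV-R² = 1 − SSE/SST pooled over folds, trials, timepoints and
features, with SST about the training-fold stimulus mean (the stimulus is
constant within trial, so the per-trial SST is counted once per timepoint).

Because the biased scheme peeks at the held-out stimulus, both schemes are
corrected by a **surrogate baseline**: stimulus rows are permuted across
trials; per fold, state weights are refit against the permuted stimulus
with the original state time courses held fixed (option `refit_weights=False`
freezes them instead), and the fold is scored identically.  The reported
baseline is the 5th percentile of the surrogate accuracy distribution
(read literally; a `percentile` switch allows 95), and
adjusted CV-R² = raw − baseline.  Note that subtracting a *5th* percentile
leaves a positive offset of roughly 1.6 surrogate-standard-deviations under
the null, so null calibration requires enough trials for the surrogate
distribution to be tight; the calibration test uses 256 trials for this
reason.

**Encoding models** reverse the regression: per sensor l and state k,
`b_lk = (Yᵀ diag(γ_k) Y)⁻¹ (Yᵀ diag(γ_k) X^l)` over the concatenated
samples, with the explained-variance map given by the γ-weighted R² of
predicting the sensor from the stimulus.  When fitted in PCA space, the
stored projection maps results back to sensors.

## The behavior chain

Reaction time is never part of the model, so RT analyses provide an
external check on the estimated timing.  The chain: discard trials without
a button press; regress the absolute relative angle (mapped to [0°, 90°]
respecting orientation periodicity) out of both the state time courses and
RT (OLS with intercept, applied before any PCA); correlate deconfounded
γ with deconfounded RT per (time, state), zeroing correlations where a
γ column has no across-trial variation (a residual-of-a-constant otherwise
produces arbitrary values); build prototypical sequences; and predict RT.

**Prototypical sequences.**  A state active at time t only on fast trials
*anti*-correlates with RT there, so the short-RT prototype takes the
per-time argmin of the correlation curves and the long-RT prototype the
argmax (`convention="fast-positive"` swaps them for the literal reading in
which the highest correlation marks the short-RT trial; that reading
contradicts the expectation that states activate earlier on fast trials,
which is why it is not the default).  A subtlety uncovered while designing
the generative check: with two trial groups shifted by a lag L, RT
information exists only inside the transition windows, where the short
prototype shows the state the fast group has already reached and the long
prototype the state the slow group still occupies.  The long sequence
therefore replays the short one delayed by the *inter-boundary spacing*
(the intermediate state's dwell) — exactly — rather than by L.  The
package measures that lead with `sequence_lead`, a weighted agreement
maximizer (weights = per-time maximum |correlation|, suppressing
uninformative stretches), and the recovery test asserts the link-state
dwell within ±2 samples on the generator's own state paths.

**RT prediction.**  Per state, the trials × timepoints matrix of
deconfounded time courses is compressed to `n_pcs` (default 25) principal
component scores; scores are concatenated across states.  Outer CV is
leave-one-subject-out when subject labels exist (subjects with fewer than
5 trials are excluded), otherwise 5 random folds; features are standardized
within each training fold; the L1 penalty is selected by inner 5-fold CV on
a 20-point logarithmic grid spanning 1e-3…1e1 times the data-scaled
λ_max.  Significance comes from permutation: the null refits the lasso on
shuffled RTs through the same folds at the penalty selected on the
unpermuted data (re-running the inner penalty search per permutation would
multiply the cost several-hundred-fold without changing the null's
location).

## The synthetic generators

`simulate_linear_states` reproduces a five-state sequential benchmark: 200
trials of 2 s at 500 Hz (1000 samples), 20 channels, 3 uniform-[0,1]
stimulus features constant within trial, 5 states visited in a fixed order,
each state driving its own disjoint set of 4 channels with uniform-[0,1]
weights, observation noise sd 0.1.  Per-trial dwell times are Gaussian with
means 0.2/0.3/0.4/0.5/0.6 s and dispersions 0.02/0.05/0.12/0.5/0.8 s —
read as standard deviations in seconds (the printed units force this
reading; `dispersion_is_variance=True` treats them as variances).  Draws
are rounded to the nearest sample and clamped to ≥1 sample (resampling
negative draws would bias the mean upward at large dispersion); overruns of
the trial are truncated and underruns extend the final state.  Because the
late states' dispersions exceed their means, many late visits clamp or
truncate: an oracle decoder with the true weights, noise and transitions
recovers only ≈89% of (trial, time) samples on this benchmark, so
sample-level path agreement is reported against that ceiling, not against
100%.

`simulate_angle_task` emulates an orientation-matching task: 16 grating
angles (5.625°–174.375° in 11.25° steps) encoded as sin/cos of twice the
angle (orientations are 180°-periodic; plain sin/cos is a switch), a
sequential linear-state backbone (defaults: 200 trials × 0.6 s at 250 Hz,
16 channels, 3 states with dwells 0.15/0.2/0.25 s), per-trial onset jitter
drawn from a configurable finite set (default {0, 80 ms}) added to the
first state's dwell, and RT = 0.3 s + 1.0 × (link-state onset in s)
+ 0.002 s/° × |relative angle| + N(0, 0.02 s), with 10% of trials flagged
as no-button-press.  These coefficient choices give an onset-dominated RT
with realistic noise so that the deconfounding and prediction steps are
exercised non-trivially.

Neither generator emulates oscillations, sensor topographies, correlated
MEG noise, artifacts or non-stationary noise levels; passing tests
demonstrate correctness of the estimation machinery under the model's own
assumptions, not robustness to real-MEG violations of them.

## Numerical choices

- Every OLS solve goes through one routine with a ridge policy: `"auto"`
  adds 1e-8 × mean Gram diagonal (floored at 1e-12) to keep PCA-reduced or
  degenerate designs solvable; `None` raises on singular normal equations,
  naming the offending timepoints.
- Across-time error matrices are computed from per-timepoint sufficient
  statistics (XᵀX, XᵀY, ‖Y‖²) via the quadratic-form identity, never by
  materializing T×T prediction tensors; tiny negative values from
  cancellation are clipped to zero.
- Forward–backward uses per-timepoint scaling plus a per-(s,t) max-shift of
  the log-likelihoods; an all-impossible observation raises an error naming
  the trial and time.
- Correlation distances treat constant weight vectors as distance 1 with a
  warning.
- All simulation randomness flows through `numpy.random.default_rng(seed)`;
  fits are deterministic given the data.

## Problem sizes used by the shipped checks

The test suite exercises the full five-state benchmark (200×1000×20) once
for recovery/monotonicity/artifact checks and uses 40–256-trial reductions
elsewhere; the acceptance script averages five independent
simulate-and-fit replicates of the full benchmark (1000 trials in total),
seeds derived from `--seed` via `SeedSequence`.  These sizes are the
package's chosen trade-off between Monte-Carlo stability and a suite that
runs in a few minutes on one CPU.

## Known limitations

- The staged estimation never revisits the decoding weights after the
  synchronous stage, so weight estimates retain some boundary blending
  (matched weight correlations with the oracle-restricted OLS reference are
  ≈0.9–0.99, not 1), and heavy dwell jitter bounds achievable path
  agreement well below 100% (see the oracle ceiling above).
- The shared-variance Gaussian observation model makes state evidence
  scale-sensitive: states with weak stimulus coupling are harder to place
  precisely.
- The surrogate correction assumes exchangeability of trials under label
  permutation; structured trial orderings (learning, drift) would violate
  it.
- Group-level RT prediction concatenates sessions after per-session
  standardization; no hierarchical shrinkage across subjects is attempted.
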