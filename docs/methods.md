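# Methods

`brainstates` implements a pipeline for discovering and characterising
transient oscillatory states in short, response-locked, multichannel
neural source recordings, and for relating those states to experimental
conditions and behaviour. This note documents the models, the tunable
parameters, the synthetic study conditions, and the numerical choices.

## The state model

### Time-delay embedding

A latent brain "state" here is a recurring *spectral* pattern — a
configuration of band-limited power and cross-channel phase-locking — not
a mean voltage level. To let a hidden Markov model see spectral structure,
each sample is replaced by a window of lagged samples: with a 60 ms
centred window at fs = 250 Hz, the frame at sample *t* stacks samples
*t−7…t+7* of all channels (channel-major), so 8 channels embed into a
15 × 8 = 120-dimensional space. Frames never span trial boundaries; edge
samples without a full window are dropped, so a 275-sample trial yields
261 frames.

The embedded frames are projected onto the top principal components
before HMM fitting — 16 by default, twice the channel count — which
regularises the 120 × 120 state covariances down to 16 × 16.

### Zero-mean Gaussian HMM

Each state k is a full covariance matrix Σ_k in PC space with the
observation mean fixed at zero: signals are baseline-corrected, and the
information of interest (autocovariance within the embedding window, i.e.
rhythm and phase-locking) lives entirely in second moments. Inference is
expectation–maximisation:

- E-step: scaled forward–backward per trial (each trial is an independent
  chain re-initialised from the initial distribution; no transitions
  across trial boundaries). Equal-length trials are processed as one
  batched recursion for speed.
- M-step: Σ_k = Σ_t γ_tk x_t x_tᵀ / Σ_t γ_tk; transition rows from
  expected transition counts (a symmetric Dirichlet prior with
  concentration 1 is flat, so the MAP update coincides with maximum
  likelihood); initial probabilities from first-frame posteriors.
- Convergence: relative log-likelihood change < 1e-6, at most 500
  iterations; the log-likelihood trace is stored and is monotone
  non-decreasing (an EM guarantee the tests assert).
- Restarts: 5 by default, each initialised from a random per-frame
  responsibilities draw with a deterministic child seed; the best final
  log-likelihood wins, ties broken by restart index.
- Degenerate covariances (condition number > 1e12) receive a diagonal
  jitter of 1e-6 × mean diagonal, and the event is logged.

Full-data EM was preferred over stochastic/minibatch variational updates:
at desk scale determinism matters more than wall-clock, and the tests
require bit-reproducible fits. K = 1 is supported (posterior trivially
one) although the pipeline default is K = 4.

The exact recursions are validated two ways: against exhaustive
enumeration over all K^T paths on small random instances, and against an
independent HMM library configured with the same parameters.

### State metrics

All dynamic metrics derive from the hard Viterbi path, not the soft
posteriors: fractional occupancy (FO, fraction of a trial's frames in a
state), lifetimes (maximal constant runs, in seconds), and switching rate
(state changes per second). Using the Viterbi path for all three keeps
them mutually consistent — the summed lifetimes of a state equal
FO × trial duration exactly, which soft-weighted FO would violate. Soft
occupancies remain available from the γ array for users who want them.

## State spectra and frequency modes

Per-state cross-spectra are posterior-weighted Welch estimates: Hann
windows of 0.5 s with 50% overlap, each segment's periodogram
cross-product weighted by the state's mean per-sample posterior over the
segment. Because the weights sum to one across states in every segment,
the weight-averaged state spectra reproduce the unconditional spectrum
exactly (asserted in tests). Coherence is |S_ij|/√(S_ii S_jj) ∈ [0, 1].
A deterministic weighted-Welch estimator was chosen over multitaper: at
0.5 s segments the frequency resolution (2 Hz) already matches the scale
of the questions asked of it, and determinism simplifies testing. The
frequency grid is restricted to 1–45 Hz.

Coherence spectra of all states and channel pairs are stacked into a
freqs × (states·pairs) matrix and factorised by non-negative matrix
factorisation (multiplicative updates, Frobenius loss, 10 restarts with
fixed child seeds, best reconstruction kept) into a small number of
frequency modes; each mode's peak and half-maximum bounds are read off
its spectral profile. Only coherence enters the factorisation; power can
be projected onto the same modes afterwards.

Per-trial state-conditional band features feed one-tailed permutation
tests (state labels shuffled independently within each trial) in each
direction, with the add-one convention p ≥ 1/(n_perm + 1).

## Condition-level inference

- FO condition tests: the analysis unit is the per-subject mean FO within
  a condition. For each state pair the statistic is the median paired
  difference; the null swaps the two states' values per unit (equivalent
  to sign-flipping the paired differences), two-tailed, with
  Benjamini–Hochberg correction across all condition × pair comparisons.
  Note a median statistic over n units cannot resolve p below roughly
  2^(−n/2); with 20 subjects that floor is ~0.001.
- Decoding: a linear SVM on trial-wise FO vectors, stratified 5-fold CV,
  regularisation selected on the 26-value grid 10^−5 … 10^0 in steps of
  0.2 log10 units. Both the best-over-grid accuracy and the top-of-grid
  (plateau) accuracy are reported; the headline is best-over-grid.
- State matching: states of two independently fitted models are compared
  by Pearson correlation between vectorised observation covariances
  (back-projected to embedded space when the models live in different PCA
  bases) and matched by exact optimal bipartite assignment.
- Half-split reliability: random subject halves, independent full
  pipeline fits per half, matching per repeat; matched-vs-unmatched
  similarity contrast summarises reliability.

## Evoked analysis

Epochs are windowed relative to the response event and each channel's
mean over a baseline interval is subtracted. Global field power is the
across-channel population standard deviation of the condition-averaged
evoked response — invariant to common offsets. The 1-D cluster
permutation test uses a one-sample t statistic per time point, a
cluster-forming threshold defaulting to the two-tailed t critical value
at 0.05 with n−1 df (flagged in output metadata as a default, since
field practice varies), summed-t cluster mass, and a max-statistic null
from whole-series sign flips — the correct exchangeability operation for
paired differences. Zero-variance time points are excluded with a
warning. Contiguity is temporal adjacency only.

## Granger causality by BIC comparison

For a source–target channel pair, the null model is the target's own
order-p autoregression and the augmented model adds source lags
j = 0…p — the instantaneous j = 0 term is included by default to match
the model-comparison definition adopted here (a flag restores the
conventional j ≥ 1 form). Both are ordinary least squares scored by
BIC = n ln(RSS/n) + k ln n. The null order p* minimises the null BIC over
1…p_max (p_max = 20, i.e. 80 ms at 250 Hz); the effect size is the mean
over p = 1…p_max of BIC_null(p*) − BIC_aug(p), positive when the source
improves prediction.

All fits inside one comparison are evaluated on the common sample
t ≥ p_max. With per-model truncation, BICs at different orders are not
comparable (different effective n) and the BIC difference would not be
invariant to a common rescaling of the two series — the n ln(c²) terms
only cancel when n matches. With the common sample, scale invariance is
exact and is asserted numerically to 1e-6.

Two consequences worth knowing: (1) averaging over p accumulates the
(2p+1) ln n complexity penalty, so the averaged dBIC of a genuinely
coupled pair at 1.1 s trial length is typically still negative — its
*ordering* (forward vs reverse, coupled vs null) is the reliable signal,
and the calibration tests check exactly that; (2) trials are analysed
separately and demeaned (not detrended) before fitting, and p* is chosen
per trial.

## Behavioural models

Percept durations are positive and heavy-tailed, so behavioural relevance
is modelled with a gamma-family, log-link GLM of duration on state
lifetime, the directed dBIC, and their product, fitted by IRLS
(tolerance 1e-8, 100 iterations). Nested models are compared by
dAIC = AIC(reduced) − AIC(full) (positive favours the full model) and
Cohen's f² = (R²_full − R²_red)/(1 − R²_full) on deviance-based R².
Duration summaries report the median, adjusted Fisher–Pearson skewness,
and *excess* kurtosis (normal ⇒ 0). Individual differences are checked in
the simplest form — fixed subject intercepts vs a pooled intercept,
compared by AIC and a χ² deviance test — rather than a full mixed model.

## The synthetic study

The generator plants the exact structure the pipeline assumes, so every
stage can be scored against ground truth. Defaults (chosen once, before
calibration results, except where noted):

- 8 ROI channels (lHP, rHP, lIPL, rIPL, ACC, PCC, PCU, V1), 250 Hz,
  275-sample trials (1 s pre-response + 100 ms padding), four conditions,
  20 subjects, 125 trials per condition.
- A first-order K = 4 Markov chain per trial (matching the model fitted,
  so recovery is a well-posed self-consistency check), self-transition
  0.97–0.99 (mean dwells 130–400 ms).
- State signatures: state 1 — 4 Hz with ACC–PCC phase coupling
  (strength 0.9); state 2 — 20 Hz with lIPL–rIPL coupling (0.8);
  state 3 — 34 Hz, uncoupled; state 4 — 11 Hz with PCU–V1 (0.9) and
  PCU–rIPL (0.7) coupling. Oscillator phases are redrawn per dwell; a
  coupled pair shares one phase (constant lag within a dwell), with the
  partner mixing shared and independent phases by weights s and √(1−s²).
- Noise: 1/f (exponent 1, SD 0.5) plus white (SD 0.5) per channel. The
  amplitude/noise ratio was set so that default-SNR frame recovery
  clears 0.85 — the one prescribed calibration.
- Condition bias enters only through the initial distribution and
  transition matrix: each condition channels transitions toward one
  indicative state (BR_dom→4, RPL_dom→2, BR_mix→3, RPL_mix→1), giving it
  a stationary occupancy near 0.68 without touching the spectral
  signatures.
- An optional lagged PCU→V1 coupling (gain 0.5 at lag 2 samples) applies
  only on frames of state 4, the planted analogue of a state-gated
  directed influence.
- Durations follow a gamma GLM on the log scale with coefficients
  (b0, b1, b2, b3) = (0.6, −0.3, −0.05, −0.4) and shape 4 — a heavy-tailed
  distribution whose lifetime × coupling interaction the behavioural
  stage must recover.

What the generator does **not** emulate: volume conduction / source
leakage, non-stationary noise, artefacts (eye movement, cardiac),
semi-Markov dwell distributions, between-subject variability in state
signatures, and any realistic forward model. Passing tests therefore
demonstrate correctness and calibration of the pipeline under its own
assumptions, not performance on real recordings.

## Problem sizes and seeds

The calibration and recovery checks run at the sizes the package's test
suite uses as its study conditions: 500 trials for state recovery and
decoding, 1000 random instances for the exact-inference oracle, 200
replicates for the Granger and cluster-test calibrations, and 100
replicates at n = 2000 for GLM coefficient coverage. A single global seed
drives everything; each stochastic stage derives a child seed
deterministically from (seed, stage name), so identical configurations
reproduce bit-identical results.

## Known limitations

- FO condition tests use a median statistic whose permutation p-floor is
  set by the subject count (see above); very small studies cannot reach
  small adjusted p-values.
- The weighted-Welch state spectra blur states near dwell boundaries
  (segments mix states in proportion to their posterior weight); with
  0.5 s segments and ~200–400 ms dwells, per-trial state-conditional
  coherence estimates are noisy and carry an elevated floor.
- The averaged-dBIC effect size is penalty-dominated at short trial
  lengths (absolute values are not comparable across trial lengths).
- The embedding halves of the window at each dwell boundary are
  inherently ambiguous, which bounds frame-wise recovery below 1 even at
  high SNR.
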