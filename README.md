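# brainstates

Latent oscillatory brain-state analysis for short, response-locked,
multichannel neural source recordings.

In bistable perception (e.g. binocular rivalry), the stimulus is constant
while the percept flips involuntarily — so whatever triggers a flip must
be endogenous. This package implements the analysis pipeline for asking
whether transient spectral states of cortical source signals carry that
endogenous trigger: it discovers recurring states with a time-delay
embedded hidden Markov model (TDE-HMM), characterises each state's power
and phase-coherence spectra, decodes the upcoming percept type from state
occupancies, measures directed precuneus → V1 coupling with a
BIC-compared Granger model, and relates state lifetimes and coupling to
percept durations with gamma GLMs. A synthetic generator with planted
states, couplings, and behavioural effects exercises every stage against
known ground truth.

## The model in brief

Each sample of an 8-channel source recording (fs = 250 Hz) is time-delay
embedded with a 60 ms centred window (15 lags × 8 channels = 120
dimensions), projected onto 16 principal components, and modelled as a
K = 4 state HMM whose observation model is a zero-mean full-covariance
Gaussian per state — i.e. each state is an autocovariance pattern
capturing band-limited power and cross-channel phase-locking:

    x_t | s_t = k  ~  N(0, Σ_k),      p(s_t | s_{t−1}) = A

EM with per-trial forward–backward yields state posteriors γ and the
Viterbi path, from which come fractional occupancy (FO), state lifetimes,
and switching rates. State cross-spectra are posterior-weighted Welch
estimates; their coherence spectra are factorised by NNMF into frequency
modes (theta/alpha/beta/gamma-like). Directed coupling between two
channels is scored by dBIC = BIC_null(p*) − BIC_augmented(p), averaged
over lags p = 1…20, and behaviour is modelled as
duration ~ Gamma(shape, mean = exp(b0 + b1·lifetime + b2·dBIC +
b3·lifetime·dBIC)).

## Worked example

```python
import numpy as np
from brainstates import synth, PipelineConfig
from brainstates.pipeline import run_state_discovery, match_to_truth
from brainstates.spectra import (state_cross_spectra,
                                 coherence_feature_matrix, nnmf_modes)
from brainstates.inference import crossval_decode, regularisation_grid

# a synthetic study: 4 planted states, 500 trials, 20 subjects
trialset, paths, durations = synth.make_dataset(
    n_trials_per_condition=125, n_subjects=20, seed=2026)

cfg = PipelineConfig(rng_seed=2026)
d = run_state_discovery(trialset, cfg)
acc, mapping = match_to_truth(paths.paths, d.posterior,
                              d.embedding.half_window, 4)
print(f"frame-wise state recovery: {acc:.3f}")

ss = state_cross_spectra(trialset, d.posterior)
matrix, _ = coherence_feature_matrix(ss)
modes = nnmf_modes(matrix, ss.freqs, n_modes=4, seed=3)
print("NNMF mode peaks (Hz):", sorted(modes.peak_freqs))

fo = d.metrics.fo
br = np.char.startswith(trialset.condition.astype(str), "BR")
y = np.char.endswith(trialset.condition[br].astype(str), "dom")
res = crossval_decode(fo[br], y, grid=regularisation_grid(), seed=0)
print(f"dominant-vs-mixed decoding accuracy: {res.best_accuracy:.3f}")
```

prints (seed 2026):

```
frame-wise state recovery: 0.889
NNMF mode peaks (Hz): [4.0, 12.0, 20.0, 34.0]
dominant-vs-mixed decoding accuracy: 0.924
```

Recovery of 0.889 means that, after optimally matching fitted to planted
state labels, 88.7% of embedded frames get the correct Viterbi label —
boundary frames inside the 60 ms window are inherently ambiguous, which
keeps this below 1 even at high SNR. The mode peaks sit within one 2 Hz
frequency bin of the planted 4, 11, 20 and 34 Hz signatures, and the
decoder reads the condition-biased occupancy far above the 0.5 chance
level (shuffling labels collapses it to ~0.5).

A command-line interface mirrors the stages
(`brainstates simulate | evoked | fit-hmm | spectra | decode | gc |
behavior | report`); every subcommand logs its config hash and seed so
outputs are regenerable.

## Layout

- `src/brainstates/containers.py`, `io.py` — TrialSet / config, disk format
- `src/brainstates/synth.py` — planted-ground-truth generator
- `src/brainstates/tde.py`, `hmm.py`, `pipeline.py` — the core method
- `src/brainstates/evoked.py` — GFP and cluster permutation test
- `src/brainstates/spectra.py` — state spectra, NNMF modes, feature tests
- `src/brainstates/inference.py` — FO tests, decoding, state matching
- `src/brainstates/gcausal.py` — averaged-dBIC Granger causality
- `src/brainstates/behavior.py` — duration summaries and gamma GLMs
- `docs/methods.md` — full methods note
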