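"""Synthetic trial generator with planted ground truth.

Emulates the statistical structure the downstream stages assume: 8 ROI
source channels sampled at 250 Hz, 1.1 s response-locked trials (1 s
pre-response + 100 ms padding), a hidden K=4 Markov state chain whose
states carry distinct band-limited power / phase-coupling signatures,
condition-dependent state occupancy, an optional lagged PCU->V1 coupling
gated by one state, and heavy-tailed percept durations from a gamma GLM
with a lifetime x Granger-causality interaction.

The generator's defaults define the study conditions of the test suite;
they are not claims about real brains (the generative structure of real
EEG source data is unknown) but planted ground truth for self-consistency
testing of the pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .containers import CONDITIONS, DEFAULT_CHANNELS, TrialSet

__all__ = [
    "Coupling", "OscComponent", "StateSpec", "StatePathTruth", "BehaviorTruth",
    "default_state_spec", "default_condition_dynamics", "sample_state_paths",
    "synthesize_signals", "inject_lagged_coupling", "sample_behavior",
    "make_dataset",
]


@dataclass
class Coupling:
    """Two channels sharing one oscillator with a fixed phase lag."""
    ch_a: int
    ch_b: int
    phase_lag: float      # radians, applied to ch_b
    strength: float       # in [0, 1]; 1 = fully shared phase, 0 = independent

    def __post_init__(self):
        if not 0.0 <= self.strength <= 1.0:
            raise ValueError(f"coupling strength must be in [0,1]; got {self.strength}")
        if self.ch_a == self.ch_b:
            raise ValueError("coupling channels must differ")


@dataclass
class OscComponent:
    """One band-limited oscillatory component of a state."""
    freq: float                       # centre frequency, Hz
    amplitudes: np.ndarray            # per-channel amplitude, signal units
    couplings: list = field(default_factory=list)

    def __post_init__(self):
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        if (self.amplitudes < 0).any():
            raise ValueError("amplitudes must be >= 0")


@dataclass
class StateSpec:
    """Per-state oscillatory signatures plus shared noise parameters."""
    components: list                  # list (per state) of lists of OscComponent
    noise_std: float = 0.5            # white noise SD per channel
    pink_std: float = 0.5             # 1/f noise SD per channel
    pink_exponent: float = 1.0

    @property
    def n_states(self) -> int:
        return len(self.components)

    def validate(self, fs: float) -> None:
        for comps in self.components:
            for c in comps:
                if not 0.0 < c.freq < fs / 2.0:
                    raise ValueError(f"component frequency {c.freq} Hz not in (0, {fs/2}) Hz")


@dataclass
class StatePathTruth:
    """Planted hidden state sequences and the chain that generated them."""
    paths: np.ndarray                 # (n_trials, n_samples), values in 0..K-1
    transition: np.ndarray            # the generating K x K matrix (may vary by condition)
    initial: np.ndarray               # initial distribution used (per condition if dict upstream)

    @property
    def n_states(self) -> int:
        return self.transition.shape[0]


@dataclass
class BehaviorTruth:
    """Gamma-GLM (log link) coefficients generating percept durations.

    mean duration = exp(b0 + b1*lifetime + b2*gc + b3*lifetime*gc),
    duration ~ Gamma(shape, that mean).
    """
    b0: float = 0.6
    b1: float = -0.3
    b2: float = -0.05
    b3: float = -0.4
    shape: float = 4.0

    def __post_init__(self):
        if self.shape <= 0:
            raise ValueError("gamma shape must be positive")


# ---------------------------------------------------------------------------
# defaults: the planted study conditions
# ---------------------------------------------------------------------------

def default_state_spec(n_channels: int = 8) -> StateSpec:
    """Four states with distinct band-limited signatures.

    State 1: 4 Hz (theta) with ACC-PCC phase coupling.
    State 2: 20 Hz (beta) with lIPL-rIPL coupling.
    State 3: 34 Hz (gamma), no coupling.
    State 4: 11 Hz (alpha) with PCU-V1 and PCU-rIPL phase coupling -- the
    planted analogue of the critical pre-dominant-percept state.

    Channel indices follow :data:`brainstates.containers.DEFAULT_CHANNELS`.
    """
    amp = np.ones(n_channels)
    iACC, iPCC, iPCU, iV1, ilIPL, irIPL = 4, 5, 6, 7, 2, 3
    components = [
        [OscComponent(4.0, amp, [Coupling(iACC, iPCC, 0.5, 0.9)])],
        [OscComponent(20.0, amp, [Coupling(ilIPL, irIPL, 0.4, 0.8)])],
        [OscComponent(34.0, amp, [])],
        [OscComponent(11.0, amp, [Coupling(iPCU, iV1, 0.8, 0.9),
                                  Coupling(iPCU, irIPL, 0.6, 0.7)])],
    ]
    return StateSpec(components=components, noise_std=0.5, pink_std=0.5)


def default_condition_dynamics(k: int = 4, biased: bool = True):
    """Per-condition transition matrices and initial distributions.

    Each condition favours one indicative state (BR_dom -> state 4,
    RPL_dom -> state 2, BR_mix -> state 3, RPL_mix -> state 1) through
    its initial distribution and transition matrix only; state signatures
    are condition-independent.  ``biased=False`` returns identical,
    unbiased dynamics for every condition (negative control).
    """
    indicative = {"BR_dom": 3, "RPL_dom": 1, "BR_mix": 2, "RPL_mix": 0}
    dynamics = {}
    for cond in CONDITIONS:
        trans = np.full((k, k), 0.02 / (k - 1))
        np.fill_diagonal(trans, 0.98)
        init = np.full(k, 1.0 / k)
        if biased:
            ind = indicative[cond]
            trans = np.full((k, k), 0.0045)
            for i in range(k):
                trans[i, ind] = 0.021
                trans[i, i] = 0.0
                trans[i, i] = 1.0 - trans[i].sum()
            init = np.full(k, 0.3 / (k - 1))
            init[ind] = 0.7
        dynamics[cond] = (trans, init)
    return dynamics


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def sample_state_paths(transition, initial, n_trials, n_samples, seed) -> StatePathTruth:
    """Sample independent first-order Markov chains, one per trial.

    ``transition`` rows must sum to 1; ``initial`` is the start-state
    distribution (per-condition bias is applied by the caller passing
    condition-specific arguments).
    """
    transition = np.asarray(transition, dtype=float)
    initial = np.asarray(initial, dtype=float)
    k = transition.shape[0]
    if transition.shape != (k, k) or not np.allclose(transition.sum(axis=1), 1.0, atol=1e-12):
        raise ValueError("transition matrix rows must sum to 1")
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    rng = np.random.default_rng(seed)
    paths = np.empty((n_trials, n_samples), dtype=np.int64)
    paths[:, 0] = rng.choice(k, size=n_trials, p=initial / initial.sum())
    cum = np.cumsum(transition, axis=1)
    u = rng.random((n_trials, n_samples - 1)) if n_samples > 1 else None
    for t in range(1, n_samples):
        paths[:, t] = (u[:, t - 1, None] > cum[paths[:, t - 1]]).sum(axis=1)
    return StatePathTruth(paths=paths, transition=transition, initial=initial)


def _pink_noise(rng, n_samples, exponent):
    """Unit-variance 1/f^exponent noise by spectral shaping of white noise."""
    white = rng.standard_normal(n_samples)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n_samples)
    shaping = np.zeros_like(freqs)
    shaping[1:] = freqs[1:] ** (-exponent / 2.0)
    x = np.fft.irfft(spec * shaping, n=n_samples)
    sd = x.std()
    return x / sd if sd > 0 else x


def _dwell_segments(path):
    """Maximal constant runs of a 1-D integer path: (start, stop, state)."""
    change = np.flatnonzero(np.diff(path)) + 1
    starts = np.concatenate(([0], change))
    stops = np.concatenate((change, [len(path)]))
    return [(int(a), int(b), int(path[a])) for a, b in zip(starts, stops)]


def synthesize_signals(paths: StatePathTruth, spec: StateSpec, fs, seed,
                       condition=None, subject=None, event_sample=None,
                       channels=DEFAULT_CHANNELS) -> TrialSet:
    """Render state paths into multichannel oscillatory signals.

    Within each dwell segment of state k, every oscillatory component of k
    contributes sinusoids whose phases are drawn fresh per dwell.  Coupled
    channel pairs share one oscillator: the second channel mixes the shared
    phase (weight = strength) with an independent phase
    (weight = sqrt(1 - strength^2)), so the within-dwell phase difference is
    constant and magnitude-squared coherence grows with the strength.
    1/f and white noise are then added per channel.
    """
    spec.validate(fs)
    n_trials, n_samples = paths.paths.shape
    n_ch = len(channels)
    rng = np.random.default_rng(seed)
    t_axis = np.arange(n_samples) / fs
    data = np.zeros((n_trials, n_samples, n_ch))
    two_pi = 2 * np.pi
    for i in range(n_trials):
        x = np.zeros((n_samples, n_ch))
        for start, stop, state in _dwell_segments(paths.paths[i]):
            tt = t_axis[start:stop]
            for comp in spec.components[state]:
                coupled = {}
                for c in comp.couplings:
                    shared = rng.uniform(0, two_pi)
                    coupled[c.ch_a] = (shared, 1.0, 0.0, 0.0)
                    indep_b = rng.uniform(0, two_pi)
                    coupled[c.ch_b] = (shared + c.phase_lag, c.strength,
                                       indep_b, np.sqrt(1 - c.strength**2))
                for ch in range(n_ch):
                    a = comp.amplitudes[ch]
                    if a == 0:
                        continue
                    if ch in coupled:
                        ph, w, ph2, w2 = coupled[ch]
                        wave = w * np.cos(two_pi * comp.freq * tt + ph)
                        if w2 > 0:
                            wave += w2 * np.cos(two_pi * comp.freq * tt + ph2)
                    else:
                        ph = rng.uniform(0, two_pi)
                        wave = np.cos(two_pi * comp.freq * tt + ph)
                    x[start:stop, ch] += a * wave
        for ch in range(n_ch):
            if spec.pink_std > 0:
                x[:, ch] += spec.pink_std * _pink_noise(rng, n_samples, spec.pink_exponent)
            if spec.noise_std > 0:
                x[:, ch] += spec.noise_std * rng.standard_normal(n_samples)
        data[i] = x
    if condition is None:
        condition = np.full(n_trials, CONDITIONS[0])
    if subject is None:
        subject = np.full(n_trials, "S01")
    if event_sample is None:
        event_sample = np.full(n_trials, int(round(1.0 * fs)))
    return TrialSet(data=data, fs=fs, channels=channels, condition=condition,
                    subject=subject, event_sample=event_sample)


def inject_lagged_coupling(t: TrialSet, src, dst, lag, gain,
                           paths: StatePathTruth = None, gate=None) -> TrialSet:
    """Add ``gain * src(t - lag)`` to ``dst`` on gated frames.

    ``src``/``dst`` are channel labels or indices.  If ``gate`` is a state
    index, the addition applies only at samples whose planted state equals
    ``gate`` (requires ``paths``); with ``gate=None`` it applies everywhere.
    The source channel is left unchanged.
    """
    isrc = t.channel_index(src) if isinstance(src, str) else int(src)
    idst = t.channel_index(dst) if isinstance(dst, str) else int(dst)
    if isrc == idst:
        raise ValueError("source and destination channels must differ")
    if not 0 < lag < t.n_samples:
        raise ValueError(f"lag must be in (0, {t.n_samples}); got {lag}")
    if gate is not None and paths is None:
        raise ValueError("gated coupling requires the planted state paths")
    out = t.copy()
    shifted = np.zeros_like(out.data[:, :, isrc])
    shifted[:, lag:] = t.data[:, :-lag, isrc]
    if gate is None:
        mask = np.ones((t.n_trials, t.n_samples), dtype=bool)
    else:
        mask = paths.paths == int(gate)
    out.data[:, :, idst] += gain * shifted * mask
    return out


def sample_behavior(lifetimes, gc, truth: BehaviorTruth, seed) -> np.ndarray:
    """Draw per-trial percept durations from the planted gamma GLM.

    duration_i ~ Gamma(shape, mean = exp(b0 + b1*L_i + b2*g_i + b3*L_i*g_i)).
    """
    lifetimes = np.asarray(lifetimes, dtype=float)
    gc = np.asarray(gc, dtype=float)
    if (lifetimes < 0).any():
        raise ValueError("lifetimes must be >= 0")
    if truth.shape <= 0:
        raise ValueError("gamma shape must be positive")
    rng = np.random.default_rng(seed)
    mean = np.exp(truth.b0 + truth.b1 * lifetimes + truth.b2 * gc
                  + truth.b3 * lifetimes * gc)
    return rng.gamma(shape=truth.shape, scale=mean / truth.shape)


# ---------------------------------------------------------------------------
# end-to-end dataset
# ---------------------------------------------------------------------------

def make_dataset(n_trials_per_condition=125, n_subjects=20, fs=250.0,
                 n_samples=275, seed=0, spec: StateSpec = None,
                 condition_bias: bool = True, gc_gain: float = 0.5,
                 gc_lag: int = 2, behavior_truth: BehaviorTruth = None):
    """Generate a full synthetic study: signals, planted paths, durations.

    Returns ``(TrialSet, StatePathTruth, durations)``.  Trials are balanced
    across the four conditions and assigned to subjects round-robin.  The
    PCU->V1 lagged coupling (gain ``gc_gain`` at ``gc_lag`` samples) is
    gated by the BR_dom-indicative state (state index 3); set
    ``gc_gain=0`` to disable it.
    """
    if spec is None:
        spec = default_state_spec()
    if behavior_truth is None:
        behavior_truth = BehaviorTruth()
    dynamics = default_condition_dynamics(spec.n_states, biased=condition_bias)
    rng = np.random.default_rng(seed)
    all_paths, conditions = [], []
    for ci, cond in enumerate(CONDITIONS):
        trans, init = dynamics[cond]
        sp = sample_state_paths(trans, init, n_trials_per_condition, n_samples,
                                seed=rng.integers(2**31 - 1))
        all_paths.append(sp.paths)
        conditions.extend([cond] * n_trials_per_condition)
    paths = StatePathTruth(paths=np.concatenate(all_paths, axis=0),
                           transition=dynamics[CONDITIONS[0]][0],
                           initial=dynamics[CONDITIONS[0]][1])
    n_total = paths.paths.shape[0]
    conditions = np.asarray(conditions)
    subjects = np.asarray([f"S{1 + (i % n_subjects):02d}" for i in range(n_total)])
    trialset = synthesize_signals(paths, spec, fs, seed=rng.integers(2**31 - 1),
                                  condition=conditions, subject=subjects)
    if gc_gain != 0.0:
        trialset = inject_lagged_coupling(trialset, "PCU", "V1", gc_lag, gc_gain,
                                          paths=paths, gate=3)
    # behaviour: durations driven by state-3 total lifetime and a per-trial
    # GC proxy (the planted gain applies only on state-3 frames, so the
    # fraction of gated frames scales the realised causal influence)
    lifetimes = (paths.paths == 3).mean(axis=1) * n_samples / fs
    gc_proxy = rng.normal(loc=gc_gain * (paths.paths == 3).mean(axis=1), scale=0.1)
    durations = sample_behavior(lifetimes, gc_proxy, behavior_truth,
                                seed=rng.integers(2**31 - 1))
    trialset.meta.update({"generator": "brainstates.synth.make_dataset",
                          "gc_gain": gc_gain, "gc_lag": gc_lag})
    return trialset, paths, durations
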