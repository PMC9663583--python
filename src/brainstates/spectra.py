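"""State-wise spectral estimation and frequency-mode factorisation.

The per-state cross-spectra are weighted Welch estimates: Hann-tapered
segments (0.5 s, 50% overlap by default) contribute their periodogram
cross-products weighted by the state's mean posterior probability over the
segment,

    S_k(f) = sum_seg w_k,seg X_seg(f) X_seg(f)^* / sum_seg w_k,seg,

so a state's spectrum is the spectrum of the frames it occupies.  Phase
coherence is the magnitude of the normalised cross-spectrum,
|S_ij| / sqrt(S_ii S_jj), bounded in [0, 1] by Cauchy-Schwarz.  Since the
per-segment weights sum to one across states, the weight-averaged state
spectra reproduce the unconditional spectrum exactly.

Coherence spectra concatenated across states and channel pairs are then
factorised into a small number of non-negative frequency modes (NNMF,
multiplicative updates, Frobenius loss), which on real EEG recover the
canonical theta/alpha/beta/gamma bands.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import get_window
from sklearn.decomposition import NMF

from .containers import TrialSet
from .hmm import StatePosterior


@dataclass
class StateSpectra:
    freqs: np.ndarray                 # Hz
    power: np.ndarray                 # (K, channels, freqs), units^2 / Hz
    coherence: np.ndarray             # (K, channels, channels, freqs) in [0, 1]
    weights: np.ndarray               # (K,) total posterior weight per state
    undefined_states: list            # states with zero weight


@dataclass
class FrequencyModes:
    profiles: np.ndarray              # (n_modes, freqs), non-negative
    loadings: np.ndarray              # (n_modes, n_features)
    freqs: np.ndarray
    peak_freqs: np.ndarray            # Hz per mode
    half_max_bounds: np.ndarray       # (n_modes, 2) Hz
    reconstruction_error: float


@dataclass
class FeatureTestResult:
    """Per (state, feature) permutation test against the other states."""
    observed: np.ndarray              # (K, n_features) observed state means
    p_higher: np.ndarray              # one-tailed p, direction "higher"
    p_lower: np.ndarray
    flags: np.ndarray                 # "higher" / "lower" / "" at alpha
    alpha: float
    n_perm: int


def _segment_starts(n_samples, seg_len, overlap=0.5):
    step = max(1, int(round(seg_len * (1 - overlap))))
    return list(range(0, n_samples - seg_len + 1, step))


def _gamma_per_sample(posterior: StatePosterior, t: TrialSet):
    """Expand frame posteriors to per-sample posteriors (edge-padded)."""
    k = posterior.gamma.shape[1]
    out = np.empty((t.n_trials, t.n_samples, k))
    for i, (g, _) in enumerate(posterior.per_trial()):
        w = (t.n_samples - len(g)) // 2
        out[i, w:w + len(g)] = g
        out[i, :w] = g[0]
        out[i, w + len(g):] = g[-1]
    return out


def state_cross_spectra(t: TrialSet, posterior: StatePosterior,
                        fmin: float = 1.0, fmax: float = 45.0,
                        segment_s: float = 0.5, overlap: float = 0.5) -> StateSpectra:
    """Posterior-weighted Welch cross-spectra and coherence per state."""
    seg_len = int(round(segment_s * t.fs))
    if seg_len > t.n_samples:
        raise ValueError(f"segment ({seg_len} samples) longer than trials ({t.n_samples})")
    k = posterior.gamma.shape[1]
    win = get_window("hann", seg_len)
    scale = 1.0 / (t.fs * (win ** 2).sum())
    freqs = np.fft.rfftfreq(seg_len, d=1.0 / t.fs)
    band = (freqs >= fmin) & (freqs <= fmax)
    gamma_s = _gamma_per_sample(posterior, t)
    n_ch = t.n_channels
    cross = np.zeros((k, n_ch, n_ch, band.sum()), dtype=complex)
    weights = np.zeros(k)
    starts = _segment_starts(t.n_samples, seg_len, overlap)
    for i in range(t.n_trials):
        for s0 in starts:
            seg = t.data[i, s0:s0 + seg_len, :]
            seg = (seg - seg.mean(axis=0)) * win[:, None]
            X = np.fft.rfft(seg, axis=0)[band].T          # (n_ch, n_freq)
            outer = np.einsum("af,bf->abf", X, np.conj(X)) * scale
            w = gamma_s[i, s0:s0 + seg_len].mean(axis=0)  # (k,)
            cross += w[:, None, None, None] * outer[None]
            weights += w
    undefined = [int(j) for j in range(k) if weights[j] == 0]
    if undefined:
        warnings.warn(f"states {undefined} have zero posterior weight; spectra undefined")
    power = np.empty((k, n_ch, band.sum()))
    coherence = np.full((k, n_ch, n_ch, band.sum()), np.nan)
    for j in range(k):
        if j in undefined:
            power[j] = np.nan
            continue
        s = cross[j] / weights[j]
        p = np.real(np.einsum("iif->if", s))
        power[j] = p
        denom = np.sqrt(p[:, None, :] * p[None, :, :])
        coherence[j] = np.abs(s) / np.maximum(denom, 1e-300)
    return StateSpectra(freqs=freqs[band], power=power, coherence=coherence,
                        weights=weights, undefined_states=undefined)


def coherence_feature_matrix(s: StateSpectra) -> tuple:
    """Stack off-diagonal coherence spectra: (freqs x (states*pairs), labels)."""
    k, n_ch = s.coherence.shape[0], s.coherence.shape[1]
    cols, labels = [], []
    for j in range(k):
        if j in s.undefined_states:
            continue
        for a in range(n_ch):
            for b in range(a + 1, n_ch):
                cols.append(s.coherence[j, a, b])
                labels.append((j, a, b))
    return np.stack(cols, axis=1), labels


def nnmf_modes(feature_matrix: np.ndarray, freqs: np.ndarray, n_modes: int,
               seed: int = 0, n_restarts: int = 10,
               max_iter: int = 2000) -> FrequencyModes:
    """Factorise freqs x features spectra into non-negative frequency modes.

    Multiplicative-update NNMF minimising Frobenius error; best of
    ``n_restarts`` random non-negative initialisations (fixed child seeds)
    is kept.  Per-mode peak and half-maximum frequencies are read off the
    spectral profiles.
    """
    m = np.asarray(feature_matrix, dtype=float)
    if (m < 0).any():
        raise ValueError("feature matrix must be non-negative")
    if n_modes > min(m.shape):
        raise ValueError(f"n_modes ({n_modes}) exceeds matrix dimensions {m.shape}")
    best = None
    root = np.random.SeedSequence(seed)
    for child in root.spawn(n_restarts):
        rs = int(np.random.default_rng(child).integers(2**31 - 1))
        model = NMF(n_components=n_modes, init="random", solver="mu",
                    beta_loss="frobenius", max_iter=max_iter, tol=1e-8,
                    random_state=rs)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            W = model.fit_transform(m)
        err = model.reconstruction_err_
        if best is None or err < best[0]:
            best = (err, W, model.components_)
    err, W, H = best
    profiles = W.T                                 # (n_modes, freqs)
    peak_idx = profiles.argmax(axis=1)
    peaks = freqs[peak_idx]
    bounds = np.empty((n_modes, 2))
    for i in range(n_modes):
        prof = profiles[i]
        half = prof[peak_idx[i]] / 2.0
        above = prof >= half
        lo = peak_idx[i]
        while lo > 0 and above[lo - 1]:
            lo -= 1
        hi = peak_idx[i]
        while hi < len(prof) - 1 and above[hi + 1]:
            hi += 1
        bounds[i] = (freqs[lo], freqs[hi])
    return FrequencyModes(profiles=profiles, loadings=H, freqs=freqs,
                          peak_freqs=peaks, half_max_bounds=bounds,
                          reconstruction_error=float(err))


def trial_state_features(t: TrialSet, posterior: StatePosterior,
                         band=(7.0, 15.0), segment_s: float = 0.5,
                         overlap: float = 0.5):
    """Per-trial state-conditional band features for permutation testing.

    For every trial, computes each state's band-mean channel power and
    pairwise coherence from that trial's posterior-weighted segments.
    Returns ``(features, labels)`` with features shaped
    (n_trials, K, n_features); features of states a trial never visits are
    NaN.  Feature order: channel powers, then upper-triangle coherences.
    """
    seg_len = int(round(segment_s * t.fs))
    k = posterior.gamma.shape[1]
    n_ch = t.n_channels
    win = get_window("hann", seg_len)
    freqs = np.fft.rfftfreq(seg_len, d=1.0 / t.fs)
    sel = (freqs >= band[0]) & (freqs <= band[1])
    gamma_s = _gamma_per_sample(posterior, t)
    starts = _segment_starts(t.n_samples, seg_len, overlap)
    pairs = [(a, b) for a in range(n_ch) for b in range(a + 1, n_ch)]
    n_feat = n_ch + len(pairs)
    feats = np.full((t.n_trials, k, n_feat), np.nan)
    for i in range(t.n_trials):
        cross = np.zeros((k, n_ch, n_ch, sel.sum()), dtype=complex)
        weights = np.zeros(k)
        for s0 in starts:
            seg = t.data[i, s0:s0 + seg_len, :]
            seg = (seg - seg.mean(axis=0)) * win[:, None]
            X = np.fft.rfft(seg, axis=0)[sel].T
            outer = np.einsum("af,bf->abf", X, np.conj(X))
            w = gamma_s[i, s0:s0 + seg_len].mean(axis=0)
            cross += w[:, None, None, None] * outer[None]
            weights += w
        for j in range(k):
            if weights[j] <= 1e-12:
                continue
            s = cross[j] / weights[j]
            p = np.real(np.einsum("iif->if", s))
            feats[i, j, :n_ch] = p.mean(axis=1)
            denom = np.sqrt(p[:, None, :] * p[None, :, :])
            coh = np.abs(s) / np.maximum(denom, 1e-300)
            for fidx, (a, b) in enumerate(pairs):
                feats[i, j, n_ch + fidx] = coh[a, b].mean()
    labels = [f"power:{t.channels[c]}" for c in range(n_ch)]
    labels += [f"coh:{t.channels[a]}-{t.channels[b]}" for a, b in pairs]
    return feats, labels


def state_feature_tests(features: np.ndarray, n_perm: int = 5000,
                        alpha: float = 0.01, seed: int = 0) -> FeatureTestResult:
    """Is a state's mean feature higher/lower than under label exchange?

    ``features`` is (n_trials, K, n_features) of per-trial state-conditional
    estimates (NaN where a state is absent from a trial).  The null shuffles
    state labels independently within each trial; one-tailed p-values are
    reported in each direction and flagged at ``alpha``.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    feats = np.asarray(features, dtype=float)
    n_trials, k, n_feat = feats.shape
    rng = np.random.default_rng(seed)
    observed = np.nanmean(feats, axis=0)                    # (K, n_feat)
    count_hi = np.zeros((k, n_feat))
    count_lo = np.zeros((k, n_feat))
    for _ in range(n_perm):
        perm = np.argsort(rng.random((n_trials, k)), axis=1)
        shuffled = np.take_along_axis(feats, perm[:, :, None], axis=1)
        null_mean = np.nanmean(shuffled, axis=0)
        count_hi += null_mean >= observed
        count_lo += null_mean <= observed
    p_higher = (1 + count_hi) / (n_perm + 1)
    p_lower = (1 + count_lo) / (n_perm + 1)
    flags = np.full((k, n_feat), "", dtype=object)
    flags[p_higher < alpha] = "higher"
    flags[p_lower < alpha] = "lower"
    return FeatureTestResult(observed=observed, p_higher=p_higher,
                             p_lower=p_lower, flags=flags, alpha=alpha,
                             n_perm=n_perm)
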