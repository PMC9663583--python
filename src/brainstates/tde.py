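"""Time-delay embedding and PCA projection.

Each frame at sample s stacks the channels at lags -w..+w around s
(channel-major: all lags of channel 1, then channel 2, ...), so a 60 ms
window at 250 Hz gives 15 lags and, with 8 channels, a 120-dimensional
embedded space.  The HMM is then fitted on the top principal components of
the embedded data (16 by default: twice the number of ROIs), so each state
encodes an autocovariance (spectral) pattern rather than a mean level.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA

from .containers import TrialSet


@dataclass
class EmbeddedData:
    """Frames x (L*C) matrix plus bookkeeping.

    ``index`` maps each frame to its (trial, centre sample); no frame spans
    a trial boundary, and edge samples without a full window are dropped.
    """
    frames: np.ndarray          # (n_frames, L*C)
    index: np.ndarray           # (n_frames, 2): trial, centre sample
    half_window: int
    n_channels: int
    trial_lengths: np.ndarray   # frames per trial

    @property
    def n_lags(self) -> int:
        return 2 * self.half_window + 1


@dataclass
class PCAModel:
    mean: np.ndarray            # (L*C,)
    loadings: np.ndarray        # (L*C, n_pcs), orthonormal columns
    explained_variance_ratio: np.ndarray

    def transform(self, frames: np.ndarray) -> np.ndarray:
        return (frames - self.mean) @ self.loadings

    def backproject_covariance(self, cov_pc: np.ndarray) -> np.ndarray:
        """Map a PC-space covariance back to embedded space."""
        return self.loadings @ cov_pc @ self.loadings.T


def embed(t: TrialSet, window_ms: float) -> EmbeddedData:
    """Time-delay embed every trial with a centred ``window_ms`` window."""
    n_lags = int(round(window_ms * t.fs / 1000.0))
    if n_lags % 2 == 0 or n_lags < 3:
        raise ValueError(f"window must contain an odd number (>=3) of samples; got {n_lags}")
    w = (n_lags - 1) // 2
    if t.n_samples <= 2 * w:
        raise ValueError(f"trials ({t.n_samples} samples) shorter than the window ({n_lags})")
    frames_per_trial = t.n_samples - 2 * w
    # sliding windows: (trials, frames, n_lags) per channel, channel-major concat
    blocks = []
    for c in range(t.n_channels):
        sw = np.lib.stride_tricks.sliding_window_view(t.data[:, :, c], n_lags, axis=1)
        blocks.append(sw)
    frames = np.concatenate(blocks, axis=2).reshape(t.n_trials * frames_per_trial,
                                                    n_lags * t.n_channels)
    trial_idx = np.repeat(np.arange(t.n_trials), frames_per_trial)
    centre = np.tile(np.arange(w, t.n_samples - w), t.n_trials)
    index = np.stack([trial_idx, centre], axis=1)
    return EmbeddedData(frames=np.ascontiguousarray(frames), index=index,
                        half_window=w, n_channels=t.n_channels,
                        trial_lengths=np.full(t.n_trials, frames_per_trial))


def fit_pca(e: EmbeddedData, n_pcs: int) -> PCAModel:
    """Top-``n_pcs`` principal components of the embedded covariance."""
    d = e.frames.shape[1]
    if n_pcs > d:
        raise ValueError(f"n_pcs ({n_pcs}) exceeds embedded dimension ({d})")
    if e.frames.shape[0] <= d:
        raise ValueError("need more frames than embedded dimensions")
    model = PCA(n_components=n_pcs, svd_solver="full")
    model.fit(e.frames)
    # guard against requesting components beyond numerical rank
    total_var = np.var(e.frames, axis=0).sum()
    if model.explained_variance_[-1] < 1e-12 * max(total_var, 1.0):
        raise ValueError(f"data rank below requested n_pcs ({n_pcs})")
    return PCAModel(mean=model.mean_, loadings=model.components_.T,
                    explained_variance_ratio=model.explained_variance_ratio_)
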