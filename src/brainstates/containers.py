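"""Core data containers shared by all pipeline stages.

A :class:`TrialSet` holds response-locked, trial-wise multichannel source
signals (trials x samples x channels) together with the sampling rate,
ordered ROI labels, per-trial condition labels, subject identifiers, and
the index of the behavioural response event within each trial.

A :class:`PipelineConfig` collects every tunable parameter of the analysis
pipeline plus a single global seed; per-stage child seeds are derived
deterministically from ``(rng_seed, stage name)``.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict

import numpy as np

#: The four experimental condition labels: binocular-rivalry / replay
#: crossed with dominant / mixed upcoming percept.
CONDITIONS = ("BR_dom", "BR_mix", "RPL_dom", "RPL_mix")

#: Default ROI channel ordering: bilateral parahippocampal gyri, bilateral
#: inferior parietal lobules, anterior/posterior cingulate, precuneus, V1.
DEFAULT_CHANNELS = ("lHP", "rHP", "lIPL", "rIPL", "ACC", "PCC", "PCU", "V1")

#: Per-condition epoch counts of the reference binocular-rivalry EEG-fMRI
#: dataset (Dryad 10.5061/dryad.bf1b1): response-locked transitions to a
#: dominant or mixed percept under rivalry (BR) and replay (RPL).
STUDY_EPOCH_COUNTS = {"BR_dom": 7795, "BR_mix": 5786,
                      "RPL_dom": 7148, "RPL_mix": 5038}


@dataclass
class TrialSet:
    """Trial-wise multichannel time series with metadata.

    Parameters
    ----------
    data : ndarray, shape (n_trials, n_samples, n_channels)
        Source signals, nominally in microvolts.
    fs : float
        Sampling rate in Hz.
    channels : sequence of str
        Ordered, unique ROI labels, one per data channel.
    condition : ndarray of str, shape (n_trials,)
        Per-trial condition label drawn from :data:`CONDITIONS`.
    subject : ndarray, shape (n_trials,)
        Per-trial subject identifier.
    event_sample : ndarray of int, shape (n_trials,)
        Index of the response event within each trial.  Sample 0 is trial
        start; times are reported in seconds relative to the event
        (negative = pre-response).
    meta : dict
        Free-form metadata, preserved on disk round-trips.
    """

    data: np.ndarray
    fs: float
    channels: tuple
    condition: np.ndarray
    subject: np.ndarray
    event_sample: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.channels = tuple(str(c) for c in self.channels)
        self.condition = np.asarray(self.condition)
        self.subject = np.asarray(self.subject)
        self.event_sample = np.atleast_1d(np.asarray(self.event_sample, dtype=np.int64))
        if self.event_sample.size == 1 and self.n_trials != 1:
            self.event_sample = np.full(self.n_trials, int(self.event_sample[0]))
        self.validate()

    # -- basic shape accessors -------------------------------------------------
    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def n_channels(self) -> int:
        return self.data.shape[2]

    @property
    def times(self) -> np.ndarray:
        """Per-sample times (s) relative to the event, for the first trial's
        event index (trials share one epoching in this pipeline)."""
        return (np.arange(self.n_samples) - self.event_sample[0]) / self.fs

    def channel_index(self, label: str) -> int:
        return self.channels.index(label)

    def validate(self) -> None:
        if self.data.ndim != 3:
            raise ValueError(f"data must be 3-D (trials, samples, channels); got shape {self.data.shape}")
        if self.n_trials == 0:
            raise ValueError("no trials")
        if self.fs <= 0:
            raise ValueError(f"fs must be positive; got {self.fs}")
        if len(self.channels) != self.n_channels:
            raise ValueError(
                f"channel labels ({len(self.channels)}) do not match data channels ({self.n_channels})"
            )
        if len(set(self.channels)) != len(self.channels):
            raise ValueError("channel labels must be unique")
        for name, arr in (("condition", self.condition), ("subject", self.subject),
                          ("event_sample", self.event_sample)):
            if arr.shape[0] != self.n_trials:
                raise ValueError(f"{name} has {arr.shape[0]} entries for {self.n_trials} trials")
        bad = set(np.unique(self.condition).tolist()) - set(CONDITIONS)
        if bad:
            raise ValueError(f"unknown condition labels {sorted(bad)}; expected subset of {CONDITIONS}")
        finite = np.isfinite(self.data).all(axis=(1, 2))
        if not finite.all():
            idx = int(np.flatnonzero(~finite)[0])
            raise ValueError(f"non-finite values in trial {idx}")

    def copy(self) -> "TrialSet":
        return TrialSet(self.data.copy(), self.fs, self.channels,
                        self.condition.copy(), self.subject.copy(),
                        self.event_sample.copy(), dict(self.meta))


@dataclass
class PipelineConfig:
    """Pipeline parameters and the single global random seed.

    ``window_ms`` is the time-delay-embedding window length; at the default
    250 Hz, 60 ms gives a 15-sample centred window, so 8 channels embed into
    a 120-dimensional space projected onto ``n_pcs`` = 16 principal
    components before HMM fitting with ``n_states`` = 4 states.
    """

    fs: float = 250.0
    window_ms: float = 60.0
    n_pcs: int = 16
    n_states: int = 4
    n_perm_fo: int = 2000
    n_perm_spectra: int = 5000
    gc_max_lag: int = 20
    cv_folds: int = 5
    cv_grid: tuple = (-5.0, 0.0, 0.2)  # log10 lower, upper, step
    rng_seed: int = 0

    def __post_init__(self) -> None:
        w = self.window_samples
        if w < 3 or w % 2 == 0:
            raise ValueError(
                f"window_ms * fs / 1000 must be an odd integer >= 3; got {w}"
            )
        if self.n_states < 2:
            raise ValueError("n_states must be >= 2")
        for name in ("n_pcs", "n_perm_fo", "n_perm_spectra", "gc_max_lag", "cv_folds"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def window_samples(self) -> int:
        return int(round(self.window_ms * self.fs / 1000.0))

    @property
    def half_window(self) -> int:
        return (self.window_samples - 1) // 2

    def child_seed(self, stage: str) -> int:
        """Deterministic per-stage seed derived from (rng_seed, stage)."""
        mix = zlib.crc32(stage.encode("utf-8"))
        return int((int(self.rng_seed) * 1_000_003 + mix) % (2**31 - 1))

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "PipelineConfig":
        payload = json.loads(text)
        if "cv_grid" in payload:
            payload["cv_grid"] = tuple(payload["cv_grid"])
        return cls(**payload)

    def config_hash(self) -> str:
        return format(zlib.crc32(self.to_json().encode("utf-8")), "08x")
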