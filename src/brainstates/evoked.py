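"""Sensor-level evoked analysis: epoching, baseline correction, Global
Field Power, and a 1-D cluster-based sign-flip permutation test.

GFP is the across-channel standard deviation of the condition-averaged
evoked response at each time point; it is invariant to adding a common
offset to all channels.  The cluster test forms contiguous supra-threshold
runs of one-sample t values, scores each by its summed t (mass), and builds
the max-statistic null by random sign flips of whole subject series —
appropriate because the statistic is a one-sample test of paired
differences.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .containers import TrialSet


@dataclass
class EvokedSeries:
    times: np.ndarray                  # s, relative to the event
    evoked: dict                       # condition -> (n_samples, n_channels) average
    gfp: dict                          # condition -> (n_samples,) GFP trace

    def __post_init__(self):
        if not np.all(np.diff(self.times) > 0):
            raise ValueError("time axis must be strictly increasing")


@dataclass
class ClusterTestResult:
    clusters: list                     # (start_time, end_time, mass, corrected p)
    n_perm: int
    threshold: float
    excluded_points: list = field(default_factory=list)

    def significant(self, alpha=0.05):
        return [c for c in self.clusters if c[3] < alpha]


def epoch_and_baseline(t: TrialSet, window, baseline) -> TrialSet:
    """Re-epoch to ``window`` (s, event-relative) and subtract each
    channel's mean over the ``baseline`` interval.

    ``baseline`` must lie within ``window`` and both within the recorded
    samples.  After correction, the baseline-interval mean of every channel
    of every epoch is zero to numerical precision.
    """
    w0, w1 = window
    b0, b1 = baseline
    if not (w0 <= b0 < b1 <= w1):
        raise ValueError(f"baseline {baseline} must lie within window {window}")
    ev = t.event_sample[0]
    if not np.all(t.event_sample == ev):
        raise ValueError("all trials must share one event sample for epoching")
    s0 = ev + int(round(w0 * t.fs))
    s1 = ev + int(round(w1 * t.fs))
    if s0 < 0 or s1 > t.n_samples:
        raise ValueError(
            f"window {window} maps to samples [{s0}, {s1}) outside the recorded "
            f"[0, {t.n_samples})"
        )
    bs0 = ev + int(round(b0 * t.fs)) - s0
    bs1 = ev + int(round(b1 * t.fs)) - s0
    data = t.data[:, s0:s1, :].copy()
    data -= data[:, bs0:bs1, :].mean(axis=1, keepdims=True)
    return TrialSet(data=data, fs=t.fs, channels=t.channels,
                    condition=t.condition, subject=t.subject,
                    event_sample=np.full(t.n_trials, ev - s0),
                    meta=dict(t.meta))


def global_field_power(t: TrialSet) -> EvokedSeries:
    """Condition-averaged evoked responses and their GFP traces.

    GFP at each time point is the population standard deviation of the
    evoked voltages across channels.
    """
    if t.n_channels < 2:
        raise ValueError("GFP requires at least 2 channels")
    evoked, gfp = {}, {}
    for cond in np.unique(t.condition):
        avg = t.data[t.condition == cond].mean(axis=0)
        evoked[cond] = avg
        gfp[cond] = avg.std(axis=1, ddof=0)
    return EvokedSeries(times=t.times, evoked=evoked, gfp=gfp)


def _clusters_from_t(tvals, threshold):
    """Two-tailed contiguous supra-threshold runs: (start, stop, mass)."""
    out = []
    for sign in (1.0, -1.0):
        above = sign * tvals > threshold
        idx = 0
        while idx < len(above):
            if above[idx]:
                stop = idx
                while stop < len(above) and above[stop]:
                    stop += 1
                out.append((idx, stop, float(tvals[idx:stop].sum())))
                idx = stop
            else:
                idx += 1
    return sorted(out)


def cluster_permutation_test(per_subject_diff, n_perm=1000, cluster_threshold=None,
                             alpha=0.05, seed=0, times=None) -> ClusterTestResult:
    """1-D cluster-based permutation test on subjects x timepoints differences.

    A one-sample t statistic is computed at each time point; contiguous runs
    exceeding ``cluster_threshold`` (default: the two-tailed t critical
    value at 0.05 with n_subjects - 1 df) form clusters scored by summed t.
    The null distribution of the maximum |cluster mass| is built from
    ``n_perm`` random sign flips of whole subject series; each observed
    cluster's corrected p is the fraction of permutations (including the
    identity) whose maximum mass is at least as large.
    """
    x = np.asarray(per_subject_diff, dtype=float)
    n_sub, n_time = x.shape
    if n_sub < 2:
        raise ValueError("need at least 2 subjects")
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    excluded = np.flatnonzero(x.std(axis=0, ddof=1) == 0)
    if excluded.size:
        warnings.warn(f"excluding {excluded.size} zero-variance time points")
        keep = np.setdiff1d(np.arange(n_time), excluded)
        x = x[:, keep]
        index_map = keep
    else:
        index_map = np.arange(n_time)
    if cluster_threshold is None:
        cluster_threshold = float(stats.t.ppf(1 - 0.05 / 2, df=n_sub - 1))

    def tmap(data):
        m = data.mean(axis=0)
        se = data.std(axis=0, ddof=1) / np.sqrt(data.shape[0])
        return m / se

    observed = _clusters_from_t(tmap(x), cluster_threshold)
    rng = np.random.default_rng(seed)
    max_mass = np.zeros(n_perm)
    for i in range(n_perm):
        signs = rng.choice([-1.0, 1.0], size=(n_sub, 1))
        cl = _clusters_from_t(tmap(signs * x), cluster_threshold)
        max_mass[i] = max((abs(m) for _, _, m in cl), default=0.0)
    clusters = []
    if times is None:
        times = np.arange(n_time, dtype=float)
    for start, stop, mass in observed:
        # identity permutation counted in the null -> p >= 1/(n_perm+1)
        p = (1 + np.sum(max_mass >= abs(mass))) / (n_perm + 1)
        clusters.append((float(times[index_map[start]]),
                         float(times[index_map[stop - 1]]), mass, float(p)))
    return ClusterTestResult(clusters=clusters, n_perm=n_perm,
                             threshold=cluster_threshold,
                             excluded_points=excluded.tolist())
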