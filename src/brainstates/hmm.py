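"""K-state hidden Markov model with a zero-mean Gaussian observation model.

Because the signals are baseline-corrected and the embedding makes each
frame a window of lagged samples, the observation model is a zero-mean
full-covariance Gaussian per state: a state is an autocovariance pattern,
which for oscillatory data captures band-limited power and cross-channel
phase-locking rather than a mean level.

Inference is expectation-maximisation with exact per-trial
forward-backward; chains never transition across trial boundaries (each
trial is an independent sequence re-initialised from the initial
distribution).  Transition rows carry a symmetric Dirichlet prior with
concentration 1 (flat), so the M-step coincides with maximum likelihood.
The best of ``n_restarts`` deterministic-seeded restarts by final
log-likelihood is returned.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import linalg

logger = logging.getLogger(__name__)


@dataclass
class StateModel:
    covariances: np.ndarray          # (K, D, D) per-state PC-space covariance
    transition: np.ndarray           # (K, K), rows sum to 1
    initial: np.ndarray              # (K,)
    objective_trace: np.ndarray      # log-likelihood per EM iteration
    converged: bool = True
    regularised: bool = False

    @property
    def n_states(self) -> int:
        return self.transition.shape[0]

    @property
    def n_dims(self) -> int:
        return self.covariances.shape[1]


@dataclass
class StatePosterior:
    gamma: np.ndarray                # (n_frames, K) marginal state probabilities
    viterbi: np.ndarray              # (n_frames,) most probable path, values 0..K-1
    trial_lengths: np.ndarray        # frames per trial

    def per_trial(self):
        """Iterate (gamma_trial, viterbi_trial) pairs."""
        edges = np.concatenate(([0], np.cumsum(self.trial_lengths)))
        for a, b in zip(edges[:-1], edges[1:]):
            yield self.gamma[a:b], self.viterbi[a:b]


@dataclass
class StateMetrics:
    """Per-trial dynamic state metrics from the Viterbi path.

    ``fo[i, k]`` is the fraction of trial i's frames spent in state k;
    ``lifetimes[i][k]`` lists the dwell durations (s) of state k in trial i;
    ``switching_rate[i]`` is state changes per second.
    """
    fo: np.ndarray
    lifetimes: list
    switching_rate: np.ndarray
    fs: float


# ---------------------------------------------------------------------------
# emission log-likelihoods
# ---------------------------------------------------------------------------

def _gaussian_loglik(frames: np.ndarray, covariances: np.ndarray) -> np.ndarray:
    """Zero-mean Gaussian log density of every frame under every state."""
    n, d = frames.shape
    k = covariances.shape[0]
    out = np.empty((n, k))
    const = d * np.log(2 * np.pi)
    for j in range(k):
        chol = linalg.cholesky(covariances[j], lower=True)
        logdet = 2.0 * np.log(np.diag(chol)).sum()
        y = linalg.solve_triangular(chol, frames.T, lower=True)
        out[:, j] = -0.5 * (const + logdet + (y * y).sum(axis=0))
    return out


def _regularise(cov: np.ndarray, cond_limit: float = 1e12) -> tuple:
    """Add 1e-6 x mean diagonal to the diagonal when ill-conditioned."""
    eig = np.linalg.eigvalsh(cov)
    if eig[0] <= 0 or eig[-1] / max(eig[0], 1e-300) > cond_limit:
        jitter = 1e-6 * np.mean(np.diag(cov))
        if jitter <= 0:
            jitter = 1e-12
        return cov + jitter * np.eye(cov.shape[0]), True
    return cov, False


# ---------------------------------------------------------------------------
# forward-backward and Viterbi (batched over equal-length trials)
# ---------------------------------------------------------------------------

def _group_by_length(loglik: np.ndarray, trial_lengths: np.ndarray):
    edges = np.concatenate(([0], np.cumsum(trial_lengths)))
    groups = {}
    for i, (a, b) in enumerate(zip(edges[:-1], edges[1:])):
        groups.setdefault(b - a, []).append((i, a, b))
    for length, members in groups.items():
        stack = np.stack([loglik[a:b] for _, a, b in members])
        yield length, members, stack


def forward_backward(loglik: np.ndarray, transition: np.ndarray,
                     initial: np.ndarray, trial_lengths: np.ndarray):
    """Scaled forward-backward per trial.

    Returns (gamma, xi_sum, total log-likelihood, first-frame gamma sums)
    where ``xi_sum`` accumulates expected transition counts over all trials.
    """
    k = transition.shape[0]
    gamma = np.empty((loglik.shape[0], k))
    xi_sum = np.zeros((k, k))
    first_gamma = np.zeros(k)
    total_ll = 0.0
    for length, members, ll in _group_by_length(loglik, trial_lengths):
        B, T, _ = ll.shape
        m = ll.max(axis=2, keepdims=True)
        b = np.exp(ll - m)
        alpha = np.empty((B, T, k))
        c = np.empty((B, T))
        a0 = initial[None, :] * b[:, 0]
        c[:, 0] = a0.sum(axis=1)
        alpha[:, 0] = a0 / c[:, 0, None]
        for t in range(1, T):
            at = (alpha[:, t - 1] @ transition) * b[:, t]
            c[:, t] = at.sum(axis=1)
            alpha[:, t] = at / c[:, t, None]
        beta = np.empty((B, T, k))
        beta[:, T - 1] = 1.0
        for t in range(T - 2, -1, -1):
            beta[:, t] = ((b[:, t + 1] * beta[:, t + 1]) @ transition.T) / c[:, t + 1, None]
        g = alpha * beta
        g /= g.sum(axis=2, keepdims=True)
        for t in range(T - 1):
            xi_sum += np.einsum("bi,bj,ij->ij", alpha[:, t],
                                b[:, t + 1] * beta[:, t + 1] / c[:, t + 1, None],
                                transition)
        first_gamma += g[:, 0].sum(axis=0)
        total_ll += float(np.log(c).sum() + m.sum())
        for (i, a, bnd), gi in zip(members, g):
            gamma[a:bnd] = gi
    return gamma, xi_sum, total_ll, first_gamma


def viterbi_path(loglik: np.ndarray, transition: np.ndarray,
                 initial: np.ndarray, trial_lengths: np.ndarray) -> np.ndarray:
    """Most probable state path per trial (max-product in log space)."""
    k = transition.shape[0]
    log_trans = np.log(np.maximum(transition, 1e-300))
    log_init = np.log(np.maximum(initial, 1e-300))
    path = np.empty(loglik.shape[0], dtype=np.int64)
    for length, members, ll in _group_by_length(loglik, trial_lengths):
        B, T, _ = ll.shape
        delta = log_init[None, :] + ll[:, 0]
        psi = np.empty((B, T, k), dtype=np.int64)
        for t in range(1, T):
            cand = delta[:, :, None] + log_trans[None, :, :]
            psi[:, t] = cand.argmax(axis=1)
            delta = cand.max(axis=1) + ll[:, t]
        states = np.empty((B, T), dtype=np.int64)
        states[:, T - 1] = delta.argmax(axis=1)
        for t in range(T - 2, -1, -1):
            states[:, t] = psi[np.arange(B), t + 1, states[:, t + 1]]
        for (i, a, bnd), s in zip(members, states):
            path[a:bnd] = s
    return path


# ---------------------------------------------------------------------------
# EM fitting
# ---------------------------------------------------------------------------

def _m_step_covariances(frames, gamma, cond_limit=1e12):
    k = gamma.shape[1]
    d = frames.shape[1]
    covs = np.empty((k, d, d))
    any_reg = False
    for j in range(k):
        w = gamma[:, j]
        nk = w.sum()
        cov = (frames * w[:, None]).T @ frames / max(nk, 1e-12)
        cov = 0.5 * (cov + cov.T)
        cov, reg = _regularise(cov, cond_limit)
        if reg:
            any_reg = True
            logger.info("state %d covariance regularised (condition number > %g)", j, cond_limit)
        covs[j] = cov
    return covs, any_reg


def fit_hmm(frames: np.ndarray, trial_lengths, n_states: int,
            n_restarts: int = 5, max_iter: int = 500, tol: float = 1e-6,
            seed: int = 0) -> StateModel:
    """Fit the zero-mean Gaussian HMM by EM with multiple restarts.

    Each restart initialises from a random per-frame responsibilities draw
    (seeded deterministically from ``seed``); the restart with the best
    final log-likelihood wins, ties broken by restart index.
    """
    frames = np.asarray(frames, dtype=np.float64)
    trial_lengths = np.asarray(trial_lengths, dtype=np.int64)
    if trial_lengths.sum() != frames.shape[0]:
        raise ValueError("trial lengths do not sum to the number of frames")
    if n_states < 1:
        raise ValueError("n_states must be >= 1")
    best = None
    root = np.random.SeedSequence(seed)
    for r, child in enumerate(root.spawn(max(n_restarts, 1))):
        rng = np.random.default_rng(child)
        model = _fit_once(frames, trial_lengths, n_states, max_iter, tol, rng)
        if best is None or model.objective_trace[-1] > best.objective_trace[-1] + 0.0:
            best = model
    return best


def _fit_once(frames, trial_lengths, k, max_iter, tol, rng):
    n, d = frames.shape
    gamma = rng.dirichlet(np.ones(k), size=n)
    covs, any_reg = _m_step_covariances(frames, gamma)
    transition = rng.dirichlet(np.ones(k) * 5.0, size=k)
    initial = np.full(k, 1.0 / k)
    trace = []
    converged = False
    for it in range(max_iter):
        loglik = _gaussian_loglik(frames, covs)
        gamma, xi_sum, total_ll, first_gamma = forward_backward(
            loglik, transition, initial, trial_lengths)
        trace.append(total_ll)
        if len(trace) > 1 and abs(trace[-1] - trace[-2]) <= tol * abs(trace[-2]):
            converged = True
            break
        covs, reg = _m_step_covariances(frames, gamma)
        any_reg = any_reg or reg
        if k > 1:
            rows = xi_sum.sum(axis=1, keepdims=True)
            transition = np.where(rows > 0, xi_sum / np.maximum(rows, 1e-300),
                                  1.0 / k)
            transition /= transition.sum(axis=1, keepdims=True)
            initial = first_gamma / first_gamma.sum()
    if not converged:
        warnings.warn(f"EM did not converge within {max_iter} iterations")
    return StateModel(covariances=covs, transition=transition, initial=initial,
                      objective_trace=np.asarray(trace), converged=converged,
                      regularised=any_reg)


def decode(model: StateModel, frames: np.ndarray, trial_lengths) -> StatePosterior:
    """Posterior state probabilities (forward-backward) and Viterbi path."""
    frames = np.asarray(frames, dtype=np.float64)
    trial_lengths = np.asarray(trial_lengths, dtype=np.int64)
    if frames.shape[1] != model.n_dims:
        raise ValueError(
            f"data dimension {frames.shape[1]} does not match model ({model.n_dims})")
    loglik = _gaussian_loglik(frames, model.covariances)
    gamma, _, _, _ = forward_backward(loglik, model.transition, model.initial,
                                      trial_lengths)
    path = viterbi_path(loglik, model.transition, model.initial, trial_lengths)
    return StatePosterior(gamma=gamma, viterbi=path, trial_lengths=trial_lengths)


# ---------------------------------------------------------------------------
# dynamic state metrics
# ---------------------------------------------------------------------------

def dwell_runs(path: np.ndarray):
    """Maximal constant runs of a state path: (start, stop, state)."""
    change = np.flatnonzero(np.diff(path)) + 1
    starts = np.concatenate(([0], change))
    stops = np.concatenate((change, [len(path)]))
    return [(int(a), int(b), int(path[a])) for a, b in zip(starts, stops)]


def state_metrics(posterior: StatePosterior, fs: float,
                  n_states: int = None) -> StateMetrics:
    """Fractional occupancy, lifetimes and switching rate per trial.

    All metrics derive from the hard Viterbi assignment so that FO and the
    dwell-based lifetimes are mutually consistent: the summed lifetimes of
    state k in a trial equal FO_k x trial duration exactly.
    """
    if n_states is None:
        n_states = posterior.gamma.shape[1]
    n_trials = len(posterior.trial_lengths)
    fo = np.zeros((n_trials, n_states))
    sr = np.zeros(n_trials)
    lifetimes = []
    for i, (_, path) in enumerate(posterior.per_trial()):
        if len(path) == 0:
            raise ValueError(f"trial {i} has no frames")
        counts = np.bincount(path, minlength=n_states)
        fo[i] = counts / len(path)
        sr[i] = np.count_nonzero(np.diff(path)) / (len(path) / fs)
        per_state = [[] for _ in range(n_states)]
        for a, b, s in dwell_runs(path):
            per_state[s].append((b - a) / fs)
        lifetimes.append(per_state)
    return StateMetrics(fo=fo, lifetimes=lifetimes, switching_rate=sr, fs=fs)


# ---------------------------------------------------------------------------
# serialisation: JSON + binary-array bundle
# ---------------------------------------------------------------------------

def save_model(model: StateModel, path) -> None:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    np.save(path / "covariances.npy", model.covariances)
    payload = {
        "transition": model.transition.tolist(),
        "initial": model.initial.tolist(),
        "objective_trace": np.asarray(model.objective_trace).tolist(),
        "converged": bool(model.converged),
        "regularised": bool(model.regularised),
    }
    (path / "model.json").write_text(json.dumps(payload, indent=2))


def load_model(path) -> StateModel:
    path = Path(path)
    payload = json.loads((path / "model.json").read_text())
    return StateModel(
        covariances=np.load(path / "covariances.npy"),
        transition=np.asarray(payload["transition"]),
        initial=np.asarray(payload["initial"]),
        objective_trace=np.asarray(payload["objective_trace"]),
        converged=payload["converged"],
        regularised=payload["regularised"],
    )
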