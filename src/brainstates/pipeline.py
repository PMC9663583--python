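"""End-to-end orchestration of the state-discovery pipeline.

Bundles the embed -> PCA -> HMM -> decode -> metrics chain behind one call,
plus ground-truth scoring helpers for synthetic studies where the planted
state paths are known.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment

from . import hmm as _hmm
from . import tde as _tde
from .containers import PipelineConfig, TrialSet


@dataclass
class StateDiscovery:
    embedding: _tde.EmbeddedData
    pca: _tde.PCAModel
    model: _hmm.StateModel
    posterior: _hmm.StatePosterior
    metrics: _hmm.StateMetrics


def run_state_discovery(t: TrialSet, cfg: PipelineConfig = None,
                        n_restarts: int = 5, max_iter: int = 500) -> StateDiscovery:
    """Embed, project, fit the K-state HMM, decode, and compute metrics."""
    if cfg is None:
        cfg = PipelineConfig()
    emb = _tde.embed(t, cfg.window_ms)
    pca = _tde.fit_pca(emb, cfg.n_pcs)
    X = pca.transform(emb.frames)
    model = _hmm.fit_hmm(X, emb.trial_lengths, cfg.n_states,
                         n_restarts=n_restarts, max_iter=max_iter,
                         seed=cfg.child_seed("fit-hmm"))
    posterior = _hmm.decode(model, X, emb.trial_lengths)
    metrics = _hmm.state_metrics(posterior, t.fs)
    return StateDiscovery(embedding=emb, pca=pca, model=model,
                          posterior=posterior, metrics=metrics)


def match_to_truth(true_paths: np.ndarray, posterior: _hmm.StatePosterior,
                   half_window: int, n_states: int) -> tuple:
    """Optimal label matching of decoded states to planted states.

    Returns ``(accuracy, mapping)`` where ``mapping[fitted] = true`` and
    accuracy is the frame-wise Viterbi agreement after matching.
    """
    true = true_paths[:, half_window:true_paths.shape[1] - half_window].ravel()
    est = posterior.viterbi
    conf = np.zeros((n_states, n_states))
    for a in range(n_states):
        for b in range(n_states):
            conf[a, b] = np.sum((true == a) & (est == b))
    row, col = linear_sum_assignment(-conf)
    accuracy = conf[row, col].sum() / len(true)
    mapping = np.empty(n_states, dtype=np.int64)
    mapping[col] = row
    return float(accuracy), mapping
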