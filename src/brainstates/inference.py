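"""Condition-level inference on state dynamics.

Covers: within-condition state-pair permutation tests of fractional
occupancy with Benjamini-Hochberg correction; cross-validated decoding of
the upcoming percept type (dominant vs mixed) from trial-wise state FOs
with a linear support-vector machine; optimal state matching between
independently fitted models; and half-split state-reliability validation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import linear_sum_assignment
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.svm import LinearSVC
from statsmodels.stats.multitest import multipletests

from .containers import TrialSet
from . import hmm as _hmm
from . import tde as _tde


@dataclass
class DecodeResult:
    grid: np.ndarray                 # regularisation values, strictly increasing
    mean_accuracy: np.ndarray        # per grid value, across folds
    sd_accuracy: np.ndarray
    chosen: float                    # grid value with best mean accuracy
    best_accuracy: float             # max over grid
    plateau_accuracy: float          # accuracy at the top of the grid


@dataclass
class MatchResult:
    permutation: np.ndarray          # state j of model b matches state perm[j] of a
    similarity: np.ndarray           # full K x K Pearson-r matrix (a x b)
    matched_r: np.ndarray            # per matched pair
    contrast: float                  # mean matched r - mean unmatched r


def regularisation_grid(log_lo: float = -5.0, log_hi: float = 0.0,
                        step: float = 0.2) -> np.ndarray:
    """Log-spaced regularisation grid; defaults give the 26 values
    10^-5, 10^-4.8, ..., 10^0."""
    n = int(round((log_hi - log_lo) / step)) + 1
    return 10.0 ** np.linspace(log_lo, log_hi, n)


def fo_condition_tests(fo: np.ndarray, condition, subject,
                       n_perm: int = 2000, seed: int = 0) -> pd.DataFrame:
    """Within-condition state-pair permutation tests of fractional occupancy.

    Analysis units are per-subject mean FOs within each condition
    (population-level inference).  For states (i, j) the statistic is the
    median over units of the paired difference FO_i - FO_j; the null swaps
    the two states' values per unit at random (a sign flip of the paired
    difference), two-tailed.  Benjamini-Hochberg adjustment is applied
    across all condition x pair comparisons.
    """
    fo = np.asarray(fo, dtype=float)
    condition = np.asarray(condition)
    subject = np.asarray(subject)
    k = fo.shape[1]
    rng = np.random.default_rng(seed)
    rows = []
    for cond in np.unique(condition):
        mask = condition == cond
        if mask.sum() < 2:
            warnings.warn(f"condition {cond} has < 2 trials; skipped")
            continue
        units = pd.DataFrame(fo[mask]).groupby(subject[mask]).mean().to_numpy()
        for i in range(k):
            for j in range(i + 1, k):
                diff = units[:, i] - units[:, j]
                obs = np.median(diff)
                signs = rng.choice([-1.0, 1.0], size=(n_perm, len(diff)))
                null = np.median(signs * diff, axis=1)
                p = (1 + np.sum(np.abs(null) >= abs(obs))) / (n_perm + 1)
                rows.append({"condition": cond, "state_a": i + 1,
                             "state_b": j + 1, "median_diff": obs, "p": p})
    table = pd.DataFrame(rows)
    if len(table):
        table["p_adj"] = multipletests(table["p"], method="fdr_bh")[1]
    return table


def crossval_decode(features: np.ndarray, target, folds: int = 5,
                    grid: np.ndarray = None, seed: int = 0) -> DecodeResult:
    """Stratified k-fold CV of a linear SVM over a regularisation grid.

    ``features`` are trial-wise state FOs; ``target`` is the binary
    dominant-vs-mixed label.  Reports mean/SD fold accuracy per grid value;
    the headline is the best mean over the grid, with the top-of-grid
    (converged-plateau) accuracy also exposed.
    """
    if grid is None:
        grid = regularisation_grid()
    grid = np.asarray(grid, dtype=float)
    if not np.all(np.diff(grid) > 0):
        raise ValueError("grid must be strictly increasing")
    y = np.asarray(target)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    X = np.asarray(features, dtype=float)
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    means = np.empty(len(grid))
    sds = np.empty(len(grid))
    for g, c in enumerate(grid):
        clf = LinearSVC(C=c, dual=True, max_iter=20000, random_state=seed)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            scores = cross_val_score(clf, X, y, cv=cv, scoring="accuracy")
        means[g] = scores.mean()
        sds[g] = scores.std(ddof=1)
    best = int(np.argmax(means))
    return DecodeResult(grid=grid, mean_accuracy=means, sd_accuracy=sds,
                        chosen=float(grid[best]), best_accuracy=float(means[best]),
                        plateau_accuracy=float(means[-1]))


def _parameter_matrix(model, pca=None) -> np.ndarray:
    """One row of vectorised observation parameters per state.

    With ``pca`` given, state covariances are back-projected to embedded
    space first, so models fitted in different PCA bases are comparable.
    """
    if isinstance(model, np.ndarray):
        return model.reshape(model.shape[0], -1)
    covs = model.covariances
    if pca is not None:
        covs = np.stack([pca.backproject_covariance(c) for c in covs])
    return covs.reshape(covs.shape[0], -1)


def match_states(a, b, pca_a=None, pca_b=None) -> MatchResult:
    """Optimal bipartite matching of states by Pearson similarity.

    ``a`` and ``b`` are :class:`~brainstates.hmm.StateModel` instances (or
    K x d parameter arrays).  The assignment maximises total similarity;
    ``permutation[j] = i`` maps state j of ``b`` to state i of ``a``.
    """
    pa = _parameter_matrix(a, pca_a)
    pb = _parameter_matrix(b, pca_b)
    if pa.shape != pb.shape:
        raise ValueError(f"state parameter shapes differ: {pa.shape} vs {pb.shape}")
    k = pa.shape[0]
    sim = np.empty((k, k))
    for i in range(k):
        for j in range(k):
            sim[i, j] = stats.pearsonr(pa[i], pb[j])[0]
    row, col = linear_sum_assignment(-sim)
    permutation = np.empty(k, dtype=np.int64)
    permutation[col] = row
    matched = sim[row, col]
    unmatched_mask = np.ones_like(sim, dtype=bool)
    unmatched_mask[row, col] = False
    contrast = float(matched.mean() - sim[unmatched_mask].mean())
    return MatchResult(permutation=permutation, similarity=sim,
                       matched_r=matched, contrast=contrast)


def halfsplit_reliability(t: TrialSet, n_repeats: int = 5, window_ms: float = 60.0,
                          n_pcs: int = 16, n_states: int = 4, seed: int = 0,
                          hmm_opts: dict = None) -> list:
    """Fit the TDE-HMM independently on random subject halves and match states.

    Each repeat draws a random half of the subjects, fits the full
    embed -> PCA -> HMM pipeline on each half, and matches states on the
    back-projected embedded-space covariances.  Returns one
    :class:`MatchResult` per repeat.
    """
    subjects = np.unique(t.subject)
    if len(subjects) < 4:
        raise ValueError("need at least 4 subjects for half-split validation")
    hmm_opts = dict(hmm_opts or {})
    rng = np.random.default_rng(seed)
    results = []
    for rep in range(n_repeats):
        perm = rng.permutation(subjects)
        halves = (perm[: len(subjects) // 2], perm[len(subjects) // 2:])
        fits = []
        for half in halves:
            mask = np.isin(t.subject, half)
            sub = TrialSet(t.data[mask], t.fs, t.channels, t.condition[mask],
                           t.subject[mask], t.event_sample[mask], dict(t.meta))
            emb = _tde.embed(sub, window_ms)
            pca = _tde.fit_pca(emb, n_pcs)
            model = _hmm.fit_hmm(pca.transform(emb.frames), emb.trial_lengths,
                                 n_states, seed=int(rng.integers(2**31 - 1)),
                                 **hmm_opts)
            fits.append((model, pca))
        (ma, pa), (mb, pb) = fits
        results.append(match_states(ma, mb, pca_a=pa, pca_b=pb))
    return results
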