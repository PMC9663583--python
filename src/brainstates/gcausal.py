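"""Granger causality between two channels via AR model comparison with BIC.

The null model is the target's own autoregression,

    X1(t) = sum_{j=1..p} b11_j X1(t-j) + E1(t),

and the augmented model adds lagged (and, following the definition used
here, instantaneous) terms of the source,

    X1(t) = sum_{j=1..p} b11_j X1(t-j) + sum_{j=0..p} b12_j X2(t-j) + E1(t).

Both are least-squares fits scored by BIC = n ln(RSS/n) + k ln(n).  The
effect size is dBIC = BIC_null(p*) - BIC_augmented(p), where p* minimises
the null BIC over 1..p_max, averaged over p = 1..p_max; positive dBIC
means the source improves prediction of the target beyond the target's own
past (BIC decreased).

All models inside one comparison are evaluated on the common sample
t >= p_max so that their BICs share one effective sample count: this makes
BICs at different orders comparable and makes dBIC exactly invariant to a
common rescaling of both series.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg

from .containers import TrialSet


@dataclass
class ARModel:
    order: int
    own_coeffs: np.ndarray           # b11_j, j = 1..p
    cross_coeffs: np.ndarray         # b12_j, j = 0..p (empty for the null model)
    residuals: np.ndarray
    residual_variance: float
    bic: float
    n_effective: int

    @property
    def n_coeffs(self) -> int:
        return len(self.own_coeffs) + len(self.cross_coeffs)


@dataclass
class GCResult:
    dbic: float                      # averaged over p = 1..p_max
    null_order: int                  # p* chosen for the target's own AR
    dbic_trace: np.ndarray           # per-p dBIC, p = 1..p_max
    p_max: int


def _lag_matrix(x, lags, t0, t1):
    """Columns x(t-j) for j in ``lags``, rows t = t0..t1-1."""
    return np.column_stack([x[t0 - j:t1 - j] for j in lags])


def fit_ar(x, p, x2=None, include_instant=True, t_start=None) -> ARModel:
    """Least-squares (augmented) autoregression of ``x`` at order ``p``.

    With ``x2`` given, source lags j = 0..p (j = 1..p when
    ``include_instant`` is False) enter as additional predictors.
    ``t_start`` fixes the first fitted time index (defaults to ``p``),
    letting callers align several models on a common sample.
    """
    x = np.asarray(x, dtype=float)
    if not np.isfinite(x).all():
        raise ValueError("series contains non-finite values")
    t0 = p if t_start is None else int(t_start)
    if t0 < p:
        raise ValueError(f"t_start ({t0}) must be >= order ({p})")
    n = len(x) - t0
    k = p + (0 if x2 is None else (p + 1 if include_instant else p))
    if n <= 3 * k:
        raise ValueError(f"series too short: {n} effective samples for {k} coefficients")
    own_lags = list(range(1, p + 1))
    design = _lag_matrix(x, own_lags, t0, len(x))
    cross_lags = []
    if x2 is not None:
        x2 = np.asarray(x2, dtype=float)
        if len(x2) != len(x):
            raise ValueError("series must have equal length")
        if not np.isfinite(x2).all():
            raise ValueError("series contains non-finite values")
        cross_lags = list(range(0 if include_instant else 1, p + 1))
        design = np.hstack([design, _lag_matrix(x2, cross_lags, t0, len(x))])
    # detect rank deficiency and name the offending lag columns
    _, r, piv = linalg.qr(design, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(design.shape) * np.finfo(float).eps if diag.size else 0.0
    rank = int((diag > tol).sum())
    if rank < design.shape[1]:
        names = [f"own lag {j}" for j in own_lags] + [f"cross lag {j}" for j in cross_lags]
        bad = sorted(names[i] for i in piv[rank:])
        raise ValueError(f"singular design matrix; collinear columns: {', '.join(bad)}")
    y = x[t0:]
    coeffs, _, _, _ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coeffs
    rss = float(resid @ resid)
    bic = n * np.log(rss / n) + design.shape[1] * np.log(n)
    return ARModel(order=p, own_coeffs=coeffs[:p],
                   cross_coeffs=coeffs[p:], residuals=resid,
                   residual_variance=rss / n, bic=float(bic), n_effective=n)


def gc_dbic(target, source, p_max: int = 20, include_instant: bool = True,
            demean: bool = True) -> GCResult:
    """Averaged-dBIC Granger effect of ``source`` on ``target``.

    The null order p* is chosen to minimise the target's own AR BIC over
    1..p_max; for every p in 1..p_max the augmented model is fitted and
    dBIC_p = BIC_null(p*) - BIC_augmented(p).  The result averages dBIC_p
    over all p, an effect size insensitive to the unknown true lag.
    """
    target = np.asarray(target, dtype=float)
    source = np.asarray(source, dtype=float)
    if len(target) != len(source):
        raise ValueError("series must have equal length")
    if demean:
        target = target - target.mean()
        source = source - source.mean()
    null_bics = np.array([fit_ar(target, p, t_start=p_max).bic
                          for p in range(1, p_max + 1)])
    p_star = int(np.argmin(null_bics)) + 1
    bic_null = null_bics[p_star - 1]
    dbic = np.empty(p_max)
    for p in range(1, p_max + 1):
        aug = fit_ar(target, p, x2=source, include_instant=include_instant,
                     t_start=p_max)
        dbic[p - 1] = bic_null - aug.bic
    return GCResult(dbic=float(dbic.mean()), null_order=p_star,
                    dbic_trace=dbic, p_max=p_max)


def trial_gc(t: TrialSet, source: str, target: str, p_max: int = 20,
             include_instant: bool = True) -> pd.DataFrame:
    """Per-trial directed dBIC between two channels of a TrialSet."""
    isrc = t.channel_index(source)
    itgt = t.channel_index(target)
    rows = []
    for i in range(t.n_trials):
        res = gc_dbic(t.data[i, :, itgt], t.data[i, :, isrc], p_max=p_max,
                      include_instant=include_instant)
        rows.append({"trial": i, "subject": t.subject[i],
                     "condition": t.condition[i], "source": source,
                     "target": target, "dbic": res.dbic,
                     "null_order": res.null_order})
    return pd.DataFrame(rows)
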