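"""Behavioural summaries and the behavioural-relevance models.

Percept durations in bistable perception are heavy-tailed and positive,
so relevance of the neural state dynamics to behaviour is modelled with a
gamma-family, log-link GLM of duration on state lifetime, the PCU->V1
Granger effect (dBIC), and their interaction; nested models are compared
by AIC and effect sizes by Cohen's f^2 on deviance-based R^2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm


@dataclass
class GlmFit:
    params: np.ndarray
    bse: np.ndarray
    tvalues: np.ndarray
    df_resid: float
    aic: float
    cohens_f2: float
    names: list
    deviance: float
    null_deviance: float

    def conf_int(self, alpha=0.05) -> np.ndarray:
        z = stats.norm.ppf(1 - alpha / 2)
        return np.column_stack([self.params - z * self.bse,
                                self.params + z * self.bse])


def duration_summary(durations) -> dict:
    """Median, adjusted Fisher-Pearson skewness, and excess kurtosis.

    Excess kurtosis follows the normal-is-zero convention (an Exp(1)
    sample has skewness ~2 and excess kurtosis ~6).  Constant data have no
    defined shape statistics and are rejected.
    """
    x = np.asarray(durations, dtype=float)
    if len(x) < 3:
        raise ValueError("need at least 3 values")
    if np.ptp(x) == 0:
        raise ValueError("zero variance: skewness/kurtosis undefined")
    return {
        "median": float(np.median(x)),
        "skewness": float(stats.skew(x, bias=False)),
        "kurtosis": float(stats.kurtosis(x, fisher=True, bias=False)),
    }


def _gamma_glm(y, X):
    model = sm.GLM(y, X, family=sm.families.Gamma(link=sm.families.links.Log()))
    return model.fit(maxiter=100, tol=1e-8)


def fit_interaction_glm(table: pd.DataFrame, level: str = "trial") -> GlmFit:
    """Gamma log-link GLM: duration ~ lifetime + dbic + lifetime:dbic.

    ``table`` needs columns ``duration``, ``lifetime``, ``dbic`` and (for
    ``level='subject-mean'``) ``subject``; the subject-mean level averages
    all variables per subject before fitting.  Cohen's f^2 is computed
    against the no-interaction model on deviance-based R^2,
    f^2 = (R2_full - R2_reduced) / (1 - R2_full).
    """
    df = table.copy()
    if level == "subject-mean":
        df = df.groupby("subject", as_index=False)[["duration", "lifetime", "dbic"]].mean()
    elif level != "trial":
        raise ValueError(f"unknown level {level!r}")
    if len(df) < 10:
        raise ValueError("need at least 10 rows")
    y = df["duration"].to_numpy(dtype=float)
    if (y <= 0).any():
        raise ValueError("durations must be positive")
    life = df["lifetime"].to_numpy(dtype=float)
    gc = df["dbic"].to_numpy(dtype=float)
    if not (np.isfinite(life).all() and np.isfinite(gc).all()):
        raise ValueError("predictors must be finite")
    X_full = np.column_stack([np.ones_like(y), life, gc, life * gc])
    if np.linalg.matrix_rank(X_full) < X_full.shape[1]:
        raise ValueError("perfectly collinear predictors")
    X_red = X_full[:, :3]
    full = _gamma_glm(y, X_full)
    reduced = _gamma_glm(y, X_red)
    r2_full = 1.0 - full.deviance / full.null_deviance
    r2_red = 1.0 - reduced.deviance / reduced.null_deviance
    f2 = max(0.0, (r2_full - r2_red) / max(1.0 - r2_full, 1e-12))
    return GlmFit(params=full.params, bse=full.bse, tvalues=full.tvalues,
                  df_resid=full.df_resid, aic=full.aic, cohens_f2=f2,
                  names=["intercept", "lifetime", "dbic", "lifetime:dbic"],
                  deviance=full.deviance, null_deviance=full.null_deviance)


def fit_reduced_glm(table: pd.DataFrame, level: str = "trial") -> GlmFit:
    """No-interaction gamma GLM: duration ~ lifetime + dbic."""
    df = table.copy()
    if level == "subject-mean":
        df = df.groupby("subject", as_index=False)[["duration", "lifetime", "dbic"]].mean()
    y = df["duration"].to_numpy(dtype=float)
    life = df["lifetime"].to_numpy(dtype=float)
    gc = df["dbic"].to_numpy(dtype=float)
    X = np.column_stack([np.ones_like(y), life, gc])
    fit = _gamma_glm(y, X)
    r2 = 1.0 - fit.deviance / fit.null_deviance
    return GlmFit(params=fit.params, bse=fit.bse, tvalues=fit.tvalues,
                  df_resid=fit.df_resid, aic=fit.aic, cohens_f2=0.0,
                  names=["intercept", "lifetime", "dbic"],
                  deviance=fit.deviance, null_deviance=fit.null_deviance)


def compare_aic(fit_full: GlmFit, fit_reduced: GlmFit) -> float:
    """dAIC = AIC(reduced) - AIC(full); positive favours the full model."""
    if fit_full.df_resid + len(fit_full.params) != fit_reduced.df_resid + len(fit_reduced.params):
        raise ValueError("fits use different numbers of observations")
    return float(fit_reduced.aic - fit_full.aic)


def subject_intercept_comparison(table: pd.DataFrame) -> dict:
    """Individual-difference check: fixed subject intercepts vs a pooled one.

    The simplest fixed-effects version of a subject random intercept:
    gamma GLMs of duration on subject dummies vs intercept only, compared
    by AIC and a chi-square deviance test.
    """
    y = table["duration"].to_numpy(dtype=float)
    subj = pd.get_dummies(table["subject"], drop_first=False).to_numpy(dtype=float)
    pooled = _gamma_glm(y, np.ones((len(y), 1)))
    per_subject = _gamma_glm(y, subj)
    # scaled deviance difference ~ chi2 with (n_subjects - 1) df
    scale = per_subject.scale
    dev_drop = (pooled.deviance - per_subject.deviance) / scale
    df = subj.shape[1] - 1
    p = float(stats.chi2.sf(dev_drop, df))
    return {"daic": float(pooled.aic - per_subject.aic),
            "deviance_drop": float(dev_drop), "df": df, "p": p}
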