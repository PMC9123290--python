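"""Multiple imputation by chained equations (PMM) and Rubin's-rules pooling.

Imputation is predictive-mean matching for every variable type: each
incomplete column is regressed (Bayesian linear regression with a
parameter draw) on all other analysis variables, and each missing cell
receives the observed value of one of the k nearest donors by predicted
mean.  Because donors are observed values, imputed categories and integer
scores stay in the observed support without type-specific models.

Pooling follows Rubin's combination rules: pooled coefficient qbar = mean,
within-variance W = mean(se^2), between-variance B = sample variance of
the coefficients, total variance T = W + (1 + 1/m) B, and t-based
intervals with df = (m-1) (1 + W / ((1+1/m) B))^2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm, t as t_dist

from .config import EDUCATION_LEVELS, MISSING_COLS
from .errors import EstimationError, ValidationError

#: Fully observed covariates always included in every imputation model.
_ALWAYS_PREDICTORS = ("female_num", "age", "has_partner")


def _encode(df: pd.DataFrame) -> pd.DataFrame:
    """Numeric working copy: sex -> female_num, education -> ordinal."""
    work = df.copy()
    work["female_num"] = (work["sex"] == "female").astype(float)
    edu_map = {lv: float(i) for i, lv in enumerate(EDUCATION_LEVELS)}
    work["education"] = work["education"].map(lambda v: edu_map.get(v, np.nan))
    return work


def _decode(work: pd.DataFrame, template: pd.DataFrame) -> pd.DataFrame:
    out = template.copy()
    for col in MISSING_COLS:
        if col == "education":
            levels = np.array(EDUCATION_LEVELS, dtype=object)
            idx = work["education"].to_numpy(dtype=float).round().astype(int)
            out["education"] = levels[np.clip(idx, 0, len(levels) - 1)]
        else:
            out[col] = work[col].to_numpy(dtype=float)
    return out


def _pmm_column(
    rng: np.random.Generator,
    ymis_pred: np.ndarray,
    yobs_pred: np.ndarray,
    yobs: np.ndarray,
    k: int,
) -> np.ndarray:
    """Draw one donor among the k nearest observed predicted means."""
    k = min(k, yobs.size)
    order = np.argsort(yobs_pred, kind="stable")
    sorted_pred = yobs_pred[order]
    out = np.empty(ymis_pred.size)
    pos = np.searchsorted(sorted_pred, ymis_pred)
    for i, (p, c) in enumerate(zip(pos, ymis_pred)):
        lo = max(0, p - k)
        hi = min(yobs.size, p + k)
        window = order[lo:hi]
        d = np.abs(yobs_pred[window] - c)
        nearest = window[np.argsort(d, kind="stable")[:k]]
        out[i] = yobs[nearest[rng.integers(0, nearest.size)]]
    return out


def _bayes_regression_draw(
    rng: np.random.Generator, X: np.ndarray, y: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """OLS fit plus an approximate posterior draw of the coefficients.

    Returns (beta_hat, beta_star); a small ridge keeps the normal-equations
    solve stable when predictors are collinear within a cycle.
    """
    n, p = X.shape
    XtX = X.T @ X + 1e-8 * np.eye(p)
    beta_hat = np.linalg.solve(XtX, X.T @ y)
    resid = y - X @ beta_hat
    dof = max(1, n - p)
    s2 = float(resid @ resid) / dof
    # sigma^2 draw from the scaled inverse chi-square, then beta | sigma^2
    g = rng.chisquare(dof)
    s2_star = s2 * dof / max(g, 1e-12)
    cov = s2_star * np.linalg.inv(XtX)
    L = np.linalg.cholesky(cov + 1e-12 * np.eye(p))
    beta_star = beta_hat + L @ rng.standard_normal(p)
    return beta_hat, beta_star


def impute(
    df: pd.DataFrame,
    m: int = 30,
    seed: int | None = None,
    cycles: int = 10,
    k: int = 5,
    columns: Sequence[str] | None = None,
) -> list[pd.DataFrame]:
    """Generate ``m`` completed cohorts by chained-equations PMM.

    Missingness is only allowed in ``columns`` (default: the standard
    imputable set).  Observed cells are never altered.  With no missing
    values the result is ``m`` identical copies.  ``m=1`` warns that
    pooling variance is undefined.
    """
    if m < 1:
        raise ValidationError(f"m must be >= 1, got {m}")
    if m == 1:
        warnings.warn(
            "m=1: single imputation; between-imputation variance undefined",
            UserWarning,
            stacklevel=2,
        )
    cols = tuple(columns) if columns is not None else MISSING_COLS
    unknown = set(cols) - set(df.columns)
    if unknown:
        raise ValidationError(f"unknown imputable columns: {sorted(unknown)}")
    other = set(df.columns) - set(cols) - {"id"}
    for col in other:
        if df[col].isna().any():
            raise ValidationError(
                f"column '{col}' has missing values but is not declared imputable"
            )
    for col in cols:
        if df[col].isna().all():
            raise EstimationError(f"column '{col}' is 100% missing; cannot impute")

    if not df[list(cols)].isna().any().any():
        return [df.copy() for _ in range(m)]

    work0 = _encode(df)
    masks = {c: work0[c].isna().to_numpy() for c in cols}
    incomplete = [c for c in cols if masks[c].any()]
    seeds = np.random.SeedSequence(seed).spawn(m)
    completed: list[pd.DataFrame] = []
    for imp in range(m):
        rng = np.random.default_rng(seeds[imp])
        work = work0.copy()
        # initial fill: random draws from the observed margin
        for c in incomplete:
            obs = work.loc[~masks[c], c].to_numpy(dtype=float)
            work.loc[masks[c], c] = rng.choice(obs, size=int(masks[c].sum()))
        for _ in range(cycles):
            for c in incomplete:
                preds = [p for p in (*_ALWAYS_PREDICTORS, *cols) if p != c]
                Xall = np.column_stack(
                    [np.ones(len(work))]
                    + [work[p].to_numpy(dtype=float) for p in preds]
                )
                yall = work[c].to_numpy(dtype=float)
                mis = masks[c]
                beta_hat, beta_star = _bayes_regression_draw(
                    rng, Xall[~mis], yall[~mis]
                )
                pred_obs = Xall[~mis] @ beta_hat
                pred_mis = Xall[mis] @ beta_star
                work.loc[mis, c] = _pmm_column(
                    rng, pred_mis, pred_obs, yall[~mis], k
                )
        completed.append(_decode(work, df))
    return completed


@dataclass
class PooledEstimate:
    """Rubin-pooled scalar estimate across ``m`` imputations."""

    qbar: float
    W: float
    B: float
    T: float
    df: float
    ci95: tuple[float, float]
    m: int

    @property
    def se(self) -> float:
        return float(np.sqrt(self.T))

    def to_dict(self) -> dict:
        return {
            "qbar": self.qbar,
            "W": self.W,
            "B": self.B,
            "T": self.T,
            "df": self.df,
            "ci95": list(self.ci95),
            "m": self.m,
        }


def pool(estimates: Sequence[tuple[float, float]]) -> PooledEstimate:
    """Combine per-imputation (coefficient, SE) pairs by Rubin's rules."""
    if len(estimates) == 0:
        raise ValidationError("no estimates to pool")
    coefs = np.array([e[0] for e in estimates], dtype=float)
    ses = np.array([e[1] for e in estimates], dtype=float)
    m = coefs.size
    if m < 2:
        raise ValidationError("pooling requires m >= 2")
    qbar = float(coefs.mean())
    W = float(np.mean(ses**2))
    B = float(np.var(coefs, ddof=1))
    T = W + (1.0 + 1.0 / m) * B
    if B > 0:
        df = (m - 1) * (1.0 + W / ((1.0 + 1.0 / m) * B)) ** 2
        q = t_dist.ppf(0.975, df)
    else:
        df = float("inf")
        q = norm.ppf(0.975)
    half = q * np.sqrt(T)
    return PooledEstimate(
        qbar=qbar,
        W=W,
        B=B,
        T=float(T),
        df=float(df),
        ci95=(qbar - float(half), qbar + float(half)),
        m=m,
    )
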