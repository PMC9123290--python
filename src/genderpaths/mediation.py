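"""Differential vulnerability (moderation) and differential exposure
(mediation) analyses.

Moderation: a tobit model of the CES-D total on a dichotomised working
condition, a binary sex/gender indicator, their interaction, and centered
age.  A non-zero interaction means the two groups react differently to the
same condition (differential vulnerability); significance is judged by a
Wald z test.

Mediation: single-mediator models in the classic path notation —
``a`` (logistic: mediator ~ exposure + age), ``b`` and ``c'`` (tobit:
cesd ~ mediator + exposure + age), ``c`` (tobit: cesd ~ exposure + age).
The average causal mediation effect (ACME, the indirect effect) for a
binary mediator is the product of the mediator's outcome coefficient and
the average counterfactual shift in mediator probability when exposure is
toggled, which is exact on the latent (linear-predictor) scale; an
alternative routes the same contrast through the censored-outcome
expectation.  Confidence intervals for the ACME are percentile intervals
over seeded nonparametric person resamples; the path coefficients keep
their Wald intervals, as is conventional.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd

from .errors import EstimationError, ValidationError
from .tobit import LogisticFit, TobitFit, censored_mean, fit_logistic, fit_tobit

GROUP_COLUMNS = {"sex": "female", "gender": "feminine"}


@dataclass
class Estimate:
    """Point estimate with a 95% interval (and optionally a Wald p)."""

    value: float
    lo: float
    hi: float
    p: float | None = None

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.value, self.lo, self.hi)


@dataclass
class ModerationResult:
    """Sex/gender-by-working-condition interaction model."""

    group_label: str
    wc_label: str
    wc_main: Estimate
    group_main: Estimate
    interaction: Estimate
    fit: TobitFit

    def to_row(self) -> dict:
        return {
            "group": self.group_label,
            "condition": self.wc_label,
            "wc_B": self.wc_main.value,
            "wc_lo": self.wc_main.lo,
            "wc_hi": self.wc_main.hi,
            "group_B": self.group_main.value,
            "group_lo": self.group_main.lo,
            "group_hi": self.group_main.hi,
            "interaction_B": self.interaction.value,
            "interaction_lo": self.interaction.lo,
            "interaction_hi": self.interaction.hi,
            "interaction_p": self.interaction.p,
        }


def _require_binary(df: pd.DataFrame, col: str) -> np.ndarray:
    x = df[col].to_numpy(dtype=float)
    if not np.isin(np.unique(x), (0.0, 1.0)).all():
        raise ValidationError(f"column '{col}' must be coded 0/1")
    return x


def _group_col(group: str) -> str:
    if group not in GROUP_COLUMNS:
        raise ValidationError(f"group must be 'sex' or 'gender', got {group!r}")
    return GROUP_COLUMNS[group]


def test_moderation(df: pd.DataFrame, group: str, wc: str) -> ModerationResult:
    """Fit cesd ~ high_wc * group + age and test the interaction.

    Reference groups are male/masculine and low exposure; an empty cell in
    the group-by-condition 2x2 raises naming the cell.
    """
    gcol = _group_col(group)
    wcol = f"high_{wc}"
    if wcol not in df.columns:
        raise ValidationError(f"missing dichotomised condition column '{wcol}'")
    g = _require_binary(df, gcol)
    w = _require_binary(df, wcol)
    y = df["cesd"].to_numpy(dtype=float)
    if np.isnan(y).any():
        raise ValidationError("cesd contains missing values; impute first")
    for gv in (0, 1):
        for wv in (0, 1):
            if not np.any((g == gv) & (w == wv)):
                raise ValidationError(
                    f"empty cell: {gcol}={gv}, {wcol}={wv}; interaction not estimable"
                )
    age_c = df["age_c"].to_numpy(dtype=float)
    X = np.column_stack([np.ones(len(df)), w, g, w * g, age_c])
    fit = fit_tobit(X, y, names=["intercept", wcol, gcol, f"{wcol}:{gcol}", "age_c"])
    ci = fit.conf_int()
    p = fit.wald_p()

    def est(j: int, with_p: bool = False) -> Estimate:
        return Estimate(fit.beta[j], ci[j, 0], ci[j, 1], p[j] if with_p else None)

    return ModerationResult(
        group_label=group,
        wc_label=wc,
        wc_main=est(1),
        group_main=est(2),
        interaction=est(3, with_p=True),
        fit=fit,
    )


def acme_binary_mediator(
    a_fit: LogisticFit,
    b_fit: TobitFit,
    df: pd.DataFrame,
    exposure: str,
    scale: Literal["latent", "expected"] = "latent",
) -> float:
    """Average causal mediation effect for a binary mediator.

    On the latent scale the ACME is ``beta_M * mean_i[p_i(M=1|T=1) -
    p_i(M=1|T=0)]``: the mediator's latent outcome coefficient times the
    average counterfactual shift in mediator probability, each person kept
    at their own age.  On the expected scale the same probability contrast
    is routed through the censored-outcome expectation (averaged over the
    two exposure arms).

    The a-model design is [1, exposure, age_c]; the b-model design is
    [1, mediator, exposure, age_c].
    """
    if scale not in ("latent", "expected"):
        raise ValidationError(f"scale must be 'latent' or 'expected', got {scale!r}")
    _group_col(exposure)  # validates the label
    age_c = df["age_c"].to_numpy(dtype=float)
    n = len(df)
    ones = np.ones(n)
    p1 = a_fit.predict_proba(np.column_stack([ones, ones, age_c]))
    p0 = a_fit.predict_proba(np.column_stack([ones, np.zeros(n), age_c]))
    contrast = p1 - p0
    beta_m = b_fit.beta[1]
    if scale == "latent":
        return float(beta_m * contrast.mean())
    # expected scale: contrast in E[y] between mediator arms, per exposure arm
    total = 0.0
    for t in (0.0, 1.0):
        tv = np.full(n, t)
        ey1 = censored_mean(
            np.column_stack([ones, ones, tv, age_c]) @ b_fit.beta, b_fit.sigma
        )
        ey0 = censored_mean(
            np.column_stack([ones, np.zeros(n), tv, age_c]) @ b_fit.beta, b_fit.sigma
        )
        total += float(np.mean(contrast * (ey1 - ey0)))
    return total / 2.0


@dataclass
class MediationResult:
    """Single-mediator model: paths a, b, c, c' and the bootstrap ACME."""

    exposure: str
    mediator: str
    a_path: Estimate
    b_path: Estimate
    c_path: Estimate
    c_prime: Estimate
    acme: Estimate
    acme_boot_sd: float
    scale: str
    n_boot: int
    n_failed: int
    seed: int | None

    def to_row(self) -> dict:
        return {
            "exposure": self.exposure,
            "mediator": self.mediator,
            "a_B": self.a_path.value,
            "a_lo": self.a_path.lo,
            "a_hi": self.a_path.hi,
            "b_B": self.b_path.value,
            "b_lo": self.b_path.lo,
            "b_hi": self.b_path.hi,
            "c_B": self.c_path.value,
            "c_lo": self.c_path.lo,
            "c_hi": self.c_path.hi,
            "c_prime_B": self.c_prime.value,
            "c_prime_lo": self.c_prime.lo,
            "c_prime_hi": self.c_prime.hi,
            "indirect_B": self.acme.value,
            "indirect_lo": self.acme.lo,
            "indirect_hi": self.acme.hi,
            "n_boot": self.n_boot,
            "n_failed_resamples": self.n_failed,
        }


def _fit_paths(
    y: np.ndarray,
    m: np.ndarray,
    t: np.ndarray,
    age_c: np.ndarray,
    compute_se: bool,
    fit_total: bool = True,
) -> tuple[LogisticFit, TobitFit, TobitFit | None]:
    n = y.size
    ones = np.ones(n)
    a_fit = fit_logistic(np.column_stack([ones, t, age_c]), m)
    bc_fit = fit_tobit(
        np.column_stack([ones, m, t, age_c]), y, compute_se=compute_se
    )
    c_fit = (
        fit_tobit(np.column_stack([ones, t, age_c]), y, compute_se=compute_se)
        if fit_total
        else None
    )
    return a_fit, bc_fit, c_fit


def mediate(
    df: pd.DataFrame,
    exposure: str,
    mediator: str,
    n_boot: int = 500,
    seed: int | None = None,
    scale: Literal["latent", "expected"] = "latent",
) -> MediationResult:
    """Single-mediator causal mediation with a percentile bootstrap ACME CI.

    ``exposure`` is "sex" or "gender" (columns ``female``/``feminine``);
    ``mediator`` names a working condition (column ``high_<mediator>``).
    Requires complete data (run after imputation).  Resamples in which any
    path model fails to fit are dropped and counted; more than 10% failures
    aborts.
    """
    if n_boot < 1:
        raise ValidationError(f"n_boot must be >= 1, got {n_boot}")
    tcol = _group_col(exposure)
    mcol = f"high_{mediator}"
    if mcol not in df.columns:
        raise ValidationError(f"missing dichotomised mediator column '{mcol}'")
    t = _require_binary(df, tcol)
    m = _require_binary(df, mcol)
    y = df["cesd"].to_numpy(dtype=float)
    age_c = df["age_c"].to_numpy(dtype=float)
    if np.isnan(y).any() or np.isnan(age_c).any():
        raise ValidationError("missing values in outcome or age; impute first")
    n = y.size

    a_fit, bc_fit, c_fit = _fit_paths(y, m, t, age_c, compute_se=True)
    sub = df[["age_c"]]
    acme_hat = acme_binary_mediator(a_fit, bc_fit, sub, exposure, scale=scale)

    rng = np.random.default_rng(seed)
    draws: list[float] = []
    n_failed = 0
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        try:
            a_b, bc_b, _ = _fit_paths(
                y[idx], m[idx], t[idx], age_c[idx], compute_se=False, fit_total=False
            )
            boot_df = pd.DataFrame({"age_c": age_c[idx]})
            draws.append(
                acme_binary_mediator(a_b, bc_b, boot_df, exposure, scale=scale)
            )
        except EstimationError:
            n_failed += 1
    if n_failed > 0.1 * n_boot:
        raise EstimationError(
            f"{n_failed} of {n_boot} bootstrap resamples failed to fit"
        )
    lo, hi = np.percentile(draws, [2.5, 97.5])

    a_ci = a_fit.conf_int()
    b_ci = bc_fit.conf_int()
    c_ci = c_fit.conf_int()
    return MediationResult(
        exposure=exposure,
        mediator=mediator,
        a_path=Estimate(a_fit.coef[1], a_ci[1, 0], a_ci[1, 1]),
        b_path=Estimate(bc_fit.beta[1], b_ci[1, 0], b_ci[1, 1]),
        c_path=Estimate(c_fit.beta[1], c_ci[1, 0], c_ci[1, 1]),
        c_prime=Estimate(bc_fit.beta[2], b_ci[2, 0], b_ci[2, 1]),
        acme=Estimate(acme_hat, float(lo), float(hi)),
        acme_boot_sd=float(np.std(draws, ddof=1)) if len(draws) > 1 else 0.0,
        scale=scale,
        n_boot=n_boot,
        n_failed=n_failed,
        seed=seed,
    )
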