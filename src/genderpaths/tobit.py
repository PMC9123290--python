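"""Maximum-likelihood estimation engines.

:func:`fit_tobit` estimates a linear model for a latent normal outcome
observed only above a left-censoring limit (here the CES-D floor at 0):

    y* = x'beta + eps,  eps ~ Normal(0, sigma^2),  y = max(limit, y*)

The log-likelihood mixes the normal density for uncensored rows with the
normal CDF mass below the limit for censored rows.  Optimisation is
quasi-Newton (BFGS with analytic gradient) over (beta, log sigma); the log
parameterisation keeps sigma positive without constraints.  Standard errors
come from the inverse observed information (numerically differentiated
analytic gradient); the delta method maps se(log sigma) to se(sigma).

:func:`fit_logistic` wraps the statsmodels Newton-Raphson logit MLE behind
the same small result surface, for the binary mediator models.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.special import log_ndtr
from scipy.stats import norm

from .errors import EstimationError, ValidationError

_LOG_2PI = float(np.log(2.0 * np.pi))


def _validate_design(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2:
        raise ValidationError("X must be a 2-d design matrix")
    if y.ndim != 1 or y.shape[0] != X.shape[0]:
        raise ValidationError("y must be 1-d and aligned with X")
    if not np.isfinite(X).all():
        raise ValidationError("design matrix contains non-finite entries")
    if not np.isfinite(y).all():
        raise ValidationError("outcome contains non-finite entries")
    return X, y


def tobit_loglik(
    beta: Sequence[float],
    sigma: float,
    X: np.ndarray,
    y: np.ndarray,
    left_limit: float = 0.0,
) -> float:
    """Left-censored normal log-likelihood.

    Uncensored rows (y > limit) contribute log phi((y - x'beta)/sigma) -
    log sigma; censored rows contribute log Phi((limit - x'beta)/sigma).
    """
    X, y = _validate_design(X, y)
    if sigma <= 0:
        raise ValidationError(f"sigma must be > 0, got {sigma}")
    beta = np.asarray(beta, dtype=float)
    xb = X @ beta
    cens = y <= left_limit
    ll = 0.0
    if (~cens).any():
        u = (y[~cens] - xb[~cens]) / sigma
        ll += float(np.sum(-0.5 * (u * u + _LOG_2PI) - np.log(sigma)))
    if cens.any():
        a = (left_limit - xb[cens]) / sigma
        ll += float(np.sum(norm.logcdf(a)))
    return ll


def _negloglik_and_grad(
    theta: np.ndarray, X: np.ndarray, y: np.ndarray, cens: np.ndarray, left: float
) -> tuple[float, np.ndarray]:
    p = X.shape[1]
    beta, s = theta[:p], theta[p]
    sigma = np.exp(s)
    xb = X @ beta
    g_beta = np.zeros(p)
    g_s = 0.0
    ll = 0.0
    if (~cens).any():
        u = (y[~cens] - xb[~cens]) / sigma
        ll += np.sum(-0.5 * (u * u + _LOG_2PI) - s)
        g_beta += X[~cens].T @ u / sigma
        g_s += np.sum(u * u - 1.0)
    if cens.any():
        a = (left - xb[cens]) / sigma
        logcdf = log_ndtr(a)
        ll += np.sum(logcdf)
        logpdf = -0.5 * (a * a + _LOG_2PI)
        lam = np.exp(logpdf - logcdf)  # stable inverse Mills ratio
        g_beta += X[cens].T @ (-lam / sigma)
        g_s += np.sum(-lam * a)
    return -float(ll), -np.concatenate([g_beta, [g_s]])


def _numeric_hessian(fun_grad, theta: np.ndarray, eps: float = 1e-6) -> np.ndarray:
    """Central finite differences of the analytic gradient."""
    k = theta.size
    H = np.zeros((k, k))
    for j in range(k):
        step = eps * max(1.0, abs(theta[j]))
        tp = theta.copy()
        tm = theta.copy()
        tp[j] += step
        tm[j] -= step
        _, gp = fun_grad(tp)
        _, gm = fun_grad(tm)
        H[:, j] = (gp - gm) / (2.0 * step)
    return 0.5 * (H + H.T)


@dataclass
class TobitFit:
    """Fitted left-censored regression.

    ``vcov`` is the covariance of (beta, log sigma); ``se`` covers beta and
    ``se_sigma`` is the delta-method SE of sigma itself.
    """

    beta: np.ndarray
    sigma: float
    se: np.ndarray
    se_log_sigma: float
    loglik: float
    loglik_start: float
    n: int
    n_censored: int
    converged: bool
    vcov: np.ndarray | None
    names: list[str] = field(default_factory=list)
    left_limit: float = 0.0
    loglik_path: list[float] = field(default_factory=list)

    @property
    def se_sigma(self) -> float:
        return self.sigma * self.se_log_sigma

    def conf_int(self, level: float = 0.95) -> np.ndarray:
        z = norm.ppf(0.5 + level / 2.0)
        return np.column_stack([self.beta - z * self.se, self.beta + z * self.se])

    def wald_z(self) -> np.ndarray:
        return self.beta / self.se

    def wald_p(self) -> np.ndarray:
        return 2.0 * norm.sf(np.abs(self.wald_z()))

    def predict_latent(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X, dtype=float) @ self.beta

    def to_dict(self) -> dict:
        return {
            "names": list(self.names),
            "beta": self.beta.tolist(),
            "se": self.se.tolist(),
            "sigma": self.sigma,
            "se_sigma": self.se_sigma,
            "loglik": self.loglik,
            "n": self.n,
            "n_censored": self.n_censored,
            "converged": bool(self.converged),
            "conf_int": self.conf_int().tolist(),
        }


def fit_tobit(
    X: np.ndarray,
    y: np.ndarray,
    left_limit: float = 0.0,
    names: Sequence[str] | None = None,
    max_iter: int = 200,
    gtol: float = 1e-6,
    compute_se: bool = True,
    track_path: bool = False,
) -> TobitFit:
    """Maximise the tobit likelihood by BFGS from an OLS start.

    Starting values are OLS on the uncensored subset with sigma_0 equal to
    the residual SD.  ``compute_se=False`` skips the observed-information
    step (used inside bootstrap loops where only point estimates matter).
    """
    X, y = _validate_design(X, y)
    n, p = X.shape
    if np.any(y < left_limit):
        raise ValidationError("outcome values below the censoring limit")
    cens = y <= left_limit
    n_unc = int((~cens).sum())
    if n_unc == 0:
        raise EstimationError("no uncensored data: all observations at the limit")
    if n <= p:
        raise EstimationError(f"need n > p, got n={n}, p={p}")
    if n_unc <= p:
        raise EstimationError(
            f"too few uncensored observations ({n_unc}) for {p} parameters"
        )

    beta0, *_ = np.linalg.lstsq(X[~cens], y[~cens], rcond=None)
    resid = y[~cens] - X[~cens] @ beta0
    dof = max(1, n_unc - p)
    sigma0 = float(np.sqrt(np.sum(resid**2) / dof))
    sigma0 = max(sigma0, 1e-3)
    theta0 = np.concatenate([beta0, [np.log(sigma0)]])

    def fg(theta: np.ndarray) -> tuple[float, np.ndarray]:
        return _negloglik_and_grad(theta, X, y, cens, left_limit)

    loglik_start = -fg(theta0)[0]
    path: list[float] = [loglik_start]

    res = minimize(
        fg,
        theta0,
        jac=True,
        method="BFGS",
        options={"gtol": gtol * 1e-2, "maxiter": max_iter},
        callback=(lambda t: path.append(-fg(t)[0])) if track_path else None,
    )
    theta = res.x
    grad_norm = float(np.max(np.abs(fg(theta)[1])))
    # polish with a few damped Newton steps if BFGS stalled short of the
    # gradient tolerance (precision-loss exits near the optimum)
    polish = 0
    while grad_norm >= gtol and polish < 5:
        H = _numeric_hessian(fg, theta)
        f0, g0 = fg(theta)
        try:
            step = np.linalg.solve(H, g0)
        except np.linalg.LinAlgError:
            break
        scale_ = 1.0
        improved = False
        ftol = 1e-10 * max(1.0, abs(f0))  # rounding slack near the optimum
        for _ in range(20):
            cand = theta - scale_ * step
            f1, g1 = fg(cand)
            if f1 <= f0 + ftol:
                theta = cand
                improved = True
                break
            scale_ *= 0.5
        if not improved:
            break
        if track_path:
            path.append(-fg(theta)[0])
        grad_norm = float(np.max(np.abs(fg(theta)[1])))
        polish += 1
    converged = grad_norm < gtol
    if not converged:
        warnings.warn(
            f"tobit fit did not reach gradient tolerance (|g|={grad_norm:.2e})",
            RuntimeWarning,
            stacklevel=2,
        )
    beta = theta[:p]
    sigma = float(np.exp(theta[p]))
    loglik = -fg(theta)[0]

    se = np.full(p, np.nan)
    se_log_sigma = float("nan")
    vcov = None
    if compute_se:
        H = _numeric_hessian(fg, theta)
        try:
            vcov = np.linalg.inv(H)
        except np.linalg.LinAlgError as exc:
            raise EstimationError("singular observed information") from exc
        d = np.diag(vcov)
        if np.any(d <= 0):
            warnings.warn(
                "non-positive-definite observed information; SEs unreliable",
                RuntimeWarning,
                stacklevel=2,
            )
            d = np.abs(d)
        se = np.sqrt(d[:p])
        se_log_sigma = float(np.sqrt(d[p]))

    return TobitFit(
        beta=beta,
        sigma=sigma,
        se=se,
        se_log_sigma=se_log_sigma,
        loglik=loglik,
        loglik_start=loglik_start,
        n=n,
        n_censored=int(cens.sum()),
        converged=converged,
        vcov=vcov,
        names=list(names) if names is not None else [f"x{j}" for j in range(p)],
        left_limit=left_limit,
        loglik_path=path,
    )


def censored_mean(xb, sigma: float, left_limit: float = 0.0):
    """E[max(limit, Z)], Z ~ Normal(xb, sigma^2): Phi(z)*xb + sigma*phi(z)
    (+ limit mass) with z = (xb - limit)/sigma."""
    xb = np.asarray(xb, dtype=float)
    z = (xb - left_limit) / sigma
    out = norm.cdf(z) * (xb - left_limit) + sigma * norm.pdf(z) + left_limit
    return float(out) if out.ndim == 0 else out


def tobit_expected(fit: TobitFit, X: np.ndarray):
    """Expected observed outcome E[y | x] under a converged tobit fit."""
    if not fit.converged:
        raise EstimationError("tobit fit did not converge; expectations unreliable")
    return censored_mean(fit.predict_latent(X), fit.sigma, fit.left_limit)


@dataclass
class LogisticFit:
    """Fitted logistic regression (log-odds scale)."""

    coef: np.ndarray
    se: np.ndarray
    loglik: float
    converged: bool
    vcov: np.ndarray
    names: list[str] = field(default_factory=list)

    def conf_int(self, level: float = 0.95) -> np.ndarray:
        z = norm.ppf(0.5 + level / 2.0)
        return np.column_stack([self.coef - z * self.se, self.coef + z * self.se])

    def odds_ratios(self, level: float = 0.95) -> np.ndarray:
        """Columns: OR, lower, upper."""
        ci = self.conf_int(level)
        return np.column_stack([np.exp(self.coef), np.exp(ci)])

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        from scipy.special import expit

        return expit(np.asarray(X, dtype=float) @ self.coef)

    def to_dict(self) -> dict:
        return {
            "names": list(self.names),
            "coef": self.coef.tolist(),
            "se": self.se.tolist(),
            "loglik": self.loglik,
            "converged": bool(self.converged),
            "odds_ratios": self.odds_ratios().tolist(),
        }


def fit_logistic(
    X: np.ndarray, b: np.ndarray, names: Sequence[str] | None = None
) -> LogisticFit:
    """Newton-Raphson logistic MLE (statsmodels Logit engine).

    Raises on a single-class outcome and on (quasi-)complete separation,
    advising a penalised fit, which this package deliberately does not
    provide.
    """
    import statsmodels.api as sm
    from statsmodels.tools.sm_exceptions import PerfectSeparationError

    X, b = _validate_design(X, b)
    vals = np.unique(b)
    if not np.isin(vals, (0.0, 1.0)).all():
        raise ValidationError("outcome must be coded 0/1")
    if vals.size < 2:
        raise EstimationError("outcome has a single class; logistic fit impossible")

    with warnings.catch_warnings():
        warnings.simplefilter("error", category=UserWarning)
        try:
            res = sm.Logit(b, X).fit(method="newton", disp=0, maxiter=100)
        except (PerfectSeparationError, UserWarning, np.linalg.LinAlgError) as exc:
            raise EstimationError(
                "complete or quasi-complete separation; consider a penalized "
                "(Firth) fit, which is not implemented here"
            ) from exc
    coef = np.asarray(res.params, dtype=float)
    if np.max(np.abs(coef)) > 30:
        raise EstimationError(
            "diverging logistic coefficients suggest separation; consider a "
            "penalized (Firth) fit, which is not implemented here"
        )
    return LogisticFit(
        coef=coef,
        se=np.asarray(res.bse, dtype=float),
        loglik=float(res.llf),
        converged=bool(res.mle_retvals.get("converged", True)),
        vcov=np.asarray(res.cov_params(), dtype=float),
        names=list(names) if names is not None else [f"x{j}" for j in range(X.shape[1])],
    )
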