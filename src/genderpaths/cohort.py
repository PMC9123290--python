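"""Synthetic cohort generation.

Emulates a two-wave occupational cohort of workers in their late fifties:
sex, age, six gender-role items on their raw scales (hours/week, euros,
percent female workers in the sector, education level, caregiving hours,
chore minutes), six working-condition sum scores, and a CES-D depressive
symptom total at follow-up.

The CES-D total is generated as a zero-left-censored latent normal,
``cesd = clip(round(max(0, X @ beta + eps)), 0, 60)``, which is exactly the
data-generating process a tobit model assumes (up to rounding and the
negligible ceiling at 60).

Working-condition sum scores are built so the *within-cohort* median split
(ties going to "low") recovers the latent high/low Bernoulli draw for every
person: "low" scores live in the lower half of the score range with a
probability clump exactly at the midpoint, "high" scores strictly above it,
and the clump is sized so the whole-sample median lands on the midpoint.
This keeps the configured per-sex "high" prevalences identifiable after the
median split, which an ordinary continuous score distribution cannot do
(a median split always yields ~50% "high" without ties).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit

from .config import (
    CAREGIVING_BANDS,
    CHORES_BANDS,
    CONDITIONS,
    EDUCATION_LEVELS,
    HOURS_BANDS,
    INCOME_BANDS,
    MISSING_COLS,
    SEGREGATION_BANDS,
    WC_SCORE_RANGES,
    GeneratorConfig,
)
from .errors import ValidationError

#: Column order of the cohort CSV schema.
COHORT_COLUMNS: tuple[str, ...] = (
    "id",
    "sex",
    "age",
    "hours_per_week",
    "income_monthly",
    "has_partner",
    "pct_female_sector",
    "education",
    "caregiving_hours_per_week",
    "chores_min_per_day",
    "wc_physical",
    "wc_psychosocial",
    "wc_cognitive",
    "wc_autonomy",
    "wc_variation",
    "wc_support",
    "cesd",
)


def _sample_banded(
    rng: np.random.Generator,
    cats: np.ndarray,
    bands: tuple[tuple[float, float], ...],
) -> np.ndarray:
    """Uniform draw inside the band selected for each person."""
    lo = np.array([bands[c][0] for c in cats])
    hi = np.array([bands[c][1] for c in cats])
    return lo + rng.random(cats.size) * (hi - lo)


def _sample_categories(
    rng: np.random.Generator, female: np.ndarray, probs: dict[str, list[float]]
) -> np.ndarray:
    """Per-sex categorical draw; one uniform per person, inverse-CDF."""
    n = female.size
    cdf_m = np.cumsum(probs["male"])
    cdf_f = np.cumsum(probs["female"])
    u = rng.random(n)
    cats = np.empty(n, dtype=np.intp)
    cats[~female] = np.searchsorted(cdf_m, u[~female], side="right")
    cats[female] = np.searchsorted(cdf_f, u[female], side="right")
    k = len(probs["male"]) - 1
    return np.minimum(cats, k)


def _wc_scores(
    rng: np.random.Generator,
    high: np.ndarray,
    score_range: tuple[int, int],
    pbar: float,
    tie_margin: float,
) -> np.ndarray:
    """Integer sum scores whose median split reproduces ``high`` exactly.

    Low scores are uniform on [lo, mid-1] except for a clump at mid sized so
    P(score < mid) < 1/2 <= P(score <= mid); then the sample median equals
    mid (w.h.p.) and ``score > median`` recovers ``high``.
    """
    lo, hi = score_range
    mid = (lo + hi) // 2
    n = high.size
    scores = np.empty(n, dtype=np.int64)
    # clump fraction among lows; the max() keeps a floor clump even when the
    # configured prevalence is close to 1/2
    denom = max(1e-9, 1.0 - pbar)
    clump = min(1.0, max(0.15, 1.0 - 0.5 / denom + tie_margin))
    n_high = int(high.sum())
    scores[high] = rng.integers(mid + 1, hi + 1, size=n_high)
    low_idx = np.flatnonzero(~high)
    at_mid = rng.random(low_idx.size) < clump
    scores[low_idx[at_mid]] = mid
    if mid - 1 >= lo:
        scores[low_idx[~at_mid]] = rng.integers(lo, mid, size=int((~at_mid).sum()))
    else:
        scores[low_idx[~at_mid]] = lo
    return scores


def generate_cohort(config: GeneratorConfig, keep_truth: bool = False) -> pd.DataFrame:
    """Generate a cohort as a DataFrame with :data:`COHORT_COLUMNS`.

    Parameters
    ----------
    config : GeneratorConfig
        Validated generator settings; ``config.seed`` makes the draw fully
        reproducible.
    keep_truth : bool
        If True, append the latent generating quantities (``true_high_*``
        indicators and ``latent_cesd``) for oracle checks.  These columns
        are not part of the CSV schema.

    Returns
    -------
    pandas.DataFrame
        One row per person.  ``sex`` and ``education`` are strings,
        ``has_partner`` is 0/1, ``cesd`` is a float column (NaN when
        degraded to missing).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    exclusions: dict[str, int] | None = None
    if config.apply_exclusions:
        # two-wave eligibility filtering applied to a source sample;
        # the final cohort size becomes random
        ns = config.n_source
        paid_t1 = rng.random(ns) < config.p_paid_t1
        part_t2 = rng.random(ns) < config.p_participate_t2
        paid_t2 = rng.random(ns) < config.p_paid_t2
        keep = paid_t1 & part_t2 & paid_t2
        exclusions = {
            "n_source": ns,
            "excluded_no_paid_work_t1": int((~paid_t1).sum()),
            "excluded_no_participation_t2": int((paid_t1 & ~part_t2).sum()),
            "excluded_no_paid_work_t2": int((paid_t1 & part_t2 & ~paid_t2).sum()),
            "n_final": int(keep.sum()),
        }
        n = exclusions["n_final"]
        if n < 1:
            raise ValidationError("exclusion filters removed every record")
    else:
        n = config.n

    female = rng.random(n) < config.p_female
    age = rng.normal(config.age_mean, config.age_sd, size=n)
    has_partner = rng.random(n) < config.p_partner

    hours = _sample_banded(
        rng, _sample_categories(rng, female, config.item_probs["hours"]), HOURS_BANDS
    )
    # income bands are on the equivalized (single-person) scale; invert the
    # equivalization to store raw household income
    inc_eq = _sample_banded(
        rng, _sample_categories(rng, female, config.item_probs["income"]), INCOME_BANDS
    )
    income = np.where(has_partner, inc_eq / 0.7, inc_eq)
    seg = _sample_banded(
        rng,
        _sample_categories(rng, female, config.item_probs["segregation"]),
        SEGREGATION_BANDS,
    )
    edu_cat = _sample_categories(rng, female, config.item_probs["education"])
    education = np.array(EDUCATION_LEVELS, dtype=object)[edu_cat]
    care = _sample_banded(
        rng,
        _sample_categories(rng, female, config.item_probs["caregiving"]),
        CAREGIVING_BANDS,
    )
    chores = _sample_banded(
        rng, _sample_categories(rng, female, config.item_probs["chores"]), CHORES_BANDS
    )

    high = {}
    wc_cols = {}
    for cond in CONDITIONS:
        pm = config.wc_prevalence[cond]["male"]
        pf = config.wc_prevalence[cond]["female"]
        p = np.where(female, pf, pm)
        h = rng.random(n) < p
        pbar = config.p_female * pf + (1.0 - config.p_female) * pm
        high[cond] = h
        wc_cols[f"wc_{cond}"] = _wc_scores(
            rng, h, WC_SCORE_RANGES[cond], pbar, config.tie_margin
        )

    coefs = config.outcome_coefs
    latent = (
        coefs["intercept"]
        + coefs["female"] * female
        + coefs["age"] * (age - config.age_mean)
        + sum(coefs[c] * high[c] for c in CONDITIONS)
        + sum(g * (female & high[c]) for c, g in config.outcome_interactions.items())
        + rng.normal(0.0, config.sigma, size=n)
    )
    cesd = np.clip(np.round(np.maximum(0.0, latent)), 0, 60)

    df = pd.DataFrame(
        {
            "id": np.arange(n),
            "sex": np.where(female, "female", "male").astype(object),
            "age": age,
            "hours_per_week": hours,
            "income_monthly": income,
            "has_partner": has_partner.astype(int),
            "pct_female_sector": seg,
            "education": education,
            "caregiving_hours_per_week": care,
            "chores_min_per_day": chores,
            **wc_cols,
            "cesd": cesd,
        }
    )
    if config.missing_rate > 0.0:
        df = inject_mar(
            df,
            rate=config.missing_rate,
            rng=rng,
            beta_female=config.miss_logit_female,
            beta_age=config.miss_logit_age,
            age_center=config.age_mean,
        )
    if keep_truth:
        for cond in CONDITIONS:
            df[f"true_high_{cond}"] = high[cond].astype(int)
        df["latent_cesd"] = latent
    if exclusions is not None:
        df.attrs["exclusions"] = exclusions
    return df


def _solve_intercept(rate: float, shift: np.ndarray) -> float:
    """Find alpha with mean(expit(alpha + shift)) == rate by bisection."""
    lo, hi = -30.0, 30.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if float(np.mean(expit(mid + shift))) < rate:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def inject_mar(
    df: pd.DataFrame,
    rate: float,
    rng: np.random.Generator,
    beta_female: float = 0.5,
    beta_age: float = 0.1,
    age_center: float | None = None,
) -> pd.DataFrame:
    """MAR degradation: missingness depends only on observed sex and age.

    Each column in :data:`MISSING_COLS` is masked independently with
    per-person probability ``expit(alpha + beta_female*female +
    beta_age*(age - center))`` where ``alpha`` is solved so the marginal
    rate equals ``rate``.  Non-missing cells are never altered.
    """
    if not 0.0 <= rate < 1.0:
        raise ValidationError(f"missing rate must be in [0, 1), got {rate}")
    out = df.copy()
    female = (out["sex"] == "female").to_numpy()
    center = age_center if age_center is not None else float(out["age"].mean())
    shift = beta_female * female + beta_age * (out["age"].to_numpy() - center)
    alpha = _solve_intercept(rate, shift)
    p = expit(alpha + shift)
    for col in MISSING_COLS:
        mask = rng.random(len(out)) < p
        if out[col].dtype == object:
            out.loc[mask, col] = None
        else:
            out[col] = out[col].astype(float)
            out.loc[mask, col] = np.nan
    return out


def censoring_fraction(df: pd.DataFrame) -> float:
    """Share of persons with a CES-D total exactly at the floor of 0.

    Raises :class:`ValidationError` listing the offending ids if any CES-D
    value is missing.
    """
    cesd = df["cesd"]
    if cesd.isna().any():
        ids = df.loc[cesd.isna(), "id"].tolist()
        raise ValidationError(f"cesd missing for ids {ids}")
    return float((cesd == 0).mean())


def expected_censored_moments(mu: float, sigma: float) -> tuple[float, float]:
    """Mean and SD of max(0, Z), Z ~ Normal(mu, sigma^2) (closed form)."""
    from scipy.stats import norm

    z = mu / sigma
    m1 = mu * norm.cdf(z) + sigma * norm.pdf(z)
    m2 = (mu**2 + sigma**2) * norm.cdf(z) + mu * sigma * norm.pdf(z)
    return m1, float(np.sqrt(m2 - m1**2))


def write_cohort(df: pd.DataFrame, path: str | Path, config: GeneratorConfig | None = None) -> None:
    """Write the cohort CSV (missing values as empty fields) plus an
    optional JSON sidecar with the generating configuration."""
    path = Path(path)
    df.to_csv(path, index=False)
    if config is not None:
        sidecar = path.with_suffix(".config.json")
        with open(sidecar, "w", encoding="utf-8") as fh:
            json.dump(config.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")


def read_cohort(path: str | Path) -> pd.DataFrame:
    """Read a cohort CSV written by :func:`write_cohort`."""
    df = pd.read_csv(path)
    missing = set(COHORT_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"cohort file {path} lacks columns {sorted(missing)}")
    return df
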