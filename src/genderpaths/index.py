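"""Six-item labour-market gender index and median dichotomisation.

Each item is coded so that a higher score means a more feminine role
profile: fewer working hours, lower (equivalized) income, a more
female-dominated sector, lower education, more informal caregiving, more
time on household chores.  The index is the plain sum of the item codes
(range 0-16 under these codings) and is dichotomised into
masculine/feminine at the within-sample median by default, or at a fixed
integer cutoff (masculine <= cutoff < feminine).

Quantile convention: sample quartiles use linear interpolation (numpy
default, "type 7"); band membership is half-open [q_k, q_{k+1}) with the
top band closed.  Scores exactly at the median go to "low"/"masculine".
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError

#: item -> (column, number of categories, reversed?)
ITEM_COLUMNS = {
    "hours": "hours_per_week",
    "income": "income_monthly",
    "segregation": "pct_female_sector",
    "education": "education",
    "caregiving": "caregiving_hours_per_week",
    "chores": "chores_min_per_day",
}

#: Maximum attainable total under the literal item codings.
MAX_TOTAL = 3 + 3 + 3 + 2 + 2 + 3


def equivalize_income(income_monthly: float, has_partner: bool) -> float:
    """Scale household income to a one-person-household equivalent.

    Income is multiplied by 0.7 (~1/sqrt(2), the inverse square root of the
    household size) when a partner lives in the household.
    """
    income = np.asarray(income_monthly, dtype=float)
    if np.any(income < 0):
        raise ValidationError("income must be nonnegative")
    factor = np.where(np.asarray(has_partner, dtype=bool), 0.7, 1.0)
    out = income * factor
    return float(out) if out.ndim == 0 else out


def quartile_codes(values: Sequence[float], reversed: bool = False) -> np.ndarray:
    """Code values into sample-quartile bands 0..3.

    Bands are [min, q25), [q25, q50), [q50, q75), [q75, max]; the lowest
    band scores 0 (or 3 when ``reversed``).
    """
    x = np.asarray(values, dtype=float)
    if x.size < 4:
        raise ValidationError("quartile coding needs at least 4 values")
    if np.unique(x).size < 2:
        raise ValidationError("degenerate quartiles: all values identical")
    breaks = np.quantile(x, [0.25, 0.5, 0.75])  # linear interpolation
    codes = np.searchsorted(breaks, x, side="right")
    # values exactly at a break belong to the upper band except nothing
    # special is needed at the top: searchsorted(side="right") already
    # closes the top band
    codes = np.minimum(codes, 3)
    return 3 - codes if reversed else codes


def code_segregation(pct_female_sector) -> np.ndarray | int:
    """Occupation-segregation band: 0 (<=25% female workers), 1 (26-50),
    2 (51-75), 3 (>=76)."""
    pct = np.asarray(pct_female_sector, dtype=float)
    if np.any((pct < 0) | (pct > 100)):
        raise ValidationError("pct_female_sector must be in [0, 100]")
    codes = np.digitize(pct, [25.0, 50.0, 75.0], right=True)
    return int(codes) if codes.ndim == 0 else codes


def code_education(level) -> np.ndarray | int:
    """Education coded by femininity: high -> 0, intermediate -> 1, low -> 2
    (lower education is the more feminine profile in this cohort)."""
    mapping = {"high": 0, "intermediate": 1, "low": 2}
    arr = np.asarray(level, dtype=object)
    flat = arr.reshape(-1)
    out = np.empty(flat.shape, dtype=np.int64)
    for i, lv in enumerate(flat):
        if lv not in mapping:
            raise ValidationError(f"unknown education level {lv!r}")
        out[i] = mapping[lv]
    out = out.reshape(arr.shape)
    return int(out) if out.ndim == 0 else out


def code_caregiving(hours) -> np.ndarray | int:
    """Informal caregiving band: 0 (none), 1 (< 8 h/week), 2 (>= 8 h/week)."""
    h = np.asarray(hours, dtype=float)
    if np.any(h < 0):
        raise ValidationError("caregiving hours must be nonnegative")
    codes = np.where(h <= 0, 0, np.where(h < 8, 1, 2))
    return int(codes) if codes.ndim == 0 else codes


def median_split(scores: Sequence[float]) -> np.ndarray:
    """Dichotomise at the sample median: "high" iff score > median.

    Values exactly at the median go to "low" (documented tie rule).
    """
    x = np.asarray(scores, dtype=float)
    if x.size < 2:
        raise ValidationError("median split needs at least 2 values")
    if np.isnan(x).any():
        raise ValidationError("median split input contains missing values")
    med = np.median(x)
    return np.where(x > med, "high", "low").astype(object)


def dichotomize_total(totals: Sequence[float], cutoff: int | str = "median") -> tuple[np.ndarray, float]:
    """Split index totals into masculine/feminine at a cutoff.

    ``cutoff="median"`` uses the within-sample median of the totals;
    an integer cutoff k yields masculine for totals <= k and feminine
    above (the fixed replication rule: masculine 0..k, feminine k+1..max).
    Returns (labels, cutoff_used).
    """
    t = np.asarray(totals, dtype=float)
    if t.size == 0:
        raise ValidationError("no totals to dichotomise")
    if cutoff == "median":
        cut = float(np.median(t))
    elif isinstance(cutoff, (int, np.integer)):
        cut = float(cutoff)
    else:
        raise ValidationError(f"cutoff must be 'median' or an integer, got {cutoff!r}")
    labels = np.where(t > cut, "feminine", "masculine").astype(object)
    return labels, cut


def build_index(
    df: pd.DataFrame, cutoff: int | str = "median"
) -> pd.DataFrame:
    """Compute item codes, total, and masculine/feminine dichotomy.

    Returns a copy of ``df`` with appended columns ``item_code_<item>``,
    ``gender_total``, ``gender_binary`` ("masculine"/"feminine") and
    ``gender_cutoff_used``.  Requires complete items (run after
    imputation); a missing raw item raises naming the record and item.

    Hours and equivalized income are quartile-coded reversed (fewer hours /
    less income = more feminine); chores are quartile-coded unreversed;
    segregation, education and caregiving use their fixed bands.  Income is
    equivalized before the quartiles are computed.
    """
    for item, col in ITEM_COLUMNS.items():
        bad = df[col].isna()
        if bad.any():
            rec = df.loc[bad, "id"].iloc[0] if "id" in df else df.index[bad][0]
            raise ValidationError(f"record {rec}: missing gender item '{item}' ({col})")

    out = df.copy()
    inc_eq = equivalize_income(
        out["income_monthly"].to_numpy(dtype=float),
        out["has_partner"].to_numpy(dtype=bool),
    )
    out["item_code_hours"] = quartile_codes(out["hours_per_week"], reversed=True)
    out["item_code_income"] = quartile_codes(inc_eq, reversed=True)
    out["item_code_segregation"] = code_segregation(out["pct_female_sector"])
    out["item_code_education"] = code_education(out["education"])
    out["item_code_caregiving"] = code_caregiving(out["caregiving_hours_per_week"])
    out["item_code_chores"] = quartile_codes(out["chores_min_per_day"], reversed=False)

    total = (
        out["item_code_hours"]
        + out["item_code_income"]
        + out["item_code_segregation"]
        + out["item_code_education"]
        + out["item_code_caregiving"]
        + out["item_code_chores"]
    )
    out["gender_total"] = total

    labels, cut = dichotomize_total(total.to_numpy(), cutoff)
    out["gender_binary"] = labels
    out["gender_cutoff_used"] = cut
    return out


def add_analysis_columns(
    df: pd.DataFrame,
    cutoff: int | str = "median",
    conditions: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Derive the binary modelling columns every analysis table uses.

    Appends ``female`` and ``feminine`` (0/1), ``high_<condition>`` (0/1
    from the median split of each ``wc_<condition>`` sum score) and
    ``age_c`` (age centered at the sample mean).
    """
    from .config import CONDITIONS

    conditions = tuple(conditions) if conditions is not None else CONDITIONS
    out = build_index(df, cutoff=cutoff)
    out["female"] = (out["sex"] == "female").astype(int)
    out["feminine"] = (out["gender_binary"] == "feminine").astype(int)
    for cond in conditions:
        labels = median_split(out[f"wc_{cond}"].to_numpy(dtype=float))
        out[f"high_{cond}"] = (labels == "high").astype(int)
    out["age_c"] = out["age"] - out["age"].mean()
    return out
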