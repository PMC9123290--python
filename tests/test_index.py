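"""Gender index: item codings, quartiles, sum score, dichotomisation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import genderpaths as gp
from genderpaths.index import MAX_TOTAL


def brute_force_quartile_code(x: float, sample: np.ndarray) -> int:
    """Independent oracle: manual linear-interpolation quantiles, bands
    [q_k, q_{k+1}) with the top band closed."""
    s = np.sort(sample)
    n = s.size

    def q(p: float) -> float:
        h = (n - 1) * p
        lo = int(np.floor(h))
        hi = min(lo + 1, n - 1)
        return s[lo] + (h - lo) * (s[hi] - s[lo])

    q1, q2, q3 = q(0.25), q(0.5), q(0.75)
    if x < q1:
        return 0
    if x < q2:
        return 1
    if x < q3:
        return 2
    return 3


class TestItemCodings:
    def test_equivalize_income(self):
        assert gp.equivalize_income(2000.0, True) == pytest.approx(1400.0)
        assert gp.equivalize_income(2000.0, False) == 2000.0
        assert gp.equivalize_income(0.0, True) == 0.0
        with pytest.raises(gp.ValidationError):
            gp.equivalize_income(-1.0, True)

    def test_quartile_codes_eight_point_sample(self):
        got = gp.quartile_codes(np.arange(1, 9), reversed=False)
        want = [brute_force_quartile_code(x, np.arange(1, 9)) for x in range(1, 9)]
        assert list(got) == want == [0, 0, 1, 1, 2, 2, 3, 3]

    def test_quartile_codes_reversal_symmetry(self):
        fwd = gp.quartile_codes(np.arange(1, 9), reversed=False)
        rev = gp.quartile_codes(np.arange(1, 9), reversed=True)
        assert list(fwd + rev) == [3] * 8

    def test_quartile_codes_degenerate(self):
        with pytest.raises(gp.ValidationError, match="degenerate"):
            gp.quartile_codes([2.0, 2.0, 2.0, 2.0])
        with pytest.raises(gp.ValidationError):
            gp.quartile_codes([1.0, 2.0])

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(
        st.lists(
            st.floats(min_value=-1e6, max_value=1e6, allow_nan=False),
            min_size=4,
            max_size=40,
        )
    )
    def test_quartile_codes_match_bruteforce_oracle(self, values):
        x = np.asarray(values)
        if np.unique(x).size < 2:
            return
        got = gp.quartile_codes(x)
        want = [brute_force_quartile_code(v, x) for v in x]
        assert list(got) == want

    @pytest.mark.parametrize(
        "pct, code", [(0, 0), (25, 0), (26, 1), (50, 1), (51, 2), (75, 2), (76, 3), (100, 3)]
    )
    def test_segregation_bands(self, pct, code):
        assert gp.code_segregation(pct) == code

    def test_segregation_out_of_range(self):
        with pytest.raises(gp.ValidationError):
            gp.code_segregation(101.0)

    @pytest.mark.parametrize("level, code", [("high", 0), ("intermediate", 1), ("low", 2)])
    def test_education_coding_reversed_for_femininity(self, level, code):
        assert gp.code_education(level) == code

    def test_education_unknown_label(self):
        with pytest.raises(gp.ValidationError, match="phd"):
            gp.code_education("phd")

    @pytest.mark.parametrize("hours, code", [(0, 0), (0.5, 1), (7.9, 1), (8, 2), (40, 2)])
    def test_caregiving_bands(self, hours, code):
        assert gp.code_caregiving(hours) == code


def _profile_frame() -> pd.DataFrame:
    """Eight hand-built persons; row 0 is the fully masculine profile,
    row 7 the fully feminine one."""
    return pd.DataFrame(
        {
            "id": range(8),
            "sex": ["male"] * 4 + ["female"] * 4,
            "age": [58.0] * 8,
            "hours_per_week": [50.0, 45, 40, 38, 30, 25, 10, 5],
            "income_monthly": [5000.0, 4500, 3000, 2800, 2200, 2000, 1500, 800],
            "has_partner": [0] * 8,
            "pct_female_sector": [10.0, 20, 30, 45, 55, 60, 80, 90],
            "education": [
                "high", "high", "intermediate", "high",
                "intermediate", "low", "low", "low",
            ],
            "caregiving_hours_per_week": [0.0, 0, 0, 2, 3, 7, 9, 10],
            "chores_min_per_day": [5.0, 10, 20, 40, 70, 90, 150, 200],
        }
    )


class TestBuildIndex:
    def test_extreme_profiles_score_0_and_16(self):
        out = gp.build_index(_profile_frame(), cutoff=7)
        assert out.loc[0, "gender_total"] == 0
        assert out.loc[0, "gender_binary"] == "masculine"
        assert out.loc[7, "gender_total"] == MAX_TOTAL == 16
        assert out.loc[7, "gender_binary"] == "feminine"
        assert out["gender_total"].between(0, MAX_TOTAL).all()

    def test_fixed_cutoff_splits_7_and_8(self):
        """Totals 7 and 8 fall on opposite sides of the masculine/feminine
        boundary under the fixed cutoff (masculine 0-7, feminine 8+)."""
        labels, cut = gp.dichotomize_total([7, 8], cutoff=7)
        assert list(labels) == ["masculine", "feminine"]
        assert cut == 7.0
        out = gp.build_index(_profile_frame(), cutoff=7)
        totals = out["gender_total"]
        assert (out.loc[totals <= 7, "gender_binary"] == "masculine").all()
        assert (out.loc[totals >= 8, "gender_binary"] == "feminine").all()

    def test_median_cutoff_default(self):
        out = gp.build_index(_profile_frame())
        med = np.median(out["gender_total"])
        assert (out["gender_binary"] == "feminine").equals(out["gender_total"] > med)
        assert (out["gender_cutoff_used"] == med).all()

    def test_missing_item_names_record_and_item(self):
        df = _profile_frame()
        df.loc[3, "chores_min_per_day"] = np.nan
        with pytest.raises(gp.ValidationError, match="record 3.*chores"):
            gp.build_index(df)

    def test_permutation_invariance(self):
        df = _profile_frame()
        out = gp.build_index(df, cutoff=7)
        perm = df.sample(frac=1.0, random_state=42)
        out_perm = gp.build_index(perm, cutoff=7).sort_values("id")
        assert list(out_perm["gender_total"]) == list(out["gender_total"])
        assert list(out_perm["gender_binary"]) == list(out["gender_binary"])

    @pytest.mark.parametrize(
        "col, direction",
        [
            ("hours_per_week", -1),
            ("income_monthly", -1),
            ("pct_female_sector", +1),
            ("caregiving_hours_per_week", +1),
            ("chores_min_per_day", +1),
        ],
    )
    def test_item_monotonicity(self, col, direction):
        """Moving any single raw item toward its feminine pole never
        lowers that person's total."""
        df = _profile_frame()
        base = gp.build_index(df, cutoff=7)
        for row in range(len(df)):
            bumped = df.copy()
            if direction > 0:
                cap = 100.0 if col == "pct_female_sector" else np.inf
                bumped.loc[row, col] = min(cap, bumped.loc[row, col] * 1.5 + 5)
            else:
                bumped.loc[row, col] = max(0.0, bumped.loc[row, col] * 0.5 - 5)
            out = gp.build_index(bumped, cutoff=7)
            assert out.loc[row, "gender_total"] >= base.loc[row, "gender_total"]

    def test_education_monotonicity(self):
        df = _profile_frame()
        base = gp.build_index(df, cutoff=7)
        df.loc[0, "education"] = "low"
        out = gp.build_index(df, cutoff=7)
        assert out.loc[0, "gender_total"] >= base.loc[0, "gender_total"]


class TestMedianSplit:
    def test_examples(self):
        assert list(gp.median_split([1, 2, 3, 4])) == ["low", "low", "high", "high"]
        assert list(gp.median_split([5, 5, 5, 6])) == ["low", "low", "low", "high"]

    def test_degenerate(self):
        with pytest.raises(gp.ValidationError):
            gp.median_split([1.0])

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(
        st.lists(
            st.floats(min_value=-1e6, max_value=1e6, allow_nan=False),
            min_size=2,
            max_size=50,
        )
    )
    def test_high_iff_above_median(self, values):
        labels = gp.median_split(values)
        med = np.median(values)
        want = ["high" if v > med else "low" for v in values]
        assert list(labels) == want


def test_feminine_share_much_higher_among_women(large_analysis_cohort):
    """Direction check against the study pattern (women ~70% feminine,
    men ~18%), within wide simulation bounds."""
    an = large_analysis_cohort
    share_w = an.loc[an["female"] == 1, "feminine"].mean()
    share_m = an.loc[an["female"] == 0, "feminine"].mean()
    assert share_w > share_m + 0.3
    assert share_w > 0.5
    assert share_m < 0.4
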