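"""Configuration objects for the synthetic cohort generator and the pipeline.

The generator emulates a single-country cohort of workers in their late
fifties observed at two waves: gender-role items and working conditions at
baseline (T1), a CES-D depressive-symptom total (0-60, floored at 0) three
years later (T2).  All defaults are the study conditions the package is
calibrated to; every one of them can be overridden from a YAML/JSON mapping
so the sex/gender/working-condition structure can be decoupled or switched
off for null simulations.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Any, Mapping, Sequence

import yaml

from .errors import ConfigurationError

#: Working-condition labels, in reporting order.
CONDITIONS: tuple[str, ...] = (
    "physical",
    "psychosocial",
    "cognitive",
    "autonomy",
    "variation",
    "support",
)

#: Integer sum-score range per condition (items x 4-point response scale).
WC_SCORE_RANGES: dict[str, tuple[int, int]] = {
    "physical": (5, 20),     # 5 items
    "psychosocial": (2, 8),  # 2 items
    "cognitive": (6, 24),    # 6 items
    "autonomy": (3, 12),     # 3 items
    "variation": (1, 4),     # 1 item
    "support": (4, 16),      # 4 items
}

#: Gender-index item labels.
GENDER_ITEMS: tuple[str, ...] = (
    "hours",
    "income",
    "segregation",
    "education",
    "caregiving",
    "chores",
)

EDUCATION_LEVELS: tuple[str, ...] = ("low", "intermediate", "high")

# Raw-scale sampling bands per categorised item (uniform within the band).
HOURS_BANDS = ((1.0, 20.0), (20.0, 35.0), (35.0, 41.0), (41.0, 60.0))
INCOME_BANDS = ((510.0, 1900.0), (1900.0, 2400.0), (2400.0, 3000.0), (3000.0, 5446.0))
CHORES_BANDS = ((0.0, 24.0), (24.0, 60.0), (60.0, 120.0), (120.0, 300.0))
CAREGIVING_BANDS = ((0.0, 0.0), (0.5, 8.0), (8.0, 30.0))
SEGREGATION_BANDS = ((0.0, 25.0), (26.0, 50.0), (51.0, 75.0), (76.0, 100.0))

#: Columns eligible for MAR degradation / imputation (sex, age, partner
#: status stay fully observed).
MISSING_COLS: tuple[str, ...] = (
    "hours_per_week",
    "income_monthly",
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


def _default_item_probs() -> dict[str, dict[str, list[float]]]:
    # Per-sex category frequencies of the six gender-role items.
    # NOTE: the male working-hours Q4 entry is not directly observable in the
    # source table (garbled print); 0.181 is back-solved from the row-sum
    # constraint and the marginal column, and should be treated as uncertain.
    return {
        "hours": {
            "male": [0.114, 0.182, 0.523, 0.181],
            "female": [0.434, 0.346, 0.176, 0.044],
        },
        "income": {
            "male": [0.207, 0.225, 0.284, 0.284],
            "female": [0.328, 0.267, 0.252, 0.153],
        },
        "segregation": {
            "male": [0.412, 0.271, 0.277, 0.040],
            "female": [0.081, 0.110, 0.654, 0.155],
        },
        "education": {
            "male": [0.299, 0.243, 0.458],
            "female": [0.294, 0.309, 0.397],
        },
        "caregiving": {
            "male": [0.832, 0.134, 0.034],
            "female": [0.623, 0.263, 0.114],
        },
        "chores": {
            "male": [0.424, 0.299, 0.158, 0.119],
            "female": [0.059, 0.169, 0.353, 0.419],
        },
    }


def _default_wc_prevalence() -> dict[str, dict[str, float]]:
    # Probability of being in the "high" half of each working-condition
    # score, by sex.
    return {
        "physical": {"male": 0.429, "female": 0.500},
        "psychosocial": {"male": 0.441, "female": 0.441},
        "cognitive": {"male": 0.384, "female": 0.331},
        "autonomy": {"male": 0.458, "female": 0.360},
        "variation": {"male": 0.403, "female": 0.341},
        "support": {"male": 0.384, "female": 0.360},
    }


def _default_outcome_coefs() -> dict[str, float]:
    # Latent-scale (uncensored) CES-D model: intercept + female + one
    # coefficient per dichotomised working condition + centered age.
    # Intercept and sigma are calibrated so the censored, rounded outcome
    # has mean ~5.7 and SD ~5.6 with ~26% of scores at the floor
    # (closed-form censored-normal moments at marginal latent mean 4.6,
    # marginal latent SD 7.1).
    return {
        "intercept": 6.1,
        "female": 1.7,
        "physical": -0.5,
        "psychosocial": -0.5,
        "cognitive": 0.4,
        "autonomy": -1.6,
        "variation": -2.1,
        "support": -1.3,
        "age": 0.1,
    }


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic cohort generator.

    Attributes
    ----------
    n : int
        Cohort size (default 313 persons).
    p_female : float
        Probability of female sex (default 0.435).
    age_mean, age_sd : float
        Age distribution in years at baseline.
    p_partner : float
        Probability of a partner in the household (affects income
        equivalization).
    item_probs : mapping
        ``item -> {"male": [...], "female": [...]}`` category probabilities
        for the six gender-role items; every row must sum to 1.
    wc_prevalence : mapping
        ``condition -> {"male": p, "female": p}`` probability of the "high"
        half of each working-condition score.
    outcome_coefs : mapping
        Latent-scale CES-D coefficients: ``intercept``, ``female``, one key
        per condition (effect of being in the high half), and ``age``
        (per year, age centered at ``age_mean``).
    sigma : float
        Latent residual SD (default 6.9; together with the covariate
        spread this puts the marginal latent SD near 7.1).
    outcome_interactions : mapping
        Optional ``condition -> extra latent effect`` added when the person
        is female *and* in the high half of that condition (a true
        differential-vulnerability effect; empty by default).
    missing_rate : float
        Marginal probability in [0, 1) that any one imputable cell is set
        missing under the MAR mechanism (default 0 = complete data).
    miss_logit_female, miss_logit_age : float
        MAR log-odds shifts for female sex and per year of (centered) age.
    tie_margin : float
        Safety margin for the probability clump placed at each
        working-condition score midpoint so the whole-sample median falls
        exactly on the midpoint (see methods note).
    apply_exclusions : bool
        If True, emulate the two-wave eligibility filtering instead of
        generating ``n`` workers directly: draw ``n_source`` source
        participants, keep those with paid work at baseline
        (``p_paid_t1``), follow-up participation (``p_participate_t2``)
        and paid work at follow-up (``p_paid_t2``); the resulting cohort
        size is then random (~313 at the defaults) and the exclusion
        counts are attached as ``DataFrame.attrs['exclusions']``.
    seed : int
        Base seed for all randomness.
    """

    n: int = 313
    p_female: float = 0.435
    age_mean: float = 58.9
    age_sd: float = 2.4
    p_partner: float = 0.80
    item_probs: dict[str, dict[str, list[float]]] = field(default_factory=_default_item_probs)
    wc_prevalence: dict[str, dict[str, float]] = field(default_factory=_default_wc_prevalence)
    outcome_coefs: dict[str, float] = field(default_factory=_default_outcome_coefs)
    sigma: float = 6.9
    outcome_interactions: dict[str, float] = field(default_factory=dict)
    missing_rate: float = 0.0
    miss_logit_female: float = 0.5
    miss_logit_age: float = 0.1
    tie_margin: float = 0.10
    apply_exclusions: bool = False
    n_source: int = 1023
    p_paid_t1: float = 0.614
    p_participate_t2: float = 0.852
    p_paid_t2: float = 0.585
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n < 1:
            raise ConfigurationError(f"n must be >= 1, got {self.n}")
        if not 0.0 <= self.p_female <= 1.0:
            raise ConfigurationError(f"p_female must be in [0, 1], got {self.p_female}")
        if self.sigma <= 0:
            raise ConfigurationError(f"sigma must be > 0, got {self.sigma}")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ConfigurationError(
                f"missing_rate must be in [0, 1), got {self.missing_rate}"
            )
        if self.age_sd <= 0:
            raise ConfigurationError(f"age_sd must be > 0, got {self.age_sd}")
        if self.n_source < 1:
            raise ConfigurationError(f"n_source must be >= 1, got {self.n_source}")
        for name in ("p_paid_t1", "p_participate_t2", "p_paid_t2"):
            p = getattr(self, name)
            if not 0.0 < p <= 1.0:
                raise ConfigurationError(f"{name} must be in (0, 1], got {p}")
        n_cats = {
            "hours": 4, "income": 4, "segregation": 4,
            "education": 3, "caregiving": 3, "chores": 4,
        }
        for item in GENDER_ITEMS:
            if item not in self.item_probs:
                raise ConfigurationError(f"item_probs missing item '{item}'")
            for sex in ("male", "female"):
                row = self.item_probs[item].get(sex)
                if row is None:
                    raise ConfigurationError(f"item_probs['{item}'] missing sex '{sex}'")
                if len(row) != n_cats[item]:
                    raise ConfigurationError(
                        f"item_probs['{item}']['{sex}'] must have "
                        f"{n_cats[item]} categories, got {len(row)}"
                    )
                if any(p < 0 for p in row):
                    raise ConfigurationError(
                        f"item_probs['{item}']['{sex}'] has a negative entry"
                    )
                if abs(sum(row) - 1.0) > 1e-12:
                    raise ConfigurationError(
                        f"item_probs['{item}']['{sex}'] sums to {sum(row)!r}, "
                        "expected 1"
                    )
        for cond in CONDITIONS:
            if cond not in self.wc_prevalence:
                raise ConfigurationError(f"wc_prevalence missing condition '{cond}'")
            for sex in ("male", "female"):
                p = self.wc_prevalence[cond].get(sex)
                if p is None or not 0.0 <= p <= 1.0:
                    raise ConfigurationError(
                        f"wc_prevalence['{cond}']['{sex}'] must be a "
                        f"probability, got {p!r}"
                    )
        required = {"intercept", "female", "age", *CONDITIONS}
        missing = required - set(self.outcome_coefs)
        if missing:
            raise ConfigurationError(f"outcome_coefs missing keys: {sorted(missing)}")
        unknown_ix = set(self.outcome_interactions) - set(CONDITIONS)
        if unknown_ix:
            raise ConfigurationError(
                f"outcome_interactions has unknown conditions: {sorted(unknown_ix)}"
            )

    def replace(self, **kwargs: Any) -> "GeneratorConfig":
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: Mapping[str, Any]) -> "GeneratorConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigurationError(f"unknown generator config keys: {sorted(unknown)}")
        return cls(**dict(data))


@dataclass
class PipelineConfig:
    """End-to-end study-replica configuration.

    ``gender_cutoff`` selects the index dichotomisation: ``"median"`` (the
    within-sample median of the totals) or an integer fixed cutoff
    (masculine <= cutoff < feminine).  The adjustment set of every outcome
    model is ``{age}``.
    """

    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    n_boot: int = 500
    m_imputations: int = 30
    mi_cycles: int = 10
    pmm_donors: int = 5
    gender_cutoff: int | str = "median"
    seed: int = 0
    conditions: Sequence[str] = CONDITIONS

    def __post_init__(self) -> None:
        if isinstance(self.generator, Mapping):
            self.generator = GeneratorConfig.from_dict(self.generator)
        if self.n_boot < 1:
            raise ConfigurationError(f"n_boot must be >= 1, got {self.n_boot}")
        if self.m_imputations < 1:
            raise ConfigurationError(
                f"m_imputations must be >= 1, got {self.m_imputations}"
            )
        unknown = set(self.conditions) - set(CONDITIONS)
        if unknown:
            raise ConfigurationError(f"unknown conditions: {sorted(unknown)}")
        if self.gender_cutoff != "median" and not isinstance(self.gender_cutoff, int):
            raise ConfigurationError(
                "gender_cutoff must be 'median' or an integer, "
                f"got {self.gender_cutoff!r}"
            )

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["conditions"] = list(self.conditions)
        return d

    @classmethod
    def from_dict(cls, data: Mapping[str, Any]) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigurationError(f"unknown pipeline config keys: {sorted(unknown)}")
        return cls(**dict(data))


def load_config(path: str, kind: str = "pipeline") -> PipelineConfig | GeneratorConfig:
    """Load a YAML or JSON config file.

    ``kind`` is ``"pipeline"`` or ``"generator"``.
    """
    with open(path, "r", encoding="utf-8") as fh:
        text = fh.read()
    data = yaml.safe_load(text)
    if not isinstance(data, Mapping):
        raise ConfigurationError(f"config file {path} does not contain a mapping")
    if kind == "pipeline":
        return PipelineConfig.from_dict(data)
    if kind == "generator":
        return GeneratorConfig.from_dict(data)
    raise ConfigurationError(f"unknown config kind {kind!r}")


def save_config(config: PipelineConfig | GeneratorConfig, path: str) -> None:
    """Write a config as JSON (stable key order, valid YAML subset)."""
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(config.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")
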