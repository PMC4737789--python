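"""Pre-test probability and combined risk modelling.

The updated Diamond-Forrester model gives the pre-test probability of
obstructive CAD as a logistic function of age, sex and chest-pain type;
its coefficient table is configuration, not code.  Probabilities map onto
four predefined risk categories (< 10 %, 10-30 %, 30-60 %, >= 60 %).  The
combined model is a logistic regression of disease on the logit of the
pre-test probability and the raw CAD-score.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression

from .config import DEFAULT_CONFIG, AlgorithmConfig
from .errors import ParameterError, SchemaError

log = logging.getLogger(__name__)

RISK_CATEGORIES = ("very_low", "low", "moderate", "high")
CHEST_PAIN_LEVELS = ("non_anginal", "atypical", "typical")
SEX_LEVELS = ("female", "male")


@dataclass
class PatientRecord:
    age: float
    sex: str
    chest_pain: str
    cacs: Optional[float] = None
    cad_score: Optional[float] = None
    disease: Optional[str] = None  # non_cad | non_obstructive | obstructive

    def __post_init__(self) -> None:
        if not (18.0 <= self.age <= 110.0):
            raise ParameterError(f"age {self.age} outside [18, 110]")
        if self.sex not in SEX_LEVELS:
            raise ParameterError(f"unknown sex {self.sex!r}")
        if self.chest_pain not in CHEST_PAIN_LEVELS:
            raise ParameterError(f"unknown chest_pain {self.chest_pain!r}")
        if self.cacs is not None and self.cacs < 0:
            raise ParameterError("cacs must be >= 0")


@dataclass
class RiskAssessment:
    df_probability: float          # percent
    df_category: str
    combined_probability: Optional[float] = None
    combined_category: Optional[str] = None


def diamond_forrester(
    age: float,
    sex: str,
    chest_pain: str,
    coeffs: Optional[dict[str, float]] = None,
    config: AlgorithmConfig = DEFAULT_CONFIG,
) -> float:
    """Pre-test probability of obstructive CAD, in percent.

    ``p = 100 * sigmoid(b0 + b_age*age + b_male*[male] + b_pain)`` with the
    coefficient table from config (or an explicit ``coeffs`` mapping with
    keys intercept, age, male, non_anginal, atypical, typical).
    """
    if sex not in SEX_LEVELS:
        raise ParameterError(f"unknown sex {sex!r}")
    if chest_pain not in CHEST_PAIN_LEVELS:
        raise ParameterError(f"unknown chest_pain level {chest_pain!r}")
    c = coeffs if coeffs is not None else config.df_coefficients
    eta = (
        c["intercept"]
        + c["age"] * age
        + (c["male"] if sex == "male" else 0.0)
        + c[chest_pain]
    )
    return float(100.0 / (1.0 + np.exp(-eta)))


def df_probability_to_age(
    p_percent: float,
    sex: str,
    chest_pain: str,
    coeffs: Optional[dict[str, float]] = None,
    config: AlgorithmConfig = DEFAULT_CONFIG,
) -> float:
    """Invert the pre-test model for age given a target probability,
    clipped to the valid age range (used by the cohort simulator)."""
    c = coeffs if coeffs is not None else config.df_coefficients
    p = np.clip(p_percent / 100.0, 1e-6, 1 - 1e-6)
    eta = np.log(p / (1 - p))
    age = (eta - c["intercept"] - (c["male"] if sex == "male" else 0.0) - c[chest_pain]) / c["age"]
    return float(np.clip(age, 18.0, 110.0))


def risk_category(p_percent: float, config: AlgorithmConfig = DEFAULT_CONFIG) -> str:
    """Map a probability (%) onto the four risk categories.

    Boundaries are right-continuous: 10 -> low, 30 -> moderate, 60 -> high.
    """
    if not (0.0 <= p_percent <= 100.0):
        raise ParameterError(f"probability {p_percent} outside [0, 100]")
    t1, t2, t3 = config.risk_thresholds
    if p_percent < t1:
        return "very_low"
    if p_percent < t2:
        return "low"
    if p_percent < t3:
        return "moderate"
    return "high"


def risk_category_index(p_percent: float, config: AlgorithmConfig = DEFAULT_CONFIG) -> int:
    return RISK_CATEGORIES.index(risk_category(p_percent, config))


def cacs_group(cacs: float, config: AlgorithmConfig = DEFAULT_CONFIG) -> str:
    """Coronary calcium groups: zero (= 0), low (0, 400), high (>= 400)."""
    if cacs < 0:
        raise ParameterError("cacs must be >= 0")
    if cacs == 0:
        return "zero"
    if cacs < config.cacs_high_threshold:
        return "low"
    return "high"


def _logit(p: np.ndarray) -> np.ndarray:
    p = np.clip(p, 1e-9, 1 - 1e-9)
    return np.log(p / (1 - p))


@dataclass
class CombinedModel:
    """Logistic combination of logit pre-test probability and CAD-score."""

    coef_df: float
    coef_score: float
    intercept: float
    penalized: bool = False

    def predict_percent(self, df_percent: Sequence[float],
                        cad_score: Sequence[float]) -> np.ndarray:
        eta = (
            self.intercept
            + self.coef_df * _logit(np.asarray(df_percent, dtype=float) / 100.0)
            + self.coef_score * np.asarray(cad_score, dtype=float)
        )
        return 100.0 / (1.0 + np.exp(-eta))

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "CombinedModel":
        return cls(**json.loads(text))


def combine_df_cad(
    df_percent: Sequence[float],
    cad_score: Sequence[float],
    labels: Sequence[int],
    include_score: bool = True,
) -> tuple[CombinedModel, np.ndarray]:
    """Fit the combined model and return it with per-patient combined
    probabilities in percent.

    ``include_score=False`` constrains the CAD-score coefficient to zero
    (the pre-test-only nested model).  On (quasi-)separation the fit falls
    back to a weakly penalised logistic regression with a warning.
    """
    df_percent = np.asarray(df_percent, dtype=float)
    cad = np.asarray(cad_score, dtype=float)
    y = np.asarray(labels, dtype=int)
    if df_percent.shape != cad.shape or df_percent.shape != y.shape:
        raise ParameterError("inputs must have equal length")
    if y.min() == y.max():
        raise ParameterError("both classes must be present")

    cols = [_logit(df_percent / 100.0)]
    if include_score:
        cols.append(cad)
    X = np.column_stack(cols)

    penalized = False
    clf = LogisticRegression(C=np.inf, solver="lbfgs", max_iter=5000)
    clf.fit(X, y)
    p_hat = clf.predict_proba(X)[:, 1]
    separated = (np.max(np.abs(clf.coef_)) > 50.0) or (
        p_hat[y == 0].max() < 1e-3 and p_hat[y == 1].min() > 1 - 1e-3
    )
    if separated:  # MLE diverges (or saturates); stabilise the fit
        log.warning("separation detected; refitting with a weak L2 penalty")
        penalized = True
        clf = LogisticRegression(C=1e3, solver="lbfgs", max_iter=5000)
        clf.fit(X, y)

    coef = clf.coef_.ravel()
    model = CombinedModel(
        coef_df=float(coef[0]),
        coef_score=float(coef[1]) if include_score else 0.0,
        intercept=float(clf.intercept_[0]),
        penalized=penalized,
    )
    return model, model.predict_percent(df_percent, cad)


# --------------------------------------------------------------------------
# Cohort table I/O
# --------------------------------------------------------------------------

COHORT_COLUMNS = ("subject_id", "age", "sex", "chest_pain", "cacs",
                  "cad_score", "disease")


def read_cohort(path: str) -> pd.DataFrame:
    """Read a cohort CSV (one row per patient); '#' lines are metadata."""
    df = pd.read_csv(path, comment="#")
    missing = [c for c in ("age", "sex", "chest_pain", "disease") if c not in df.columns]
    if missing:
        raise SchemaError(f"cohort table missing columns: {missing}")
    return df


def write_cohort(path: str, df: pd.DataFrame, seed: Optional[int] = None) -> None:
    with open(path, "w") as fh:
        if seed is not None:
            fh.write(f"# seed: {seed}\n")
        df.to_csv(fh, index=False)


def attach_df_probability(
    df: pd.DataFrame, config: AlgorithmConfig = DEFAULT_CONFIG
) -> pd.DataFrame:
    """Add/overwrite the df_probability column from age/sex/chest pain."""
    out = df.copy()
    out["df_probability"] = [
        diamond_forrester(a, s, cp, config=config)
        for a, s, cp in zip(df["age"], df["sex"], df["chest_pain"])
    ]
    return out
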