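"""Raw survey responses -> analysis population, binary behavior matrix,
and ordinal outcome scores.

Dichotomization rules
---------------------
* inadequate sleep: usual sleep strictly less than 6 hours
* insufficient fruit / vegetable intake: frequency response C or D
* salty diet: flavor preference exactly 'salty'
* smoking / drinking: current use answered 'yes'
* irregular exercise: regular exercise answered 'no'
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._utils import BEHAVIOR_NAMES
from .exceptions import CodingError, InputValidationError

__all__ = [
    "BEHAVIOR_FIELDS",
    "apply_exclusions",
    "code_behaviors",
    "behavior_count",
    "score_outcomes",
    "read_survey_csv",
    "ExclusionLog",
]

#: raw fields that must be present and non-missing for a record to be codable
BEHAVIOR_FIELDS = (
    "fruit_freq",
    "veg_freq",
    "flavor",
    "smoking_now",
    "drinking_now",
    "regular_exercise",
    "sleep_hours",
)

DEMOGRAPHIC_REQUIRED = ("gender", "age", "residence")

FREQ_VOCAB = {"A", "B", "C", "D"}
YESNO_VOCAB = {"yes", "no"}
RATING_VOCAB = {"A", "B", "C", "D", "E"}
GENDER_VOCAB = {"male", "female"}
RESIDENCE_VOCAB = {"city", "town", "rural"}
CO_RESIDENCE_VOCAB = {"household", "alone", "institution"}
ECONOMIC_VOCAB = {"very_rich", "rich", "so_so", "poor", "very_poor"}

RATING_SCORES = {"A": 5, "B": 4, "C": 3, "D": 2, "E": 1}

MIN_AGE = 65


@dataclass
class ExclusionLog:
    """Counts removed per criterion, in application order."""

    n_input: int
    n_under_age: int
    n_missing_demographics: int
    n_missing_behaviors: int
    n_retained: int

    def as_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "excluded_under_age": self.n_under_age,
            "excluded_missing_demographics": self.n_missing_demographics,
            "excluded_missing_behaviors": self.n_missing_behaviors,
            "n_retained": self.n_retained,
        }


def _missing(series: pd.Series) -> pd.Series:
    if series.dtype == object:
        return series.isna() | (series.astype(str).str.strip() == "")
    return series.isna()


def apply_exclusions(table: pd.DataFrame) -> tuple[pd.DataFrame, ExclusionLog]:
    """Drop records under 65, missing core demographics, or missing any
    behavior field. Criteria apply in that order; each record is counted
    against the first criterion it fails.
    """
    n_input = len(table)
    df = table.copy()

    age_ok = pd.to_numeric(df.get("age"), errors="coerce") >= MIN_AGE
    n_under_age = int((~age_ok.fillna(False)).sum())
    df = df[age_ok.fillna(False)]

    demo_ok = pd.Series(True, index=df.index)
    for col in DEMOGRAPHIC_REQUIRED:
        if col not in df.columns:
            raise InputValidationError(f"required column {col!r} absent")
        demo_ok &= ~_missing(df[col])
    n_missing_demo = int((~demo_ok).sum())
    df = df[demo_ok]

    behav_ok = pd.Series(True, index=df.index)
    for col in BEHAVIOR_FIELDS:
        if col not in df.columns:
            raise InputValidationError(f"required column {col!r} absent")
        behav_ok &= ~_missing(df[col])
    n_missing_behav = int((~behav_ok).sum())
    df = df[behav_ok]

    log = ExclusionLog(
        n_input=n_input,
        n_under_age=n_under_age,
        n_missing_demographics=n_missing_demo,
        n_missing_behaviors=n_missing_behav,
        n_retained=len(df),
    )
    if len(df) == 0:
        import warnings

        warnings.warn("all records excluded; analysis population is empty", stacklevel=2)
    return df, log


def _check_vocab(series: pd.Series, vocab: set, field_name: str) -> None:
    values = series.astype(str)
    bad = ~values.isin(vocab)
    if bad.any():
        idx = series.index[bad][0]
        raise CodingError(
            f"record {idx}: field {field_name!r} has out-of-vocabulary value "
            f"{series.loc[idx]!r} (allowed: {sorted(vocab)})"
        )


def code_behaviors(table: pd.DataFrame) -> pd.DataFrame:
    """Code the 7 binary risk behaviors in canonical column order.

    Returns an N x 7 DataFrame of {0,1} with columns BEHAVIOR_NAMES, indexed
    like the input so rows link back to the source records. Requires a table
    that already passed :func:`apply_exclusions` (no missing behavior field).
    """
    for col in BEHAVIOR_FIELDS:
        if col not in table.columns:
            raise InputValidationError(f"required column {col!r} absent")
        if _missing(table[col]).any():
            idx = table.index[_missing(table[col])][0]
            raise CodingError(f"record {idx}: behavior field {col!r} is missing")

    _check_vocab(table["fruit_freq"], FREQ_VOCAB, "fruit_freq")
    _check_vocab(table["veg_freq"], FREQ_VOCAB, "veg_freq")
    _check_vocab(table["smoking_now"], YESNO_VOCAB, "smoking_now")
    _check_vocab(table["drinking_now"], YESNO_VOCAB, "drinking_now")
    _check_vocab(table["regular_exercise"], YESNO_VOCAB, "regular_exercise")

    sleep = pd.to_numeric(table["sleep_hours"], errors="coerce")
    if sleep.isna().any() or (sleep < 0).any():
        idx = table.index[sleep.isna() | (sleep < 0)][0]
        raise CodingError(
            f"record {idx}: sleep_hours value {table.loc[idx, 'sleep_hours']!r} "
            "is not a non-negative number"
        )

    coded = pd.DataFrame(index=table.index)
    coded["insufficient_fruit"] = table["fruit_freq"].isin({"C", "D"}).astype(np.int8)
    coded["insufficient_vegetable"] = table["veg_freq"].isin({"C", "D"}).astype(np.int8)
    coded["salty_diet"] = (table["flavor"].astype(str) == "salty").astype(np.int8)
    coded["smoking"] = (table["smoking_now"].astype(str) == "yes").astype(np.int8)
    coded["drinking"] = (table["drinking_now"].astype(str) == "yes").astype(np.int8)
    coded["irregular_exercise"] = (table["regular_exercise"].astype(str) == "no").astype(np.int8)
    # strict "< 6 hours": exactly 6 hours is adequate
    coded["inadequate_sleep"] = (sleep < 6).astype(np.int8)
    return coded[list(BEHAVIOR_NAMES)]


def behavior_count(matrix) -> dict:
    """Row-wise behavior counts plus the count distribution and P(count>=2)."""
    values = np.asarray(matrix, dtype=int)
    if values.ndim != 2 or not np.isin(values, (0, 1)).all():
        raise InputValidationError("behavior matrix must be 2-D over {0,1}")
    counts = values.sum(axis=1)
    dist = {int(k): int(v) for k, v in zip(*np.unique(counts, return_counts=True))}
    return {
        "counts": counts,
        "distribution": dist,
        "proportion_ge2": float((counts >= 2).mean()),
    }


def score_outcomes(table: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Score A..E ratings to 5..1 for both ordinal outcomes.

    Records missing either rating are dropped from the returned frame (they
    stay in all behavior analyses); the dropped count is returned alongside.
    """
    for col in ("qol_rating", "health_rating"):
        if col not in table.columns:
            raise InputValidationError(f"required column {col!r} absent")
    present = ~(_missing(table["qol_rating"]) | _missing(table["health_rating"]))
    df = table[present]
    n_dropped = int((~present).sum())
    _check_vocab(df["qol_rating"], RATING_VOCAB, "qol_rating")
    _check_vocab(df["health_rating"], RATING_VOCAB, "health_rating")
    scores = pd.DataFrame(
        {
            "qol_score": df["qol_rating"].map(RATING_SCORES).astype(int),
            "health_score": df["health_rating"].map(RATING_SCORES).astype(int),
        },
        index=df.index,
    )
    return scores, n_dropped


def read_survey_csv(path, column_mapping: dict | None = None) -> pd.DataFrame:
    """Read a survey table from UTF-8 CSV, optionally renaming foreign headers.

    ``column_mapping`` maps foreign header -> canonical header.
    """
    df = pd.read_csv(path, encoding="utf-8")
    if column_mapping:
        df = df.rename(columns=dict(column_mapping))
    return df
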