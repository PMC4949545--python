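"""Long-format longitudinal data containers and response transforms.

The universal input is a tidy table with one row per subject-visit-
outcome: ``subject_id, sex, age, outcome, value`` (ages in decimal
years).  Tanner-stage data use ``subject_id, sex, age, measure, stage``.
Both are validated pandas DataFrames wrapped in light classes; units
(cm, ug/L, nmol/L) are metadata and are not checked.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "LongSeries",
    "StageSeries",
    "ValidationError",
    "TRANSFORMS",
    "apply_transform",
    "inverse_transform",
]

logger = logging.getLogger("pysitar")


class ValidationError(ValueError):
    """Input table violates the long-format contract."""


LONG_COLUMNS = ["subject_id", "sex", "age", "outcome", "value"]
STAGE_COLUMNS = ["subject_id", "sex", "age", "measure", "stage"]

TRANSFORMS = ("identity", "sqrt", "log")


def apply_transform(values: np.ndarray, transform: str) -> np.ndarray:
    if transform == "identity":
        return np.asarray(values, dtype=float)
    if transform == "sqrt":
        return np.sqrt(values)
    if transform == "log":
        return np.log(values)
    raise ValueError(f"unknown transform {transform!r}")


def inverse_transform(values: np.ndarray, transform: str) -> np.ndarray:
    if transform == "identity":
        return np.asarray(values, dtype=float)
    if transform == "sqrt":
        return np.square(values)
    if transform == "log":
        return np.exp(values)
    raise ValueError(f"unknown transform {transform!r}")


def _check_common(df: pd.DataFrame, columns: list[str], age_window) -> pd.DataFrame:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValidationError(f"missing columns: {missing}")
    out = df.loc[:, columns].copy()
    out["age"] = pd.to_numeric(out["age"], errors="coerce")
    bad = out.index[out["age"].isna()]
    if len(bad):
        raise ValidationError(f"non-numeric age at rows {list(bad[:5])}")
    lo, hi = age_window
    outside = out.index[(out["age"] < lo) | (out["age"] > hi)]
    if len(outside):
        raise ValidationError(
            f"{len(outside)} ages outside [{lo}, {hi}] "
            f"(first offending rows {list(outside[:5])})"
        )
    return out


@dataclass(frozen=True)
class LongSeries:
    """Validated long-format measurement table.

    Invariants enforced at construction: ages inside the declared
    window, finite values, no duplicated (subject, outcome, age)
    triples.  Rows are sorted by (subject, outcome, age).
    """

    df: pd.DataFrame
    age_window: tuple[float, float] = (8.0, 16.5)

    def __post_init__(self) -> None:
        df = _check_common(pd.DataFrame(self.df), LONG_COLUMNS, self.age_window)
        df["value"] = pd.to_numeric(df["value"], errors="coerce")
        nonfinite = df.index[~np.isfinite(df["value"])]
        if len(nonfinite):
            raise ValidationError(
                f"non-finite values at rows {list(nonfinite[:5])}"
            )
        dup = df.duplicated(["subject_id", "outcome", "age"], keep=False)
        if dup.any():
            pairs = df.index[dup].tolist()
            raise ValidationError(
                f"duplicated (subject, outcome, age) rows: {pairs[:6]}"
            )
        df = df.sort_values(["subject_id", "outcome", "age"], kind="mergesort")
        object.__setattr__(self, "df", df.reset_index(drop=True))

    @property
    def outcomes(self) -> list[str]:
        return sorted(self.df["outcome"].unique())

    @property
    def subjects(self) -> list:
        return sorted(self.df["subject_id"].unique())

    def select(self, outcome: str | None = None, sex: str | None = None) -> "LongSeries":
        df = self.df
        if outcome is not None:
            df = df[df["outcome"] == outcome]
        if sex is not None:
            df = df[df["sex"] == sex]
        if df.empty:
            raise ValidationError(
                f"no rows for outcome={outcome!r}, sex={sex!r}"
            )
        return LongSeries(df, self.age_window)

    def require_positive(self, transform: str) -> None:
        """sqrt/log transforms need strictly positive data; checked at fit time."""
        if transform in ("sqrt", "log") and (self.df["value"] <= 0).any():
            n = int((self.df["value"] <= 0).sum())
            raise ValidationError(
                f"{transform} transform declared but {n} values are <= 0"
            )

    def __len__(self) -> int:
        return len(self.df)


@dataclass(frozen=True)
class StageSeries:
    """Validated Tanner-stage table (stages 1-5, integer).

    Within-subject stage regressions (a later visit rated lower) are
    *kept* — rater noise is real — but counted and logged.
    """

    df: pd.DataFrame
    age_window: tuple[float, float] = (8.0, 16.5)

    def __post_init__(self) -> None:
        df = _check_common(pd.DataFrame(self.df), STAGE_COLUMNS, self.age_window)
        stages = pd.to_numeric(df["stage"], errors="coerce")
        bad = df.index[stages.isna() | ~stages.isin([1, 2, 3, 4, 5])]
        if len(bad):
            raise ValidationError(
                f"stages must be integers 1-5; bad rows {list(bad[:5])}"
            )
        df["stage"] = stages.astype(int)
        dup = df.duplicated(["subject_id", "measure", "age"], keep=False)
        if dup.any():
            raise ValidationError(
                f"duplicated (subject, measure, age) rows: "
                f"{df.index[dup].tolist()[:6]}"
            )
        df = df.sort_values(["subject_id", "measure", "age"], kind="mergesort")
        df = df.reset_index(drop=True)
        n_regress = int(
            (df.groupby(["subject_id", "measure"])["stage"].diff() < 0).sum()
        )
        if n_regress:
            logger.info("stage regressions observed and kept: %d", n_regress)
        object.__setattr__(self, "df", df)
        object.__setattr__(self, "n_regressions", n_regress)

    @property
    def measures(self) -> list[str]:
        return sorted(self.df["measure"].unique())

    @property
    def subjects(self) -> list:
        return sorted(self.df["subject_id"].unique())

    def select(self, measure: str | None = None, sex: str | None = None) -> "StageSeries":
        df = self.df
        if measure is not None:
            df = df[df["measure"] == measure]
        if sex is not None:
            df = df[df["sex"] == sex]
        if df.empty:
            raise ValidationError(f"no rows for measure={measure!r}, sex={sex!r}")
        return StageSeries(df, self.age_window)

    def __len__(self) -> int:
        return len(self.df)
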