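"""Cross-outcome synthesis of pubertal timing.

If each individual has one underlying pubertal tempo, their tempo
random effects estimated from height, IGF-1, the sex steroids and the
Tanner stages should rank them the same way — i.e. be strongly
correlated across outcomes.  This module assembles the per-subject
tempo effects from several fits into one table (rows subjects, columns
outcomes, missing cells where a subject was not in that outcome's
sample, e.g. the hormone subsample) and reports pairwise Pearson
correlations with t-based two-sided p-values, pairwise-complete.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .metrics import value_at_age
from .model import SitarResults
from .stages import StageResults

__all__ = [
    "TempoTable",
    "CorrelationReport",
    "collect_tempo_table",
    "tempo_correlations",
    "within_fit_re_correlations",
    "tempo_vs_value_at_age",
    "UndefinedCorrelationError",
]


class UndefinedCorrelationError(ValueError):
    """A column has zero variance (or too few pairs) for a correlation."""


@dataclass
class TempoTable:
    """Per-subject tempo random effects aligned across outcomes (years)."""

    table: pd.DataFrame

    @property
    def outcomes(self) -> list[str]:
        return list(self.table.columns)

    def pairwise_n(self) -> pd.DataFrame:
        notna = self.table.notna().astype(int)
        return notna.T @ notna


@dataclass
class CorrelationReport:
    """Pairwise Pearson correlations with pairwise-complete n and
    two-sided p-values from the t transform with n - 2 df."""

    pairs: pd.DataFrame  # columns: var1, var2, r, n, p

    def matrix(self) -> pd.DataFrame:
        names = sorted(set(self.pairs["var1"]) | set(self.pairs["var2"]))
        m = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
        for _, row in self.pairs.iterrows():
            m.loc[row["var1"], row["var2"]] = row["r"]
            m.loc[row["var2"], row["var1"]] = row["r"]
        return m

    def __str__(self) -> str:
        lines = ["pair                              r        n      p"]
        for _, row in self.pairs.iterrows():
            lines.append(
                f"{row['var1']} vs {row['var2']:<18} "
                f"{row['r']:+.3f}  {int(row['n']):5d}  {row['p']:.2g}"
            )
        return "\n".join(lines)


def _tempo_series(fit) -> pd.Series:
    if isinstance(fit, (SitarResults, StageResults)):
        if "tempo" not in fit.ranef.columns:
            raise ValueError("fit has no tempo random effect")
        if isinstance(fit, SitarResults) and "tempo" not in fit.spec.random_effects:
            raise ValueError("fit has no tempo random effect")
        return fit.ranef["tempo"]
    raise TypeError(f"not a fitted SITAR object: {type(fit)!r}")


def collect_tempo_table(fits: dict[str, object]) -> TempoTable:
    """Align tempo random effects across outcome fits by subject id.

    A cell is present iff that subject was in that outcome's fitted
    subject set; with a hormone subsample, rows for height-only
    subjects have missing hormone cells.
    """
    if len(fits) < 2:
        raise ValueError("need at least 2 fits")
    cols = {name: _tempo_series(fit) for name, fit in fits.items()}
    table = pd.DataFrame(cols)
    shared = table.dropna()
    if len(shared) < 3:
        raise ValueError(
            f"fits share only {len(shared)} subject(s); need at least 3"
        )
    table.index.name = "subject_id"
    return TempoTable(table)


def _pearson(x: np.ndarray, y: np.ndarray) -> tuple[float, float, int]:
    mask = np.isfinite(x) & np.isfinite(y)
    n = int(mask.sum())
    if n < 3:
        raise UndefinedCorrelationError(f"only {n} complete pairs")
    xs, ys = x[mask], y[mask]
    if np.std(xs) == 0 or np.std(ys) == 0:
        raise UndefinedCorrelationError("zero variance in a column")
    r, p = stats.pearsonr(xs, ys)
    return float(r), float(p), n


def tempo_correlations(table: TempoTable) -> CorrelationReport:
    """Pairwise-complete Pearson correlations of the tempo table."""
    rows = []
    cols = table.outcomes
    vals = table.table.to_numpy(float)
    for i in range(len(cols)):
        for j in range(i + 1, len(cols)):
            r, p, n = _pearson(vals[:, i], vals[:, j])
            rows.append({"var1": cols[i], "var2": cols[j], "r": r, "n": n, "p": p})
    return CorrelationReport(pairs=pd.DataFrame(rows))


def within_fit_re_correlations(fit) -> CorrelationReport:
    """Correlations among a single fit's random-effect components
    (size-tempo, size-velocity, tempo-velocity), from the
    empirical-Bayes modes."""
    effects = [c for c in fit.ranef.columns
               if fit.ranef[c].std() > 0 or _declared(fit, c)]
    effects = [c for c in effects if _declared(fit, c)]
    rows = []
    for i in range(len(effects)):
        for j in range(i + 1, len(effects)):
            r, p, n = _pearson(
                fit.ranef[effects[i]].to_numpy(float),
                fit.ranef[effects[j]].to_numpy(float),
            )
            rows.append({"var1": effects[i], "var2": effects[j],
                         "r": r, "n": n, "p": p})
    return CorrelationReport(pairs=pd.DataFrame(
        rows, columns=["var1", "var2", "r", "n", "p"]))


def _declared(fit, effect: str) -> bool:
    if isinstance(fit, SitarResults):
        return effect in fit.spec.random_effects
    return True


def tempo_vs_value_at_age(fit: SitarResults, age: float) -> tuple[float, float]:
    """Correlate tempo with each subject's predicted outcome level at
    one age (e.g. IGF-1 at age 10: on a rising curve, early-timed
    subjects are further along, so tempo and level correlate
    negatively).  Returns (r, p)."""
    if "tempo" not in fit.spec.random_effects:
        raise ValueError("fit has no tempo random effect")
    tempo = fit.ranef["tempo"].to_numpy(float)
    values = np.array([value_at_age(fit, sid, age) for sid in fit.ranef.index])
    r, p, _ = _pearson(tempo, values)
    return r, p
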