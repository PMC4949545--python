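"""Modified SITAR for ordinal Tanner stages.

Tanner stages (1-5) are treated as numeric values on a logistic mean
curve

    S(t) = 1 + 4 / (1 + exp(-k (t - m)))

so the population curve runs from stage 1 to stage 5 with its midpoint
(stage 3, the point of steepest slope — the stages' "peak velocity")
at age m.  Each subject gets tempo and velocity random effects only:

    S_i(t) = 1 + 4 / (1 + exp(-k exp(gamma_i) (t - m - beta_i)))

A size effect is not needed because all individuals traverse the same
five stages; the asymptotes are fixed at 1 and 5 for identifiability.
Subject i's timing (mean age in stage 3) is m + beta_i.  Estimation
uses the same Laplace machinery as the spline SITAR model.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import optimize

from .data import StageSeries, ValidationError
from .engine import GroupedData, LaplaceResult, maximize_laplace
from .model import variance_explained

__all__ = [
    "stage_mean_curve",
    "StageModel",
    "StageResults",
    "fit_stage_model",
    "stage_variance_explained",
    "UnidentifiableStageModelError",
]

logger = logging.getLogger("pysitar")

STAGE_EFFECTS = ("tempo", "velocity")


class UnidentifiableStageModelError(ValueError):
    """All observations in one stage: the logistic curve is unidentifiable."""


def stage_mean_curve(m: float, k: float, ages) -> np.ndarray:
    """Logistic stage curve 1 + 4/(1 + exp(-k (t - m))).

    S(m) = 3 exactly; the slope is maximal at m and equals k there
    (4k * 1/4).
    """
    if k <= 0:
        raise ValueError("rate k must be positive")
    ages = np.asarray(ages, dtype=float)
    return 1.0 + 4.0 / (1.0 + np.exp(-k * (ages - m)))


class _LogisticStageFamily:
    """Engine curve family: fixed = (m, log k); b = (beta, gamma)."""

    n_fixed = 2
    q = 2

    def mean_and_jac(self, fixed, b_obs, t):
        m, k = fixed[0], np.exp(fixed[1])
        beta, gam = b_obs[:, 0], b_obs[:, 1]
        eta = k * np.exp(gam) * (t - m - beta)
        p = 1.0 / (1.0 + np.exp(-eta))
        f = 1.0 + 4.0 * p
        dfdeta = 4.0 * p * (1.0 - p)
        J = np.empty((t.size, 2))
        J[:, 0] = dfdeta * (-k * np.exp(gam))
        J[:, 1] = dfdeta * eta
        return f, J

    def fixed_jac(self, fixed, b_obs, t):
        """d f / d (m, log k)."""
        m, k = fixed[0], np.exp(fixed[1])
        beta, gam = b_obs[:, 0], b_obs[:, 1]
        eta = k * np.exp(gam) * (t - m - beta)
        p = 1.0 / (1.0 + np.exp(-eta))
        dfdeta = 4.0 * p * (1.0 - p)
        F = np.empty((t.size, 2))
        F[:, 0] = dfdeta * (-k * np.exp(gam))
        F[:, 1] = dfdeta * eta
        return F


class StageModel:
    """Modified SITAR bound to one Tanner measure's stage data."""

    def __init__(self, data: StageSeries, min_obs_per_subject: int = 4):
        if len(data.measures) != 1:
            raise ValidationError(
                f"StageModel needs a single measure, got {data.measures}; "
                "use data.select(measure=...)"
            )
        self.measure = data.measures[0]
        counts = data.df.groupby("subject_id").size()
        keep = counts.index[counts >= min_obs_per_subject]
        n_excluded = len(counts) - len(keep)
        if n_excluded:
            logger.info("excluding %d subject(s) with < %d stage ratings",
                        n_excluded, min_obs_per_subject)
        df = data.df[data.df["subject_id"].isin(keep)]
        if df["subject_id"].nunique() < 8:
            raise ValidationError("need at least 8 subjects with enough ratings")
        if df["stage"].nunique() < 2:
            raise UnidentifiableStageModelError(
                f"all observations are stage {df['stage'].iloc[0]}; "
                "the logistic curve cannot be identified"
            )
        self.data = data
        self.n_excluded = n_excluded
        self.subject_ids = np.array(sorted(df["subject_id"].unique()))
        id_map = {s: i for i, s in enumerate(self.subject_ids)}
        self._grouped = GroupedData(
            t=df["age"].to_numpy(float),
            y=df["stage"].to_numpy(float),
            idx=np.array([id_map[s] for s in df["subject_id"]]),
            n_subjects=len(self.subject_ids),
        )

    def _crosssectional(self):
        """Single pooled logistic least-squares fit; (m, k, residual SD)."""
        t, y = self._grouped.t, self._grouped.y
        m0 = float(np.median(t))

        def resid(p):
            return stage_mean_curve(p[0], np.exp(p[1]), t) - y
        sol = optimize.least_squares(resid, x0=[m0, 0.0], method="lm")
        if not sol.success:
            raise RuntimeError("cross-sectional logistic fit did not converge")
        dof = t.size - 2
        sd = float(np.sqrt(np.sum(sol.fun**2) / dof))
        return float(sol.x[0]), float(np.exp(sol.x[1])), sd

    def fit(self, max_iter: int = 200) -> "StageResults":
        m0, k0, cross_sd = self._crosssectional()
        family = _LogisticStageFamily()
        t = self._grouped.t
        res = maximize_laplace(
            family,
            self._grouped,
            fixed0=np.array([m0, np.log(k0)]),
            Sigma0=np.diag([0.5**2, 0.1**2]),
            sigma0=max(cross_sd / 2.0, 0.05),
            max_iter=max_iter,
        )
        return StageResults(self, res, cross_sd)


class StageResults:
    """Fitted ordinal-stage SITAR: logistic midpoint/rate, tempo and
    velocity random effects, residual SD in stage units."""

    def __init__(self, model: StageModel, res: LaplaceResult, cross_sd: float):
        self.model = model
        self.measure = model.measure
        self.midpoint_age = float(res.fixed[0])
        self.rate = float(np.exp(res.fixed[1]))
        self.Sigma = pd.DataFrame(res.Sigma, index=STAGE_EFFECTS,
                                  columns=STAGE_EFFECTS)
        self.sigma = res.sigma
        self.loglik = res.loglik
        self.converged = res.converged
        self.cross_sd = cross_sd
        self.n_subjects = model._grouped.n_subjects
        self.n_obs = model._grouped.t.size
        ranef = pd.DataFrame(res.b_hat, index=model.subject_ids,
                             columns=STAGE_EFFECTS)
        ranef.index.name = "subject_id"
        self.ranef = ranef

    @property
    def resid_sd(self) -> float:
        return self.sigma

    def mean_stage(self, ages) -> np.ndarray:
        """Population mean stage curve (passes through 3 at midpoint_age)."""
        return stage_mean_curve(self.midpoint_age, self.rate, ages)

    def predict(self, ages, subject_id=None) -> np.ndarray:
        ages = np.asarray(ages, dtype=float)
        if subject_id is None:
            return self.mean_stage(ages)
        if subject_id not in self.ranef.index:
            raise KeyError(f"unknown subject {subject_id!r}")
        beta, gam = self.ranef.loc[subject_id]
        k = self.rate * np.exp(gam)
        return 1.0 + 4.0 / (1.0 + np.exp(-k * (ages - self.midpoint_age - beta)))

    def timing(self) -> pd.Series:
        """Per-subject mean age in stage 3: midpoint_age + tempo_i."""
        return (self.midpoint_age + self.ranef["tempo"]).rename("stage3_age")

    def variance_explained(self) -> float:
        return stage_variance_explained(self)

    def summary(self) -> str:
        sds = np.sqrt(np.diag(self.Sigma.to_numpy()))
        corr = self.Sigma.iloc[0, 1] / (sds[0] * sds[1]) if sds.min() > 0 else np.nan
        return "\n".join([
            f"Stage SITAR fit: measure={self.measure!r}",
            f"subjects={self.n_subjects}  obs={self.n_obs}",
            f"midpoint age (stage 3) {self.midpoint_age:.2f} y, "
            f"rate {self.rate:.2f} /y",
            f"tempo SD {sds[0]:.3f} y, velocity SD {sds[1]:.3f}, "
            f"corr {corr:+.2f}",
            f"residual SD {self.sigma:.3f} stages; variance explained "
            f"{100 * self.variance_explained():.1f}%",
            f"log-likelihood {self.loglik:.2f}  converged={self.converged}",
        ])

    def __repr__(self) -> str:
        return (f"<StageResults {self.measure!r}: m={self.midpoint_age:.2f}, "
                f"k={self.rate:.2f}, converged={self.converged}>")


def fit_stage_model(data: StageSeries, **kwargs) -> StageResults:
    """Functional form of ``StageModel(data).fit()``."""
    return StageModel(data).fit(**kwargs)


def stage_variance_explained(fit: StageResults) -> float:
    """Variance explained by the tempo/velocity adjustment, relative to
    a single pooled logistic curve fit by least squares."""
    return variance_explained(fit.sigma, fit.cross_sd)
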