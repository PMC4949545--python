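"""The SITAR growth-curve model (super-imposition by translation and rotation).

SITAR assumes every individual's growth curve has the shape of the
population mean curve h(.), a natural cubic regression spline, after
three subject-specific adjustments estimated as Gaussian random effects:

    y_ij = alpha_i + h((t_ij - c - beta_i) * exp(gamma_i)) + e_ij

* ``alpha`` (size) shifts the curve up or down, in transformed outcome
  units;
* ``beta`` (tempo) shifts it left or right, in years — negative tempo
  means early puberty;
* ``gamma`` (velocity) stretches or shrinks the age scale about the
  centring age c; positive gamma compresses time, i.e. a faster, more
  intense pubertal spurt with a higher peak velocity.

(alpha, beta, gamma) ~ N(0, Sigma) with unstructured Sigma, e ~ N(0,
sigma^2); responses may be analysed on a sqrt or log scale (hormones)
and back-transformed for display.  Estimation is maximum likelihood via
the Laplace approximation (see :mod:`pysitar.engine`); the per-subject
effects reported are the empirical-Bayes posterior modes.

Usage follows the statsmodels convention::

    model = SitarModel.from_dataframe(df, outcome="height", sex="M",
                                      spec=SitarSpec(df=5))
    res = model.fit()
    print(res.summary())
    apv, phv = res.apv()
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .basis import DegenerateDesignError, SplineModel, build_spline_basis
from .data import LongSeries, TRANSFORMS, ValidationError, apply_transform
from .engine import (
    ConvergenceWarning,
    GroupedData,
    LaplaceResult,
    em_alternation,
    laplace_loglik,
    maximize_laplace,
)

__all__ = [
    "SitarSpec",
    "RandomEffects",
    "SitarModel",
    "SitarResults",
    "fit_sitar",
    "crosssectional_fit",
    "variance_explained",
    "marginal_loglik",
    "sitar_predict",
    "ExtrapolationError",
]

logger = logging.getLogger("pysitar")

EFFECT_NAMES = ("size", "tempo", "velocity")

DEFAULT_SEED = 20150108


class ExtrapolationError(ValueError):
    """Prediction requested outside the guard band around the knots."""


@dataclass(frozen=True)
class SitarSpec:
    """Configuration of a SITAR fit.

    Parameters
    ----------
    df : int
        Spline degrees of freedom (>= 2).  The study convention is 5
        for height and 3 for hormones.
    transform : {"identity", "sqrt", "log"}
        Response transform applied before fitting (sqrt for IGF-1, log
        for the sex steroids); the residual SD is reported on this
        scale.
    random_effects : tuple
        Non-empty subset of ("size", "tempo", "velocity").
    age_center : float or None
        Centring age c in years; None means the mean observed age.
    min_obs_per_subject : int
        Subjects with fewer observations are excluded (with a logged
        count) before fitting.
    """

    df: int = 5
    transform: str = "identity"
    random_effects: tuple[str, ...] = EFFECT_NAMES
    age_center: float | None = None
    min_obs_per_subject: int = 4

    def __post_init__(self) -> None:
        if self.df < 2:
            raise ValueError("df must be >= 2")
        if self.transform not in TRANSFORMS:
            raise ValueError(f"transform must be one of {TRANSFORMS}")
        if not self.random_effects:
            raise ValueError("random_effects must be non-empty")
        bad = set(self.random_effects) - set(EFFECT_NAMES)
        if bad:
            raise ValueError(f"unknown random effects: {sorted(bad)}")
        # normalize order
        object.__setattr__(
            self,
            "random_effects",
            tuple(e for e in EFFECT_NAMES if e in self.random_effects),
        )


@dataclass(frozen=True)
class RandomEffects:
    """A subject's (size, tempo, velocity) triple; absent effects are 0."""

    size: float = 0.0
    tempo: float = 0.0
    velocity: float = 0.0


class _SplineSitarFamily:
    """Curve family plugged into the Laplace engine: alpha + h((t-beta)e^gamma)."""

    def __init__(self, spline: SplineModel, effects: tuple[str, ...]):
        self.spline = spline
        self.effects = effects
        self.q = len(effects)
        self.n_fixed = spline.df + 1  # intercept + basis coefficients
        self._i_size = effects.index("size") if "size" in effects else None
        self._i_tempo = effects.index("tempo") if "tempo" in effects else None
        self._i_vel = effects.index("velocity") if "velocity" in effects else None

    def shifted_age(self, b_obs: np.ndarray, t: np.ndarray) -> np.ndarray:
        beta = b_obs[:, self._i_tempo] if self._i_tempo is not None else 0.0
        gam = b_obs[:, self._i_vel] if self._i_vel is not None else 0.0
        return (t - beta) * np.exp(gam)

    def fixed_jac(self, fixed, b_obs, t):
        """d f / d (intercept, coef): [1, basis columns] at the shifted ages."""
        u = self.shifted_age(b_obs, t)
        return np.column_stack([np.ones(t.size), self.spline.design(u)])

    def mean_only(self, fixed, b_obs, t):
        u = self.shifted_age(b_obs, t)
        S = fixed[0] + self.spline.design(u) @ fixed[1:]
        if self._i_size is not None:
            return b_obs[:, self._i_size] + S
        return S

    def mean_and_jac(self, fixed, b_obs, t):
        u = self.shifted_age(b_obs, t)
        intercept, coef = fixed[0], fixed[1:]
        D = self.spline.design(u)
        S = intercept + D @ coef
        alpha = b_obs[:, self._i_size] if self._i_size is not None else 0.0
        f = alpha + S
        J = np.empty((t.size, self.q))
        Sp = None
        if self._i_tempo is not None or self._i_vel is not None:
            Sp = self.spline.design_deriv(u) @ coef
        if self._i_size is not None:
            J[:, self._i_size] = 1.0
        if self._i_tempo is not None:
            gam = b_obs[:, self._i_vel] if self._i_vel is not None else 0.0
            J[:, self._i_tempo] = -np.exp(gam) * Sp
        if self._i_vel is not None:
            J[:, self._i_vel] = u * Sp
        return f, J


def _recentred_spline(basis: SplineModel, fixed: np.ndarray,
                      means: np.ndarray, effects: tuple[str, ...]):
    """Re-express the spline after removing the random-effect means.

    With mean size a, tempo b and velocity g, the recentred curve is
    h_new(w) = a + h((w - b) e^g) represented exactly on the mapped
    knots  knots/e^g + b  (a natural cubic spline composed with an
    affine age map is again a natural cubic spline); exact up to the
    O(b * gamma_i) cross term, which the follow-up optimizer pass
    absorbs.  Returns (new_basis, new_theta).
    """
    a = means[effects.index("size")] if "size" in effects else 0.0
    b = means[effects.index("tempo")] if "tempo" in effects else 0.0
    g = means[effects.index("velocity")] if "velocity" in effects else 0.0
    new_basis = SplineModel(knots=basis.knots * np.exp(-g) + b)
    knots = new_basis.knots
    w = np.linspace(knots[0], knots[-1], 40 * (basis.df + 2))
    target = a + fixed[0] + basis.design((w - b) * np.exp(g)) @ fixed[1:]
    D = np.column_stack([np.ones(w.size), new_basis.design(w)])
    theta, *_ = np.linalg.lstsq(D, target, rcond=None)
    return new_basis, theta


class SitarModel:
    """SITAR model bound to one outcome's longitudinal data.

    Build with a :class:`~pysitar.data.LongSeries` (or use
    :meth:`from_dataframe`), then call :meth:`fit`.
    """

    def __init__(self, data: LongSeries, spec: SitarSpec | None = None):
        self.spec = spec or SitarSpec()
        if len(data.outcomes) != 1:
            raise ValidationError(
                f"SitarModel needs a single outcome, got {data.outcomes}; "
                "use data.select(outcome=...)"
            )
        self.outcome = data.outcomes[0]
        data.require_positive(self.spec.transform)

        counts = data.df.groupby("subject_id").size()
        keep = counts.index[counts >= self.spec.min_obs_per_subject]
        n_excluded = len(counts) - len(keep)
        if n_excluded:
            logger.info(
                "excluding %d subject(s) with < %d observations",
                n_excluded,
                self.spec.min_obs_per_subject,
            )
        df = data.df[data.df["subject_id"].isin(keep)]
        if df["subject_id"].nunique() < 8:
            raise ValidationError(
                "need at least 8 subjects with enough observations"
            )
        self.data = data
        self.n_excluded = n_excluded
        self.subject_ids = np.array(sorted(df["subject_id"].unique()))
        id_map = {s: i for i, s in enumerate(self.subject_ids)}
        self.age_center = (
            float(df["age"].mean())
            if self.spec.age_center is None
            else float(self.spec.age_center)
        )
        self._grouped = GroupedData(
            t=df["age"].to_numpy(float) - self.age_center,
            y=apply_transform(df["value"].to_numpy(float), self.spec.transform),
            idx=np.array([id_map[s] for s in df["subject_id"]]),
            n_subjects=len(self.subject_ids),
        )
        self.basis = build_spline_basis(self._grouped.t, self.spec.df)

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        outcome: str | None = None,
        sex: str | None = None,
        spec: SitarSpec | None = None,
        age_window: tuple[float, float] = (8.0, 16.5),
    ) -> "SitarModel":
        data = LongSeries(df, age_window).select(outcome=outcome, sex=sex)
        return cls(data, spec)

    # -- fitting -----------------------------------------------------------

    def _crosssectional(self, basis: SplineModel):
        """Pooled OLS spline fit; returns (intercept+coef vector, residual SD)."""
        D = np.column_stack(
            [np.ones(self._grouped.t.size), basis.design(self._grouped.t)]
        )
        theta, *_ = np.linalg.lstsq(D, self._grouped.y, rcond=None)
        resid = self._grouped.y - D @ theta
        dof = self._grouped.t.size - self.spec.df - 1
        if dof <= 0:
            raise ValidationError("too few observations for the spline df")
        sd = float(np.sqrt(resid @ resid / dof))
        return theta, sd

    def _initial_cov(self, cross_sd: float) -> np.ndarray:
        start_sd = {"size": 0.5 * cross_sd, "tempo": 0.5, "velocity": 0.1}
        return np.diag(
            [start_sd[e] ** 2 for e in self.spec.random_effects]
        )

    def fit(
        self,
        max_iter: int = 60,
        refresh_knots: bool = True,
        drop_singular: bool = True,
        max_recenter: int = 4,
        start: "SitarResults | None" = None,
    ) -> "SitarResults":
        """Maximum-likelihood fit via the Laplace approximation.

        The likelihood is nearly flat along directions that shift the
        mean of the tempo/velocity effects into the spline, so after
        each optimizer pass any drift of the posterior-mode means is
        re-centred into the fixed curve and the optimizer re-run until
        the effects are centred (random effects have mean ~0 by
        construction).  Knots are placed on the observed centred ages
        for the first pass, refreshed once on the subject-adjusted age
        scale, then frozen.  A random effect whose fitted variance
        collapses to zero is dropped with a warning and the model
        refit.
        """
        spec = self.spec
        basis = self.basis
        theta0, cross_sd = self._crosssectional(basis)
        if start is not None:
            # warm restart from a previous fit (bootstrap replicates):
            # keep its knots and parameters, skip the EM warm-up
            effects = tuple(start.spec.random_effects)
            basis = SplineModel(knots=start.spline.knots.copy())
            theta_w = np.concatenate([[start.spline.intercept],
                                      start.spline.coef])
            res = self._run(basis, effects, theta_w, start.Sigma.to_numpy(),
                            start.sigma, min(max_iter, 15))
            basis, res = self._recenter_rounds(basis, effects, res, 10, 2)
            return SitarResults(self, replace(spec, random_effects=effects),
                                basis, res, cross_sd)
        effects = spec.random_effects
        Sigma0, sigma0 = self._initial_cov(cross_sd), cross_sd / 5.0
        family, fixed, Sigma, sigma, b = em_alternation(
            _SplineSitarFamily(basis, effects), self._grouped,
            theta0, Sigma0, sigma0, recenter=self._recenter_cb(effects),
        )
        basis = family.spline
        res = self._run(basis, effects, fixed, Sigma, sigma, max_iter, b0=b)
        basis, res = self._recenter_rounds(basis, effects, res, max_iter,
                                           max_recenter)

        if refresh_knots and len(effects) > 1:
            family = _SplineSitarFamily(basis, effects)
            u = family.shifted_age(res.b_hat[self._grouped.idx], self._grouped.t)
            t = self._grouped.t
            span = np.ptp(t)
            span_ok = (u.min() > t.min() - 0.5 * span
                       and u.max() < t.max() + 0.5 * span)
            basis2 = None
            if span_ok:
                try:
                    basis2 = build_spline_basis(u, spec.df)
                except DegenerateDesignError:
                    pass
            if basis2 is not None:
                theta2 = self._reinit_theta(basis2, family, res)
                family2, fixed2, Sigma2, sigma2, b2 = em_alternation(
                    _SplineSitarFamily(basis2, effects), self._grouped,
                    theta2, res.Sigma, res.sigma, b0=res.b_hat,
                    n_rounds=20, recenter=self._recenter_cb(effects),
                )
                res2 = self._run(family2.spline, effects, fixed2, Sigma2,
                                 sigma2, max_iter, b0=b2)
                if res2.loglik >= res.loglik - 1e-6:
                    basis, res = family2.spline, res2
                    basis, res = self._recenter_rounds(
                        basis, effects, res, max_iter, max_recenter)

        if drop_singular:
            while len(effects) > 1:
                sds = np.sqrt(np.diag(res.Sigma))
                floor = 1e-4 * max(sds.max(), 1e-12)
                if sds.min() >= floor:
                    break
                drop = effects[int(np.argmin(sds))]
                warnings.warn(
                    f"variance of random effect {drop!r} collapsed to zero; "
                    "refitting without it",
                    ConvergenceWarning,
                    stacklevel=2,
                )
                keep = [i for i, e in enumerate(effects) if e != drop]
                effects = tuple(effects[i] for i in keep)
                res = self._run(
                    basis, effects, res.fixed,
                    res.Sigma[np.ix_(keep, keep)], res.sigma,
                    max_iter, b0=res.b_hat[:, keep],
                )
                basis, res = self._recenter_rounds(
                    basis, effects, res, max_iter, max_recenter)

        return SitarResults(self, replace(spec, random_effects=effects),
                            basis, res, cross_sd)

    def _run(self, basis, effects, theta0, Sigma0, sigma0, max_iter,
             b0=None) -> LaplaceResult:
        family = _SplineSitarFamily(basis, effects)
        return maximize_laplace(
            family, self._grouped, theta0, Sigma0, sigma0,
            max_iter=max_iter, b0=b0,
        )

    def _recenter_cb(self, effects):
        """Recentring hook for the alternation: absorbs mode-mean drift
        into the spline whenever it exceeds 2% of the effect SD."""

        def cb(family, fixed, b):
            means = b.mean(axis=0)
            sds = np.maximum(b.std(axis=0), 1e-12)
            if np.all(np.abs(means) <= 0.02 * sds):
                return family, fixed, b
            new_basis, theta = _recentred_spline(family.spline, fixed, means,
                                                 effects)
            return (_SplineSitarFamily(new_basis, effects), theta,
                    b - means[None, :])

        return cb

    def _reinit_theta(self, basis, family, res: LaplaceResult) -> np.ndarray:
        """OLS spline start values on the subject-adjusted age scale."""
        u = family.shifted_age(res.b_hat[self._grouped.idx], self._grouped.t)
        alpha = 0.0
        if "size" in family.effects:
            alpha = res.b_hat[self._grouped.idx, family.effects.index("size")]
        D = np.column_stack([np.ones(u.size), basis.design(u)])
        theta, *_ = np.linalg.lstsq(D, self._grouped.y - alpha, rcond=None)
        return theta

    def _recenter_rounds(self, basis, effects, res, max_iter, max_recenter):
        """Absorb posterior-mode mean drift into the fixed curve.

        A common shift of all size effects moves into the intercept; a
        common tempo shift translates the spline; a common velocity
        factor rescales its age axis (a natural cubic spline composed
        with an affine age map is again a natural cubic spline on the
        mapped knots).  After each absorption the optimizer is re-run
        warm-started; rounds stop once every effect's mean is small
        relative to its SD.
        """
        for _ in range(max_recenter):
            means = res.b_hat.mean(axis=0)
            sds = np.maximum(res.b_hat.std(axis=0), 1e-12)
            if np.all(np.abs(means) <= 0.02 * sds):
                break
            basis, theta0 = _recentred_spline(basis, res.fixed, means,
                                              effects)
            res = self._run(
                basis, effects, theta0, res.Sigma, res.sigma, max_iter,
                b0=res.b_hat - means[None, :],
            )
        return basis, res


class SitarResults:
    """Fitted SITAR model: mean spline, random-effect covariance,
    residual SD and per-subject empirical-Bayes effects.

    Derived pubertal-timing quantities (APV, peak velocity, timing
    summaries, bootstrap SEs) are exposed as methods; see
    :mod:`pysitar.metrics`.
    """

    def __init__(self, model: SitarModel, spec: SitarSpec, basis: SplineModel,
                 res: LaplaceResult, cross_sd: float):
        self.model = model
        self.spec = spec
        self.outcome = model.outcome
        self.age_center = model.age_center
        self.spline = SplineModel(
            knots=basis.knots, coef=res.fixed[1:], intercept=float(res.fixed[0])
        )
        self.Sigma = pd.DataFrame(
            res.Sigma, index=spec.random_effects, columns=spec.random_effects
        )
        self.sigma = res.sigma
        self.loglik = res.loglik
        self.converged = res.converged
        self.n_outer_iter = res.n_outer_iter
        self.cross_sd = cross_sd
        self.n_subjects = model._grouped.n_subjects
        self.n_obs = model._grouped.t.size
        self.n_excluded = model.n_excluded
        self.age_range = (
            float(model._grouped.t.min() + model.age_center),
            float(model._grouped.t.max() + model.age_center),
        )
        ranef = pd.DataFrame(0.0, index=model.subject_ids, columns=EFFECT_NAMES)
        ranef.loc[:, list(spec.random_effects)] = res.b_hat
        ranef.index.name = "subject_id"
        self.ranef = ranef

    # -- core prediction ---------------------------------------------------

    @property
    def resid_sd(self) -> float:
        """Residual SD on the transformed scale."""
        return self.sigma

    def guard_band(self, margin: float = 1.0) -> tuple[float, float]:
        """Ages at which prediction is allowed: the span of the knots
        and the observed ages, extended by ``margin`` years."""
        lo, hi = self.spline.boundary_knots
        lo, hi = lo + self.age_center, hi + self.age_center
        d_lo, d_hi = getattr(self, "age_range", (lo, hi))
        return min(lo, d_lo) - margin, max(hi, d_hi) + margin

    def _check_ages(self, ages, allow_extrapolation):
        ages = np.atleast_1d(np.asarray(ages, dtype=float))
        lo, hi = self.guard_band()
        if not allow_extrapolation and (ages.min() < lo or ages.max() > hi):
            raise ExtrapolationError(
                f"ages outside guard band [{lo:.2f}, {hi:.2f}]; "
                "pass allow_extrapolation=True to override"
            )
        return ages

    def predict_transformed(
        self,
        ages,
        effects: RandomEffects | None = None,
        allow_extrapolation: bool = False,
    ) -> np.ndarray:
        """Predicted values on the transformed scale for one effect triple.

        With all effects zero this is the population mean curve.
        """
        e = effects or RandomEffects()
        ages = self._check_ages(ages, allow_extrapolation)
        u = (ages - self.age_center - e.tempo) * np.exp(e.velocity)
        return e.size + self.spline(u)

    def subject_effects(self, subject_id) -> RandomEffects:
        if subject_id not in self.ranef.index:
            raise KeyError(f"unknown subject {subject_id!r}")
        row = self.ranef.loc[subject_id]
        return RandomEffects(
            size=float(row["size"]),
            tempo=float(row["tempo"]),
            velocity=float(row["velocity"]),
        )

    def variance_explained(self) -> float:
        """Fraction of cross-sectional variance removed by the SITAR
        adjustment: 1 - (sigma / cross-sectional residual SD)^2."""
        return variance_explained(self.sigma, self.cross_sd)

    # -- derived metrics (delegating to pysitar.metrics) --------------------

    def mean_curve(self, grid=None, grid_step: float = 0.01):
        from .metrics import back_transform_curve

        return back_transform_curve(self, grid=grid, grid_step=grid_step)

    def velocity_curve(self, grid=None, grid_step: float = 0.01):
        from .metrics import back_transform_curve

        return back_transform_curve(
            self, grid=grid, grid_step=grid_step, scale="velocity"
        )

    def apv(self) -> tuple[float, float]:
        from .metrics import age_at_peak_velocity

        return age_at_peak_velocity(self)

    def age_at_peak_level(self) -> float:
        from .metrics import age_at_peak_level

        return age_at_peak_level(self)

    def timing_summary(self):
        from .metrics import age_at_peak_velocity, individual_timings

        apv, _ = age_at_peak_velocity(self)
        return individual_timings(self, apv)

    def value_at_age(self, subject_id, age: float) -> float:
        from .metrics import value_at_age

        return value_at_age(self, subject_id, age)

    def to_json(self, path=None):
        from .serialize import fit_to_json

        return fit_to_json(self, path)

    def plot(self, ax=None, adjusted: bool = False):
        from .plotting import plot_fit

        return plot_fit(self, ax=ax, adjusted=adjusted)

    # -- reporting ----------------------------------------------------------

    def summary(self) -> str:
        sds = np.sqrt(np.diag(self.Sigma.to_numpy()))
        lines = [
            f"SITAR fit: outcome={self.outcome!r}  "
            f"transform={self.spec.transform}  df={self.spec.df}",
            f"subjects={self.n_subjects} (excluded {self.n_excluded})  "
            f"obs={self.n_obs}  age_center={self.age_center:.2f} y",
            f"log-likelihood {self.loglik:.2f}   "
            f"converged={self.converged} ({self.n_outer_iter} outer iter)",
            "",
            "Random effects (SD / correlations):",
        ]
        for i, e in enumerate(self.spec.random_effects):
            unit = {"size": "units", "tempo": "y", "velocity": "log"}[e]
            lines.append(f"  {e:<9} SD {sds[i]:.4g} {unit}")
        if len(sds) > 1:
            corr = self.Sigma.to_numpy() / np.outer(sds, sds)
            for i in range(len(sds)):
                for j in range(i + 1, len(sds)):
                    lines.append(
                        f"  corr({self.spec.random_effects[i]}, "
                        f"{self.spec.random_effects[j]}) = {corr[i, j]:+.3f}"
                    )
        lines += [
            f"Residual SD {self.sigma:.4g} (transformed scale)",
            f"Cross-sectional residual SD {self.cross_sd:.4g}",
            f"Variance explained {100 * self.variance_explained():.1f}%",
        ]
        return "\n".join(lines)

    def __repr__(self) -> str:
        return (
            f"<SitarResults {self.outcome!r}: {self.n_subjects} subjects, "
            f"loglik={self.loglik:.1f}, converged={self.converged}>"
        )


# -- functional wrappers ---------------------------------------------------


def fit_sitar(data: LongSeries, spec: SitarSpec | None = None, **kwargs) -> SitarResults:
    """Fit a SITAR model (functional form of ``SitarModel(data, spec).fit()``)."""
    return SitarModel(data, spec).fit(**kwargs)


def crosssectional_fit(data: LongSeries, spec: SitarSpec | None = None) -> float:
    """Residual SD of a pooled spline fit ignoring subject identity.

    This is the comparator in the variance-explained statistic: one
    mean curve fit to all observations as if cross-sectional, residual
    SD with denominator n_obs - df - 1, on the transformed scale.
    """
    model = SitarModel(data, spec)
    _, sd = model._crosssectional(model.basis)
    return sd


def variance_explained(sitar_resid_sd: float, crosssectional_resid_sd: float) -> float:
    """1 - (adjusted residual SD / cross-sectional residual SD)^2.

    The headline SITAR statistic: the fraction of pooled variance
    removed by the size/tempo/velocity adjustment.
    """
    if sitar_resid_sd <= 0 or crosssectional_resid_sd <= 0:
        raise ValueError("residual SDs must be positive")
    if sitar_resid_sd > crosssectional_resid_sd:
        warnings.warn(
            "adjusted residual SD exceeds cross-sectional residual SD; "
            "variance explained clamped to 0",
            stacklevel=2,
        )
        return 0.0
    return 1.0 - (sitar_resid_sd / crosssectional_resid_sd) ** 2


def marginal_loglik(
    data: LongSeries,
    spec: SitarSpec,
    coefficients: np.ndarray,
    re_cov: np.ndarray,
    sigma: float,
    basis: SplineModel | None = None,
) -> float:
    """Laplace-approximate marginal log likelihood at given parameters.

    ``coefficients`` is (intercept, basis coefs) of length df + 1;
    ``re_cov`` is the covariance of the declared random effects.  The
    likelihood integrates the per-subject random effects out via an
    inner Newton mode search and a second-order expansion; it is exact
    when only the size effect is random.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    re_cov = np.atleast_2d(np.asarray(re_cov, dtype=float))
    eigs = np.linalg.eigvalsh(re_cov)
    if eigs.min() < -1e-10:
        raise ValueError("re_cov must be positive semi-definite")
    model = SitarModel(data, spec)
    family = _SplineSitarFamily(basis or model.basis, spec.random_effects)
    return laplace_loglik(
        family, np.asarray(coefficients, float), re_cov, sigma, model._grouped
    )


def sitar_predict(
    fit: SitarResults,
    effects: RandomEffects,
    ages,
    allow_extrapolation: bool = False,
) -> np.ndarray:
    """Transformed-scale prediction for an arbitrary effect triple."""
    return fit.predict_transformed(ages, effects, allow_extrapolation)
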