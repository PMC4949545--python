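"""Pubertal-timing metrics derived from a fitted SITAR model.

Age at peak velocity (APV) is the age at which the first derivative of
the back-transformed mean curve is maximal; the peak velocity is the
derivative's value there.  Velocities are computed analytically from
the spline derivative with the chain rule for the sqrt/log response
transforms (finite differences are kept only as a test oracle).
Individual timings follow the SITAR construction: subject i's APV is
the mean APV plus their tempo random effect, negative tempo meaning
early puberty.  Standard errors for the mean APV come from a
nonparametric bootstrap that resamples subjects with replacement,
respecting the hierarchical design.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import LongSeries
from .model import SitarResults, SitarSpec, fit_sitar

__all__ = [
    "CurveOnGrid",
    "TimingSummary",
    "PeakLevel",
    "back_transform_curve",
    "age_at_peak_velocity",
    "age_at_peak_level",
    "individual_timings",
    "individual_apv_remaximized",
    "bootstrap_apv_se",
    "value_at_age",
    "BoundaryPeakWarning",
    "NoSpurtError",
    "UnstableBootstrapError",
]

# peak searches stay this far inside the boundary knots to avoid spline
# edge artefacts
EDGE_MARGIN = 0.25


class BoundaryPeakWarning(UserWarning):
    """The peak sits at the edge of the search window (not identifiable)."""


class NoSpurtError(ValueError):
    """Velocity is negative everywhere in the window: no growth spurt."""


class UnstableBootstrapError(RuntimeError):
    """Too many bootstrap replicates failed to converge."""


@dataclass
class CurveOnGrid:
    """A mean curve (level or velocity) evaluated on a dense age grid,
    in the outcome's natural units."""

    ages: np.ndarray
    values: np.ndarray
    scale: str  # "level" or "velocity"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"age": self.ages, self.scale: self.values})


@dataclass
class PeakLevel:
    """Age at which the level curve peaks; ``at_boundary`` flags a
    monotone curve whose maximum is at the window edge (expected for
    the sex steroids, which keep rising into adulthood)."""

    age: float
    level: float
    at_boundary: bool


@dataclass
class TimingSummary:
    """Table-style summary of age at peak velocity for one outcome."""

    apv_mean: float
    apv_sd: float
    peak_velocity: float
    individual_apv: pd.Series
    apv_se: float | None = None

    def __str__(self) -> str:
        se = f" ({self.apv_se:.2f})" if self.apv_se is not None else ""
        return (
            f"APV mean {self.apv_mean:.2f}{se} y, SD {self.apv_sd:.2f} y, "
            f"peak velocity {self.peak_velocity:.2f}/y, "
            f"N={len(self.individual_apv)}"
        )


def _level_and_velocity(fit: SitarResults, u: np.ndarray):
    """Back-transformed level and velocity at centred-shifted ages u."""
    h = fit.spline(u)
    hp = fit.spline.deriv(u)
    tr = fit.spec.transform
    if tr == "identity":
        return h, hp
    if tr == "sqrt":
        if np.any(h < 0):
            raise ValueError(
                "sqrt back-transform with negative fitted spline values: "
                "the model is badly fitted"
            )
        return h * h, 2.0 * h * hp
    if tr == "log":
        eh = np.exp(h)
        return eh, hp * eh
    raise ValueError(tr)


def back_transform_curve(
    fit: SitarResults,
    grid: np.ndarray | None = None,
    grid_step: float = 0.01,
    scale: str = "level",
    allow_extrapolation: bool = False,
) -> CurveOnGrid:
    """Population mean curve in natural units on a dense age grid.

    identity -> h; sqrt -> h^2 (velocity 2 h h'); log -> exp(h)
    (velocity h' exp(h)).  The default grid spans the knots and the
    observed ages; beyond the boundary knots the spline continues
    linearly (natural condition), but explicit grids outside the guard
    band need ``allow_extrapolation``.
    """
    k_lo, k_hi = fit.spline.boundary_knots
    k_lo, k_hi = k_lo + fit.age_center, k_hi + fit.age_center
    d_lo, d_hi = getattr(fit, "age_range", (k_lo, k_hi))
    lo, hi = min(k_lo, d_lo), max(k_hi, d_hi)
    if grid is None:
        grid = np.arange(lo, hi + 1e-9, grid_step)
    grid = np.asarray(grid, dtype=float)
    if not allow_extrapolation and (grid.min() < lo - 1e-9
                                    or grid.max() > hi + 1e-9):
        raise ValueError(
            "grid extends beyond the knots and the observed ages; pass "
            "allow_extrapolation=True to override"
        )
    u = grid - fit.age_center
    level, vel = _level_and_velocity(fit, u)
    values = level if scale == "level" else vel
    return CurveOnGrid(ages=grid, values=values, scale=scale)


def _refine_peak(ages, values, i):
    """Quadratic refinement of a grid maximum through 3 points."""
    if i == 0 or i == len(ages) - 1:
        return float(ages[i]), float(values[i])
    y0, y1, y2 = values[i - 1], values[i], values[i + 1]
    denom = y0 - 2 * y1 + y2
    if denom >= 0:  # not locally concave; keep grid point
        return float(ages[i]), float(values[i])
    delta = 0.5 * (y0 - y2) / denom
    h = ages[i + 1] - ages[i]
    age = float(ages[i] + delta * h)
    val = float(y1 - 0.25 * (y0 - y2) * delta)
    return age, val


def _peak_of(fit: SitarResults, scale: str, grid_step: float = 0.01,
             min_prominence: float = 0.025):
    """Grid maximum of a curve; a maximum counts as interior only when
    it exceeds both window-end values by ``min_prominence`` of the
    curve's range — a wiggle on a flat (noisy) tail is not a peak."""
    lo, hi = fit.spline.boundary_knots
    lo, hi = lo + fit.age_center, hi + fit.age_center
    d_lo, d_hi = getattr(fit, "age_range", (lo, hi))
    # search inside both the knot span and the observed ages
    lo, hi = max(lo, d_lo), min(hi, d_hi)
    grid = np.arange(lo + EDGE_MARGIN, hi - EDGE_MARGIN + grid_step / 2,
                     grid_step)
    curve = back_transform_curve(fit, grid=grid, scale=scale,
                                 allow_extrapolation=True)
    i = int(np.argmax(curve.values))
    vrange = float(curve.values.max() - curve.values.min())
    edge_val = max(curve.values[0], curve.values[-1])
    at_boundary = (
        i == 0
        or i == len(grid) - 1
        or (curve.values[i] - edge_val) < min_prominence * vrange
    )
    age, val = _refine_peak(curve.ages, curve.values, i)
    if at_boundary and curve.values[-1] >= curve.values[0]:
        # report the window end for an effectively monotone curve
        age, val = float(curve.ages[-1]), float(curve.values[-1])
    return age, val, at_boundary, curve


def age_at_peak_velocity(
    fit: SitarResults, grid_step: float = 0.01
) -> tuple[float, float]:
    """Age at peak velocity and the peak velocity of the mean curve.

    Dense grid search (default 0.01 y) inside the knot range, followed
    by local quadratic refinement.  A maximum at the window edge
    triggers :class:`BoundaryPeakWarning` (APV not identifiable in the
    observed age window); an everywhere-negative velocity raises
    :class:`NoSpurtError`.
    """
    age, val, at_boundary, curve = _peak_of(fit, "velocity", grid_step)
    if np.all(curve.values < 0):
        raise NoSpurtError("velocity negative throughout the age window")
    if at_boundary:
        warnings.warn(
            f"velocity maximum at the window edge ({age:.2f} y); "
            "APV is not identifiable within the observed ages",
            BoundaryPeakWarning,
            stacklevel=2,
        )
    return age, val


def age_at_peak_level(fit: SitarResults, grid_step: float = 0.01) -> PeakLevel:
    """Age at which the back-transformed level curve peaks.

    Monotone curves (sex steroids keep rising into adulthood) yield a
    boundary maximum, flagged via ``at_boundary`` rather than an error.
    """
    age, val, at_boundary, _ = _peak_of(fit, "level", grid_step)
    if at_boundary:
        warnings.warn(
            "level curve is monotone in the window; no interior peak",
            BoundaryPeakWarning,
            stacklevel=2,
        )
    return PeakLevel(age=age, level=val, at_boundary=at_boundary)


def individual_timings(fit: SitarResults, apv_mean: float) -> TimingSummary:
    """Per-subject APVs: mean APV plus each subject's tempo effect.

    ``apv_sd`` is by construction the SD of the tempo random effects —
    the spread of pubertal timing in the cohort.
    """
    if "tempo" not in fit.spec.random_effects:
        raise ValueError("fit has no tempo random effect")
    tempo = fit.ranef["tempo"]
    individual = apv_mean + tempo
    sd = float(tempo.std(ddof=1)) if len(tempo) > 1 else 0.0
    _, pv = age_at_peak_velocity(fit)
    return TimingSummary(
        apv_mean=float(apv_mean),
        apv_sd=sd,
        peak_velocity=pv,
        individual_apv=individual.rename("apv"),
    )


def individual_apv_remaximized(fit: SitarResults, grid_step: float = 0.01) -> pd.Series:
    """Diagnostic: per-subject APV by re-maximizing each subject's own
    velocity curve (differs from mean APV + tempo when velocity gamma
    is non-zero, since gamma rescales time about the centring age)."""
    apv_mean, _ = age_at_peak_velocity(fit, grid_step)
    out = {}
    for sid in fit.ranef.index:
        e = fit.subject_effects(sid)
        # subject's curve peaks where the mean curve argument hits its peak:
        # (t - c - beta) e^gamma = apv_mean - c  =>  t = c + beta + (apv - c) e^-gamma
        out[sid] = (
            fit.age_center
            + e.tempo
            + (apv_mean - fit.age_center) * np.exp(-e.velocity)
        )
    return pd.Series(out, name="apv_remax")


def value_at_age(fit: SitarResults, subject_id, age: float) -> float:
    """Back-transformed individual prediction at one age."""
    from .data import inverse_transform

    e = fit.subject_effects(subject_id)
    y = fit.predict_transformed([age], e)
    return float(inverse_transform(y, fit.spec.transform)[0])


def bootstrap_apv_se(
    data: LongSeries,
    spec: SitarSpec,
    n_boot: int = 200,
    seed: int = 20150108,
    max_frac_failed: float = 0.10,
    start: SitarResults | None = None,
) -> float:
    """Bootstrap standard error of the mean APV.

    Nonparametric bootstrap resampling *subjects* with replacement
    (respecting the hierarchical design); each replicate is refitted
    and its APV extracted; the SE is the SD over replicates.
    Non-converged or boundary-peak replicates are dropped and counted;
    more than ``max_frac_failed`` failures raises
    :class:`UnstableBootstrapError`.
    """
    if n_boot < 50:
        raise ValueError("n_boot must be >= 50")
    if start is None:
        start = fit_sitar(data, spec)  # replicates warm-start from this fit
    rng = np.random.default_rng(seed)
    df = data.df
    subjects = np.array(sorted(df["subject_id"].unique()))
    groups = {s: g for s, g in df.groupby("subject_id")}
    apvs = []
    n_failed = 0
    for _ in range(n_boot):
        draw = rng.choice(subjects, size=len(subjects), replace=True)
        parts = []
        for k, sid in enumerate(draw):
            g = groups[sid].copy()
            g["subject_id"] = f"b{k}"
            parts.append(g)
        boot = LongSeries(pd.concat(parts, ignore_index=True), data.age_window)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("error", BoundaryPeakWarning)
                res = fit_sitar(boot, spec, refresh_knots=False, start=start)
                apv, _ = age_at_peak_velocity(res)
            if not res.converged:
                n_failed += 1
                continue
            apvs.append(apv)
        except (ValueError, BoundaryPeakWarning, np.linalg.LinAlgError, Warning):
            n_failed += 1
    if n_failed > max_frac_failed * n_boot:
        raise UnstableBootstrapError(
            f"{n_failed}/{n_boot} bootstrap replicates failed"
        )
    return float(np.std(apvs, ddof=1))
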