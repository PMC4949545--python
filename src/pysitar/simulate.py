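"""Synthetic pubertal cohorts with known ground truth.

Generates multi-outcome longitudinal data emulating a 1980s school
cohort followed 6-monthly from age 8.5 to 16: height (54 boys / 70
girls), IGF-1 and a sex steroid in a blood subsample (24 / 27), and
ordinal Tanner stages.  Parametric curve families give analytic ground
truth:

* height — Preece-Baines model 1,
  h(t) = h1 - 2 (h1 - h_theta) / (exp(s0 (t - theta)) + exp(s1 (t - theta)));
* IGF-1 — a rise-minus-decline double logistic on the sqrt scale
  (constant in childhood, steep pubertal rise, peak ~1.5 y after peak
  velocity, then decline);
* sex steroids — a single logistic on the log scale (steep rise that
  continues into adulthood, so no interior level peak);
* Tanner stages — a latent logistic from 1 to 5 plus rater noise,
  rounded and clamped.

Subjects differ by SITAR-style size / tempo / velocity effects.  One
latent timing variable T_i per subject drives the tempo of every
outcome through loadings lambda (tempo = sd * (lambda T + jitter)), so
cross-outcome tempo correlations are lambda_1 * lambda_2 by
construction.  Default curve parameters are calibrated at run time so
each outcome's population age at peak velocity (by a brute-force grid
oracle) hits its target exactly; boys' height APV 13.9 y with peak
velocity 9.9 cm/y, girls 12.3 y and 8.0 cm/y, and so on.

Everything is deterministic given (spec, seed).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import optimize

from .data import LongSeries, StageSeries

__all__ = [
    "PB1Params",
    "pb1_height",
    "pb1_velocity",
    "pb1_apv_oracle",
    "DoubleLogistic",
    "LogisticCurve",
    "OutcomeSpec",
    "StageSpec",
    "CohortSpec",
    "TrueEffects",
    "SimulatedCohort",
    "default_cohort_spec",
    "sample_height_cohort",
    "sample_igf1_cohort",
    "sample_steroid_cohort",
    "sample_stage_cohort",
    "sample_full_cohort",
    "grid_peak",
]

DEFAULT_SEED = 20150108


# -- curve families --------------------------------------------------------


@dataclass(frozen=True)
class PB1Params:
    """Preece-Baines model 1: adult height h1, height h_theta at age
    theta, and rate constants s0 < s1 (per year)."""

    h1: float
    h_theta: float
    theta: float
    s0: float
    s1: float

    def __post_init__(self) -> None:
        if not (0 < self.s0 < self.s1):
            raise ValueError("need 0 < s0 < s1")
        if not self.h_theta < self.h1:
            raise ValueError("need h_theta < h1")


def pb1_height(t, p: PB1Params) -> np.ndarray:
    """h(t) = h1 - 2(h1 - h_theta) / (exp(s0(t-theta)) + exp(s1(t-theta)))."""
    t = np.asarray(t, dtype=float)
    tau = t - p.theta
    return p.h1 - 2.0 * (p.h1 - p.h_theta) / (
        np.exp(p.s0 * tau) + np.exp(p.s1 * tau)
    )


def pb1_velocity(t, p: PB1Params) -> np.ndarray:
    """Analytic first derivative of the PB1 curve (cm/year)."""
    t = np.asarray(t, dtype=float)
    tau = t - p.theta
    e0, e1 = np.exp(p.s0 * tau), np.exp(p.s1 * tau)
    return 2.0 * (p.h1 - p.h_theta) * (p.s0 * e0 + p.s1 * e1) / (e0 + e1) ** 2


def grid_peak(fn, lo: float, hi: float, step: float = 0.001):
    """Brute-force maximizer of fn on a grid; (argmax, max, at_boundary)."""
    grid = np.arange(lo, hi + step / 2, step)
    vals = fn(grid)
    i = int(np.argmax(vals))
    return float(grid[i]), float(vals[i]), i in (0, len(grid) - 1)


def pb1_apv_oracle(p: PB1Params, lo: float = 8.0, hi: float = 18.0,
                   step: float = 0.001) -> tuple[float, float]:
    """Brute-force APV/PHV: maximize the analytic PB1 derivative on a
    0.001-year grid.  The independent oracle for all height APV checks."""
    apv, phv, at_boundary = grid_peak(lambda t: pb1_velocity(t, p), lo, hi, step)
    if at_boundary:
        warnings.warn("PB1 velocity peak at grid boundary", stacklevel=2)
    return apv, phv


@dataclass(frozen=True)
class DoubleLogistic:
    """Rise-minus-decline curve on a transformed scale:
    f(t) = b + A/(1+exp(-k1(t-m1))) - D/(1+exp(-k2(t-m2))), m2 > m1."""

    b: float
    A: float
    k1: float
    m1: float
    D: float
    k2: float
    m2: float

    def __post_init__(self) -> None:
        if self.D < 0 or self.A <= 0 or self.k1 <= 0 or self.k2 <= 0:
            raise ValueError("need A, k1, k2 > 0 and D >= 0")
        if self.D > 0 and self.m2 <= self.m1:
            raise ValueError("decline midpoint m2 must exceed rise midpoint m1")

    def value(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        rise = self.A / (1.0 + np.exp(-self.k1 * (t - self.m1)))
        fall = self.D / (1.0 + np.exp(-self.k2 * (t - self.m2)))
        return self.b + rise - fall

    def deriv(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        p1 = 1.0 / (1.0 + np.exp(-self.k1 * (t - self.m1)))
        p2 = 1.0 / (1.0 + np.exp(-self.k2 * (t - self.m2)))
        return self.A * self.k1 * p1 * (1 - p1) - self.D * self.k2 * p2 * (1 - p2)

    def shifted(self, delta: float) -> "DoubleLogistic":
        return replace(self, m1=self.m1 + delta, m2=self.m2 + delta)


@dataclass(frozen=True)
class LogisticCurve:
    """Single logistic on a transformed scale: b + A/(1+exp(-k(t-m)))."""

    b: float
    A: float
    k: float
    m: float

    def value(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return self.b + self.A / (1.0 + np.exp(-self.k * (t - self.m)))

    def deriv(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        p = 1.0 / (1.0 + np.exp(-self.k * (t - self.m)))
        return self.A * self.k * p * (1 - p)

    def shifted(self, delta: float) -> "LogisticCurve":
        return replace(self, m=self.m + delta)


def _natural_velocity(curve, transform: str):
    """Velocity of the back-transformed (natural-unit) level curve."""
    if transform == "identity":
        return curve.deriv
    if transform == "sqrt":
        return lambda t: 2.0 * curve.value(t) * curve.deriv(t)
    if transform == "log":
        return lambda t: curve.deriv(t) * np.exp(curve.value(t))
    raise ValueError(transform)


def _natural_level(curve, transform: str):
    if transform == "identity":
        return curve.value
    if transform == "sqrt":
        return lambda t: np.square(curve.value(t))
    if transform == "log":
        return lambda t: np.exp(curve.value(t))
    raise ValueError(transform)


# -- cohort configuration --------------------------------------------------


@dataclass(frozen=True)
class OutcomeSpec:
    """One outcome's generator settings: effect SDs, latent-timing
    loading, and the noise model (additive SD in natural units, or
    lognormal CV for assay-style multiplicative noise)."""

    name: str
    transform: str
    tempo_sd: float
    size_sd: float
    velocity_sd: float
    loading: float
    noise_sd: float = 0.0          # additive, natural units
    noise_cv: float = 0.0          # multiplicative lognormal
    size_velocity_corr: float = 0.0
    apv_target: float = 0.0        # population APV the defaults calibrate to

    def __post_init__(self) -> None:
        if not 0.0 <= self.loading <= 1.0:
            raise ValueError("loading must be in [0, 1]")
        for name in ("tempo_sd", "size_sd", "velocity_sd", "noise_sd", "noise_cv"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not -1.0 < self.size_velocity_corr < 1.0:
            raise ValueError("size_velocity_corr must be in (-1, 1)")


@dataclass(frozen=True)
class StageSpec:
    """One Tanner measure: logistic midpoint age, rate, effect SDs,
    loading, and rater noise in stage units."""

    measure: str
    midpoint_age: float
    rate: float = 1.4
    tempo_sd: float = 1.0
    velocity_sd: float = 0.2
    loading: float = 0.9
    rater_noise_sd: float = 0.4

    def __post_init__(self) -> None:
        if not 0.0 <= self.loading <= 1.0:
            raise ValueError("loading must be in [0, 1]")
        if self.rate <= 0:
            raise ValueError("rate must be positive")


@dataclass(frozen=True)
class CohortSpec:
    """Study design: per-sex sample sizes, 6-monthly visit schedule
    with small age jitter, latent timing SD, and per-outcome settings."""

    sex: str = "M"
    n_subjects: int = 54
    n_hormone_subsample: int = 24
    visit_start: float = 8.5
    visit_end: float = 16.0
    visit_step: float = 0.5
    visit_jitter: float = 0.05
    missingness: float = 0.0
    latent_timing_sd: float = 1.0
    outcomes: tuple[OutcomeSpec, ...] = ()
    stage_measures: tuple[StageSpec, ...] = ()

    def __post_init__(self) -> None:
        if self.sex not in ("M", "F"):
            raise ValueError("sex must be 'M' or 'F'")
        if not (8.0 <= self.visit_start < self.visit_end <= 16.45):
            raise ValueError("visit schedule must lie within [8, 16.5]")
        if not 0.0 <= self.missingness < 1.0:
            raise ValueError("missingness must be in [0, 1)")
        if self.latent_timing_sd < 0:
            raise ValueError("latent_timing_sd must be >= 0")

    def outcome(self, name: str) -> OutcomeSpec:
        for o in self.outcomes:
            if o.name == name:
                return o
        raise KeyError(f"no outcome {name!r} in this cohort spec")

    def stage(self, measure: str) -> StageSpec:
        for s in self.stage_measures:
            if s.measure == measure:
                return s
        raise KeyError(f"no stage measure {measure!r} in this cohort spec")


_BOYS_OUTCOMES = (
    OutcomeSpec("height", "identity", tempo_sd=0.97, size_sd=2.5,
                velocity_sd=0.12, loading=np.sqrt(0.9), noise_sd=0.3,
                apv_target=13.9),
    OutcomeSpec("igf1", "sqrt", tempo_sd=0.93, size_sd=1.0,
                velocity_sd=0.15, loading=np.sqrt(0.9), noise_cv=0.12,
                size_velocity_corr=0.8, apv_target=13.2),
    OutcomeSpec("testosterone", "log", tempo_sd=1.04, size_sd=0.30,
                velocity_sd=0.15, loading=np.sqrt(0.9), noise_cv=0.09,
                apv_target=13.5),
)
_BOYS_STAGES = (
    StageSpec("genitalia", midpoint_age=13.1, tempo_sd=1.01, loading=0.85),
    StageSpec("pubic_hair", midpoint_age=13.5, tempo_sd=0.96, loading=0.85),
)
_GIRLS_OUTCOMES = (
    OutcomeSpec("height", "identity", tempo_sd=1.03, size_sd=2.5,
                velocity_sd=0.12, loading=0.85, noise_sd=0.3,
                apv_target=12.3),
    OutcomeSpec("igf1", "sqrt", tempo_sd=0.76, size_sd=1.0,
                velocity_sd=0.15, loading=0.85, noise_cv=0.12,
                size_velocity_corr=0.6, apv_target=12.0),
    OutcomeSpec("oestradiol", "log", tempo_sd=0.77, size_sd=0.30,
                velocity_sd=0.15, loading=0.72, noise_cv=0.09,
                apv_target=12.7),
)
_GIRLS_STAGES = (
    StageSpec("breast", midpoint_age=12.3, tempo_sd=1.27, loading=0.80),
    StageSpec("pubic_hair", midpoint_age=12.8, tempo_sd=1.13, loading=0.80),
)


def default_cohort_spec(sex: str = "M") -> CohortSpec:
    """Study-design defaults: 54 boys / 70 girls, hormone subsample
    24 / 27, 16 six-monthly visits from 8.5 to 16.0."""
    if sex == "M":
        return CohortSpec(sex="M", n_subjects=54, n_hormone_subsample=24,
                          outcomes=_BOYS_OUTCOMES, stage_measures=_BOYS_STAGES)
    return CohortSpec(sex="F", n_subjects=70, n_hormone_subsample=27,
                      outcomes=_GIRLS_OUTCOMES, stage_measures=_GIRLS_STAGES)


# -- calibrated mean curves ------------------------------------------------

_PHV_TARGET = {"M": 9.9, "F": 8.0}
# peak IGF-1 level lags peak IGF-1 velocity by ~1.3 y (boys: 14.5 vs
# 13.2) / ~1.8 y (girls: 13.8 vs 12.0)
_IGF1_PEAK_LEVEL_LAG = {"M": 1.3, "F": 1.8}


@lru_cache(maxsize=None)
def mean_height_curve(sex: str, apv_target: float) -> PB1Params:
    """PB1 defaults with the classic published rate constants; the
    spurt amplitude (h1 - h_theta) is solved so the grid-oracle PHV
    matches the sex's mean peak velocity, and theta is translated so
    the APV equals the target exactly."""
    if sex == "M":
        h1, s0, s1 = 175.0, 0.1124, 1.2397
    else:
        h1, s0, s1 = 163.5, 0.1108, 1.1798
    phv_target = _PHV_TARGET[sex]

    def phv_of(delta):
        p = PB1Params(h1=h1, h_theta=h1 - delta, theta=14.0, s0=s0, s1=s1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # boundary peaks while bracketing
            return pb1_apv_oracle(p)[1]

    delta = optimize.brentq(lambda d: phv_of(d) - phv_target, 5.0, 25.0,
                            xtol=1e-6)
    p = PB1Params(h1=h1, h_theta=h1 - delta, theta=14.0, s0=s0, s1=s1)
    apv0, _ = pb1_apv_oracle(p)
    # translation in theta shifts APV one-for-one
    return replace(p, theta=14.0 + (apv_target - apv0))


@lru_cache(maxsize=None)
def mean_igf1_curve(sex: str, apv_target: float) -> DoubleLogistic:
    """Double-logistic IGF-1 defaults (sqrt of ug/L) calibrated so the
    natural-scale velocity peaks at the target age and the level peaks
    ~1.3-1.8 y later."""
    # boys' level peak trails peak velocity by only ~1.3 y, needing a
    # steeper decline than the girls' ~1.8 y lag
    k2, bracket = (2.0, (1.25, 2.6)) if sex == "M" else (1.2, (2.0, 3.6))
    base = dict(b=12.0, A=10.0, k1=1.5, D=4.0, k2=k2)
    lag_target = _IGF1_PEAK_LEVEL_LAG[sex]

    def build(spacing):
        c = DoubleLogistic(m1=13.0, m2=13.0 + spacing, **base)
        apv, _, _ = grid_peak(_natural_velocity(c, "sqrt"), 6.0, 20.0)
        return c.shifted(apv_target - apv)

    def lag_of(spacing):
        c = build(spacing)
        apv, _, b1 = grid_peak(_natural_velocity(c, "sqrt"), 6.0, 20.0)
        peak, _, b2 = grid_peak(_natural_level(c, "sqrt"), 6.0, 20.0)
        if b1 or b2:
            raise RuntimeError("IGF-1 calibration hit the grid boundary")
        return peak - apv

    spacing = optimize.brentq(lambda s: lag_of(s) - lag_target, *bracket,
                              xtol=1e-4)
    curve = build(spacing)
    if curve.deriv(apv_target) <= 0:
        raise RuntimeError("IGF-1 defaults failed the rise-then-decline shape")
    return curve


_STEROID_SHAPE = {
    # log nmol/L for testosterone, log pmol/L for oestradiol
    "testosterone": dict(b=np.log(0.4), A=np.log(17.0 / 0.4), k=1.1),
    # oestradiol keeps rising through the window: gentler slope, higher
    # adult asymptote, so fitted curves stay monotone to age 16
    "oestradiol": dict(b=np.log(20.0), A=np.log(500.0 / 20.0), k=0.75),
}


@lru_cache(maxsize=None)
def mean_steroid_curve(name: str, apv_target: float) -> LogisticCurve:
    """Single-logistic steroid defaults (log scale), velocity of the
    back-transformed curve peaking at the target age; the level keeps
    rising into adulthood."""
    c = LogisticCurve(m=13.0, **_STEROID_SHAPE[name])
    apv, _, _ = grid_peak(_natural_velocity(c, "log"), 6.0, 24.0)
    return c.shifted(apv_target - apv)


# -- ground truth containers -----------------------------------------------


@dataclass
class TrueEffects:
    """Ground truth for recovery tests: the shared latent timing T_i,
    per-outcome (size, tempo, velocity, true APV) per subject, and the
    population APV of each outcome's mean curve."""

    latent_timing: pd.Series
    effects: dict[str, pd.DataFrame]
    mean_apv: dict[str, float]

    def tempo(self, outcome: str) -> pd.Series:
        return self.effects[outcome]["tempo"]

    def merge(self, other: "TrueEffects") -> "TrueEffects":
        latent = self.latent_timing.combine_first(other.latent_timing)
        return TrueEffects(
            latent_timing=latent,
            effects={**self.effects, **other.effects},
            mean_apv={**self.mean_apv, **other.mean_apv},
        )


@dataclass
class SimulatedCohort:
    """A full multi-outcome cohort: continuous outcomes, Tanner stages
    and the generating truth."""

    long: LongSeries
    stages: StageSeries
    truth: TrueEffects


# -- sampling machinery ----------------------------------------------------


def _subject_ids(spec: CohortSpec) -> np.ndarray:
    return np.array([f"{spec.sex}{i + 1:03d}" for i in range(spec.n_subjects)])


def _visit_ages(spec: CohortSpec, rng: np.random.Generator, n: int) -> np.ndarray:
    base = np.arange(spec.visit_start, spec.visit_end + spec.visit_step / 2,
                     spec.visit_step)
    jitter = rng.uniform(-spec.visit_jitter, spec.visit_jitter,
                         size=(n, base.size))
    return base[None, :] + jitter


def _centred(x: np.ndarray) -> np.ndarray:
    """Remove the sample mean: the SITAR model assumes mean-zero random
    effects, and moment-matched draws emulate exactly that at cohort
    level (the cohort's mean timing equals the calibrated target)."""
    return x - x.mean()


def _draw_latent(spec: CohortSpec, rng: np.random.Generator) -> pd.Series:
    ids = _subject_ids(spec)
    T = _centred(rng.normal(0.0, spec.latent_timing_sd, size=len(ids)))
    return pd.Series(T, index=ids, name="latent_timing")


def _draw_effects(ospec, latent: pd.Series, latent_sd: float,
                  rng: np.random.Generator, velocity_sd=None) -> pd.DataFrame:
    """tempo = sd (lambda T/sd_T + sqrt(1-lambda^2) eps); size and
    velocity jointly Gaussian, independent of tempo."""
    n = len(latent)
    lam = ospec.loading
    z = latent.to_numpy() / latent_sd if latent_sd > 0 else np.zeros(n)
    jitter = _centred(rng.normal(size=n))
    tempo = ospec.tempo_sd * (lam * z + np.sqrt(1 - lam**2) * jitter)
    out = pd.DataFrame(index=latent.index)
    # re-centre within the sampled cohort (hormone subsamples inherit a
    # non-zero mean from the full cohort's latent timing otherwise)
    out["tempo"] = _centred(tempo)
    if isinstance(ospec, StageSpec):
        out["velocity"] = ospec.velocity_sd * _centred(rng.normal(size=n))
        return out
    rho = ospec.size_velocity_corr
    zs = _centred(rng.normal(size=n))
    zv = rho * zs + np.sqrt(1 - rho**2) * _centred(rng.normal(size=n))
    out["size"] = ospec.size_sd * zs
    out["velocity"] = ospec.velocity_sd * zv
    return out


def _sitar_transformed_values(curve, transform, center, ages, size, tempo,
                              velocity) -> np.ndarray:
    """Individual transformed-scale curve: size + f(c + (t-c-tempo) e^v)."""
    u = center + (ages - center - tempo[:, None]) * np.exp(velocity[:, None])
    return size[:, None] + curve.value(u)


def _long_rows(spec, ospec, ids, ages, natural, rng):
    n, m = natural.shape
    keep = np.ones((n, m), dtype=bool)
    if spec.missingness > 0:
        keep = rng.uniform(size=(n, m)) >= spec.missingness
    df = pd.DataFrame({
        "subject_id": np.repeat(ids, m),
        "sex": spec.sex,
        "age": ages.ravel(),
        "outcome": ospec.name,
        "value": natural.ravel(),
    })
    return df[keep.ravel()]


def _continuous_cohort(spec: CohortSpec, name: str, curve, center: float,
                       seed, latent: pd.Series | None,
                       subsample: bool) -> tuple[LongSeries, TrueEffects]:
    ospec = spec.outcome(name)
    rng = np.random.default_rng(seed)
    if latent is None:
        latent = _draw_latent(spec, rng)
    if subsample:
        latent = latent.iloc[: spec.n_hormone_subsample]
    ids = np.asarray(latent.index)
    eff = _draw_effects(ospec, latent, spec.latent_timing_sd, rng)
    ages = _visit_ages(spec, rng, len(ids))
    transformed = _sitar_transformed_values(
        curve, ospec.transform, center, ages,
        eff["size"].to_numpy(), eff["tempo"].to_numpy(),
        eff["velocity"].to_numpy(),
    )
    from .data import inverse_transform

    natural = inverse_transform(transformed, ospec.transform)
    if ospec.noise_sd > 0:
        natural = natural + rng.normal(0.0, ospec.noise_sd, natural.shape)
    if ospec.noise_cv > 0:
        s = ospec.noise_cv
        natural = natural * np.exp(rng.normal(0.0, s, natural.shape) - s**2 / 2)
    apv0, _, _ = grid_peak(_natural_velocity(curve, ospec.transform), 6.0, 22.0)
    if name == "oestradiol":
        # menstrual-cycle variability: extra noise after each girl's APV
        post = ages > (apv0 + eff["tempo"].to_numpy())[:, None]
        extra = rng.normal(0.0, 0.30, natural.shape)
        natural = np.where(post, natural * np.exp(extra - 0.30**2 / 2), natural)
    eff["true_apv"] = apv0 + eff["tempo"]
    df = _long_rows(spec, ospec, ids, ages, natural, rng)
    truth = TrueEffects(latent_timing=latent, effects={name: eff},
                        mean_apv={name: apv0})
    return LongSeries(df), truth


def sample_height_cohort(spec: CohortSpec | None = None,
                         seed: int = DEFAULT_SEED,
                         latent: pd.Series | None = None):
    """Height cohort from subject-specific PB1 curves.

    Each subject's curve is the calibrated sex mean PB1 curve shifted
    vertically by size, in time by tempo, with the age scale about
    theta compressed by exp(velocity); plus additive measurement noise
    (default SD 0.3 cm: ~0.2 cm technical error of measurement plus
    day-to-day biological variation).
    """
    spec = spec or default_cohort_spec()
    ospec = spec.outcome("height")
    rng = np.random.default_rng(seed)
    if latent is None:
        latent = _draw_latent(spec, rng)
    ids = np.asarray(latent.index)
    eff = _draw_effects(ospec, latent, spec.latent_timing_sd, rng)
    p0 = mean_height_curve(spec.sex, ospec.apv_target)
    ages = _visit_ages(spec, rng, len(ids))
    tempo = eff["tempo"].to_numpy()[:, None]
    vel = eff["velocity"].to_numpy()[:, None]
    size = eff["size"].to_numpy()[:, None]
    # per-subject PB1: theta shifted by tempo, rates scaled by exp(velocity),
    # the whole curve shifted vertically by size
    tau = (ages - p0.theta - tempo) * np.exp(vel)
    height = size + p0.h1 - 2.0 * (p0.h1 - p0.h_theta) / (
        np.exp(p0.s0 * tau) + np.exp(p0.s1 * tau)
    )
    if ospec.noise_sd > 0:
        height = height + rng.normal(0.0, ospec.noise_sd, height.shape)
    apv0, _ = pb1_apv_oracle(p0)
    # time runs as theta + tempo + (t - theta) e^-v, so each subject's
    # true APV is exactly:
    eff["true_apv"] = p0.theta + eff["tempo"] + (apv0 - p0.theta) * np.exp(
        -eff["velocity"]
    )
    df = _long_rows(spec, ospec, ids, ages, height, rng)
    truth = TrueEffects(latent_timing=latent, effects={"height": eff},
                        mean_apv={"height": apv0})
    return LongSeries(df), truth


def sample_igf1_cohort(spec: CohortSpec | None = None,
                       seed: int = DEFAULT_SEED,
                       latent: pd.Series | None = None,
                       subsample: bool = True):
    """IGF-1 cohort (blood subsample): double-logistic mean on the sqrt
    scale, SITAR-style subject effects, lognormal assay noise (CV 12%)."""
    spec = spec or default_cohort_spec()
    ospec = spec.outcome("igf1")
    curve = mean_igf1_curve(spec.sex, ospec.apv_target)
    return _continuous_cohort(spec, "igf1", curve, ospec.apv_target, seed,
                              latent, subsample)


def sample_steroid_cohort(spec: CohortSpec | None = None,
                          seed: int = DEFAULT_SEED,
                          latent: pd.Series | None = None,
                          subsample: bool = True):
    """Sex-steroid cohort: single logistic on the log scale (levels keep
    rising into adulthood), assay noise CV < 10%, plus extra
    post-APV variability for girls (menstrual cycle)."""
    spec = spec or default_cohort_spec()
    name = "testosterone" if spec.sex == "M" else "oestradiol"
    ospec = spec.outcome(name)
    curve = mean_steroid_curve(name, ospec.apv_target)
    return _continuous_cohort(spec, name, curve, ospec.apv_target, seed,
                              latent, subsample)


def sample_stage_cohort(spec: CohortSpec | None = None,
                        seed: int = DEFAULT_SEED,
                        latent: pd.Series | None = None,
                        measure: str | None = None):
    """Tanner stages: latent logistic from 1 to 5 in
    (t - m - tempo) exp(velocity), plus Gaussian rater noise, rounded
    and clamped to {1..5}."""
    spec = spec or default_cohort_spec()
    measures = ([spec.stage(measure)] if measure is not None
                else list(spec.stage_measures))
    rng = np.random.default_rng(seed)
    if latent is None:
        latent = _draw_latent(spec, rng)
    ids = np.asarray(latent.index)
    frames = []
    effects = {}
    mean_apv = {}
    for sspec in measures:
        eff = _draw_effects(sspec, latent, spec.latent_timing_sd, rng)
        ages = _visit_ages(spec, rng, len(ids))
        tempo = eff["tempo"].to_numpy()[:, None]
        vel = eff["velocity"].to_numpy()[:, None]
        eta = sspec.rate * np.exp(vel) * (ages - sspec.midpoint_age - tempo)
        stage_latent = 1.0 + 4.0 / (1.0 + np.exp(-eta))
        noisy = stage_latent + rng.normal(0.0, sspec.rater_noise_sd,
                                          stage_latent.shape)
        observed = np.clip(np.rint(noisy), 1, 5).astype(int)
        n, m = observed.shape
        keep = np.ones((n, m), dtype=bool)
        if spec.missingness > 0:
            keep = rng.uniform(size=(n, m)) >= spec.missingness
        df = pd.DataFrame({
            "subject_id": np.repeat(ids, m),
            "sex": spec.sex,
            "age": ages.ravel(),
            "measure": sspec.measure,
            "stage": observed.ravel(),
        })
        frames.append(df[keep.ravel()])
        key = f"stage_{sspec.measure}"
        eff["true_apv"] = sspec.midpoint_age + eff["tempo"]
        effects[key] = eff
        mean_apv[key] = sspec.midpoint_age
    truth = TrueEffects(latent_timing=latent, effects=effects,
                        mean_apv=mean_apv)
    return StageSeries(pd.concat(frames, ignore_index=True)), truth


def sample_full_cohort(spec: CohortSpec | None = None,
                       seed: int = DEFAULT_SEED) -> SimulatedCohort:
    """All outcomes for one sex, sharing a single latent timing T_i per
    subject so the tempo effects are correlated across outcomes
    (corr = lambda_1 lambda_2); hormone outcomes restricted to the
    blood subsample."""
    spec = spec or default_cohort_spec()
    seeds = np.random.SeedSequence(seed).generate_state(5)
    rng = np.random.default_rng(int(seeds[0]) % 2**31)
    latent = _draw_latent(spec, rng)
    height, t_h = sample_height_cohort(spec, int(seeds[1]) % 2**31, latent)
    igf1, t_i = sample_igf1_cohort(spec, int(seeds[2]) % 2**31, latent)
    steroid, t_s = sample_steroid_cohort(spec, int(seeds[3]) % 2**31, latent)
    stages, t_t = sample_stage_cohort(spec, int(seeds[4]) % 2**31, latent)
    long = LongSeries(pd.concat([height.df, igf1.df, steroid.df],
                                ignore_index=True))
    truth = t_h.merge(t_i).merge(t_s).merge(t_t)
    return SimulatedCohort(long=long, stages=stages, truth=truth)
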