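"""Curve metrics: back-transforms, peak extraction, individual timing
and the bootstrap SE."""

import numpy as np
import pandas as pd
import pytest

from conftest import make_synthetic_fit
from pysitar import LongSeries, SitarSpec
from pysitar.basis import build_spline_basis
from pysitar.metrics import (
    BoundaryPeakWarning,
    age_at_peak_level,
    age_at_peak_velocity,
    back_transform_curve,
    bootstrap_apv_se,
    individual_apv_remaximized,
    individual_timings,
    value_at_age,
)
from pysitar.simulate import mean_height_curve, pb1_apv_oracle, pb1_height


def _ols_fit(ages, values, df, transform="identity", age_center=0.0):
    """Build a synthetic results object from a pooled OLS spline fit."""
    x = ages - age_center
    basis = build_spline_basis(x, df)
    D = np.column_stack([np.ones(x.size), basis.design(x)])
    theta, *_ = np.linalg.lstsq(D, values, rcond=None)
    return make_synthetic_fit(basis.knots, theta[1:], theta[0],
                              transform=transform, age_center=age_center)


# -- back-transform identities ---------------------------------------------


def test_identity_level_equals_spline():
    fit = make_synthetic_fit([0.0, 1.0, 2.0], [1.0, 0.0], 5.0)
    curve = back_transform_curve(fit, grid=np.linspace(0, 2, 21))
    np.testing.assert_allclose(curve.values, fit.spline(curve.ages))


def test_log_constant_curve():
    fit = make_synthetic_fit([0.0, 1.0, 2.0], [0.0, 0.0], 2.0,
                             transform="log")
    curve = back_transform_curve(fit, grid=np.linspace(0, 2, 11))
    np.testing.assert_allclose(curve.values, np.exp(2.0))
    vel = back_transform_curve(fit, grid=curve.ages, scale="velocity")
    np.testing.assert_allclose(vel.values, 0.0, atol=1e-12)


def test_sqrt_chain_rule():
    """h(t) = t on [1, 2] with a sqrt transform: level t^2, velocity 2t."""
    fit = make_synthetic_fit([1.0, 1.5, 2.0], [1.0, 0.0], 0.0,
                             transform="sqrt")
    grid = np.linspace(1.0, 2.0, 11)
    level = back_transform_curve(fit, grid=grid)
    vel = back_transform_curve(fit, grid=grid, scale="velocity")
    np.testing.assert_allclose(level.values, grid**2, rtol=1e-12)
    np.testing.assert_allclose(vel.values, 2 * grid, rtol=1e-12)


# -- peak extraction -------------------------------------------------------


def test_logistic_apv_at_midpoint():
    """A logistic level curve's velocity peaks at the midpoint."""
    ages = np.linspace(8.5, 16, 200)
    m, k, L = 12.5, 1.3, 170.0
    y = 110 + 60 / (1 + np.exp(-k * (ages - m)))
    fit = _ols_fit(ages, y, df=8)
    apv, pv = age_at_peak_velocity(fit)
    assert apv == pytest.approx(m, abs=0.05)
    assert pv == pytest.approx(60 * k / 4, rel=0.05)


def test_pb1_apv_matches_grid_oracle():
    """Noiseless PB1 mean curve fit with ample df: APV within 0.05 y
    of the brute-force derivative oracle."""
    p = mean_height_curve("M", 13.9)
    apv0, phv0 = pb1_apv_oracle(p)
    ages = np.linspace(8.5, 16.0, 400)
    fit = _ols_fit(ages, pb1_height(ages, p), df=6, age_center=12.25)
    apv, phv = age_at_peak_velocity(fit)
    assert apv == pytest.approx(apv0, abs=0.05)
    assert phv == pytest.approx(phv0, rel=0.05)


def test_concave_parabola_peak_level():
    ages = np.linspace(8.5, 16, 200)
    y = 100 - (ages - 12.0) ** 2
    fit = _ols_fit(ages, y, df=6)
    peak = age_at_peak_level(fit)
    assert not peak.at_boundary
    assert peak.age == pytest.approx(12.0, abs=0.05)


def test_monotone_curve_flags_boundary():
    ages = np.linspace(8.5, 16, 100)
    fit = _ols_fit(ages, 2.0 + 0.3 * ages, df=4)
    with pytest.warns(BoundaryPeakWarning):
        peak = age_at_peak_level(fit)
    assert peak.at_boundary


# -- individual timing -----------------------------------------------------


def _fit_with_effects(effects):
    return make_synthetic_fit(
        [-3.75, -2.25, -0.25, 1.75, 3.75],
        [8.0, -1.0, -14.0, 9.0], 130.0,
        age_center=12.25, subject_effects=effects,
    )


def test_individual_timings_zero_tempo():
    fit = _fit_with_effects({f"s{i}": {"size": 0.0, "tempo": 0.0,
                                       "velocity": 0.0} for i in range(5)})
    ts = individual_timings(fit, apv_mean=13.5)
    assert ts.apv_sd == 0.0
    assert (ts.individual_apv == 13.5).all()


def test_individual_timings_spread():
    fit = _fit_with_effects({
        "a": {"size": 0.0, "tempo": -1.0, "velocity": 0.0},
        "b": {"size": 0.0, "tempo": 0.0, "velocity": 0.0},
        "c": {"size": 0.0, "tempo": 1.0, "velocity": 0.0},
    })
    ts = individual_timings(fit, apv_mean=13.0)
    assert ts.apv_sd == pytest.approx(1.0)
    assert list(ts.individual_apv) == [12.0, 13.0, 14.0]


def test_remaximized_apv_tempo_and_velocity_shifts():
    """Tempo adds delta to a subject's APV; velocity rescales the
    distance from the centring age."""
    fit = _fit_with_effects({
        "base": {"size": 0.0, "tempo": 0.0, "velocity": 0.0},
        "late": {"size": 0.0, "tempo": 0.7, "velocity": 0.0},
        "fast": {"size": 0.0, "tempo": 0.0, "velocity": np.log(2)},
    })
    remax = individual_apv_remaximized(fit)
    apv0 = remax["base"]
    assert remax["late"] == pytest.approx(apv0 + 0.7, abs=1e-9)
    assert remax["fast"] - fit.age_center == pytest.approx(
        (apv0 - fit.age_center) / 2, abs=1e-9
    )


def test_value_at_age_identities():
    effects = {
        "zero": {"size": 0.0, "tempo": 0.0, "velocity": 0.0},
        "big": {"size": 0.5, "tempo": 0.0, "velocity": 0.0},
    }
    # knots on the centred-age scale
    fit = make_synthetic_fit([-3.75, -1.25, 1.25, 3.75],
                             [0.2, 0.05, -0.3], 4.0,
                             age_center=12.25, transform="log",
                             subject_effects=effects)
    v0 = value_at_age(fit, "zero", 12.0)
    v1 = value_at_age(fit, "big", 12.0)
    assert v1 / v0 == pytest.approx(np.exp(0.5), rel=1e-10)
    with pytest.raises(KeyError):
        value_at_age(fit, "nobody", 12.0)


# -- bootstrap -------------------------------------------------------------


def test_bootstrap_requires_enough_replicates(height_cohort):
    data, _ = height_cohort
    with pytest.raises(ValueError):
        bootstrap_apv_se(data, SitarSpec(df=5), n_boot=10)


def test_bootstrap_identical_subjects_gives_near_zero_se(height_fit):
    """All subjects identical (one subject's curve cloned): resampling
    cannot change the fit, so the SE collapses."""
    p = mean_height_curve("M", 13.9)
    rng = np.random.default_rng(0)
    rows = []
    ages = np.arange(8.5, 16.01, 0.5)
    base = pb1_height(ages, p)
    for i in range(10):
        jit = rng.normal(0, 0.05, ages.size)  # tiny independent noise
        for a, v in zip(ages, base + jit):
            rows.append({"subject_id": f"s{i}", "sex": "M", "age": a,
                         "outcome": "height", "value": v})
    data = LongSeries(pd.DataFrame(rows))
    spec = SitarSpec(df=5, random_effects=("size", "tempo"))
    se = bootstrap_apv_se(data, spec, n_boot=50, seed=3)
    assert 0 <= se < 0.05
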