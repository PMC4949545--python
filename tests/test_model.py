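"""SITAR model: prediction identities, estimation equivariance,
variance explained, and parameter recovery on generator cohorts."""

import numpy as np
import pandas as pd
import pytest

from pysitar import (
    LongSeries,
    RandomEffects,
    SitarModel,
    SitarSpec,
    crosssectional_fit,
    fit_sitar,
    sample_height_cohort,
    variance_explained,
)
from pysitar.model import ExtrapolationError
from pysitar.simulate import CohortSpec, OutcomeSpec, default_cohort_spec


# -- prediction identities -------------------------------------------------


def test_zero_effects_reproduce_mean_curve(height_fit):
    ages = np.linspace(9.5, 15.5, 40)
    mu = height_fit.predict_transformed(ages)
    mu2 = height_fit.predict_transformed(ages, RandomEffects())
    np.testing.assert_allclose(mu, mu2)


def test_tempo_is_pure_translation(height_fit):
    ages = np.linspace(10.5, 15.0, 25)
    shifted = height_fit.predict_transformed(ages, RandomEffects(tempo=1.0))
    base = height_fit.predict_transformed(ages - 1.0)
    np.testing.assert_allclose(shifted, base, rtol=1e-12)


def test_velocity_is_pure_time_scaling(height_fit):
    c = height_fit.age_center
    u = np.linspace(0.2, 2.5, 15)
    scaled = height_fit.predict_transformed(
        c + u / 2, RandomEffects(velocity=np.log(2.0))
    )
    base = height_fit.predict_transformed(c + u)
    np.testing.assert_allclose(scaled, base, rtol=1e-10)


def test_size_shifts_vertically(height_fit):
    ages = np.linspace(10, 15, 10)
    up = height_fit.predict_transformed(ages, RandomEffects(size=3.0))
    base = height_fit.predict_transformed(ages)
    np.testing.assert_allclose(up - base, 3.0, rtol=1e-12)


def test_extrapolation_guard(height_fit):
    lo, hi = height_fit.guard_band()
    with pytest.raises(ExtrapolationError):
        height_fit.predict_transformed([hi + 1.0])
    # explicit opt-in works
    height_fit.predict_transformed([hi + 1.0], allow_extrapolation=True)


# -- equivariance ----------------------------------------------------------

def _small_cohort(seed=3):
    spec = default_cohort_spec("M")
    spec = CohortSpec(sex="M", n_subjects=12, n_hormone_subsample=8,
                      outcomes=spec.outcomes, stage_measures=spec.stage_measures)
    return sample_height_cohort(spec, seed=seed)


def test_age_translation_equivariance():
    """Shifting all ages and the centring age by the same amount leaves
    the fit unchanged."""
    data, _ = _small_cohort()
    spec = SitarSpec(df=4, age_center=12.25)
    res1 = fit_sitar(data, spec, refresh_knots=False)

    df2 = data.df.copy()
    df2["age"] = df2["age"] + 2.0
    data2 = LongSeries(df2, age_window=(10.0, 18.5))
    res2 = fit_sitar(data2, SitarSpec(df=4, age_center=14.25),
                     refresh_knots=False)
    assert res2.loglik == pytest.approx(res1.loglik, abs=1e-4)
    np.testing.assert_allclose(res2.ranef.to_numpy(), res1.ranef.to_numpy(),
                               atol=1e-4)


def test_constant_response_shift_moves_only_intercept():
    data, _ = _small_cohort()
    spec = SitarSpec(df=4, age_center=12.25)
    res1 = fit_sitar(data, spec, refresh_knots=False)
    df2 = data.df.copy()
    df2["value"] = df2["value"] + 25.0
    res2 = fit_sitar(LongSeries(df2), spec, refresh_knots=False)
    assert res2.spline.intercept - res1.spline.intercept == pytest.approx(
        25.0, abs=0.05
    )
    assert res2.sigma == pytest.approx(res1.sigma, rel=0.01)


# -- degenerate / null cases ----------------------------------------------


def test_null_tempo_velocity_variance_recovered():
    """Data simulated without tempo/velocity variation: their fitted
    SDs collapse (or the effects are dropped)."""
    base = default_cohort_spec("M")
    height = base.outcome("height")
    null_spec = CohortSpec(
        sex="M", n_subjects=20, n_hormone_subsample=8,
        outcomes=(OutcomeSpec("height", "identity", tempo_sd=0.0,
                              size_sd=2.5, velocity_sd=0.0,
                              loading=height.loading, noise_sd=0.3,
                              apv_target=13.9),),
        stage_measures=base.stage_measures,
    )
    data, _ = sample_height_cohort(null_spec, seed=4)
    res = fit_sitar(data, SitarSpec(df=4), refresh_knots=False)
    kept = res.spec.random_effects
    sds = dict(zip(kept, np.sqrt(np.diag(res.Sigma.to_numpy()))))
    size_sd = sds.get("size", 0.0)
    for e in ("tempo", "velocity"):
        assert e not in kept or sds[e] < 0.1 * size_sd


def test_too_few_subjects_rejected():
    data, _ = _small_cohort()
    few = data.df[data.df["subject_id"].isin(data.subjects[:4])]
    with pytest.raises(Exception):
        SitarModel(LongSeries(few), SitarSpec(df=4))


# -- variance explained ----------------------------------------------------


@pytest.mark.parametrize(
    "pair, expected",
    [((0.6, 7.4), 0.99343), ((0.5, 5.8), 0.99257)],
)
def test_variance_explained_study_values(pair, expected):
    ve = variance_explained(*pair)
    assert ve == pytest.approx(expected, abs=1e-5)
    assert ve > 0.99


def test_variance_explained_edges():
    assert variance_explained(2.0, 2.0) == 0.0
    with pytest.raises(ValueError):
        variance_explained(-1.0, 2.0)
    with pytest.warns(UserWarning):
        assert variance_explained(3.0, 2.0) == 0.0


def test_crosssectional_exact_spline_data_gives_zero_residual():
    rng = np.random.default_rng(0)
    ages = np.linspace(8.5, 16, 16)
    rows = []
    for i in range(10):
        y = 100 + 4 * ages + 0.3 * (ages - 12) ** 2
        for a, v in zip(ages + rng.uniform(-0.01, 0.01, ages.size), y):
            rows.append({"subject_id": f"s{i}", "sex": "M", "age": a,
                         "outcome": "height", "value": v})
    sd = crosssectional_fit(LongSeries(pd.DataFrame(rows)), SitarSpec(df=4))
    assert sd < 0.05


def test_crosssectional_noise_recovery_chi_square():
    """200 points on a curve plus N(0, 2) noise: residual SD inside the
    chi-square interval around 2."""
    rng = np.random.default_rng(12)
    rows = []
    for i in range(20):
        ages = np.sort(rng.uniform(8.2, 16.3, 10))
        y = 120 + 3 * ages + rng.normal(0, 2.0, 10)
        for a, v in zip(ages, y):
            rows.append({"subject_id": f"s{i}", "sex": "M", "age": a,
                         "outcome": "height", "value": v})
    sd = crosssectional_fit(LongSeries(pd.DataFrame(rows)), SitarSpec(df=3))
    assert 1.7 <= sd <= 2.3


def test_crosssectional_scale_on_generator_cohort(height_cohort, height_fit):
    """Pooled residual SD is centimetres-scale (5-10 cm), an order of
    magnitude above the SITAR residual SD."""
    data, _ = height_cohort
    sd = crosssectional_fit(data, SitarSpec(df=5))
    assert 5.0 <= sd <= 10.0
    assert sd > 10 * height_fit.sigma


# -- recovery on the shared fit -------------------------------------------


def test_tempo_recovery_and_sd_calibration(height_cohort, height_fit):
    data, truth = height_cohort
    e = truth.effects["height"]
    r = np.corrcoef(e["tempo"], height_fit.ranef["tempo"])[0, 1]
    assert r >= 0.95
    sds = np.sqrt(np.diag(height_fit.Sigma.to_numpy()))
    true_sds = [e["size"].std(), e["tempo"].std(), e["velocity"].std()]
    for est, tru in zip(sds, true_sds):
        assert abs(est - tru) / tru < 0.20


def test_random_effects_are_centred(height_fit):
    means = height_fit.ranef.mean()
    sds = height_fit.ranef.std()
    for e in height_fit.spec.random_effects:
        assert abs(means[e]) < 0.1 * sds[e]


def test_summary_mentions_key_quantities(height_fit):
    text = height_fit.summary()
    assert "Variance explained" in text
    assert "tempo" in text
    assert "Residual SD" in text
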