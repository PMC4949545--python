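"""Synthetic cohort generator: curve-family identities, calibration
closure against the grid oracles, and determinism."""

import numpy as np
import pandas as pd
import pytest
from dataclasses import replace

from pysitar import (
    pb1_apv_oracle,
    pb1_height,
    pb1_velocity,
    sample_full_cohort,
    sample_height_cohort,
    sample_stage_cohort,
)
from pysitar.simulate import (
    CohortSpec,
    DoubleLogistic,
    OutcomeSpec,
    PB1Params,
    default_cohort_spec,
    grid_peak,
    mean_height_curve,
    mean_igf1_curve,
    mean_steroid_curve,
    _natural_level,
    _natural_velocity,
)

P_BOYS = PB1Params(h1=175.0, h_theta=161.0, theta=14.3, s0=0.1124, s1=1.2397)


# -- PB1 identities --------------------------------------------------------


def test_pb1_height_at_theta():
    assert pb1_height(P_BOYS.theta, P_BOYS) == pytest.approx(P_BOYS.h_theta)


def test_pb1_monotone_and_adult_limit():
    t = np.linspace(2, 30, 500)
    h = pb1_height(t, P_BOYS)
    assert (np.diff(h) > 0).all()
    assert pb1_height(80.0, P_BOYS) == pytest.approx(P_BOYS.h1, abs=1e-6)


def test_pb1_invalid_parameters():
    with pytest.raises(ValueError):
        PB1Params(h1=170, h_theta=160, theta=14, s0=1.0, s1=0.5)
    with pytest.raises(ValueError):
        PB1Params(h1=150, h_theta=160, theta=14, s0=0.1, s1=1.0)


def test_pb1_velocity_matches_finite_difference():
    t = np.linspace(9, 17, 50)
    h = 1e-6
    fd = (pb1_height(t + h, P_BOYS) - pb1_height(t - h, P_BOYS)) / (2 * h)
    np.testing.assert_allclose(pb1_velocity(t, P_BOYS), fd, rtol=1e-6)


def test_pb1_apv_oracle_logistic_limit():
    """As s0 -> 0 the PB1 curve degenerates to a symmetric logistic
    whose velocity peaks exactly at theta."""
    p = PB1Params(h1=175, h_theta=160, theta=13.0, s0=1e-8, s1=1.2)
    apv, phv = pb1_apv_oracle(p)
    assert apv == pytest.approx(13.0, abs=0.002)
    # logistic peak velocity: 2 (h1 - h_theta) s1 / 4
    assert phv == pytest.approx(2 * 15 * 1.2 / 4, rel=1e-3)


def test_pb1_apv_translates_with_theta():
    p2 = replace(P_BOYS, theta=P_BOYS.theta + 1.0)
    apv1, phv1 = pb1_apv_oracle(P_BOYS)
    apv2, phv2 = pb1_apv_oracle(p2)
    assert apv2 - apv1 == pytest.approx(1.0, abs=0.005)
    assert phv2 == pytest.approx(phv1, rel=1e-6)


# -- calibration closure ---------------------------------------------------


@pytest.mark.parametrize("sex, apv, phv", [("M", 13.9, 9.9), ("F", 12.3, 8.0)])
def test_height_defaults_hit_targets(sex, apv, phv):
    p = mean_height_curve(sex, apv)
    apv_hat, phv_hat = pb1_apv_oracle(p)
    assert apv_hat == pytest.approx(apv, abs=0.05)
    assert phv_hat == pytest.approx(phv, abs=0.05)


@pytest.mark.parametrize("sex, apv, peak", [("M", 13.2, 14.5), ("F", 12.0, 13.8)])
def test_igf1_defaults_hit_targets(sex, apv, peak):
    c = mean_igf1_curve(sex, apv)
    apv_hat, _, b1 = grid_peak(_natural_velocity(c, "sqrt"), 6, 20)
    peak_hat, _, b2 = grid_peak(_natural_level(c, "sqrt"), 6, 20)
    assert not b1 and not b2
    assert apv_hat == pytest.approx(apv, abs=0.05)
    assert peak_hat == pytest.approx(peak, abs=0.05)


@pytest.mark.parametrize("name, apv", [("testosterone", 13.5), ("oestradiol", 12.7)])
def test_steroid_defaults_hit_targets(name, apv):
    c = mean_steroid_curve(name, apv)
    apv_hat, _, _ = grid_peak(_natural_velocity(c, "log"), 6, 24)
    assert apv_hat == pytest.approx(apv, abs=0.05)
    # level keeps rising through the visit window
    t = np.linspace(8.5, 16.0, 100)
    assert (np.diff(_natural_level(c, "log")(t)) > 0).all()


def test_girls_earlier_than_boys_everywhere():
    """Every outcome's calibrated APV is earlier in girls; the height
    gap is 1.6 years."""
    for getter in (lambda s: s.outcome("height").apv_target,
                   lambda s: s.outcome("igf1").apv_target):
        assert getter(default_cohort_spec("F")) < getter(default_cohort_spec("M"))
    boys, girls = default_cohort_spec("M"), default_cohort_spec("F")
    assert boys.outcome("height").apv_target - girls.outcome("height").apv_target \
        == pytest.approx(1.6)
    assert girls.stage("pubic_hair").midpoint_age < boys.stage("pubic_hair").midpoint_age


def test_double_logistic_without_decline_is_monotone():
    c = DoubleLogistic(b=12, A=10, k1=1.5, m1=12.0, D=0.0, k2=1.0, m2=13.0)
    t = np.linspace(6, 20, 200)
    assert (c.deriv(t) > 0).all()
    _, _, at_boundary = grid_peak(_natural_level(c, "sqrt"), 6, 20)
    assert at_boundary


def test_double_logistic_shape_validation():
    with pytest.raises(ValueError):
        DoubleLogistic(b=12, A=10, k1=1.5, m1=13.0, D=2.0, k2=1.0, m2=12.0)


# -- cohort sampling -------------------------------------------------------


def test_height_cohort_determinism(boys_spec):
    d1, t1 = sample_height_cohort(boys_spec, seed=99)
    d2, t2 = sample_height_cohort(boys_spec, seed=99)
    pd.testing.assert_frame_equal(d1.df, d2.df)
    pd.testing.assert_series_equal(t1.latent_timing, t2.latent_timing)
    d3, _ = sample_height_cohort(boys_spec, seed=100)
    assert not d1.df["value"].equals(d3.df["value"])


def test_full_cohort_determinism(boys_spec):
    c1 = sample_full_cohort(boys_spec, seed=5)
    c2 = sample_full_cohort(boys_spec, seed=5)
    pd.testing.assert_frame_equal(c1.long.df, c2.long.df)
    pd.testing.assert_frame_equal(c1.stages.df, c2.stages.df)


def test_cohort_counts_and_subsample(boys_spec):
    cohort = sample_full_cohort(boys_spec, seed=2)
    counts = cohort.long.df.groupby("outcome")["subject_id"].nunique()
    assert counts["height"] == 54
    assert counts["igf1"] == 24
    assert counts["testosterone"] == 24
    assert set(cohort.long.df.query("outcome == 'igf1'")["subject_id"]) \
        <= set(cohort.long.df.query("outcome == 'height'")["subject_id"])


def test_height_true_apv_calibration(boys_spec):
    """Cohort-level truth: mean true APV hits the calibrated target
    (moment-matched draws) and its SD tracks the tempo SD."""
    _, truth = sample_height_cohort(boys_spec, seed=3)
    e = truth.effects["height"]
    assert e["true_apv"].mean() == pytest.approx(13.9, abs=0.05)
    assert 0.75 <= e["true_apv"].std() <= 1.2
    assert e["tempo"].mean() == pytest.approx(0.0, abs=1e-12)


def test_stage_values_always_valid(boys_spec):
    noisy = replace(
        boys_spec,
        stage_measures=tuple(replace(s, rater_noise_sd=3.0)
                             for s in boys_spec.stage_measures),
    )
    data, _ = sample_stage_cohort(noisy, seed=1)
    assert data.df["stage"].between(1, 5).all()


def test_stage_noiseless_steps(boys_spec):
    quiet = replace(
        boys_spec,
        stage_measures=(replace(boys_spec.stage("genitalia"),
                                rater_noise_sd=0.0, rate=50.0),),
    )
    data, _ = sample_stage_cohort(quiet, seed=1, measure="genitalia")
    per_subject = data.df.groupby("subject_id")["stage"]
    assert (per_subject.min() == 1).all()
    assert (per_subject.max() == 5).all()
    # noise-free steep curves never regress
    assert data.n_regressions == 0


def test_loading_extremes(boys_spec):
    """lambda = 1 with no jitter gives perfectly correlated timing;
    lambda = 0 decouples the outcomes."""
    unit = replace(
        boys_spec,
        outcomes=tuple(replace(o, loading=1.0) for o in boys_spec.outcomes),
    )
    cohort = sample_full_cohort(unit, seed=8)
    th = cohort.truth.tempo("height") / boys_spec.outcome("height").tempo_sd
    tt = cohort.truth.tempo("testosterone") / boys_spec.outcome("testosterone").tempo_sd
    r = np.corrcoef(th.loc[tt.index], tt)[0, 1]
    assert r == pytest.approx(1.0, abs=1e-10)

    null = replace(
        boys_spec,
        outcomes=tuple(replace(o, loading=0.0) for o in boys_spec.outcomes),
    )
    rs = []
    for seed in range(8):
        cohort = sample_full_cohort(null, seed=seed)
        tt = cohort.truth.tempo("testosterone")
        th = cohort.truth.tempo("height").loc[tt.index]
        rs.append(np.corrcoef(th, tt)[0, 1])
    assert abs(np.mean(rs)) < 2 / np.sqrt(24 * 8)


def test_invalid_cohort_specs():
    with pytest.raises(ValueError):
        CohortSpec(sex="X")
    with pytest.raises(ValueError):
        CohortSpec(visit_start=7.0)
    with pytest.raises(ValueError):
        OutcomeSpec("h", "identity", tempo_sd=1, size_sd=1, velocity_sd=0.1,
                    loading=1.5)


def test_generated_data_pass_container_validation(boys_spec):
    """LongSeries/StageSeries invariants hold without repair."""
    cohort = sample_full_cohort(boys_spec, seed=4)  # constructors validate
    assert len(cohort.long) > 0 and len(cohort.stages) > 0
    assert (cohort.long.df["value"] > 0).all()
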