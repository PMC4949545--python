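"""Shared fixtures: synthetic cohorts and fitted models are expensive,
so one fit of each kind is shared session-wide."""

import pytest

from pysitar import (
    SitarSpec,
    fit_sitar,
    fit_stage_model,
    sample_full_cohort,
    sample_height_cohort,
    sample_igf1_cohort,
    sample_stage_cohort,
)
from pysitar.simulate import default_cohort_spec


@pytest.fixture(scope="session")
def boys_spec():
    return default_cohort_spec("M")


@pytest.fixture(scope="session")
def height_cohort(boys_spec):
    return sample_height_cohort(boys_spec, seed=1)


@pytest.fixture(scope="session")
def height_fit(height_cohort):
    data, _ = height_cohort
    return fit_sitar(data, SitarSpec(df=5))


@pytest.fixture(scope="session")
def igf1_cohort(boys_spec):
    return sample_igf1_cohort(boys_spec, seed=1)


@pytest.fixture(scope="session")
def igf1_fit(igf1_cohort):
    data, _ = igf1_cohort
    return fit_sitar(data, SitarSpec(df=3, transform="sqrt"))


@pytest.fixture(scope="session")
def stage_cohort(boys_spec):
    return sample_stage_cohort(boys_spec, seed=1, measure="genitalia")


@pytest.fixture(scope="session")
def stage_fit(stage_cohort):
    data, _ = stage_cohort
    return fit_stage_model(data)


@pytest.fixture(scope="session")
def full_cohort_fits(boys_spec):
    """Boys' multi-outcome cohort with height and IGF-1 SITAR fits."""
    cohort = sample_full_cohort(boys_spec, seed=1)
    fits = {
        "height": fit_sitar(cohort.long.select(outcome="height"),
                            SitarSpec(df=5)),
        "igf1": fit_sitar(cohort.long.select(outcome="igf1"),
                          SitarSpec(df=3, transform="sqrt")),
    }
    return cohort, fits


def make_synthetic_fit(knots, coef, intercept, transform="identity",
                       age_center=0.0, subject_effects=None,
                       random_effects=("size", "tempo", "velocity"),
                       sigma=0.1, cross_sd=1.0):
    """A SitarResults with a hand-chosen spline, for metric identities
    (synthetic: not produced by an actual fit)."""
    from pysitar.serialize import fit_from_json

    coef = list(map(float, coef))
    df = len(coef)
    q = len(random_effects)
    payload = {
        "format_version": 1,
        "kind": "sitar",
        "outcome": "synthetic",
        "spec": {
            "df": df,
            "transform": transform,
            "random_effects": list(random_effects),
            "age_center": age_center,
            "min_obs_per_subject": 4,
        },
        "knots": list(map(float, knots)),
        "intercept": float(intercept),
        "coef": coef,
        "re_covariance_lower": [[1.0 if i == j else 0.0 for j in range(i + 1)]
                                for i in range(q)],
        "residual_sd": sigma,
        "crosssectional_resid_sd": cross_sd,
        "loglik": 0.0,
        "converged": True,
        "n_subjects": len(subject_effects or {"s1": {}}),
        "n_obs": 0,
        "n_excluded": 0,
        "subject_effects": subject_effects or
        {"s1": {e: 0.0 for e in random_effects}},
    }
    return fit_from_json(payload)
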