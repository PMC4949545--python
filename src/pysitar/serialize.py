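"""JSON round-tripping of fitted models.

Fits are written as human-diffable JSON (schema-versioned via
``format_version``): spec, knots, spline coefficients, the
random-effect covariance as a lower-triangular list, residual SD,
per-subject effects keyed by subject id, log likelihood and
convergence diagnostics.  Reading back reconstructs a results object
whose predictions match the original to machine precision.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .basis import SplineModel
from .model import EFFECT_NAMES, SitarResults, SitarSpec
from .stages import STAGE_EFFECTS, StageResults

__all__ = ["fit_to_json", "fit_from_json", "stage_fit_to_json"]

FORMAT_VERSION = 1


def _lower_triangular(mat: np.ndarray) -> list[list[float]]:
    return [[float(mat[i, j]) for j in range(i + 1)] for i in range(mat.shape[0])]


def _from_lower_triangular(tri: list[list[float]]) -> np.ndarray:
    q = len(tri)
    m = np.zeros((q, q))
    for i, row in enumerate(tri):
        for j, v in enumerate(row):
            m[i, j] = m[j, i] = v
    return m


def fit_to_json(fit: SitarResults, path=None):
    """Serialize a SITAR fit; returns the dict, optionally writing it."""
    payload = {
        "format_version": FORMAT_VERSION,
        "kind": "sitar",
        "outcome": fit.outcome,
        "spec": {
            "df": fit.spec.df,
            "transform": fit.spec.transform,
            "random_effects": list(fit.spec.random_effects),
            "age_center": fit.age_center,
            "min_obs_per_subject": fit.spec.min_obs_per_subject,
        },
        "knots": fit.spline.knots.tolist(),
        "intercept": fit.spline.intercept,
        "coef": fit.spline.coef.tolist(),
        "re_covariance_lower": _lower_triangular(fit.Sigma.to_numpy()),
        "residual_sd": fit.sigma,
        "crosssectional_resid_sd": fit.cross_sd,
        "loglik": fit.loglik,
        "converged": fit.converged,
        "n_subjects": fit.n_subjects,
        "n_obs": fit.n_obs,
        "n_excluded": fit.n_excluded,
        "age_range": list(getattr(fit, "age_range",
                                  fit.guard_band(margin=0.0))),
        "subject_effects": {
            str(sid): {e: float(fit.ranef.loc[sid, e])
                       for e in fit.spec.random_effects}
            for sid in fit.ranef.index
        },
    }
    if path is not None:
        Path(path).write_text(json.dumps(payload, indent=1))
    return payload


def fit_from_json(source) -> SitarResults:
    """Rebuild a :class:`SitarResults` from its JSON form.

    The reconstructed object predicts and yields metrics identically;
    it has no attached model/data, so it cannot be refit.
    """
    if isinstance(source, (str, Path)):
        payload = json.loads(Path(source).read_text())
    else:
        payload = source
    if payload.get("kind") != "sitar":
        raise ValueError(f"not a SITAR fit file: kind={payload.get('kind')!r}")
    spec = SitarSpec(
        df=payload["spec"]["df"],
        transform=payload["spec"]["transform"],
        random_effects=tuple(payload["spec"]["random_effects"]),
        age_center=payload["spec"]["age_center"],
        min_obs_per_subject=payload["spec"]["min_obs_per_subject"],
    )
    fit = SitarResults.__new__(SitarResults)
    fit.model = None
    fit.spec = spec
    fit.outcome = payload["outcome"]
    fit.age_center = float(payload["spec"]["age_center"])
    fit.spline = SplineModel(
        knots=np.array(payload["knots"]),
        coef=np.array(payload["coef"]),
        intercept=float(payload["intercept"]),
    )
    fit.Sigma = pd.DataFrame(
        _from_lower_triangular(payload["re_covariance_lower"]),
        index=spec.random_effects,
        columns=spec.random_effects,
    )
    fit.sigma = float(payload["residual_sd"])
    fit.cross_sd = float(payload["crosssectional_resid_sd"])
    fit.loglik = float(payload["loglik"])
    fit.converged = bool(payload["converged"])
    fit.n_outer_iter = -1
    if "age_range" in payload:
        fit.age_range = tuple(payload["age_range"])
    fit.n_subjects = int(payload["n_subjects"])
    fit.n_obs = int(payload["n_obs"])
    fit.n_excluded = int(payload["n_excluded"])
    ranef = pd.DataFrame(0.0, index=list(payload["subject_effects"]),
                         columns=EFFECT_NAMES)
    for sid, eff in payload["subject_effects"].items():
        for e, v in eff.items():
            ranef.loc[sid, e] = v
    ranef.index.name = "subject_id"
    fit.ranef = ranef
    return fit


def stage_fit_to_json(fit: StageResults, path=None):
    """Serialize an ordinal-stage fit."""
    payload = {
        "format_version": FORMAT_VERSION,
        "kind": "stage",
        "measure": fit.measure,
        "midpoint_age": fit.midpoint_age,
        "rate": fit.rate,
        "re_covariance_lower": _lower_triangular(fit.Sigma.to_numpy()),
        "residual_sd": fit.sigma,
        "crosssectional_resid_sd": fit.cross_sd,
        "loglik": fit.loglik,
        "converged": fit.converged,
        "n_subjects": fit.n_subjects,
        "n_obs": fit.n_obs,
        "subject_effects": {
            str(sid): {e: float(fit.ranef.loc[sid, e]) for e in STAGE_EFFECTS}
            for sid in fit.ranef.index
        },
    }
    if path is not None:
        Path(path).write_text(json.dumps(payload, indent=1))
    return payload
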