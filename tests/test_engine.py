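"""Laplace marginal likelihood against independent oracles.

The size-only model is linear in its single random effect, so the
Laplace approximation is exact and must match the closed-form Gaussian
marginal of a random-intercept model; low-dimensional toy problems are
checked against Gauss-Hermite quadrature."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import multivariate_normal
from numpy.polynomial.hermite_e import hermegauss

from pysitar import LongSeries, SitarSpec, marginal_loglik
from pysitar.basis import build_spline_basis
from pysitar.engine import (
    GroupedData,
    find_modes,
    laplace_loglik,
    pack_cov,
    unpack_cov,
)
from pysitar.model import SitarModel, _SplineSitarFamily


def _random_intercept_data(rng, n_subj=10, n_per=6, tau=1.5, sigma=0.4):
    """Toy cohort: spline-shaped mean + random intercept + noise."""
    rows = []
    for i in range(n_subj):
        ages = np.sort(rng.uniform(8.2, 16.3, n_per))
        alpha = rng.normal(0, tau)
        y = 100 + 3 * ages - 0.08 * (ages - 12) ** 3 + alpha \
            + rng.normal(0, sigma, n_per)
        for a, v in zip(ages, y):
            rows.append({"subject_id": f"s{i}", "sex": "M", "age": a,
                         "outcome": "height", "value": v})
    return LongSeries(pd.DataFrame(rows))


def _closed_form_random_intercept(model, theta, tau2, sigma):
    """Exact marginal: y_i ~ N(B_i theta, sigma^2 I + tau^2 11')."""
    g = model._grouped
    D = np.column_stack([np.ones(g.t.size), model.basis.design(g.t)])
    mean = D @ theta
    ll = 0.0
    for i in range(g.n_subjects):
        m = g.idx == i
        n_i = int(m.sum())
        cov = sigma**2 * np.eye(n_i) + tau2 * np.ones((n_i, n_i))
        ll += multivariate_normal.logpdf(g.y[m], mean[m], cov)
    return ll


@pytest.mark.parametrize("seed", range(20))
def test_size_only_laplace_equals_closed_form(seed):
    """Size-only SITAR is a linear random-intercept model, where the
    Laplace integral is exact."""
    rng = np.random.default_rng(seed)
    data = _random_intercept_data(rng)
    spec = SitarSpec(df=3, random_effects=("size",), min_obs_per_subject=3)
    model = SitarModel(data, spec)
    theta = rng.normal(0, 1, 4) + np.array([130.0, 3, 0, 0])
    tau = rng.uniform(0.5, 3.0)
    sigma = rng.uniform(0.2, 1.0)
    ll_laplace = marginal_loglik(data, spec, theta, [[tau**2]], sigma)
    ll_exact = _closed_form_random_intercept(model, theta, tau**2, sigma)
    assert ll_laplace == pytest.approx(ll_exact, rel=1e-6)


def test_zero_variance_prior_equals_fixed_effects_loglik():
    """With re_cov -> 0 the marginal collapses to the ordinary Gaussian
    likelihood of the pooled spline regression."""
    rng = np.random.default_rng(5)
    data = _random_intercept_data(rng, tau=0.0)
    spec = SitarSpec(df=3, random_effects=("size",), min_obs_per_subject=3)
    model = SitarModel(data, spec)
    g = model._grouped
    D = np.column_stack([np.ones(g.t.size), model.basis.design(g.t)])
    theta = np.linalg.lstsq(D, g.y, rcond=None)[0]
    sigma = 0.7
    resid = g.y - D @ theta
    ll_ols = float(
        -0.5 * g.t.size * np.log(2 * np.pi * sigma**2)
        - 0.5 * resid @ resid / sigma**2
    )
    ll = marginal_loglik(data, spec, theta, [[1e-14]], sigma)
    assert ll == pytest.approx(ll_ols, abs=1e-3)


def _gauss_hermite_loglik(family, fixed, Sigma, sigma, data, n_nodes=40):
    """Adaptive Gauss-Hermite oracle for a 1-subject toy: nodes centred
    on the posterior mode and scaled by its curvature."""
    q = family.q
    Sigma = np.atleast_2d(Sigma)
    Sigma_inv = np.linalg.inv(Sigma)
    b_hat, H, _, _ = find_modes(family, fixed, Sigma_inv, sigma**2, data)
    C = np.linalg.cholesky(np.linalg.inv(H[0]))
    logdetC = float(np.sum(np.log(np.diag(C))))
    nodes, weights = hermegauss(n_nodes)
    if q == 1:
        grid = nodes[:, None]
        w = weights
    else:
        g1, g2 = np.meshgrid(nodes, nodes)
        grid = np.column_stack([g1.ravel(), g2.ravel()])
        w = np.outer(weights, weights).ravel()
    prior_logdet = float(np.linalg.slogdet(Sigma)[1])
    vals = []
    for z, wi in zip(grid, w):
        b = b_hat[0] + C @ z
        f, _ = family.mean_and_jac(fixed, np.tile(b, (data.t.size, 1)),
                                   data.t)
        r = data.y - f
        h = (-0.5 * data.t.size * np.log(2 * np.pi * sigma**2)
             - 0.5 * r @ r / sigma**2
             - 0.5 * q * np.log(2 * np.pi) - 0.5 * prior_logdet
             - 0.5 * b @ Sigma_inv @ b)
        vals.append(np.log(wi) + h + 0.5 * z @ z + logdetC)
    vals = np.array(vals)
    m = vals.max()
    return float(m + np.log(np.exp(vals - m).sum()))


def test_laplace_close_to_quadrature_one_subject():
    """Nonlinear one-subject toy: Laplace within 1e-3 of Gauss-Hermite
    quadrature, and the log likelihood drops when sigma doubles."""
    rng = np.random.default_rng(7)
    t = np.linspace(-4, 4, 16)
    basis = build_spline_basis(t, df=4)
    family = _SplineSitarFamily(basis, ("size", "tempo"))
    theta = np.array([150.0, 4.0, 10.0, 6.0, 2.0])
    Sigma = np.diag([2.0**2, 0.5**2])
    f0, _ = family.mean_and_jac(theta, np.tile([1.2, -0.3], (t.size, 1)), t)
    y = f0 + rng.normal(0, 0.3, t.size)
    data = GroupedData(t=t, y=y, idx=np.zeros(t.size, dtype=int), n_subjects=1)

    ll_lap = laplace_loglik(family, theta, Sigma, 0.3, data)
    ll_qud = _gauss_hermite_loglik(family, theta, Sigma, 0.3, data)
    assert ll_lap == pytest.approx(ll_qud, abs=1e-3 * abs(ll_qud))

    ll_wide = laplace_loglik(family, theta, Sigma, 0.6, data)
    assert ll_wide < ll_lap


def test_pack_unpack_cov_roundtrip():
    rng = np.random.default_rng(11)
    for q in (1, 2, 3):
        A = rng.normal(size=(q, q))
        Sigma = A @ A.T + q * np.eye(q)
        L = unpack_cov(pack_cov(Sigma), q)
        np.testing.assert_allclose(L @ L.T, Sigma, rtol=1e-12)


def test_find_modes_solves_penalized_problem():
    """Modes satisfy the stationarity condition of the penalized
    least-squares objective."""
    rng = np.random.default_rng(2)
    t = np.tile(np.linspace(-4, 4, 10), 6)
    idx = np.repeat(np.arange(6), 10)
    basis = build_spline_basis(t, df=3)
    family = _SplineSitarFamily(basis, ("size", "tempo"))
    theta = np.array([100.0, 5.0, 8.0, 3.0])
    b_true = rng.normal(0, [2.0, 0.6], size=(6, 2))
    f, _ = family.mean_and_jac(theta, b_true[idx], t)
    y = f + rng.normal(0, 0.2, t.size)
    data = GroupedData(t=t, y=y, idx=idx, n_subjects=6)
    Sigma_inv = np.diag([1 / 4.0, 1 / 0.36])
    b, H, g, conv = find_modes(family, theta, Sigma_inv, 0.04, data)
    assert conv.all()
    f, J = family.mean_and_jac(theta, b[idx], t)
    r = y - f
    for i in range(6):
        m = idx == i
        grad = J[m].T @ r[m] / 0.04 - Sigma_inv @ b[i]
        # stationarity relative to the curvature scale
        scale = np.trace(H[i])
        np.testing.assert_allclose(grad / scale, 0.0, atol=1e-7)
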