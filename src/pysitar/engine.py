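"""Laplace-approximate maximum likelihood for curve models with
per-subject random effects.

The model is

    y_ij = f(theta, b_i; t_ij) + e_ij,   b_i ~ N(0, Sigma),  e ~ N(0, sigma^2)

with ``f`` supplied by a curve family (spline SITAR or logistic stage
curve).  The marginal likelihood integrates the b_i out; here that
integral is approximated by Laplace's method: an inner, per-subject
Gauss-Newton search for the posterior mode b_hat_i, and a second-order
expansion of the integrand around it.  The outer problem maximizes the
Laplace log likelihood jointly over the fixed parameters, the
log-Cholesky factor of Sigma and log sigma with L-BFGS-B; inner modes
are warm-started between outer evaluations (Lindstrom-Bates flavour).

Per-subject quantities are accumulated with bincount over a flat
observation array, so one likelihood evaluation is a handful of
vectorized passes regardless of the number of subjects.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Protocol

import numpy as np
from scipy import optimize
from scipy.linalg import solve_triangular

__all__ = [
    "CurveFamily",
    "GroupedData",
    "LaplaceResult",
    "laplace_loglik",
    "maximize_laplace",
    "pack_cov",
    "unpack_cov",
    "ConvergenceWarning",
]


class ConvergenceWarning(UserWarning):
    pass


class CurveFamily(Protocol):
    """Mean function f(theta, b; t) and its Jacobian in b."""

    n_fixed: int
    q: int

    def mean_and_jac(
        self, fixed: np.ndarray, b_obs: np.ndarray, t: np.ndarray
    ) -> tuple[np.ndarray, np.ndarray]:
        """Return (f, J): f shape (n_obs,), J shape (n_obs, q)."""
        ...


@dataclass
class GroupedData:
    """Flat observation arrays with a subject index.

    ``idx`` maps each observation to 0..n_subjects-1; ``t`` is the
    (centred) time axis the family expects; ``y`` the (transformed)
    response.
    """

    t: np.ndarray
    y: np.ndarray
    idx: np.ndarray
    n_subjects: int

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.idx = np.asarray(self.idx, dtype=np.intp)
        self.n_per_subject = np.bincount(self.idx, minlength=self.n_subjects)
        if np.any(self.n_per_subject == 0):
            raise ValueError("every subject index in range must have observations")


# -- Sigma parameterization ------------------------------------------------


def pack_cov(Sigma: np.ndarray) -> np.ndarray:
    """Log-Cholesky parameters of a covariance matrix (diag logged)."""
    L = np.linalg.cholesky(np.asarray(Sigma, dtype=float))
    q = L.shape[0]
    out = []
    for i in range(q):
        for j in range(i + 1):
            out.append(np.log(L[i, i]) if i == j else L[i, j])
    return np.array(out)


def unpack_cov(params: np.ndarray, q: int) -> np.ndarray:
    """Lower-triangular Cholesky factor from log-Cholesky parameters."""
    L = np.zeros((q, q))
    k = 0
    for i in range(q):
        for j in range(i + 1):
            L[i, j] = np.exp(params[k]) if i == j else params[k]
            k += 1
    return L


def n_cov_params(q: int) -> int:
    return q * (q + 1) // 2


# -- inner problem ---------------------------------------------------------


def _group_quadratics(J, r, idx, n_subjects):
    """Per-subject J'J (n,q,q) and J'r (n,q) via bincount."""
    q = J.shape[1]
    JtJ = np.empty((n_subjects, q, q))
    Jtr = np.empty((n_subjects, q))
    for a in range(q):
        Jtr[:, a] = np.bincount(idx, J[:, a] * r, minlength=n_subjects)
        for b in range(a, q):
            s = np.bincount(idx, J[:, a] * J[:, b], minlength=n_subjects)
            JtJ[:, a, b] = s
            JtJ[:, b, a] = s
    return JtJ, Jtr


def _penalized_obj(family, fixed, b, Sigma_inv, sigma2, t, y, idx, n_subjects):
    """g_i = ||r_i||^2 / (2 sigma^2) + b_i' Sigma^-1 b_i / 2, per subject."""
    mean_only = getattr(family, "mean_only", None)
    if mean_only is not None:
        f = mean_only(fixed, b[idx], t)
    else:
        f, _ = family.mean_and_jac(fixed, b[idx], t)
    r = y - f
    rss = np.bincount(idx, r * r, minlength=n_subjects)
    quad = np.einsum("ni,ij,nj->n", b, Sigma_inv, b)
    return rss / (2.0 * sigma2) + 0.5 * quad


def find_modes(
    family,
    fixed,
    Sigma_inv,
    sigma2,
    data: GroupedData,
    b0: np.ndarray | None = None,
    step_tol: float = 1e-8,
    max_iter: int = 60,
):
    """Batched Gauss-Newton search for the per-subject posterior modes.

    Subjects whose Newton step has shrunk below ``step_tol`` drop out
    of the iteration, so warm-started calls touch only the few
    stragglers.  Returns (b_hat, hess, g, converged_mask); ``hess`` is
    the Gauss-Newton Hessian J'J/sigma^2 + Sigma^-1 at the mode, the
    matrix entering the Laplace determinant.
    """
    N, q = data.n_subjects, family.q
    b = np.zeros((N, q)) if b0 is None else np.array(b0, dtype=float)
    g = _penalized_obj(family, fixed, b, Sigma_inv, sigma2,
                       data.t, data.y, data.idx, N)
    active_ids = np.arange(N)
    done_by_step = np.zeros(N, dtype=bool)
    for _ in range(max_iter):
        if active_ids.size == 0:
            break
        mask = np.isin(data.idx, active_ids)
        t_a, y_a = data.t[mask], data.y[mask]
        idx_a = np.searchsorted(active_ids, data.idx[mask])
        n_a = active_ids.size
        ba = b[active_ids]
        f, J = family.mean_and_jac(fixed, ba[idx_a], t_a)
        r = y_a - f
        JtJ, Jtr = _group_quadratics(J, r, idx_a, n_a)
        H = JtJ / sigma2 + Sigma_inv[None, :, :]
        grad = Jtr / sigma2 - ba @ Sigma_inv
        step = np.linalg.solve(H, grad[:, :, None])[:, :, 0]
        ga = g[active_ids]
        scale = np.ones(n_a)
        stuck = np.zeros(n_a, dtype=bool)
        for _ in range(12):
            b_try = ba + scale[:, None] * step
            g_try = _penalized_obj(family, fixed, b_try, Sigma_inv, sigma2,
                                   t_a, y_a, idx_a, n_a)
            worse = g_try > ga + 1e-12
            if not worse.any():
                break
            scale[worse] *= 0.5
        else:
            stuck = g_try > ga + 1e-12
        take = ~stuck
        moved = active_ids[take]
        b[moved] = b_try[take]
        g[moved] = g_try[take]
        small = np.max(np.abs(scale[:, None] * step), axis=1) < step_tol
        finished = small | stuck
        done_by_step[active_ids[finished]] = True
        active_ids = active_ids[~finished]
    # final full pass for Hessians, gradients and convergence flags
    f, J = family.mean_and_jac(fixed, b[data.idx], data.t)
    r = data.y - f
    JtJ, Jtr = _group_quadratics(J, r, data.idx, N)
    H = JtJ / sigma2 + Sigma_inv[None, :, :]
    grad = Jtr / sigma2 - b @ Sigma_inv
    # scale-aware gradient check: compare against the curvature H
    gscale = np.sqrt(np.einsum("nii->n", H)) * np.sqrt(sigma2)
    converged = done_by_step | (
        np.max(np.abs(grad), axis=1) <= 1e-5 * np.maximum(gscale, 1.0)
    )
    g = _penalized_obj(family, fixed, b, Sigma_inv, sigma2,
                       data.t, data.y, data.idx, N)
    return b, H, g, converged


# -- Laplace log likelihood ------------------------------------------------


def laplace_loglik(
    family,
    fixed,
    Sigma,
    sigma,
    data: GroupedData,
    b0=None,
    return_modes: bool = False,
):
    """Laplace-approximate marginal log likelihood.

    For each subject the random effects are integrated out by a
    second-order expansion of the joint density around the posterior
    mode:

        ll_i = -n_i/2 log(2 pi sigma^2) - 1/2 log|Sigma|
               - g_i(b_hat_i) - 1/2 log|H_i|

    with g the penalized least-squares objective and H its Gauss-Newton
    Hessian.  Exact when f is linear in b (e.g. size-only SITAR).
    """
    Sigma = np.atleast_2d(np.asarray(Sigma, dtype=float))
    try:
        L = np.linalg.cholesky(Sigma)
    except np.linalg.LinAlgError:
        # numerically singular prior: treat as an infeasible point
        b = np.zeros((data.n_subjects, family.q)) if b0 is None else b0
        return (-np.inf, b) if return_modes else -np.inf
    Linv = solve_triangular(L, np.eye(family.q), lower=True)
    Sigma_inv = Linv.T @ Linv
    logdet_Sigma = 2.0 * np.sum(np.log(np.diag(L)))
    sigma2 = float(sigma) ** 2

    b_hat, H, g, conv = find_modes(family, fixed, Sigma_inv, sigma2, data, b0=b0)
    if not conv.all():
        warnings.warn(
            f"inner mode search did not fully converge for "
            f"{int((~conv).sum())} subject(s); using best-found modes",
            ConvergenceWarning,
            stacklevel=2,
        )
    sign, logdet_H = np.linalg.slogdet(H)
    if np.any(sign <= 0):
        return (-np.inf, b_hat) if return_modes else -np.inf
    ll = (
        -0.5 * data.n_per_subject * np.log(2.0 * np.pi * sigma2)
        - 0.5 * logdet_Sigma
        - g
        - 0.5 * logdet_H
    )
    total = float(np.sum(ll))
    return (total, b_hat) if return_modes else total


def _gn_fixed_step(family, fixed, b, data: GroupedData):
    """One Gauss-Newton update of the fixed parameters with the modes
    held; step-halved on the residual sum of squares.  Returns the new
    fixed vector and its residuals."""
    f, _ = family.mean_and_jac(fixed, b[data.idx], data.t)
    r = data.y - f
    F = family.fixed_jac(fixed, b[data.idx], data.t)
    step, *_ = np.linalg.lstsq(F, r, rcond=None)
    rss0 = r @ r
    scale = 1.0
    for _ in range(10):
        fixed_try = fixed + scale * step
        f_try, _ = family.mean_and_jac(fixed_try, b[data.idx], data.t)
        r_try = data.y - f_try
        if r_try @ r_try <= rss0 + 1e-12:
            return fixed_try, r_try
        scale *= 0.5
    return fixed, r


def em_alternation(
    family,
    data: GroupedData,
    fixed: np.ndarray,
    Sigma: np.ndarray,
    sigma: float,
    b0: np.ndarray | None = None,
    n_rounds: int = 40,
    ll_tol: float = 1e-4,
    recenter=None,
):
    """Fast alternating updates before the quasi-Newton polish.

    Each round: (1) per-subject posterior modes; (2) one Gauss-Newton
    update of the fixed parameters holding the modes; (3) closed-form
    EM-style updates of Sigma and sigma from the modes and their
    Laplace posterior covariances.  An optional ``recenter`` callback
    (family, fixed, b) -> (family, fixed, b) may absorb mode-mean
    drift into the fixed curve between rounds.  Returns
    (family, fixed, Sigma, sigma, b).
    """
    N = data.n_subjects
    q = family.q
    b = b0
    last_ll = -np.inf
    for rnd in range(n_rounds):
        L = np.linalg.cholesky(Sigma)
        Linv = solve_triangular(L, np.eye(q), lower=True)
        Sigma_inv = Linv.T @ Linv
        sigma2 = sigma**2
        b, H, g, _ = find_modes(family, fixed, Sigma_inv, sigma2, data, b0=b)

        # Gauss-Newton step on the fixed parameters (exact for linear)
        fixed, r = _gn_fixed_step(family, fixed, b, data)

        # EM updates from the Laplace posterior N(b_hat, H^-1)
        C = np.linalg.inv(H)
        Sigma_new = (np.einsum("ni,nj->ij", b, b) + C.sum(axis=0)) / N
        JtJ = (H - Sigma_inv[None, :, :]) * sigma2
        trace_term = np.einsum("nij,nji->", JtJ, C)
        sigma2_new = (r @ r + trace_term) / data.t.size
        Sigma = Sigma_new + 1e-12 * np.eye(q)
        sigma = float(np.sqrt(max(sigma2_new, 1e-12)))

        if recenter is not None:
            family, fixed, b = recenter(family, fixed, b)

        if rnd % 5 == 4:
            ll = laplace_loglik(family, fixed, Sigma, sigma, data, b0=b)
            if abs(ll - last_ll) < ll_tol * (1 + abs(ll)) * 5:
                break
            last_ll = ll
    return family, fixed, Sigma, sigma, b


# -- outer problem ---------------------------------------------------------


@dataclass
class LaplaceResult:
    fixed: np.ndarray
    Sigma: np.ndarray
    sigma: float
    b_hat: np.ndarray
    loglik: float
    converged: bool
    n_outer_iter: int
    message: str


def _pnls(family, fixed, Sigma_inv, sigma2, data, b, max_rounds=12,
          rel_tol=1e-9):
    """Penalized nonlinear least squares: alternate per-subject modes
    and Gauss-Newton fixed-parameter updates until the fixed step is
    negligible (the Lindstrom-Bates PNLS step)."""
    for _ in range(max_rounds):
        b, H, g, _ = find_modes(family, fixed, Sigma_inv, sigma2, data, b0=b)
        new_fixed, _ = _gn_fixed_step(family, fixed, b, data)
        delta = np.max(np.abs(new_fixed - fixed))
        scale = np.max(np.abs(fixed)) + 1.0
        fixed = new_fixed
        if delta < rel_tol * scale:
            break
    return fixed, b


def _segment_outer(idx, n_subjects, A, B):
    """Per-subject sums of a_i b_i' for row-wise arrays A (n,qa), B (n,qb)."""
    qa, qb = A.shape[1], B.shape[1]
    out = np.empty((n_subjects, qa, qb))
    for a in range(qa):
        for b in range(qb):
            out[:, a, b] = np.bincount(idx, A[:, a] * B[:, b],
                                       minlength=n_subjects)
    return out


def _lmm_ml(w, F, Z, idx, n_subjects, Psi0, max_iter=30):
    """Exact ML for the linear mixed model w = F theta + Z b + e,
    b_i ~ N(0, sigma^2 Psi), e ~ N(0, sigma^2 I).

    theta and sigma^2 are profiled out in closed form (GLS), so the
    optimization runs only over the log-Cholesky factor of Psi.
    Returns (theta, Psi, sigma).  This is the LME step of the
    Lindstrom-Bates algorithm; with one random intercept it is also
    the closed-form oracle for the size-only SITAR model.
    """
    n, p = F.shape
    q = Z.shape[1]
    ZtZ = _segment_outer(idx, n_subjects, Z, Z)
    ZtF = _segment_outer(idx, n_subjects, Z, F)
    Ztw = _segment_outer(idx, n_subjects, Z, w[:, None])[:, :, 0]
    FtF = F.T @ F
    Ftw = F.T @ w
    wtw = float(w @ w)
    Iq = np.eye(q)

    def profile(params, want_grad=False):
        L = unpack_cov(params, q)
        Psi = L @ L.T
        Linv = solve_triangular(L, Iq, lower=True)
        Psi_inv = Linv.T @ Linv
        G = Psi_inv[None, :, :] + ZtZ          # (N, q, q)
        sign, logdet_G = np.linalg.slogdet(G)
        if np.any(sign <= 0):
            return None
        logdet_M = float(np.sum(logdet_G)) + \
            2.0 * n_subjects * float(np.sum(np.log(np.diag(L))))
        A = np.linalg.inv(G)                   # (N, q, q)
        # X' M^-1 Y = X'Y - sum_i (Z'X)_i' A_i (Z'Y)_i
        FMF = FtF - np.einsum("nqp,nqr,nrs->ps", ZtF, A, ZtF)
        FMw = Ftw - np.einsum("nqp,nqr,nr->p", ZtF, A, Ztw)
        wMw = wtw - float(np.einsum("nq,nqr,nr->", Ztw, A, Ztw))
        try:
            theta = np.linalg.solve(FMF, FMw)
        except np.linalg.LinAlgError:
            return None
        rss = wMw - float(theta @ FMw)
        if rss <= 0:
            return None
        sigma2 = rss / n
        ll = -0.5 * n * (np.log(2 * np.pi * sigma2) + 1.0) - 0.5 * logdet_M
        if not want_grad:
            return ll, theta, Psi, float(np.sqrt(sigma2))
        # analytic gradient wrt the log-Cholesky parameters:
        # d ll = tr(Gmat dPsi), Gmat = n/(2 rss) sum_i u_i u_i'
        #        - 1/2 sum_i (S - S A S),  u_i = Z'M^-1 e_i
        Ze = Ztw - ZtF @ theta                  # (N, q): Z'e per subject
        u = Ze - np.einsum("nqr,nrs,ns->nq", ZtZ, A, Ze)
        SAS = np.einsum("nqr,nrs,nst->nqt", ZtZ, A, ZtZ)
        Gmat = (n / (2.0 * rss)) * np.einsum("nq,nr->qr", u, u) \
            - 0.5 * (ZtZ.sum(axis=0) - SAS.sum(axis=0))
        GL = 2.0 * Gmat @ L
        grad = np.empty(len(params))
        k = 0
        for i in range(q):
            for j in range(i + 1):
                g = GL[i, j]
                if i == j:
                    g *= L[i, i]  # chain rule for the log-diagonal
                grad[k] = -g      # neg log likelihood
                k += 1
        return ll, theta, Psi, float(np.sqrt(sigma2)), grad

    def neg_ll_and_grad(params):
        out = profile(params, want_grad=True)
        if out is None:
            return 1e12, np.zeros(len(params))
        return -out[0], out[4]

    bounds = [(-10.0, 8.0) if i == j else (None, None)
              for i in range(q) for j in range(i + 1)]
    res = optimize.minimize(
        neg_ll_and_grad, pack_cov(Psi0), method="L-BFGS-B", jac=True,
        bounds=bounds, options={"maxiter": max_iter, "ftol": 1e-12},
    )
    out = profile(res.x)
    if out is None:
        raise np.linalg.LinAlgError("LME step failed at the optimum")
    ll, theta, Psi, sigma = out
    return theta, Psi, sigma


def maximize_laplace(
    family,
    data: GroupedData,
    fixed0: np.ndarray,
    Sigma0: np.ndarray,
    sigma0: float,
    max_iter: int = 60,
    ll_tol: float = 1e-7,
    b0: np.ndarray | None = None,
) -> LaplaceResult:
    """Maximize the Laplace marginal log likelihood, Lindstrom-Bates
    style.

    Alternates (1) a penalized nonlinear least-squares step updating
    the fixed parameters and the per-subject modes at the current
    variance parameters, and (2) an LME step: the model is linearized
    in the random effects around the modes and the resulting linear
    mixed model is solved exactly by ML (theta and sigma^2 profiled in
    closed form, a small quasi-Newton search over the scaled
    random-effect covariance).  Iterates until the Laplace log
    likelihood is stationary.
    """
    fixed = np.asarray(fixed0, float)
    Sigma = np.atleast_2d(np.asarray(Sigma0, float))
    sigma = float(sigma0)
    b = b0
    q = family.q
    Iq = np.eye(q)

    def pnls_and_ll(fixed, Sigma, sigma, b):
        L = np.linalg.cholesky(Sigma)
        Linv = solve_triangular(L, Iq, lower=True)
        fixed, b = _pnls(family, fixed, Linv.T @ Linv, sigma**2, data, b,
                         max_rounds=8)
        ll = laplace_loglik(family, fixed, Sigma, sigma, data, b0=b)
        return fixed, b, ll

    fixed, b, ll_old = pnls_and_ll(fixed, Sigma, sigma, b)
    best = (ll_old, fixed, Sigma, sigma, b)
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        # linearize about the modes and solve the LMM exactly
        f, Z = family.mean_and_jac(fixed, b[data.idx], data.t)
        F = family.fixed_jac(fixed, b[data.idx], data.t)
        w = data.y - f + np.einsum("nq,nq->n", Z, b[data.idx]) + F @ fixed
        try:
            theta, Psi, sig = _lmm_ml(w, F, Z, data.idx, data.n_subjects,
                                      Sigma / sigma**2)
        except np.linalg.LinAlgError:
            break
        # damped acceptance against the Laplace objective: the LME step
        # maximizes the linearized likelihood, which can overshoot
        step = 1.0
        accepted = False
        for _ in range(4):
            Sigma_try = (1 - step) * Sigma + step * (sig**2 * Psi) + 1e-12 * Iq
            sigma_try = float(np.sqrt((1 - step) * sigma**2 + step * sig**2))
            fixed_try = fixed + step * (theta - fixed)
            f_try, b_try, ll = pnls_and_ll(fixed_try, Sigma_try, sigma_try, b)
            if np.isfinite(ll) and ll >= ll_old - 1e-10 * (1 + abs(ll_old)):
                fixed, Sigma, sigma, b = f_try, Sigma_try, sigma_try, b_try
                accepted = True
                break
            step *= 0.25
        if not accepted:
            converged = True  # no uphill LME direction left
            break
        if ll > best[0]:
            best = (ll, fixed, Sigma, sigma, b)
        if abs(ll - ll_old) < ll_tol * (1.0 + abs(ll)):
            converged = True
            ll_old = ll
            break
        ll_old = ll
    if best[0] > ll_old:
        _, fixed, Sigma, sigma, b = best
    L = np.linalg.cholesky(Sigma)
    Linv = solve_triangular(L, Iq, lower=True)
    fixed, b = _pnls(family, fixed, Linv.T @ Linv, sigma**2, data, b)
    ll, b_hat = laplace_loglik(family, fixed, Sigma, sigma, data, b0=b,
                               return_modes=True)
    return LaplaceResult(
        fixed=fixed,
        Sigma=Sigma,
        sigma=sigma,
        b_hat=b_hat,
        loglik=float(ll),
        converged=converged,
        n_outer_iter=n_iter,
        message="Lindstrom-Bates alternation with Laplace line search",
    )
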