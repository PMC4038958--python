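"""Maximum-likelihood estimation of confirmatory factor models.

The log-likelihood is the casewise multivariate-normal form

    l(theta; x_i) = log N(x_i | mu_g(theta), Sigma_g(theta)),

with group-specific implied moments ``mu_g = nu_g`` (factor means fixed at 0)
and ``Sigma_g = Lambda_g Phi_g Lambda_g' + Theta_g``.  Optimization runs on a
transformed scale (log for variances) via L-BFGS-B with an analytic gradient,
followed by Newton polishing with a finite-difference Hessian so the
first-order condition holds tightly; on failure the start values are jittered
and the fit restarted.

Casewise scores (the per-observation gradient of the log-likelihood at the
estimate) are computed analytically via matrix-calculus identities; a central
finite-difference fallback is available for cross-checking.  Three estimates
of the (per-observation) information matrix are provided: observed (negative
scaled Hessian), outer product of scores, and expected (via Jacobians of the
implied moments).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats

from .model import (
    CFAModel,
    CFAModelSpec,
    IdentificationError,
    ParameterTable,
    ROLE_FCOV,
    ROLE_FVAR,
    ROLE_INTERCEPT,
    ROLE_LOADING,
    ROLE_UNIQUE,
    build_parameter_table,
)

__all__ = [
    "FitOptions",
    "FittedCFA",
    "ConvergenceError",
    "fit_ml",
    "casewise_loglik",
    "score_matrix",
    "information_matrix",
    "InformationMatrix",
    "lr_test",
    "LRTestResult",
]

logger = logging.getLogger("scoreinv")

_LOG2PI = np.log(2.0 * np.pi)


class ConvergenceError(RuntimeError):
    """Raised when the optimizer fails to satisfy the first-order condition."""


@dataclass
class FitOptions:
    """Tuning knobs for :func:`fit_ml`.

    ``gtol`` is the convergence threshold on the infinity norm of the
    gradient of the *mean* log-likelihood (per-observation scale), so it is
    comparable across sample sizes.
    """

    gtol: float = 1e-8
    accept_tol: float = 1e-5
    max_iter: int = 500
    restarts: int = 3
    seed: int = 0
    polish_iter: int = 25


def _suffstats(X: np.ndarray, gc: np.ndarray, G: int):
    """Per-group (n_g, mean, ML covariance) sufficient statistics."""
    out = []
    for g in range(G):
        Xg = X[gc == g]
        ng = Xg.shape[0]
        if ng == 0:
            raise ValueError(f"group {g} has no observations")
        xbar = Xg.mean(axis=0)
        D = Xg - xbar
        S = D.T @ D / ng
        out.append((ng, xbar, S))
    return out


def _nll_grad(model: CFAModel, theta: np.ndarray, stats_: list, want_grad: bool = True):
    """Mean negative log-likelihood and its gradient w.r.t. the free vector.

    Works from per-group sufficient statistics; returns a large penalized
    value (with an inward-pointing gradient) when an implied covariance is
    not positive definite, so line searches back off.
    """
    n = sum(s[0] for s in stats_)
    nu, Lam, th, Phi = model.matrices(theta)
    p = model.p
    f = 0.0
    grad = np.zeros(model.k) if want_grad else None
    for g, (ng, xbar, S) in enumerate(stats_):
        Sigma = Lam[g] @ Phi[g] @ Lam[g].T + np.diag(th[g])
        try:
            c, low = linalg.cho_factor(Sigma, lower=True, check_finite=False)
        except linalg.LinAlgError:
            pen = 1e6 * (1.0 + float(theta @ theta))
            return (pen, 2e6 * theta.copy()) if want_grad else pen
        logdet = 2.0 * np.log(np.diag(c)).sum()
        A = linalg.cho_solve((c, low), np.eye(p), check_finite=False)
        d = xbar - nu[g]
        C = S + np.outer(d, d)
        f += 0.5 * ng * (p * _LOG2PI + logdet + float(np.sum(A * C)))
        if not want_grad:
            continue
        # gradient of the negative log-likelihood w.r.t. model matrices
        Gm = 0.5 * ng * (A - A @ C @ A)          # w.r.t. Sigma_g (symmetric)
        gnu = -ng * (A @ d)                       # w.r.t. nu_g
        _accumulate_matrix_grads(model, grad, g, Gm, gnu, Lam[g], Phi[g])
    f /= n
    if want_grad:
        grad /= n
        return f, grad
    return f


def _accumulate_matrix_grads(model, grad, g, Gm, gnu, Lam_g, Phi_g):
    """Chain-rule matrix gradients into the free-parameter vector for group g."""
    gl_g, gl_i, gl_j, gl_fi, _ = model._by_role[ROLE_LOADING]
    GLP = 2.0 * Gm @ Lam_g @ Phi_g
    sel = (gl_g == g) & (gl_fi >= 0)
    np.add.at(grad, gl_fi[sel], GLP[gl_i[sel], gl_j[sel]])
    if model.spec.mean_structure:
        gn_g, gn_i, _, gn_fi, _ = model._by_role[ROLE_INTERCEPT]
        sel = (gn_g == g) & (gn_fi >= 0)
        np.add.at(grad, gn_fi[sel], gnu[gn_i[sel]])
    gu_g, gu_i, _, gu_fi, _ = model._by_role[ROLE_UNIQUE]
    sel = (gu_g == g) & (gu_fi >= 0)
    np.add.at(grad, gu_fi[sel], np.diag(Gm)[gu_i[sel]])
    M = Lam_g.T @ Gm @ Lam_g
    gv_g, gv_i, _, gv_fi, _ = model._by_role[ROLE_FVAR]
    sel = (gv_g == g) & (gv_fi >= 0)
    np.add.at(grad, gv_fi[sel], np.diag(M)[gv_i[sel]])
    gc_g, gc_i, gc_j, gc_fi, _ = model._by_role[ROLE_FCOV]
    sel = (gc_g == g) & (gc_fi >= 0)
    np.add.at(grad, gc_fi[sel], 2.0 * M[gc_i[sel], gc_j[sel]])


def casewise_loglik(model: CFAModel, theta: np.ndarray, X: np.ndarray,
                    group_codes: np.ndarray | None = None) -> np.ndarray:
    """Per-observation multivariate-normal log-density under the model at theta."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n = X.shape[0]
    gc = np.zeros(n, dtype=int) if group_codes is None else np.asarray(group_codes, int)
    nu, Sigma = model.implied_moments(theta)
    out = np.empty(n)
    for g in range(model.G):
        mask = gc == g
        if not mask.any():
            continue
        try:
            c, low = linalg.cho_factor(Sigma[g], lower=True, check_finite=False)
        except linalg.LinAlgError as e:
            raise ValueError(f"implied covariance for group {g} is not positive definite") from e
        logdet = 2.0 * np.log(np.diag(c)).sum()
        U = X[mask] - nu[g]
        sol = linalg.cho_solve((c, low), U.T, check_finite=False)
        quad = np.einsum("ip,pi->i", U, sol)
        out[mask] = -0.5 * (model.p * _LOG2PI + logdet + quad)
    return out


def _analytic_scores(model: CFAModel, theta: np.ndarray, X: np.ndarray,
                     gc: np.ndarray) -> np.ndarray:
    """Casewise gradient of the log-likelihood at theta (n x k)."""
    n = X.shape[0]
    out = np.zeros((n, model.k))
    nu, Lam, th, Phi = model.matrices(theta)
    for g in range(model.G):
        mask = gc == g
        if not mask.any():
            continue
        Sigma = Lam[g] @ Phi[g] @ Lam[g].T + np.diag(th[g])
        A = linalg.inv(Sigma, check_finite=False)
        U = X[mask] - nu[g]
        W = U @ A                       # rows: A u_i
        T = Lam[g] @ Phi[g]             # p x q
        MT = A @ T                      # p x q
        V = W @ T                       # n_g x q
        P = W @ Lam[g]                  # n_g x q
        Q = Lam[g].T @ A @ Lam[g]       # q x q
        sub = np.zeros((int(mask.sum()), model.k))
        gl_g, gl_i, gl_j, gl_fi, _ = model._by_role[ROLE_LOADING]
        for i_, j_, fi_ in zip(gl_i[gl_g == g], gl_j[gl_g == g], gl_fi[gl_g == g]):
            if fi_ >= 0:
                sub[:, fi_] += W[:, i_] * V[:, j_] - MT[i_, j_]
        if model.spec.mean_structure:
            gn_g, gn_i, _, gn_fi, _ = model._by_role[ROLE_INTERCEPT]
            for i_, fi_ in zip(gn_i[gn_g == g], gn_fi[gn_g == g]):
                if fi_ >= 0:
                    sub[:, fi_] += W[:, i_]
        gu_g, gu_i, _, gu_fi, _ = model._by_role[ROLE_UNIQUE]
        for i_, fi_ in zip(gu_i[gu_g == g], gu_fi[gu_g == g]):
            if fi_ >= 0:
                sub[:, fi_] += 0.5 * (W[:, i_] ** 2 - A[i_, i_])
        gv_g, gv_i, _, gv_fi, _ = model._by_role[ROLE_FVAR]
        for i_, fi_ in zip(gv_i[gv_g == g], gv_fi[gv_g == g]):
            if fi_ >= 0:
                sub[:, fi_] += 0.5 * (P[:, i_] ** 2 - Q[i_, i_])
        gc_g, gc_i, gc_j, gc_fi, _ = model._by_role[ROLE_FCOV]
        for i_, j_, fi_ in zip(gc_i[gc_g == g], gc_j[gc_g == g], gc_fi[gc_g == g]):
            if fi_ >= 0:
                sub[:, fi_] += P[:, i_] * P[:, j_] - Q[i_, j_]
        out[mask] = sub
    return out


def _fd_scores(model: CFAModel, theta: np.ndarray, X: np.ndarray, gc: np.ndarray,
               step: float = 1e-6) -> np.ndarray:
    """Central finite-difference casewise scores (cross-check fallback)."""
    k = model.k
    n = X.shape[0]
    out = np.empty((n, k))
    for j in range(k):
        h = step * max(1.0, abs(theta[j]))
        tp = theta.copy(); tp[j] += h
        tm = theta.copy(); tm[j] -= h
        out[:, j] = (casewise_loglik(model, tp, X, gc) -
                     casewise_loglik(model, tm, X, gc)) / (2 * h)
    return out


@dataclass
class InformationMatrix:
    """A per-observation k x k information estimate of a given kind."""

    matrix: np.ndarray
    kind: str
    labels: list[str] = field(default_factory=list)


@dataclass
class FittedCFA:
    """A converged maximum-likelihood CFA fit."""

    model: CFAModel
    table: ParameterTable
    theta: np.ndarray
    loglik: float
    casewise: np.ndarray
    converged: bool
    grad_inf: float
    n: int
    k: int
    data: pd.DataFrame
    X: np.ndarray
    group_codes: np.ndarray
    group_levels: np.ndarray
    n_dropped: int = 0

    @property
    def estimates(self) -> pd.Series:
        return pd.Series(self.theta, index=self.table.free_labels, name="estimate")

    @property
    def aic(self) -> float:
        return -2.0 * self.loglik + 2.0 * self.k

    @property
    def bic(self) -> float:
        return -2.0 * self.loglik + self.k * np.log(self.n)

    @property
    def df(self) -> int:
        p = self.model.p
        per = p * (p + 3) // 2 if self.model.spec.mean_structure else p * (p + 1) // 2
        return self.model.G * per - self.k

    def scores(self, method: str = "analytic") -> np.ndarray:
        return score_matrix(self, method=method).matrix

    def information(self, kind: str = "observed") -> np.ndarray:
        return information_matrix(self, kind=kind).matrix


@dataclass
class ScoreMatrix:
    matrix: np.ndarray
    labels: list[str]


def score_matrix(fitted: FittedCFA, method: str = "analytic") -> ScoreMatrix:
    """Casewise scores at the estimate (rows sum to ~0 by the first-order condition)."""
    if not fitted.converged:
        raise ConvergenceError("cannot compute scores for a non-converged fit")
    fn = _analytic_scores if method == "analytic" else _fd_scores
    S = fn(fitted.model, fitted.theta, fitted.X, fitted.group_codes)
    return ScoreMatrix(matrix=S, labels=list(fitted.table.free_labels))


def _observed_information(model, theta, stats_, step: float = 1e-5) -> np.ndarray:
    """Numeric Hessian of the mean negative log-likelihood (central differences)."""
    k = model.k
    H = np.empty((k, k))
    for j in range(k):
        h = step * max(1.0, abs(theta[j]))
        tp = theta.copy(); tp[j] += h
        tm = theta.copy(); tm[j] -= h
        _, gp = _nll_grad(model, tp, stats_)
        _, gm = _nll_grad(model, tm, stats_)
        H[:, j] = (gp - gm) / (2 * h)
    return 0.5 * (H + H.T)


def _expected_information(model, theta, weights, step: float = 1e-6) -> np.ndarray:
    """Expected information per observation via implied-moment Jacobians."""
    k, p, G = model.k, model.p, model.G
    nu0, Sigma0 = model.implied_moments(theta)
    Jmu = np.empty((G, p, k))
    Jsig = np.empty((G, p * p, k))
    for j in range(k):
        h = step * max(1.0, abs(theta[j]))
        tp = theta.copy(); tp[j] += h
        tm = theta.copy(); tm[j] -= h
        nup, Sp = model.implied_moments(tp)
        num, Sm = model.implied_moments(tm)
        Jmu[:, :, j] = (nup - num) / (2 * h)
        Jsig[:, :, j] = ((Sp - Sm) / (2 * h)).reshape(G, p * p)
    I = np.zeros((k, k))
    for g in range(G):
        A = linalg.inv(Sigma0[g], check_finite=False)
        I += weights[g] * (Jmu[g].T @ A @ Jmu[g])
        # 0.5 * J' (A (x) A) J  computed column-wise
        AJ = np.empty_like(Jsig[g])
        for j in range(k):
            M = Jsig[g][:, j].reshape(p, p)
            AJ[:, j] = (A @ M @ A).ravel()
        I += 0.5 * weights[g] * (Jsig[g].T @ AJ)
    return 0.5 * (I + I.T)


def information_matrix(fitted: FittedCFA, kind: str = "observed") -> InformationMatrix:
    """Per-observation information estimate: observed, outer-product (opg), or expected."""
    model, theta = fitted.model, fitted.theta
    if kind == "observed":
        stats_ = _suffstats(fitted.X, fitted.group_codes, model.G)
        M = _observed_information(model, theta, stats_)
        eig = np.linalg.eigvalsh(M)
        if eig.min() < -1e-8 * max(eig.max(), 1.0):
            logger.warning(
                "observed information is numerically indefinite (min eig %.3g); "
                "falling back to the outer product of scores", eig.min())
            return information_matrix(fitted, kind="opg")
    elif kind in ("opg", "outer-product"):
        S = _analytic_scores(model, theta, fitted.X, fitted.group_codes)
        M = S.T @ S / fitted.n
        kind = "opg"
    elif kind == "expected":
        w = np.bincount(fitted.group_codes, minlength=model.G) / fitted.n
        M = _expected_information(model, theta, w)
    else:
        raise ValueError(f"unknown information kind {kind!r}")
    return InformationMatrix(matrix=M, kind=kind, labels=list(fitted.table.free_labels))


def expected_information_at(model: CFAModel, theta: np.ndarray,
                            weights: Sequence[float] | None = None) -> np.ndarray:
    """Expected per-observation information at an arbitrary theta (no data needed)."""
    w = np.full(model.G, 1.0 / model.G) if weights is None else np.asarray(weights, float)
    return _expected_information(model, theta, w)


def _start_values(model: CFAModel, stats_: list) -> np.ndarray:
    """Moment-based starting values: means, half-variances, covariance heuristics."""
    table = model.table
    theta = np.ones(model.k)
    df = table.df
    ind_names = model.spec.indicators
    for row in df[df.free].itertuples():
        g = row.group
        _, xbar, S = stats_[g]
        if row.role == ROLE_INTERCEPT:
            theta[row.free_index] = xbar[row.i]
        elif row.role == ROLE_UNIQUE:
            theta[row.free_index] = max(0.5 * S[row.i, row.i], 0.05)
        elif row.role == ROLE_FVAR:
            f = model.spec.factors[row.i]
            inds = [ind_names.index(x) for x in model.spec.loadings[f]]
            if len(inds) >= 2:
                covs = [S[a, b] for ai, a in enumerate(inds) for b in inds[ai + 1:]]
                theta[row.free_index] = max(float(np.mean(covs)), 0.1 * float(np.mean(np.diag(S)[inds])), 0.05)
            else:
                theta[row.free_index] = max(0.5 * S[row.i, row.i], 0.05)
        elif row.role == ROLE_FCOV:
            theta[row.free_index] = 0.0
        elif row.role == ROLE_LOADING:
            if model.spec.identification == "variance":
                j_m = row.i
                theta[row.free_index] = np.sign(S[j_m, j_m]) * np.sqrt(
                    max(0.3 * S[j_m, j_m], 0.05))
            else:
                theta[row.free_index] = 1.0
    return theta


def fit_ml(
    data: pd.DataFrame,
    spec: CFAModelSpec,
    *,
    equal: Sequence[str] = (),
    group: str | None = None,
    table: ParameterTable | None = None,
    options: FitOptions | None = None,
) -> FittedCFA:
    """Fit a CFA model by multivariate-normal maximum likelihood.

    Rows with missing values in the indicators (or the group column) are
    dropped (complete-case analysis) and the count is logged.  Raises
    :class:`ConvergenceError` when the first-order condition cannot be met
    after jittered restarts — no silent partial results.
    """
    opts = options or FitOptions()
    for f in spec.factors:
        if len(spec.loadings[f]) < 2:
            raise IdentificationError(
                f"factor {f!r} has a single indicator; the model is not identified")
    group = group or spec.group_var
    cols = list(spec.indicators) + ([group] if group else [])
    missing_cols = [c for c in cols if c not in data.columns]
    if missing_cols:
        raise ValueError(f"columns missing from data: {missing_cols}")
    for c in spec.indicators:
        if not pd.api.types.is_numeric_dtype(data[c]):
            raise ValueError(f"indicator column {c!r} is not numeric")
    keep = data[cols].notna().all(axis=1)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("dropped %d incomplete rows of %d", n_dropped, len(data))
    sub = data[keep]
    X = sub[list(spec.indicators)].to_numpy(float)
    if group:
        levels, gc = np.unique(sub[group].to_numpy(), return_inverse=True)
    else:
        levels = np.array([0])
        gc = np.zeros(len(sub), dtype=int)
    G = len(levels)
    if table is None:
        table = build_parameter_table(spec, n_groups=G, equal=equal)
    model = CFAModel(table)
    stats_ = _suffstats(X, gc, G)
    n = X.shape[0]

    vmask = table.variance_mask

    def to_opt(th):
        x = th.copy()
        x[vmask] = np.log(np.clip(th[vmask], 1e-10, None))
        return x

    def from_opt(x):
        th = x.copy()
        th[vmask] = np.exp(np.clip(x[vmask], -30, 30))
        return th

    def fg(x):
        th = from_opt(x)
        f, g = _nll_grad(model, th, stats_)
        g = g.copy()
        g[vmask] *= th[vmask]
        return f, g

    rng = np.random.default_rng(opts.seed)
    theta0 = _start_values(model, stats_)
    best = None
    for attempt in range(opts.restarts + 1):
        x0 = to_opt(theta0)
        if attempt > 0:
            x0 = x0 + rng.normal(scale=0.2, size=x0.shape)
        res = optimize.minimize(fg, x0, jac=True, method="L-BFGS-B",
                                options=dict(maxiter=opts.max_iter, ftol=1e-14,
                                             gtol=opts.gtol / 10))
        x = res.x
        # Newton polishing on the transformed scale
        f, g = fg(x)
        for _ in range(opts.polish_iter):
            ginf = np.abs(g).max()
            if ginf < opts.gtol:
                break
            H = _fd_hessian_transformed(fg, x)
            try:
                step = np.linalg.solve(H + 1e-10 * np.eye(len(x)), -g)
            except np.linalg.LinAlgError:
                step = -g
            ok = False
            for _ in range(20):
                xn = x + step
                fn_, gn = fg(xn)
                if fn_ <= f + 1e-12 * abs(f):
                    x, f, g = xn, fn_, gn
                    ok = True
                    break
                step *= 0.5
            if not ok:
                break
        ginf = np.abs(g).max()
        if best is None or f < best[1] - 1e-12 or (abs(f - best[1]) < 1e-9 and ginf < best[2]):
            best = (x, f, ginf)
        if ginf < opts.gtol:
            break
    x, f, ginf = best
    converged = ginf < opts.accept_tol
    if not converged:
        raise ConvergenceError(
            f"fit did not converge after {opts.restarts + 1} attempts "
            f"(gradient inf-norm {ginf:.3g})")
    theta = from_opt(x)
    cw = casewise_loglik(model, theta, X, gc)
    return FittedCFA(
        model=model, table=table, theta=theta, loglik=float(cw.sum()),
        casewise=cw, converged=converged, grad_inf=float(ginf), n=n, k=model.k,
        data=sub.reset_index(drop=True), X=X, group_codes=gc,
        group_levels=levels, n_dropped=n_dropped,
    )


def _fd_hessian_transformed(fg, x, step: float = 1e-5) -> np.ndarray:
    k = len(x)
    H = np.empty((k, k))
    for j in range(k):
        h = step * max(1.0, abs(x[j]))
        xp = x.copy(); xp[j] += h
        xm = x.copy(); xm[j] -= h
        _, gp = fg(xp)
        _, gm = fg(xm)
        H[:, j] = (gp - gm) / (2 * h)
    return 0.5 * (H + H.T)


@dataclass
class LRTestResult:
    statistic: float
    df: int
    pvalue: float


def lr_test(full: FittedCFA, restricted: FittedCFA) -> LRTestResult:
    """Likelihood-ratio (chi-square difference) test of nested fits."""
    df = full.k - restricted.k
    if df < 0:
        raise ValueError("'full' must have at least as many free parameters as 'restricted'")
    if full.n != restricted.n:
        raise ValueError("fits are on different sample sizes")
    stat = 2.0 * (full.loglik - restricted.loglik)
    if stat < -1e-6:
        raise ValueError(
            f"negative LR statistic ({stat:.3g}): models not nested or fit not converged")
    stat = max(stat, 0.0)
    pvalue = float(stats.chi2.sf(stat, df)) if df > 0 else 1.0
    return LRTestResult(statistic=stat, df=df, pvalue=pvalue)
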