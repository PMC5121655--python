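"""Logistic mixed models by penalised quasi-likelihood with a Laplace
marginal likelihood.

A small, dependency-light GLMM routine for Bernoulli responses with
independent random-intercept factors (e.g. study year and animal).
Estimation alternates (a) the joint mode of fixed effects and random
effects given the variance components — penalised iteratively
reweighted least squares, the PQL inner loop — with (b) variance
updates from the Laplace approximation,

    sigma_g^2  <-  ( ||b_g||^2 + tr(T_gg) ) / m_g ,

where T is the inverse of the penalised Hessian at the mode.  The
reported log-likelihood is the Laplace approximation

    l(beta, sigma) = l_cond(y | b_hat) - b_hat' D^-1 b_hat / 2
                     - log det(I + Z' W Z D) / 2 ,

used for likelihood-ratio tests between nested fixed-effect models.

Separation (some covariate pattern predicting the outcome perfectly)
makes the unpenalised fixed effects diverge; :func:`firth_logistic`
provides the bias-reduced (Jeffreys-prior penalised) fallback.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = ["GlmmFit", "fit_logistic_glmm", "firth_logistic", "FirthFit"]

_CLIP = 30.0


def _sigmoid(eta: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(eta, -_CLIP, _CLIP)))


def _group_indicators(codes: np.ndarray, n_levels: int) -> np.ndarray:
    Z = np.zeros((codes.size, n_levels))
    Z[np.arange(codes.size), codes] = 1.0
    return Z


@dataclass
class GlmmFit:
    """Fitted logistic GLMM."""

    beta: np.ndarray
    beta_se: np.ndarray
    random_sds: dict
    b: dict  # per-factor random-effect modes
    loglik: float  # Laplace approximation
    n_obs: int
    converged: bool
    n_iter: int
    separation: bool = False
    notes: list = field(default_factory=list)

    def predict_marginal(self, X: np.ndarray, n_quad: int = 25) -> np.ndarray:
        """Population-averaged probabilities.

        Integrates the logistic curve over the fitted random-effect
        distribution (all factors pooled into one Gaussian on the
        log-odds scale) by Gauss–Hermite quadrature — the prediction
        "averaged over years and individuals".
        """
        total_var = sum(sd**2 for sd in self.random_sds.values())
        eta = np.asarray(X) @ self.beta
        if total_var <= 0:
            return _sigmoid(eta)
        nodes, weights = np.polynomial.hermite_e.hermegauss(n_quad)
        w = weights / weights.sum()
        sd = np.sqrt(total_var)
        return np.array(
            [float(w @ _sigmoid(e + sd * nodes)) for e in eta]
        )


def fit_logistic_glmm(
    X: np.ndarray,
    y: np.ndarray,
    groups: dict[str, np.ndarray],
    max_outer: int = 60,
    tol: float = 1e-6,
    min_var: float = 1e-10,
) -> GlmmFit:
    """Bernoulli GLMM with independent random-intercept factors.

    Parameters
    ----------
    X : (n, p) fixed-effect design (include the intercept column).
    y : (n,) 0/1 outcomes.
    groups : mapping factor name -> integer codes of length n.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    names = list(groups)
    codes = {g: np.asarray(groups[g]) for g in names}
    levels = {g: int(codes[g].max()) + 1 for g in names}
    Z = np.hstack([_group_indicators(codes[g], levels[g]) for g in names])
    q = Z.shape[1]
    # slices of the concatenated random-effect vector per factor
    sl, off = {}, 0
    for g in names:
        sl[g] = slice(off, off + levels[g])
        off += levels[g]

    C = np.hstack([X, Z])
    beta = np.zeros(p)
    beta[0] = np.log(max(y.mean(), 1e-3) / max(1 - y.mean(), 1e-3))
    b = np.zeros(q)
    var = {g: 0.5 for g in names}
    separation = False

    loglik = -np.inf
    it = 0
    converged_ll = False
    var_hist: list[dict] = []
    for it in range(1, max_outer + 1):
        # ---- inner: joint Newton for (beta, b) at current variances
        pen = np.zeros(p + q)
        for g in names:
            pen[p + np.arange(q)[sl[g]]] = 1.0 / max(var[g], min_var)
        theta = np.concatenate([beta, b])
        for _ in range(25):
            eta = C @ theta
            mu = _sigmoid(eta)
            w = np.maximum(mu * (1 - mu), 1e-10)
            grad = C.T @ (y - mu) - pen * theta
            H = (C * w[:, None]).T @ C
            H[np.diag_indices_from(H)] += pen
            try:
                step = np.linalg.solve(H, grad)
            except np.linalg.LinAlgError:
                H[np.diag_indices_from(H)] += 1e-8
                step = np.linalg.solve(H, grad)
            theta = theta + step
            if np.abs(step).max() < 1e-9:
                break
        beta, b = theta[:p], theta[p:]
        if np.abs(beta).max() > 15:
            separation = True

        # ---- outer: Laplace variance updates
        eta = C @ theta
        mu = _sigmoid(eta)
        w = np.maximum(mu * (1 - mu), 1e-10)
        H = (C * w[:, None]).T @ C
        H[np.diag_indices_from(H)] += pen
        T = np.linalg.inv(H)
        new_var = {}
        for g in names:
            idx = p + np.arange(q)[sl[g]]
            m_g = levels[g]
            new_var[g] = max(
                (b[sl[g]] @ b[sl[g]] + np.trace(T[np.ix_(idx, idx)])) / m_g,
                min_var,
            )

        ll = _laplace_loglik(y, mu, b, var, sl, Z, w, names, min_var)
        # convergence on the Laplace log-likelihood: weakly identified
        # variance components (near-flat likelihood directions) may
        # keep drifting long after the likelihood has stabilised
        if it >= 6 and abs(ll - loglik) < tol * (1 + abs(ll)):
            loglik = ll
            converged_ll = True
            break
        done = all(abs(new_var[g] - var[g]) < tol * (1 + var[g]) for g in names)
        var_hist.append(dict(var))
        # Aitken extrapolation of the slowly-converging variance
        # fixed point: v* ~ v1 + (v1 - v0) * r / (1 - r)
        if len(var_hist) >= 2 and it % 2 == 0 and not done:
            prev, cur = var_hist[-2], var_hist[-1]
            for g in names:
                d1 = cur[g] - prev[g]
                d2 = new_var[g] - cur[g]
                if abs(d1) > 0:
                    r = d2 / d1
                    if 0 < r < 0.995:
                        new_var[g] = max(new_var[g] + d2 * r / (1 - r), min_var)
        var = new_var
        if done:
            loglik = ll
            converged_ll = True
            break
        loglik = ll

    # fixed-effect covariance from the joint penalised Hessian
    eta = C @ np.concatenate([beta, b])
    mu = _sigmoid(eta)
    w = np.maximum(mu * (1 - mu), 1e-10)
    pen = np.zeros(p + q)
    for g in names:
        pen[p + np.arange(q)[sl[g]]] = 1.0 / max(var[g], min_var)
    H = (C * w[:, None]).T @ C
    H[np.diag_indices_from(H)] += pen
    cov = np.linalg.inv(H)
    beta_se = np.sqrt(np.diag(cov)[:p])

    return GlmmFit(
        beta=beta,
        beta_se=beta_se,
        random_sds={g: float(np.sqrt(var[g])) for g in names},
        b={g: b[sl[g]].copy() for g in names},
        loglik=float(loglik),
        n_obs=n,
        converged=converged_ll,
        n_iter=it,
        separation=separation,
    )


def _laplace_loglik(y, mu, b, var, sl, Z, w, names, min_var):
    mu_c = np.clip(mu, 1e-12, 1 - 1e-12)
    l_cond = float(y @ np.log(mu_c) + (1 - y) @ np.log(1 - mu_c))
    quad = 0.0
    d = np.empty(Z.shape[1])
    for g in names:
        v = max(var[g], min_var)
        quad += b[sl[g]] @ b[sl[g]] / v
        d[sl[g]] = v
    # log det(I + Z'WZ D); Z'WZ is q x q
    A = (Z * w[:, None]).T @ Z * d[None, :]
    A[np.diag_indices_from(A)] += 1.0
    sign, logdet = np.linalg.slogdet(A)
    return l_cond - 0.5 * quad - 0.5 * logdet


@dataclass
class FirthFit:
    beta: np.ndarray
    beta_se: np.ndarray
    loglik: float  # penalised
    converged: bool


def firth_logistic(
    X: np.ndarray, y: np.ndarray, max_iter: int = 100, tol: float = 1e-10
) -> FirthFit:
    """Bias-reduced logistic regression (Jeffreys-prior penalty).

    Finite estimates exist even under complete separation, which is
    the use case here (old females reproduce with probability 1).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    beta = np.zeros(p)
    converged = False
    for _ in range(max_iter):
        eta = X @ beta
        mu = _sigmoid(eta)
        w = np.maximum(mu * (1 - mu), 1e-12)
        XW = X * w[:, None]
        F = XW.T @ X
        Finv = np.linalg.inv(F)
        h = np.einsum("ij,jk,ik->i", X, Finv, XW)
        U = X.T @ (y - mu + h * (0.5 - mu))
        step = Finv @ U
        # damp large steps for stability near separation
        norm = np.abs(step).max()
        if norm > 5.0:
            step *= 5.0 / norm
        beta = beta + step
        if np.abs(step).max() < tol:
            converged = True
            break
    eta = X @ beta
    mu = np.clip(_sigmoid(eta), 1e-12, 1 - 1e-12)
    w = np.maximum(mu * (1 - mu), 1e-12)
    F = (X * w[:, None]).T @ X
    sign, logdet = np.linalg.slogdet(F)
    ll = float(y @ np.log(mu) + (1 - y) @ np.log(1 - mu)) + 0.5 * logdet
    se = np.sqrt(np.diag(np.linalg.inv(F)))
    return FirthFit(beta=beta, beta_se=se, loglik=ll, converged=converged)
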