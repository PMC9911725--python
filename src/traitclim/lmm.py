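"""Restricted-maximum-likelihood estimation of variance-components
linear mixed models.

The model is

    y = X beta + sum_k Z_k b_k + e,
    b_k ~ N(0, sigma2_k I),   e ~ N(0, sigma2_eps W^{-1}),

with each random block (habitat intercepts, one habitat x climate-PC slope
block per PC, the low-rank spatial smooth) carrying a single i.i.d.
variance.  Observation weights W scale residual precision; rows are
pre-multiplied by sqrt(w), which reduces the weighted problem to the
unweighted one.

Estimation profiles beta and sigma2_eps out of the REML criterion and
optimises the profiled deviance over the log variance ratios
phi_k = log(sigma2_k / sigma2_eps).  All per-evaluation work uses cached
cross-products, so one evaluation costs one q x q Cholesky factorisation
(q = total number of random-effect columns).  The profiled deviance is

    d(phi) = log|L_Z|^2 + log|L_X|^2 + (n - p) [1 + log(2 pi r^2 / (n - p))]

where L_Z is the Cholesky factor of Lambda' Z'Z Lambda + I, L_X comes from
the profiled fixed-effects block and r^2 is the penalized residual sum of
squares — the same profiled criterion used by penalized-least-squares
mixed-model software.  BLUPs and their conditional standard errors, and
the joint covariance of (BLUP error, beta-hat) needed for habitat-specific
slope inference, come from the mixed-model equations at the optimum.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import scipy.sparse as sp
from scipy.linalg import solve_triangular
from scipy.optimize import minimize
from sklearn.base import BaseEstimator

__all__ = ["RandomBlock", "VarianceComponentsREML", "ConvergenceError"]

_PHI_LO, _PHI_HI = -30.0, 15.0


class ConvergenceError(RuntimeError):
    """REML optimisation failed; carries the deviance trace."""

    def __init__(self, message: str, trace=None):
        super().__init__(message)
        self.trace = trace


@dataclass
class RandomBlock:
    """One i.i.d.-variance random-effect block.

    ``Z`` is the (n, q_k) design; for a grouped intercept it is the group
    indicator matrix, for a random slope the indicator scaled by the
    covariate, for the spatial smooth the whitened radial basis.
    ``labels`` names the q_k columns (group codes or knot ids).
    """

    name: str
    Z: object  # scipy sparse or ndarray, shape (n, q_k)
    labels: Optional[Sequence] = None

    @classmethod
    def from_groups(cls, name: str, groups, covariate=None) -> "RandomBlock":
        """Indicator (optionally covariate-scaled) block from group labels."""
        groups = np.asarray(groups)
        codes, labels = _factorize(groups)
        n = len(groups)
        vals = np.ones(n) if covariate is None else np.asarray(covariate, dtype=float)
        Z = sp.csr_matrix((vals, (np.arange(n), codes)), shape=(n, len(labels)))
        return cls(name=name, Z=Z, labels=list(labels))

    @property
    def q(self) -> int:
        return self.Z.shape[1]

    def group_sizes(self) -> np.ndarray:
        Zb = self.Z
        if sp.issparse(Zb):
            return np.asarray((Zb != 0).sum(axis=0)).ravel()
        return (np.asarray(Zb) != 0).sum(axis=0)


def _factorize(groups):
    labels, codes = np.unique(groups, return_inverse=True)
    return codes, labels


class VarianceComponentsREML(BaseEstimator):
    """Scikit-learn style estimator for variance-components LMMs by REML.

    Parameters
    ----------
    max_iter : maximum optimiser iterations.
    rel_tol : relative deviance-change convergence tolerance.
    variance_floor_ratio : reported variance components are floored at
        ``variance_floor_ratio * var(y)`` (non-negativity at a small floor).

    Fitted attributes (trailing underscore)
    ---------------------------------------
    beta_, beta_se_, beta_cov_ : fixed effects, standard errors, covariance.
    sigma2_ : residual variance.
    varcomp_ : dict block name -> variance component.
    theta_ : dict block name -> variance ratio sigma2_k / sigma2_eps.
    blups_ : dict block name -> dict with ``labels``, ``estimate``,
        ``cond_se`` and ``cov_with_beta`` (q_k x p cross-covariance of
        BLUP error with beta-hat).
    loglik_reml_ : restricted log-likelihood (up to an additive constant).
    convergence_ : dict with iteration count, deviance trace, an
        approximate gradient norm at the optimum and the optimiser message.
    """

    def __init__(self, max_iter: int = 500, rel_tol: float = 1e-8,
                 variance_floor_ratio: float = 1e-10):
        self.max_iter = max_iter
        self.rel_tol = rel_tol
        self.variance_floor_ratio = variance_floor_ratio

    # ------------------------------------------------------------------
    def fit(self, X, y, blocks: Sequence[RandomBlock] = (), weights=None):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        n, p = X.shape
        if len(y) != n:
            raise ValueError("X and y length mismatch")
        if n <= p:
            raise ValueError("need n > number of fixed effects")
        if not (np.isfinite(X).all() and np.isfinite(y).all()):
            raise ValueError("non-finite values in design or response")
        blocks = list(blocks)
        for b in blocks:
            if b.Z.shape[0] != n:
                raise ValueError(f"block {b.name!r} row count mismatch")

        if weights is not None:
            w = np.asarray(weights, dtype=float).ravel()
            if (w <= 0).any():
                raise ValueError("weights must be positive")
            sw = np.sqrt(w)
            Xw, yw = X * sw[:, None], y * sw
            Zs = [b.Z.multiply(sw[:, None]).tocsr() if sp.issparse(b.Z)
                  else np.asarray(b.Z) * sw[:, None] for b in blocks]
        else:
            Xw, yw = X, y
            Zs = [b.Z for b in blocks]

        self.n_obs_, self.n_fixed_ = n, p
        self.blocks_ = blocks
        self._X, self._y = X, y

        if not blocks:
            self._fit_ols(Xw, yw)
            return self

        # cached cross-products -----------------------------------------
        Z = sp.hstack([sp.csr_matrix(Zb) for Zb in Zs], format="csr")
        q = Z.shape[1]
        slices, start = [], 0
        for b in blocks:
            slices.append(slice(start, start + b.q))
            start += b.q
        ZtZ = np.asarray((Z.T @ Z).todense())
        ZtX = np.asarray(Z.T @ Xw)
        Zty = np.asarray(Z.T @ yw).ravel()
        XtX = Xw.T @ Xw
        Xty = Xw.T @ yw
        yty = float(yw @ yw)
        rankcheck = np.linalg.matrix_rank(XtX)
        if rankcheck < p:
            raise np.linalg.LinAlgError("singular fixed-effect design")

        K = len(blocks)
        col_block = np.concatenate([np.full(b.q, k) for k, b in enumerate(blocks)])

        def profiled(phi, want=False):
            theta = np.exp(np.clip(phi, _PHI_LO, _PHI_HI))
            s = np.sqrt(theta)[col_block]
            A = ZtZ * np.outer(s, s)
            A[np.diag_indices(q)] += 1.0
            try:
                L = np.linalg.cholesky(A)
            except np.linalg.LinAlgError:
                return (np.inf, None) if want else np.inf
            cu = solve_triangular(L, s * Zty, lower=True)
            CZX = solve_triangular(L, s[:, None] * ZtX, lower=True)
            XtVX = XtX - CZX.T @ CZX
            try:
                LX = np.linalg.cholesky(XtVX)
            except np.linalg.LinAlgError:
                return (np.inf, None) if want else np.inf
            cb = solve_triangular(LX, Xty - CZX.T @ cu, lower=True)
            r2 = max(yty - cu @ cu - cb @ cb, 1e-300)
            dev = (2 * np.log(np.diag(L)).sum() + 2 * np.log(np.diag(LX)).sum()
                   + (n - p) * (1.0 + np.log(2 * np.pi * r2 / (n - p))))
            if not want:
                return dev
            beta = solve_triangular(LX.T, cb, lower=False)
            return dev, dict(theta=theta, s=s, L=L, LX=LX, cu=cu, CZX=CZX,
                             XtVX=XtVX, beta=beta, r2=r2)

        phi0 = np.full(K, np.log(0.1))
        trace: list[float] = [profiled(phi0)]

        def cb_record(xk):
            trace.append(float(profiled(xk)))

        res = minimize(
            profiled, phi0, method="Powell",
            bounds=[(_PHI_LO, _PHI_HI)] * K,
            callback=cb_record,
            options=dict(maxiter=self.max_iter, xtol=1e-10, ftol=self.rel_tol),
        )
        if not res.success and "maxiter" not in str(res.message).lower():
            raise ConvergenceError(f"REML optimisation failed: {res.message}", trace)
        if not res.success:
            raise ConvergenceError(
                f"REML did not converge in {self.max_iter} iterations", trace)
        phi_hat = np.clip(res.x, _PHI_LO, _PHI_HI)
        dev, parts = profiled(phi_hat, want=True)
        trace.append(float(dev))

        sigma2 = parts["r2"] / (n - p)
        theta = parts["theta"]
        floor = self.variance_floor_ratio * float(np.var(y))
        self.sigma2_ = float(sigma2)
        self.theta_ = {b.name: float(theta[k]) for k, b in enumerate(blocks)}
        self.varcomp_ = {
            b.name: float(max(theta[k] * sigma2, floor)) for k, b in enumerate(blocks)
        }
        self.beta_ = parts["beta"]
        XtVX_inv = np.linalg.inv(parts["XtVX"])
        self.beta_cov_ = sigma2 * XtVX_inv
        self.beta_se_ = np.sqrt(np.diag(self.beta_cov_))

        # mixed-model equations: joint covariance of (u_hat - u, beta_hat)
        s = parts["s"]
        A = ZtZ * np.outer(s, s)
        A[np.diag_indices(q)] += 1.0
        M = np.block([[A, s[:, None] * ZtX], [(s[:, None] * ZtX).T, XtX]])
        Minv = np.linalg.inv(M)
        u_hat = solve_triangular(
            parts["L"].T, parts["cu"] - parts["CZX"] @ self.beta_, lower=False
        )
        b_hat = s * u_hat
        cond_var_b = sigma2 * (s**2) * np.diag(Minv)[:q]
        cov_b_beta = sigma2 * (s[:, None] * Minv[:q, q:])

        self.blups_ = {}
        for k, (b, sl) in enumerate(zip(blocks, slices)):
            self.blups_[b.name] = dict(
                labels=list(b.labels) if b.labels is not None else list(range(b.q)),
                estimate=b_hat[sl].copy(),
                cond_se=np.sqrt(np.maximum(cond_var_b[sl], 0.0)),
                cov_with_beta=cov_b_beta[sl].copy(),
            )
        self._b_hat_full = b_hat
        self._Z = Z
        self.loglik_reml_ = -0.5 * float(dev)
        grad = _fd_grad(profiled, phi_hat)
        self.convergence_ = dict(
            n_iter=int(res.nit), n_fev=int(res.nfev), converged=True,
            deviance_trace=[float(t) for t in trace],
            grad_norm=float(np.linalg.norm(grad)), message=str(res.message),
        )
        self.fitted_values_ = X @ self.beta_ + np.asarray(Z @ b_hat).ravel()
        return self

    # ------------------------------------------------------------------
    def _fit_ols(self, Xw, yw):
        n, p = Xw.shape
        XtX = Xw.T @ Xw
        if np.linalg.matrix_rank(XtX) < p:
            raise np.linalg.LinAlgError("singular fixed-effect design")
        XtX_inv = np.linalg.inv(XtX)
        beta = XtX_inv @ (Xw.T @ yw)
        resid = yw - Xw @ beta
        sigma2 = float(resid @ resid / (n - p))
        self.beta_ = beta
        self.sigma2_ = sigma2
        self.beta_cov_ = sigma2 * XtX_inv
        self.beta_se_ = np.sqrt(np.diag(self.beta_cov_))
        self.varcomp_, self.theta_, self.blups_ = {}, {}, {}
        self.loglik_reml_ = -0.5 * (
            (n - p) * (1 + np.log(2 * np.pi * sigma2)) + np.log(np.linalg.det(XtX))
            - p * np.log(sigma2)
        )
        self.convergence_ = dict(n_iter=0, n_fev=1, converged=True,
                                 deviance_trace=[], grad_norm=0.0, message="OLS")
        self.fitted_values_ = self._X @ beta

    def predict(self, X):
        """Population-level prediction (fixed effects only)."""
        return np.asarray(X, dtype=float) @ self.beta_


def _fd_grad(fun, x, eps=1e-5):
    g = np.zeros_like(x)
    f0 = fun(x)
    for i in range(len(x)):
        xp = x.copy(); xp[i] += eps
        xm = x.copy(); xm[i] -= eps
        fp, fm = fun(xp), fun(xm)
        if np.isfinite(fp) and np.isfinite(fm):
            g[i] = (fp - fm) / (2 * eps)
        else:
            g[i] = (fp - f0) / eps if np.isfinite(fp) else 0.0
    return g
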