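"""Spatial lag regression by maximum likelihood, OLS baseline, and forward
simulation from the spatial lag process.

The spatial lag model is

    y = rho * W y + X beta + eps,     eps ~ N(0, sigma^2 I),

with ``W`` a row-standardised spatial weight matrix.  The Gaussian
log-likelihood concentrates beta and sigma^2 out by GLS at each rho, leaving a
one-dimensional problem in rho whose Jacobian term log|I - rho W| is evaluated
through the eigenvalues of W:  log|I - rho W| = sum_k log(1 - rho w_k).  The
admissible interval for rho is (1/w_min, 1/w_max), which for a row-standardised
W is (1/w_min, 1) with w_min < 0.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.linalg import qr

from .results import FitResults
from .weights import SpatialWeights

__all__ = ["SpatialLag", "fit_spatial_lag_ml", "fit_ols", "simulate_spatial_lag"]

#: Guard keeping the rho search away from the interval endpoints.
RHO_BOUNDARY_DELTA = 1e-6


def _check_design(y, X):
    y = np.asarray(y, dtype=float).ravel()
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] != len(y):
        raise ValueError("X must be n x p aligned with y")
    return y, X


def _require_full_rank(X, names):
    """Raise naming the dependent columns if X is rank deficient."""
    _, R, piv = qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps if diag.size else 0.0
    rank = int(np.sum(diag > tol))
    if rank < X.shape[1]:
        bad = [names[j] for j in piv[rank:]]
        raise ValueError(f"design matrix is rank deficient; collinear column(s): {bad}")


def fit_ols(y, X, names=None, ci_level: float = 0.95) -> FitResults:
    """Ordinary least squares with classical SEs and two-sided Wald CIs."""
    import statsmodels.api as sm

    y, X = _check_design(y, X)
    names = list(names) if names is not None else [f"x{j}" for j in range(X.shape[1])]
    if X.shape[0] <= X.shape[1]:
        raise ValueError("need n > p for OLS")
    _require_full_rank(X, names)
    res = sm.OLS(y, X).fit()
    ci = res.conf_int(alpha=1 - ci_level)
    params = pd.Series(res.params, index=names)
    return FitResults("ols", params, pd.Series(res.bse, index=names),
                      pd.Series(ci[:, 0], index=names),
                      pd.Series(ci[:, 1], index=names),
                      llf=res.llf, nobs=len(y), ci_level=ci_level)


def simulate_spatial_lag(W: SpatialWeights, X, rho: float, beta, noise_sd: float,
                         link: str = "identity", seed=None, rng=None):
    """Draw one outcome vector from the spatial lag process.

    Solves ``y = (I - rho W)^{-1} (X beta + eps)`` with ``eps ~ N(0,
    noise_sd^2 I)``.  ``link="probit"`` thresholds the latent vector at zero
    and returns the 0/1 indicator.
    """
    X = np.asarray(X, dtype=float)
    beta = np.asarray(beta, dtype=float)
    if X.shape[0] != W.n or X.shape[1] != len(beta):
        raise ValueError("X, beta and W dimensions are inconsistent")
    if abs(rho) >= 1 and W.normalized:
        raise ValueError("|rho| must be < 1 for a row-normalized W")
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    if link not in ("identity", "probit"):
        raise ValueError(f"unknown link {link!r}")
    if rng is None:
        rng = np.random.default_rng(seed)
    eps = rng.normal(0.0, noise_sd, size=W.n) if noise_sd > 0 else np.zeros(W.n)
    A = np.eye(W.n) - rho * W.toarray()
    try:
        latent = np.linalg.solve(A, X @ beta + eps)
    except np.linalg.LinAlgError as exc:
        raise ValueError(f"(I - rho W) is singular at rho={rho}") from exc
    if not np.all(np.isfinite(latent)):
        raise ValueError(f"(I - rho W) is numerically singular at rho={rho}")
    if link == "probit":
        return (latent > 0).astype(float)
    return latent


class SpatialLag:
    """Maximum-likelihood spatial lag model ``y = rho W y + X beta + eps``.

    Parameters
    ----------
    y, X : outcome vector and design matrix (intercept included in X),
        aligned to ``W.unit_order``.
    W : row-normalized :class:`SpatialWeights`.
    names : column names for X.
    eigenvalues : optional precomputed spectrum of W — pass this when fitting
        many replicates that share one W, so the eigendecomposition is done
        once.
    """

    def __init__(self, y, X, W: SpatialWeights, names=None, eigenvalues=None):
        if not isinstance(W, SpatialWeights):
            raise TypeError("W must be a SpatialWeights")
        if not W.normalized:
            raise ValueError("spatial lag ML requires a row-normalized W")
        y, X = _check_design(y, X)
        if len(y) != W.n:
            raise ValueError("y length must match W")
        if len(y) <= X.shape[1] + 1:
            raise ValueError("need n > p + 1")
        self.y = y
        self.X = X
        self.W = W
        self.names = list(names) if names is not None else \
            [f"x{j}" for j in range(X.shape[1])]
        _require_full_rank(X, self.names)
        self._omega = np.asarray(eigenvalues) if eigenvalues is not None \
            else W.eigenvalues()
        self._Wy = W.dot(y)
        # QR of X reused by every profile evaluation
        self._Q, self._R = np.linalg.qr(X)

    @classmethod
    def from_dataframe(cls, dataset, formula: str, W: SpatialWeights, **kw):
        """Build from a SurveyDataset (rows must align with W.unit_order)."""
        y, X, names = dataset.design_matrix(formula)
        return cls(y, X, W, names=names, **kw)

    # -- likelihood ----------------------------------------------------------
    def rho_interval(self, delta: float = RHO_BOUNDARY_DELTA):
        w = self._omega
        w_min, w_max = float(w.min()), float(w.max())
        lo = 1.0 / w_min + delta if w_min < 0 else -1.0 + delta
        hi = 1.0 / w_max - delta if w_max > 0 else 1.0 - delta
        return lo, hi

    def _profile(self, rho: float):
        """beta, sigma2 and residuals at fixed rho (GLS profile)."""
        e = self.y - rho * self._Wy
        beta = np.linalg.solve(self._R, self._Q.T @ e)
        u = e - self.X @ beta
        sigma2 = float(u @ u) / len(e)
        return beta, sigma2, u

    def concentrated_loglike(self, rho: float) -> float:
        """Profile log-likelihood in rho alone."""
        n = len(self.y)
        _, sigma2, _ = self._profile(rho)
        logdet = float(np.sum(np.log(np.abs(1.0 - rho * self._omega))))
        return -0.5 * n * (np.log(2.0 * np.pi * sigma2) + 1.0) + logdet

    def loglike(self, rho: float, beta, sigma2: float) -> float:
        """Full Gaussian log-likelihood."""
        n = len(self.y)
        u = self.y - rho * self._Wy - self.X @ np.asarray(beta, dtype=float)
        logdet = float(np.sum(np.log(np.abs(1.0 - rho * self._omega))))
        return -0.5 * n * np.log(2.0 * np.pi * sigma2) + logdet \
            - 0.5 * float(u @ u) / sigma2

    # -- estimation ----------------------------------------------------------
    def fit(self, ci_level: float = 0.95) -> FitResults:
        lo, hi = self.rho_interval()
        opt = optimize.minimize_scalar(
            lambda r: -self.concentrated_loglike(r),
            bounds=(lo, hi), method="bounded",
            options={"xatol": 1e-10},
        )
        rho_hat = float(opt.x)
        beta_hat, sigma2_hat, _ = self._profile(rho_hat)
        llf = self.loglike(rho_hat, beta_hat, sigma2_hat)

        theta = np.concatenate([[rho_hat], beta_hat, [sigma2_hat]])
        H = self._numeric_hessian(theta)
        cov = self._covariance(H)
        se = np.sqrt(np.diag(cov)[: 1 + len(beta_hat)])

        names = ["rho"] + self.names
        est = np.concatenate([[rho_hat], beta_hat])
        zq = stats.norm.ppf(0.5 + ci_level / 2.0)
        params = pd.Series(est, index=names)
        bse = pd.Series(se, index=names)
        warns = []
        if rho_hat - lo < 10 * RHO_BOUNDARY_DELTA or hi - rho_hat < 10 * RHO_BOUNDARY_DELTA:
            warns.append(f"rho estimate {rho_hat:.6f} is at the boundary of "
                         f"({lo:.6f}, {hi:.6f})")
        res = FitResults("ml", params, bse, params - zq * bse, params + zq * bse,
                         llf=llf, nobs=len(self.y), ci_level=ci_level,
                         warnings_=warns)
        res.sigma2 = sigma2_hat
        res.rho_interval = (lo, hi)
        return res

    def _numeric_hessian(self, theta, rel_step: float = 1e-5) -> np.ndarray:
        """Central-difference Hessian of the full log-likelihood at theta
        ordered (rho, beta..., sigma2)."""
        def f(t):
            return self.loglike(t[0], t[1:-1], t[-1])

        k = len(theta)
        h = rel_step * np.maximum(1.0, np.abs(theta))
        h[-1] = min(h[-1], 0.5 * theta[-1])  # keep sigma2 positive
        H = np.empty((k, k))
        f0 = f(theta)
        for i in range(k):
            ei = np.zeros(k); ei[i] = h[i]
            H[i, i] = (f(theta + ei) - 2.0 * f0 + f(theta - ei)) / h[i] ** 2
            for j in range(i + 1, k):
                ej = np.zeros(k); ej[j] = h[j]
                H[i, j] = H[j, i] = (
                    f(theta + ei + ej) - f(theta + ei - ej)
                    - f(theta - ei + ej) + f(theta - ei - ej)
                ) / (4.0 * h[i] * h[j])
        return H

    @staticmethod
    def _covariance(H: np.ndarray) -> np.ndarray:
        try:
            cov = np.linalg.inv(-H)
        except np.linalg.LinAlgError:
            cov = np.linalg.pinv(-H)
        d = np.diag(cov).copy()
        d[d < 0] = np.nan
        cov = cov.copy()
        np.fill_diagonal(cov, d)
        return cov


def fit_spatial_lag_ml(y, X, W: SpatialWeights, names=None,
                       ci_level: float = 0.95, eigenvalues=None) -> FitResults:
    """Functional wrapper around :class:`SpatialLag` ``.fit()``."""
    return SpatialLag(y, X, W, names=names, eigenvalues=eigenvalues).fit(ci_level=ci_level)
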