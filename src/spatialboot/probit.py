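"""Bayesian spatial-lag probit via data augmentation.

The binary outcome y is modelled through a latent index that follows the
spatial lag process,

    z = rho * W z + X beta + eps,   eps ~ N(0, I),   y_i = 1{z_i > 0}.

A Gibbs sampler cycles through

1. the latent vector z, element by element from its truncated-normal full
   conditional (precision matrix P = A'A with A = I - rho W, truncation side
   fixed by the observed y);
2. beta from its conjugate normal conditional under a diffuse flat prior,
   N((X'X)^{-1} X' A z, (X'X)^{-1});
3. rho by griddy Gibbs on a fixed grid over (-1, 1), with the Jacobian
   log|I - rho W| evaluated through the eigenvalues of W.

Posterior means, SDs and central credible intervals are reported from the
kept draws.  Fixing ``rho_fixed=0`` degenerates the sampler to the classic
augmented probit, which must agree with standard ML probit — a reduction the
test suite checks against statsmodels.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.special import ndtr, ndtri

from .results import FitResults
from .weights import SpatialWeights

__all__ = ["SpatialProbit", "fit_spatial_probit"]

_U_EPS = 1e-12  # clamp for inverse-CDF truncated normal draws


def _truncated_normal(rng, mean, sd, positive: bool) -> float:
    """One draw from N(mean, sd^2) truncated to (0, inf) or (-inf, 0]."""
    a = ndtr(-mean / sd)  # P(X <= 0)
    if positive:
        u = a + (1.0 - a) * rng.random()
    else:
        u = a * rng.random()
    u = min(max(u, _U_EPS), 1.0 - _U_EPS)
    return mean + sd * ndtri(u)


class SpatialProbit:
    """Spatial-lag probit model for a binary outcome on a row-normalized W."""

    def __init__(self, y, X, W: SpatialWeights, names=None):
        y = np.asarray(y, dtype=float).ravel()
        X = np.asarray(X, dtype=float)
        if not isinstance(W, SpatialWeights) or not W.normalized:
            raise ValueError("spatial probit requires a row-normalized SpatialWeights")
        if X.shape[0] != len(y) or len(y) != W.n:
            raise ValueError("y, X and W dimensions are inconsistent")
        uniq = set(np.unique(y))
        if not uniq <= {0.0, 1.0}:
            raise ValueError("outcome must be binary 0/1")
        if len(uniq) < 2:
            raise ValueError("outcome has no variation")
        self.y = y
        self.X = X
        self.W = W
        self.names = list(names) if names is not None else \
            [f"x{j}" for j in range(X.shape[1])]

    @classmethod
    def from_dataframe(cls, dataset, formula: str, W: SpatialWeights):
        y, X, names = dataset.design_matrix(formula)
        return cls(y, X, W, names=names)

    def _separation_warning(self):
        warns = []
        for j, name in enumerate(self.names):
            col = self.X[:, j]
            if np.ptp(col) == 0:
                continue
            x1, x0 = col[self.y == 1], col[self.y == 0]
            if x1.min() > x0.max() or x1.max() < x0.min():
                warns.append(f"possible perfect separation on {name!r}")
        return warns

    def fit(self, n_draws: int = 2000, burn_in: int = 500, seed: int | None = None,
            rho_fixed: float | None = None, ci_level: float = 0.95,
            rho_grid_step: float = 0.005) -> FitResults:
        """Run the Gibbs sampler and summarise the kept draws.

        ``rho_fixed`` pins rho (e.g. 0 for the non-spatial reduction) instead
        of sampling it.  The draw sequence is fully determined by ``seed``.
        """
        if n_draws < 1 or burn_in < 0:
            raise ValueError("need n_draws >= 1 and burn_in >= 0")
        rng = np.random.default_rng(seed)
        n, p = self.X.shape
        X, y, Wd = self.X, self.y, self.W.toarray()

        XtX = X.T @ X
        XtX_inv = np.linalg.inv(XtX)
        chol_b = np.linalg.cholesky(XtX_inv)
        WtW = Wd.T @ Wd
        WplusWt = Wd + Wd.T

        if rho_fixed is None:
            omega = self.W.eigenvalues()
            grid = np.arange(-0.99, 0.99 + rho_grid_step / 2, rho_grid_step)
            logdet_grid = np.sum(np.log(np.abs(1.0 - np.outer(grid, omega))), axis=1)
        else:
            grid = logdet_grid = None

        rho = 0.0 if rho_fixed is None else float(rho_fixed)
        beta = np.zeros(p)
        z = np.where(y > 0, 0.5, -0.5)

        keep_beta = np.empty((n_draws, p))
        keep_rho = np.empty(n_draws)
        total = burn_in + n_draws
        positive = y > 0

        P = None
        rho_of_P = None
        for it in range(total):
            # latent z sweep
            if P is None or rho != rho_of_P:
                P = np.eye(n) - rho * WplusWt + rho * rho * WtW
                rho_of_P = rho
                P_diag = P.diagonal().copy()
                cond_sd = 1.0 / np.sqrt(P_diag)
            Xb = X @ beta
            b = Xb - rho * (Wd.T @ Xb)  # linear term A'Xbeta of the Gaussian
            for i in range(n):
                r = P[i] @ z - P_diag[i] * z[i]
                m = (b[i] - r) / P_diag[i]
                z[i] = _truncated_normal(rng, m, cond_sd[i], positive[i])

            # beta | z, rho
            Az = z - rho * (Wd @ z)
            bmean = XtX_inv @ (X.T @ Az)
            beta = bmean + chol_b @ rng.standard_normal(p)

            # rho | z, beta (griddy Gibbs)
            if rho_fixed is None:
                e0 = z - X @ beta
                Wz = Wd @ z
                s0 = e0 @ e0
                s1 = e0 @ Wz
                s2 = Wz @ Wz
                logpost = logdet_grid - 0.5 * (s0 - 2.0 * grid * s1 + grid ** 2 * s2)
                logpost -= logpost.max()
                w = np.exp(logpost)
                cdf = np.cumsum(w)
                rho = float(grid[np.searchsorted(cdf, rng.random() * cdf[-1])])

            if it >= burn_in:
                keep_beta[it - burn_in] = beta
                keep_rho[it - burn_in] = rho

        draws = np.column_stack([keep_rho, keep_beta])
        names = ["rho"] + self.names
        mean = draws.mean(axis=0)
        sd = draws.std(axis=0, ddof=1)
        a = (1.0 - ci_level) / 2.0
        lo = np.quantile(draws, a, axis=0)
        hi = np.quantile(draws, 1.0 - a, axis=0)
        if rho_fixed is not None:
            sd[0] = 0.0
            lo[0] = hi[0] = mean[0]
        method = "gibbs_data_augmentation" if rho_fixed is None \
            else "standard_probit_reduction"
        res = FitResults(method, pd.Series(mean, index=names),
                         pd.Series(sd, index=names),
                         pd.Series(lo, index=names), pd.Series(hi, index=names),
                         nobs=n, ci_level=ci_level, seed=seed,
                         warnings_=self._separation_warning())
        res.draws = pd.DataFrame(draws, columns=names)
        res.draws_kept = n_draws
        res.burn_in = burn_in
        return res


def fit_spatial_probit(y, X, W: SpatialWeights, n_draws: int = 2000,
                       burn_in: int = 500, seed: int | None = None,
                       names=None, **kw) -> FitResults:
    """Functional wrapper around :class:`SpatialProbit` ``.fit()``."""
    return SpatialProbit(y, X, W, names=names).fit(
        n_draws=n_draws, burn_in=burn_in, seed=seed, **kw)
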