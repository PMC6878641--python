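"""Global Moran's I with normal-approximation or permutation inference."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .weights import SpatialWeights

__all__ = ["MoranResult", "morans_i"]


@dataclass
class MoranResult:
    """Moran's I and its inference.

    ``expected`` is the null expectation -1/(n-1); ``z`` and ``p_value`` come
    from either the normality approximation or the permutation distribution.
    """

    I: float
    expected: float
    variance: float
    z: float
    p_value: float
    inference: str
    n: int
    n_perm: int | None = None
    seed: int | None = None

    def to_frame(self) -> pd.DataFrame:
        """One-row table (statistic, sd, p)."""
        return pd.DataFrame(
            {"morans_i": [self.I], "sd": [np.sqrt(self.variance)],
             "p_value": [self.p_value], "expected": [self.expected],
             "inference": [self.inference], "n": [self.n]}
        )

    def to_csv(self, path):
        self.to_frame().to_csv(path, index=False)


def morans_i(values, W: SpatialWeights, inference: str = "normal_approx",
             n_perm: int = 999, seed: int | None = None) -> MoranResult:
    """Moran's I spatial autocorrelation statistic.

        I = (n / S0) * sum_ij W_ij z_i z_j / sum_i z_i^2,   z = values - mean,

    with S0 the total weight.  W is used as given (raw or row-standardised).
    ``inference="normal_approx"`` uses the classic moments under normality;
    ``inference="permutation"`` uses ``n_perm`` random relabelings of the
    values (two-sided pseudo p-value, so p >= 1/(n_perm+1)).
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or len(x) != W.n:
        raise ValueError(f"values must be a vector of length {W.n}")
    z = x - x.mean()
    den = float(z @ z)
    if den == 0.0:
        raise ValueError("zero variance: Moran's I is undefined for constant values")
    Wd = W.toarray()
    n = W.n
    S0 = float(Wd.sum())
    if S0 == 0.0:
        raise ValueError("weight matrix has zero total weight")
    I = (n / S0) * float(z @ Wd @ z) / den
    expected = -1.0 / (n - 1)

    if inference == "normal_approx":
        S1 = 0.5 * float(((Wd + Wd.T) ** 2).sum())
        S2 = float(((Wd.sum(axis=1) + Wd.sum(axis=0)) ** 2).sum())
        var = (n * n * S1 - n * S2 + 3.0 * S0 * S0) / ((n * n - 1.0) * S0 * S0) \
            - expected ** 2
        zscore = (I - expected) / np.sqrt(var)
        p = 2.0 * stats.norm.sf(abs(zscore))
        return MoranResult(I, expected, var, zscore, p, "normal_approx", n)
    if inference == "permutation":
        if n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        rng = np.random.default_rng(seed)
        Zp = rng.permuted(np.broadcast_to(z, (n_perm, n)).copy(), axis=1)
        Ip = (n / S0) * np.einsum("pi,ij,pj->p", Zp, Wd, Zp) / den
        var = float(np.var(Ip, ddof=1))
        sd = np.sqrt(var) if var > 0 else np.nan
        zscore = (I - float(Ip.mean())) / sd if var > 0 else np.nan
        extreme = np.sum(np.abs(Ip - expected) >= abs(I - expected) - 1e-15)
        p = (1.0 + float(extreme)) / (n_perm + 1.0)
        return MoranResult(I, expected, var, zscore, min(p, 1.0),
                           "permutation", n, n_perm=n_perm, seed=seed)
    raise ValueError(f"unknown inference {inference!r}")
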