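"""Shared results container for the regression-style fits."""

from __future__ import annotations

import json

import numpy as np
import pandas as pd

__all__ = ["FitResults"]


class FitResults:
    """Point estimates with uncertainty for one model fit.

    ``params`` is a named Series; spatial fits include the spatial lag
    coefficient under the name ``"rho"`` alongside the regression
    coefficients.  ``bse`` are standard errors (posterior SDs for the Bayesian
    probit), and ``conf_int()`` returns the (1-a) interval bounds.
    """

    def __init__(self, method: str, params: pd.Series, bse: pd.Series,
                 ci_low: pd.Series, ci_high: pd.Series, *, llf=None,
                 nobs=None, ci_level=0.95, seed=None, warnings_=()):
        self.method = method
        self.params = params.astype(float)
        self.bse = bse.astype(float)
        self._ci_low = ci_low.astype(float)
        self._ci_high = ci_high.astype(float)
        self.llf = None if llf is None else float(llf)
        self.nobs = None if nobs is None else int(nobs)
        self.ci_level = float(ci_level)
        self.seed = seed
        self.warnings = list(warnings_)
        bad = (self._ci_low > self.params + 1e-12) | (self._ci_high < self.params - 1e-12)
        if bad.any():
            raise ValueError(f"interval does not bracket estimate for {list(self.params.index[bad])}")

    @property
    def rho(self):
        return float(self.params["rho"]) if "rho" in self.params.index else None

    @property
    def beta(self) -> pd.Series:
        return self.params.drop("rho", errors="ignore")

    def conf_int(self) -> pd.DataFrame:
        return pd.DataFrame({"ci_low": self._ci_low, "ci_high": self._ci_high})

    def coefficients_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"est": self.params, "se": self.bse,
                             "ci_low": self._ci_low, "ci_high": self._ci_high})

    def summary(self) -> str:
        head = [f"Method: {self.method}"]
        if self.nobs is not None:
            head.append(f"N: {self.nobs}")
        if self.llf is not None:
            head.append(f"log-likelihood: {self.llf:.4f}")
        head.append(f"CI level: {self.ci_level:.0%}")
        lines = ["  ".join(head), "-" * 72,
                 f"{'coef':>14} {'est':>12} {'se':>12} {'ci_low':>12} {'ci_high':>12}"]
        for name in self.params.index:
            lines.append(
                f"{name:>14} {self.params[name]:>12.6f} {self.bse[name]:>12.6f} "
                f"{self._ci_low[name]:>12.6f} {self._ci_high[name]:>12.6f}"
            )
        for w in self.warnings:
            lines.append(f"warning: {w}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "rho": self.rho,
            "coefficients": {
                name: {"est": float(self.params[name]), "se": float(self.bse[name]),
                       "ci_low": float(self._ci_low[name]),
                       "ci_high": float(self._ci_high[name])}
                for name in self.params.index
            },
            "loglik": self.llf,
            "n": self.nobs,
            "ci_level": self.ci_level,
            "seed": self.seed,
            "warnings": self.warnings,
        }

    def to_json(self, path=None, **kw):
        s = json.dumps(self.to_dict(), indent=2, **kw)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s + "\n")
        return s

    def __repr__(self):
        coefs = ", ".join(f"{k}={v:.4g}" for k, v in self.params.items())
        return f"<{type(self).__name__} {self.method}: {coefs}>"
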