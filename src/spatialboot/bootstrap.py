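"""One-observation-per-cluster bootstrap for spatial models.

Each replicate draws a single participant uniformly at random from every
cluster.  Because all members of a cluster share the cluster's coordinate,
every replicate has the same pairwise distances — the cluster-level
inverse-distance matrix — so the weight matrix is built and row-standardised
once and reused for all B replicates.  The chosen spatial model (ML spatial
lag, or Gibbs spatial probit) is fitted on each subsample and the replicate
fits are aggregated into means, spreads, percentile confidence intervals,
per-coefficient coverage probabilities against a stated truth, and mean
squared errors.

Coverage counts each replicate's own 95% Wald (or credible) interval against
a fixed truth; MSE averages squared deviations of the replicate point
estimates from that truth, the divisor being the number of replicates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .lag import SpatialLag
from .probit import SpatialProbit
from .results import FitResults
from .survey import SurveyDataset
from .weights import (SpatialWeights, build_inverse_distance_matrix,
                      cluster_centroid_matrix, row_normalize)

__all__ = ["OnePerClusterBootstrap", "BootstrapResults", "BootstrapReplicate",
           "sample_one_per_cluster", "run_bootstrap", "coverage_probability",
           "mse", "summarize_replicates"]

logger = logging.getLogger("spatialboot")

MODELS = ("lag_ols", "spatial_probit")

#: Hard ceiling on the tolerated fraction of failed replicate fits.
MAX_FAILURE_FRACTION = 0.10


@dataclass
class BootstrapReplicate:
    """One bootstrap draw: which participant represented each cluster, and
    the model fit on that subsample."""

    replicate_index: int
    selected_obs: dict
    fit: FitResults
    seed_key: tuple


def _cluster_groups(dataset: SurveyDataset):
    """Row indices per cluster, ordered by sorted cluster id."""
    cl = dataset.df["cluster_id"].to_numpy()
    order = np.argsort(cl, kind="stable")
    sorted_cl = cl[order]
    bounds = np.flatnonzero(np.r_[True, sorted_cl[1:] != sorted_cl[:-1], True])
    groups = [order[bounds[k]:bounds[k + 1]] for k in range(len(bounds) - 1)]
    return groups


def _select_indices(groups, rng) -> np.ndarray:
    sizes = np.array([len(g) for g in groups])
    if (sizes == 0).any():
        raise ValueError("empty cluster encountered")
    offs = np.minimum((rng.random(len(groups)) * sizes).astype(np.int64),
                      sizes - 1)
    return np.array([g[o] for g, o in zip(groups, offs)])


def sample_one_per_cluster(dataset: SurveyDataset, rng=None,
                           seed=None) -> SurveyDataset:
    """Draw one uniformly chosen participant from every cluster.

    The subsample has one row per cluster, ordered by sorted cluster id, so
    it aligns with the cluster-level weight matrix's unit order.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    groups = _cluster_groups(dataset)
    return dataset.subset(_select_indices(groups, rng))


def mse(estimates, truth: float) -> float:
    """Mean squared deviation of replicate estimates from the true value."""
    est = np.asarray(estimates, dtype=float)
    if est.size == 0:
        raise ValueError("mse needs at least one estimate")
    return float(np.mean((est - truth) ** 2))


def _ci_arrays(replicates, coefficient):
    fits = [r.fit if isinstance(r, BootstrapReplicate) else r for r in replicates]
    lo = np.array([f.conf_int().loc[coefficient, "ci_low"] for f in fits])
    hi = np.array([f.conf_int().loc[coefficient, "ci_high"] for f in fits])
    return lo, hi


def coverage_probability(replicates, truth: float, coefficient=None,
                         ci_low=None, ci_high=None) -> float:
    """Percentage of replicate confidence intervals containing the truth.

    Pass either ``replicates`` (fits or BootstrapReplicate objects) with a
    ``coefficient`` name, or precomputed ``ci_low``/``ci_high`` arrays.
    """
    if ci_low is None or ci_high is None:
        if not replicates:
            raise ValueError("no successful replicates")
        lo, hi = _ci_arrays(replicates, coefficient)
    else:
        lo = np.asarray(ci_low, dtype=float)
        hi = np.asarray(ci_high, dtype=float)
    if lo.size == 0:
        raise ValueError("no successful replicates")
    inside = (lo <= truth) & (truth <= hi)
    return 100.0 * float(inside.mean())


class BootstrapResults:
    """Aggregated one-per-cluster bootstrap output (a simulation summary).

    ``table`` is a per-coefficient DataFrame with columns mean_est, sd_est,
    mean_se, ci_low, ci_high (percentile bounds across replicate estimates),
    norm_ci_low/high (normal approximation), coverage_pct, mse, truth_used.
    """

    def __init__(self, table: pd.DataFrame, replicates, *, B, n_failed,
                 ci_level, seed, model, truth):
        self.table = table
        self.replicates = list(replicates)
        self.B = int(B)
        self.n_failed = int(n_failed)
        self.ci_level = float(ci_level)
        self.seed = seed
        self.model = model
        self.truth = dict(truth) if truth else None

    @property
    def n_success(self) -> int:
        return self.B - self.n_failed

    def replicate_estimates(self) -> pd.DataFrame:
        """Replicate-level point estimates, one row per successful replicate."""
        rows = {r.replicate_index: r.fit.params for r in self.replicates}
        return pd.DataFrame(rows).T

    def summary(self) -> str:
        lines = [
            f"One-per-cluster bootstrap: model={self.model} B={self.B} "
            f"failed={self.n_failed} seed={self.seed} CI level={self.ci_level:.0%}",
            self.table.to_string(float_format=lambda v: f"{v: .6f}"),
        ]
        return "\n".join(lines)

    def to_csv(self, path):
        out = self.table.copy()
        out.insert(0, "coefficient", out.index)
        with open(path, "w") as fh:
            fh.write(f"# spatialboot bootstrap summary: model={self.model} "
                     f"B={self.B} failed={self.n_failed} seed={self.seed} "
                     f"ci_level={self.ci_level}\n")
            out.to_csv(fh, index=False)


def summarize_replicates(replicates, truth=None, ci_level: float = 0.95,
                         **meta) -> BootstrapResults:
    """Aggregate replicate fits into a simulation summary table.

    mean_est / sd_est are the mean and sample SD of the replicate point
    estimates; mean_se the mean of replicate SEs; ci bounds the empirical
    (1-ci_level)/2 percentiles of the estimates; coverage and MSE are
    evaluated against ``truth`` for each coefficient named there.
    """
    reps = [r for r in replicates]
    if len(reps) < 2:
        raise ValueError("need at least 2 successful replicates to summarize")
    fits = [r.fit if isinstance(r, BootstrapReplicate) else r for r in reps]
    est = pd.DataFrame([f.params for f in fits]).reset_index(drop=True)
    ses = pd.DataFrame([f.bse for f in fits]).reset_index(drop=True)
    a = (1.0 - ci_level) / 2.0
    truth = dict(truth) if truth else {}

    rows = {}
    for name in est.columns:
        e = est[name].to_numpy()
        row = {
            "mean_est": float(np.mean(e)),
            "sd_est": float(np.std(e, ddof=1)),
            "mean_se": float(np.mean(ses[name].to_numpy())),
            "ci_low": float(np.percentile(e, 100 * a)),
            "ci_high": float(np.percentile(e, 100 * (1 - a))),
            "norm_ci_low": float(np.mean(e) - 1.959963984540054 * np.std(e, ddof=1)),
            "norm_ci_high": float(np.mean(e) + 1.959963984540054 * np.std(e, ddof=1)),
        }
        if name in truth:
            t = float(truth[name])
            lo, hi = _ci_arrays(reps, name)
            row["coverage_pct"] = 100.0 * float(((lo <= t) & (t <= hi)).mean())
            row["mse"] = mse(e, t)
            row["truth_used"] = t
        else:
            row["coverage_pct"] = np.nan
            row["mse"] = np.nan
            row["truth_used"] = np.nan
        rows[name] = row
    table = pd.DataFrame(rows).T
    meta.setdefault("B", len(reps))
    meta.setdefault("n_failed", 0)
    meta.setdefault("seed", None)
    meta.setdefault("model", None)
    return BootstrapResults(table, reps, ci_level=ci_level, truth=truth, **meta)


class OnePerClusterBootstrap:
    """The bootstrap procedure: constant cluster-level weight matrix, one
    random participant per cluster per replicate, model refit each time.

    Parameters
    ----------
    dataset : SurveyDataset.
    model : "lag_ols" (ML spatial lag on the continuous outcome) or
        "spatial_probit".
    formula : e.g. ``"outcome ~ wealth + education"``.
    alpha : inverse-distance decay exponent for the weight matrix.
    """

    def __init__(self, dataset: SurveyDataset, model: str = "lag_ols",
                 formula: str = "outcome ~ wealth + education",
                 alpha: float = 1.0, ci_level: float = 0.95):
        if model not in MODELS:
            raise ValueError(f"unknown model {model!r}; expected one of {MODELS}")
        self.dataset = dataset
        self.model = model
        self.formula = formula
        self.alpha = float(alpha)
        self.ci_level = float(ci_level)
        self.W = row_normalize(cluster_centroid_matrix(dataset, alpha=alpha))
        self._eigs = self.W.eigenvalues()

    def full_data_fit(self) -> FitResults:
        """Reference fit on all rows, with the zero-weight policy resolving
        the duplicated-coordinate pairs in the full-data matrix."""
        import warnings as _w

        with _w.catch_warnings():
            _w.simplefilter("ignore")
            W_full = row_normalize(build_inverse_distance_matrix(
                self.dataset.coordinates(), alpha=self.alpha,
                zero_policy="zero_weight"))
        y, X, names = self.dataset.design_matrix(self.formula)
        if self.model == "lag_ols":
            return SpatialLag(y, X, W_full, names=names).fit(ci_level=self.ci_level)
        return SpatialProbit(y, X, W_full, names=names).fit(seed=0,
                                                            ci_level=self.ci_level)

    def _fit_subsample(self, y, X, names, rng, probit_opts):
        if self.model == "lag_ols":
            return SpatialLag(y, X, self.W, names=names,
                              eigenvalues=self._eigs).fit(ci_level=self.ci_level)
        seed = int(rng.integers(2 ** 31))
        return SpatialProbit(y, X, self.W, names=names).fit(
            seed=seed, ci_level=self.ci_level, **probit_opts)

    def run(self, B: int, seed: int, truth=None, keep_fits: bool = True,
            probit_opts: dict | None = None) -> BootstrapResults:
        """Run B replicates and aggregate.

        ``truth`` is a dict of generating values, the string
        ``"full_data_fit"`` for a reference fit on the original data, or None
        to use the dataset's recorded generating parameters when present.
        Replicate b uses the RNG stream keyed by ``(seed, b)``; failed fits
        are logged and skipped, with a hard error above a 10% failure rate.
        """
        if B < 2:
            raise ValueError("B must be >= 2")
        if truth is None:
            truth = self.dataset.truth
        elif truth == "full_data_fit":
            ref = self.full_data_fit()
            truth = {k: float(v) for k, v in ref.params.items()}
        probit_opts = dict(probit_opts or {})
        if self.model == "spatial_probit":
            probit_opts.setdefault("n_draws", 600)
            probit_opts.setdefault("burn_in", 200)

        groups = _cluster_groups(self.dataset)
        df = self.dataset.df
        obs_ids = df["obs_id"].to_numpy()
        from .survey import parse_formula
        lhs, terms = parse_formula(self.formula)
        y_all = df[lhs].to_numpy(dtype=float)
        X_all = np.column_stack([np.ones(len(df))] +
                                [df[t].to_numpy(dtype=float) for t in terms])
        names = ["Intercept"] + terms

        replicates = []
        n_failed = 0
        cluster_ids = self.W.unit_order
        for b in range(B):
            rng = np.random.default_rng([seed, b])
            pick = _select_indices(groups, rng)
            try:
                fit = self._fit_subsample(y_all[pick], X_all[pick], names, rng,
                                          probit_opts)
            except Exception as exc:  # noqa: BLE001 — replicate-level guard
                n_failed += 1
                logger.warning("replicate %d failed: %s", b, exc)
                continue
            selected = dict(zip(cluster_ids, obs_ids[pick]))
            replicates.append(BootstrapReplicate(b, selected, fit, (seed, b)))
        if n_failed > MAX_FAILURE_FRACTION * B:
            raise RuntimeError(
                f"{n_failed}/{B} replicate fits failed (> {MAX_FAILURE_FRACTION:.0%})")
        res = summarize_replicates(replicates, truth=truth,
                                   ci_level=self.ci_level, B=B,
                                   n_failed=n_failed, seed=seed,
                                   model=self.model)
        if not keep_fits:
            res.replicates = []
        return res


def run_bootstrap(dataset: SurveyDataset, model: str, formula: str, B: int,
                  seed: int, truth=None, alpha: float = 1.0,
                  ci_level: float = 0.95, **kw) -> BootstrapResults:
    """Functional wrapper: build the engine and run it."""
    boot = OnePerClusterBootstrap(dataset, model=model, formula=formula,
                                  alpha=alpha, ci_level=ci_level)
    return boot.run(B=B, seed=seed, truth=truth, **kw)
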