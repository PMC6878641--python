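"""Clustered survey datasets.

The data model mirrors cluster-released health surveys: one row per
participant, each participant belonging to a primary sampling unit
("cluster") whose single GPS coordinate is shared by all of its members.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .weights import CoordinateSet

__all__ = ["SurveyDataset", "load_survey", "parse_formula"]

logger = logging.getLogger("spatialboot")

_CANON = ["obs_id", "cluster_id", "x", "y", "outcome"]


def parse_formula(formula: str):
    """Parse a simple additive formula ``outcome ~ a + b`` into (lhs, terms).

    An intercept is always included; only additive terms referring to columns
    are supported.
    """
    if "~" not in formula:
        raise ValueError(f"formula must contain '~': {formula!r}")
    lhs, rhs = formula.split("~", 1)
    lhs = lhs.strip()
    terms = [t.strip() for t in rhs.split("+")]
    terms = [t for t in terms if t not in ("", "1")]
    if not lhs:
        raise ValueError("formula needs a left-hand side")
    return lhs, terms


class SurveyDataset:
    """Participant rows with cluster membership, shared coordinates, outcome
    and covariates.

    Parameters
    ----------
    df : DataFrame with at least columns obs_id, cluster_id, x, y, outcome.
    covariates : names of covariate columns in ``df``.
    outcome_kind : "continuous" or "binary".
    truth : optional dict of generating parameters (synthetic data carries
        ``{"rho": ..., "Intercept": ..., ...}``) used as the default truth in
        simulation summaries.
    """

    def __init__(self, df: pd.DataFrame, covariates, outcome_kind="continuous",
                 truth=None, validate=True):
        self.df = df.reset_index(drop=True)
        self.covariates = list(covariates)
        self.outcome_kind = outcome_kind
        self.truth = dict(truth) if truth else None
        if validate:
            self._validate()

    def _validate(self):
        df = self.df
        missing = [c for c in _CANON + self.covariates if c not in df.columns]
        if missing:
            raise ValueError(f"dataset is missing columns: {missing}")
        if outk := self.outcome_kind:
            if outk not in ("continuous", "binary"):
                raise ValueError(f"unknown outcome_kind {outk!r}")
        if df["obs_id"].duplicated().any():
            dup = df.loc[df["obs_id"].duplicated(), "obs_id"].iloc[0]
            raise ValueError(f"duplicate obs_id: {dup!r}")
        num_cols = ["x", "y", "outcome"] + self.covariates
        block = df[num_cols].to_numpy(dtype=float)
        if np.isnan(block).any():
            raise ValueError("dataset contains missing values after load")
        if not np.isfinite(block).all():
            raise ValueError("dataset contains non-finite values")
        if self.outcome_kind == "binary":
            vals = set(np.unique(df["outcome"].to_numpy()))
            if not vals <= {0.0, 1.0, 0, 1}:
                raise ValueError("binary outcome must take values in {0, 1}")
        # all members of a cluster share one coordinate pair
        for col in ("x", "y"):
            nun = df.groupby("cluster_id")[col].nunique()
            bad = nun[nun > 1]
            if len(bad):
                raise ValueError(
                    f"cluster {bad.index[0]!r} has inconsistent {col} coordinates"
                )

    # -- accessors ----------------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.df)

    @property
    def cluster_ids(self) -> np.ndarray:
        """Cluster ids in sorted order — the canonical alignment for
        cluster-level vectors and weight matrices."""
        return np.sort(self.df["cluster_id"].unique())

    @property
    def n_clusters(self) -> int:
        return len(self.cluster_ids)

    def cluster_sizes(self) -> pd.Series:
        return self.df["cluster_id"].value_counts().reindex(self.cluster_ids)

    def cluster_coordinates(self) -> CoordinateSet:
        """One coordinate per cluster, ordered by sorted cluster id."""
        firsts = (self.df.groupby("cluster_id")[["x", "y"]].first()
                  .reindex(self.cluster_ids))
        return CoordinateSet(self.cluster_ids, firsts["x"].to_numpy(),
                             firsts["y"].to_numpy())

    def coordinates(self) -> CoordinateSet:
        """Per-participant coordinates (duplicated within clusters)."""
        return CoordinateSet(self.df["obs_id"].to_numpy(),
                             self.df["x"].to_numpy(), self.df["y"].to_numpy())

    def design_matrix(self, formula: str):
        """(y, X, names) for an additive formula; intercept always included."""
        lhs, terms = parse_formula(formula)
        for c in [lhs] + terms:
            if c not in self.df.columns:
                raise ValueError(f"formula references unknown column {c!r}")
        y = self.df[lhs].to_numpy(dtype=float)
        X = np.column_stack([np.ones(self.n)] +
                            [self.df[t].to_numpy(dtype=float) for t in terms])
        return y, X, ["Intercept"] + terms

    def subset(self, row_indices) -> "SurveyDataset":
        sub = self.df.iloc[np.asarray(row_indices)].reset_index(drop=True)
        return SurveyDataset(sub, self.covariates, self.outcome_kind,
                             truth=self.truth, validate=False)

    def to_csv(self, path):
        cols = _CANON + self.covariates
        self.df[cols].to_csv(path, index=False)

    def __repr__(self):
        return (f"<SurveyDataset n={self.n} clusters={self.n_clusters} "
                f"outcome={self.outcome_kind} covariates={self.covariates}>")


def load_survey(path, column_map=None, missing_policy="drop",
                outcome_kind="continuous", covariates=None) -> SurveyDataset:
    """Load a delimited survey extract into a :class:`SurveyDataset`.

    Parameters
    ----------
    column_map : dict mapping canonical names (obs_id, cluster_id, x, y,
        outcome) to the file's column names.  Identity by default.
    missing_policy : "drop" removes rows with missing mapped fields (count is
        logged); "error" rejects the file.
    covariates : covariate column names (post-mapping).  Defaults to every
        remaining column.
    """
    if missing_policy not in ("drop", "error"):
        raise ValueError(f"unknown missing_policy {missing_policy!r}")
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    raw = pd.read_csv(path, sep=sep)
    column_map = dict(column_map or {})
    rename = {v: k for k, v in column_map.items()}
    missing_src = [v for v in column_map.values() if v not in raw.columns]
    if missing_src:
        raise ValueError(f"mapped column(s) not in file: {missing_src}")
    df = raw.rename(columns=rename)
    for c in _CANON:
        if c not in df.columns:
            raise ValueError(f"no column mapped to required field {c!r}")
    if covariates is None:
        covariates = [c for c in df.columns if c not in _CANON]
    used = _CANON + list(covariates)
    n_missing = int(df[used].isna().any(axis=1).sum())
    if n_missing:
        if missing_policy == "error":
            raise ValueError(f"{n_missing} row(s) with missing values")
        df = df.dropna(subset=used)
        logger.info("dropped %d row(s) with missing values", n_missing)
    ds = SurveyDataset(df[used], covariates, outcome_kind=outcome_kind)
    ds.n_dropped = n_missing
    return ds
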