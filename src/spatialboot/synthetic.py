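"""Synthetic clustered surveys with known spatial structure.

Emulates the structure of cluster-released household surveys: a few hundred
primary sampling units ("clusters"), tens of participants each, and — the
defining pathology — every participant carrying the single GPS coordinate of
their cluster, so that within-cluster distances are all zero.

Outcomes are generated from an individual-level spatial lag process whose
weight matrix is a block expansion of the row-standardised cluster
inverse-distance matrix: the weight from participant j (in cluster c') to
participant i (in cluster c != c') is the cluster weight divided by the
member count of c', and within-cluster weights are zero.  Rows then still sum
to one, and the spatial term aggregates to cluster means, so a one-per-cluster
subsample follows (up to within-cluster sampling noise) the cluster-level
spatial lag model — making the generating rho and beta a well-defined estimand
for the bootstrap.  With equal cluster sizes the expanded matrix restricted to
any one-per-cluster subsample is exactly proportional to the cluster matrix.

Covariates are simple parametric stand-ins for survey wealth and education:
wealth is a uniform integer quintile 1..5 and education a Poisson(6) year
count truncated to 0..20, both drawn per participant.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .lag import simulate_spatial_lag
from .survey import SurveyDataset
from .weights import (CoordinateSet, SpatialWeights,
                      build_inverse_distance_matrix, row_normalize)

__all__ = ["SyntheticConfig", "generate_clusters", "generate_survey",
           "block_expand_weights", "dhs_like_config"]


@dataclass
class SyntheticConfig:
    """Full description of one synthetic survey; with the seed it determines
    the dataset exactly.

    members_per_cluster may be an int (equal sizes) or a (min, max) range
    sampled uniformly per cluster.
    """

    n_clusters: int = 100
    members_per_cluster: int | tuple[int, int] = 20
    extent: tuple[float, float, float, float] = (0.0, 100.0, 0.0, 100.0)
    rho_true: float = 0.3
    beta_true: dict = field(default_factory=lambda: {
        "Intercept": 0.5, "wealth": 0.2, "education": 0.1})
    noise_sd: float = 1.0
    outcome_link: str = "identity"
    alpha: float = 1.0
    min_separation: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.n_clusters < 2:
            raise ValueError("need at least 2 clusters")
        if not -1.0 < self.rho_true < 1.0:
            raise ValueError("rho_true must lie in (-1, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if self.outcome_link not in ("identity", "probit"):
            raise ValueError(f"unknown outcome_link {self.outcome_link!r}")
        m = self.members_per_cluster
        if isinstance(m, int):
            if m < 1:
                raise ValueError("members_per_cluster must be >= 1")
        else:
            lo, hi = m
            if lo < 1 or hi < lo:
                raise ValueError("members_per_cluster range must satisfy 1 <= min <= max")

    def truth(self) -> dict:
        t = {"rho": self.rho_true}
        t.update(self.beta_true)
        return t

    def to_json(self, path):
        d = {**self.__dict__}
        with open(path, "w") as fh:
            json.dump({"rho_true": self.rho_true, "beta_true": self.beta_true,
                       "noise_sd": self.noise_sd, "seed": self.seed,
                       "config": {k: list(v) if isinstance(v, tuple) else v
                                  for k, v in d.items() if k != "beta_true"}
                       | {"beta_true": self.beta_true}},
                      fh, indent=2)


def dhs_like_config(**overrides) -> SyntheticConfig:
    """An 850-cluster preset at the scale of a national household survey
    (~tens of members per cluster, ~24k participants)."""
    base = dict(n_clusters=850, members_per_cluster=(10, 45),
                extent=(0.0, 300.0, 0.0, 300.0), min_separation=1.0)
    base.update(overrides)
    return SyntheticConfig(**base)


def generate_clusters(n_clusters: int, extent, min_separation: float,
                      seed=None, rng=None, max_tries: int = 200_000) -> CoordinateSet:
    """Cluster coordinates by rejection sampling: uniform points in the
    bounding box, each at least ``min_separation`` from all earlier ones."""
    if rng is None:
        rng = np.random.default_rng(seed)
    x0, x1, y0, y1 = extent
    if x1 <= x0 or y1 <= y0:
        raise ValueError("extent must be (xmin, xmax, ymin, ymax) with positive area")
    pts = np.empty((n_clusters, 2))
    k = 0
    tries = 0
    min2 = min_separation * min_separation
    while k < n_clusters:
        if tries >= max_tries:
            raise RuntimeError(
                f"placed only {k}/{n_clusters} clusters after {max_tries} tries; "
                "enlarge the extent or reduce min_separation")
        cand = np.array([rng.uniform(x0, x1), rng.uniform(y0, y1)])
        tries += 1
        if k == 0 or np.min(np.sum((pts[:k] - cand) ** 2, axis=1)) >= min2:
            pts[k] = cand
            k += 1
    ids = np.arange(1, n_clusters + 1)
    return CoordinateSet(ids, pts[:, 0], pts[:, 1])


def block_expand_weights(Wc_norm: SpatialWeights, cluster_of: np.ndarray,
                         sizes: dict) -> np.ndarray:
    """Individual-level weight matrix from a row-normalized cluster matrix.

    Entry (i, j) for i in cluster c, j in cluster c' is 0 when c == c' and
    ``Wc[c, c'] / m_{c'}`` otherwise (m the member count of j's cluster), so
    every row sums to one and ``W_ind @ y`` equals the cluster-weighted
    average of other clusters' mean outcomes.
    """
    order = {c: k for k, c in enumerate(Wc_norm.unit_order)}
    idx = np.array([order[c] for c in cluster_of])
    Wc = Wc_norm.toarray()
    m = np.array([sizes[c] for c in cluster_of], dtype=float)
    W_ind = Wc[np.ix_(idx, idx)] / m[None, :]
    W_ind[idx[:, None] == idx[None, :]] = 0.0
    return W_ind


def generate_survey(config: SyntheticConfig):
    """Generate a synthetic survey; returns (SurveyDataset, truth dict).

    Deterministic in the config: independent child RNG streams (cluster
    placement, member counts, covariates, outcome noise) are spawned from the
    config seed, so the exported CSV is byte-identical across runs.
    """
    ss = np.random.SeedSequence(config.seed)
    rng_coord, rng_members, rng_cov, rng_out = \
        [np.random.default_rng(s) for s in ss.spawn(4)]

    coords = generate_clusters(config.n_clusters, config.extent,
                               config.min_separation, rng=rng_coord)
    m = config.members_per_cluster
    if isinstance(m, int):
        counts = np.full(config.n_clusters, m, dtype=int)
    else:
        counts = rng_members.integers(m[0], m[1] + 1, size=config.n_clusters)
    n = int(counts.sum())

    cluster_of = np.repeat(coords.unit_ids, counts)
    x = np.repeat(coords.x, counts)
    y = np.repeat(coords.y, counts)

    wealth = rng_cov.integers(1, 6, size=n).astype(float)
    education = rng_cov.poisson(6.0, size=n).astype(float)
    over = education > 20
    while over.any():  # truncated Poisson: resample the tail
        education[over] = rng_cov.poisson(6.0, size=int(over.sum()))
        over = education > 20

    Wc = build_inverse_distance_matrix(coords, alpha=config.alpha)
    Wc_norm = row_normalize(Wc)
    sizes = dict(zip(coords.unit_ids, counts))
    W_ind = block_expand_weights(Wc_norm, cluster_of, sizes)
    W_ind_sw = SpatialWeights(W_ind, config.alpha, np.arange(1, n + 1),
                              normalized=True)

    covs = {"wealth": wealth, "education": education}
    terms = [b for b in config.beta_true if b != "Intercept"]
    unknown = [t for t in terms if t not in covs]
    if unknown:
        raise ValueError(f"beta_true names unknown covariate(s): {unknown}")
    X = np.column_stack([np.ones(n)] + [covs[t] for t in terms])
    beta = np.array([config.beta_true.get("Intercept", 0.0)] +
                    [config.beta_true[t] for t in terms])
    outcome = simulate_spatial_lag(W_ind_sw, X, config.rho_true, beta,
                                   config.noise_sd, link=config.outcome_link,
                                   rng=rng_out)

    df = pd.DataFrame({
        "obs_id": np.arange(1, n + 1),
        "cluster_id": cluster_of,
        "x": x, "y": y,
        "outcome": outcome,
        "wealth": wealth,
        "education": education,
    })
    kind = "binary" if config.outcome_link == "probit" else "continuous"
    ds = SurveyDataset(df, ["wealth", "education"], outcome_kind=kind,
                       truth=config.truth())
    return ds, config.truth()
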