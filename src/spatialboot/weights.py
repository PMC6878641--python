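"""Inverse-distance spatial weight matrices.

A spatial weight matrix ``W`` is an ``n x n`` nonnegative matrix whose entry
``W[i, j]`` encodes how strongly unit ``j``'s outcome is allowed to influence
unit ``i``'s.  This module builds the inverse-distance variant,

    W[i, j] = 1 / d(i, j)**alpha   for i != j,      W[i, i] = 0,

optionally row-standardised so that every nonzero row sums to one (making the
spatial lag ``W @ y`` a weighted average of neighbouring outcomes).

The construction fails loudly when two units share a coordinate (``d = 0``),
which is exactly the situation in cluster-released survey GPS data where every
member of a cluster carries the cluster's single coordinate pair.  The
cluster-level matrix :func:`cluster_centroid_matrix` — one row per cluster,
built on the shared coordinates — is the object every one-per-cluster
bootstrap replicate reuses, because any such subsample has the same pairwise
distances as the cluster centroids themselves.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.io
import scipy.sparse as sp
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "CoordinateSet",
    "SpatialWeights",
    "pairwise_distance",
    "build_inverse_distance_matrix",
    "row_normalize",
    "cluster_centroid_matrix",
    "EARTH_RADIUS_KM",
    "DENSE_LIMIT",
]

#: Mean Earth radius used for great-circle distances, in kilometres.
EARTH_RADIUS_KM = 6371.0088

#: Above this many units the weight matrix is stored as scipy CSR.
DENSE_LIMIT = 2000

_CRS_MODES = ("planar_euclidean", "lonlat_euclidean", "lonlat_greatcircle")
_ZERO_POLICIES = ("error", "zero_weight", "epsilon")


class ZeroDistanceError(ValueError):
    """Raised when distinct units share a coordinate under zero_policy='error'."""

    def __init__(self, pairs):
        self.pairs = list(pairs)
        shown = ", ".join(f"({a!r}, {b!r})" for a, b in self.pairs[:10])
        more = "" if len(self.pairs) <= 10 else f" and {len(self.pairs) - 10} more"
        super().__init__(
            "zero distance between distinct units — inverse-distance weight is "
            f"undefined for unit pairs: {shown}{more}. Use a one-per-cluster "
            "subsample, or zero_policy='zero_weight'/'epsilon'."
        )


@dataclass
class CoordinateSet:
    """Point locations of the spatial units.

    ``x``/``y`` are longitude/latitude in decimal degrees for the ``lonlat_*``
    modes, or abstract planar units for ``planar_euclidean``.
    """

    unit_ids: np.ndarray
    x: np.ndarray
    y: np.ndarray
    crs_mode: str = "planar_euclidean"

    def __post_init__(self):
        self.unit_ids = np.asarray(self.unit_ids)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.crs_mode not in _CRS_MODES:
            raise ValueError(f"unknown crs_mode {self.crs_mode!r}; expected one of {_CRS_MODES}")
        if not (len(self.unit_ids) == len(self.x) == len(self.y)):
            raise ValueError("unit_ids, x and y must have equal length")
        if len(np.unique(self.unit_ids)) != len(self.unit_ids):
            raise ValueError("unit_ids must be unique")
        bad = ~(np.isfinite(self.x) & np.isfinite(self.y))
        if bad.any():
            raise ValueError(
                f"non-finite coordinate for unit_id(s): {list(self.unit_ids[bad][:10])}"
            )

    @property
    def n(self) -> int:
        return len(self.unit_ids)

    @property
    def has_distinct_coordinates(self) -> bool:
        """True iff no two units share an (x, y) pair."""
        pts = np.column_stack([self.x, self.y])
        return len(np.unique(pts, axis=0)) == self.n


def pairwise_distance(coords: CoordinateSet) -> np.ndarray:
    """Symmetric matrix of pairwise distances per the coordinate set's crs_mode.

    Planar and lonlat Euclidean modes take straight-line distance on the raw
    coordinates; ``lonlat_greatcircle`` uses the haversine formula on a sphere
    of radius :data:`EARTH_RADIUS_KM` (result in kilometres).
    """
    if coords.n < 2:
        raise ValueError("need at least 2 units for pairwise distances")
    if coords.crs_mode in ("planar_euclidean", "lonlat_euclidean"):
        pts = np.column_stack([coords.x, coords.y])
        return squareform(pdist(pts, metric="euclidean"))
    # haversine
    lon = np.radians(coords.x)
    lat = np.radians(coords.y)
    dlat = lat[:, None] - lat[None, :]
    dlon = lon[:, None] - lon[None, :]
    h = np.sin(dlat / 2.0) ** 2 + np.cos(lat)[:, None] * np.cos(lat)[None, :] * np.sin(dlon / 2.0) ** 2
    np.clip(h, 0.0, 1.0, out=h)
    d = 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(h))
    np.fill_diagonal(d, 0.0)
    return d


class SpatialWeights:
    """An ``n x n`` nonnegative weight matrix with zero diagonal.

    Dense ``ndarray`` storage up to :data:`DENSE_LIMIT` units, scipy CSR above;
    :meth:`row_sums` uses one shared code path so the two representations give
    bit-identical sums.  ``unit_order`` records which unit each row/column
    refers to — downstream vectors are always aligned to it, never to input
    file order.
    """

    def __init__(self, matrix, alpha, unit_order, *, normalized=False,
                 zero_policy="error", n_zero_rows=0):
        self.alpha = float(alpha)
        self.normalized = bool(normalized)
        self.zero_policy = zero_policy
        self.unit_order = np.asarray(unit_order)
        self.n_zero_rows = int(n_zero_rows)
        self._eigs = None
        n = self.unit_order.shape[0]
        if sp.issparse(matrix):
            self.matrix = matrix.tocsr()
        else:
            matrix = np.asarray(matrix, dtype=float)
            self.matrix = sp.csr_matrix(matrix) if n > DENSE_LIMIT else matrix
        if self.shape != (n, n):
            raise ValueError("matrix shape does not match unit_order length")
        self._validate()

    # -- basic protocol ----------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.unit_order)

    @property
    def shape(self):
        return self.matrix.shape

    @property
    def is_sparse(self) -> bool:
        return sp.issparse(self.matrix)

    def toarray(self) -> np.ndarray:
        return self.matrix.toarray() if self.is_sparse else np.asarray(self.matrix)

    def dot(self, v: np.ndarray) -> np.ndarray:
        return self.matrix @ v

    def _validate(self):
        diag = self.matrix.diagonal()
        if np.any(diag != 0.0):
            raise ValueError("weight matrix diagonal must be exactly zero")
        data = self.matrix.data if self.is_sparse else self.matrix
        if not np.all(np.isfinite(data)):
            raise ValueError("weight matrix entries must be finite")
        if np.any(data < 0.0):
            raise ValueError("weight matrix entries must be nonnegative")

    def row_sums(self, block: int = 512) -> np.ndarray:
        """Row sums, computed blockwise through a single dense code path."""
        out = np.empty(self.n)
        for lo in range(0, self.n, block):
            hi = min(lo + block, self.n)
            rows = self.matrix[lo:hi]
            if sp.issparse(rows):
                rows = rows.toarray()
            out[lo:hi] = np.sum(rows, axis=1)
        return out

    # -- spectral ----------------------------------------------------------
    def eigenvalues(self) -> np.ndarray:
        """Real eigenvalue spectrum (cached); requires modest n."""
        if self._eigs is None:
            if self.n > 3000:
                raise ValueError("eigenvalue log-determinant supported for n <= 3000")
            ev = np.linalg.eigvals(self.toarray())
            if np.max(np.abs(ev.imag)) > 1e-8 * max(1.0, np.max(np.abs(ev.real))):
                warnings.warn("weight matrix has notably complex eigenvalues; "
                              "using real parts", stacklevel=2)
            self._eigs = np.sort(ev.real)
        return self._eigs

    # -- transforms ---------------------------------------------------------
    def row_normalized(self) -> "SpatialWeights":
        return row_normalize(self)

    # -- I/O -----------------------------------------------------------------
    def to_mtx(self, path, ids_path=None):
        """Write MatrixMarket coordinate file plus a sidecar unit-id file."""
        path = str(path)
        scipy.io.mmwrite(path, sp.coo_matrix(self.matrix))
        if ids_path is None:
            base = path[:-4] if path.endswith(".mtx") else path
            ids_path = base + ".ids.txt"
        with open(ids_path, "w") as fh:
            for u in self.unit_order:
                fh.write(f"{u}\n")
        return path, str(ids_path)

    @classmethod
    def from_mtx(cls, path, ids_path=None, *, alpha=1.0, normalized=False,
                 zero_policy="error"):
        path = str(path)
        if ids_path is None:
            base = path[:-4] if path.endswith(".mtx") else path
            ids_path = base + ".ids.txt"
        mat = scipy.io.mmread(path)
        with open(ids_path) as fh:
            ids = [line.strip() for line in fh if line.strip()]
        if sp.issparse(mat) and len(ids) <= DENSE_LIMIT:
            mat = mat.toarray()
        return cls(mat, alpha, np.asarray(ids), normalized=normalized,
                   zero_policy=zero_policy)

    def to_dense_csv(self, path):
        """Dense CSV with a header row/column of unit ids."""
        import pandas as pd

        pd.DataFrame(self.toarray(), index=self.unit_order,
                     columns=self.unit_order).to_csv(path)

    def __repr__(self):
        kind = "sparse" if self.is_sparse else "dense"
        norm = "row-normalized" if self.normalized else "raw"
        return f"<SpatialWeights n={self.n} alpha={self.alpha} {norm} {kind}>"


def build_inverse_distance_matrix(coords: CoordinateSet, alpha: float = 1.0,
                                  zero_policy: str = "error",
                                  epsilon: float = 1e-6) -> SpatialWeights:
    """Raw (unnormalised) inverse-distance weights ``1/d**alpha``, zero diagonal.

    Off-diagonal zero distances — distinct units at the same point — are
    handled per ``zero_policy``: ``error`` rejects and names the colliding
    units, ``zero_weight`` sets the weight to 0 with a warning, ``epsilon``
    substitutes ``1/epsilon**alpha``.
    """
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    if zero_policy not in _ZERO_POLICIES:
        raise ValueError(f"unknown zero_policy {zero_policy!r}")
    d = pairwise_distance(coords)
    n = coords.n
    off = ~np.eye(n, dtype=bool)
    zero_off = off & (d == 0.0)
    if zero_off.any():
        ii, jj = np.nonzero(np.triu(zero_off))
        pairs = list(zip(coords.unit_ids[ii], coords.unit_ids[jj]))
        if zero_policy == "error":
            raise ZeroDistanceError(pairs)
        if zero_policy == "zero_weight":
            warnings.warn(
                f"{len(pairs)} unit pair(s) at zero distance assigned weight 0",
                stacklevel=2,
            )
    w = np.zeros_like(d)
    pos = off & (d > 0.0)
    w[pos] = d[pos] ** -alpha
    if zero_policy == "epsilon" and zero_off.any():
        if epsilon <= 0:
            raise ValueError("epsilon must be positive")
        w[zero_off] = 1.0 / epsilon ** alpha
    return SpatialWeights(w, alpha, coords.unit_ids, normalized=False,
                          zero_policy=zero_policy)


def row_normalize(W: SpatialWeights) -> SpatialWeights:
    """Row-standardise: each row with a positive sum is divided by its sum.

    All-zero rows stay all-zero; their count is reported on the returned
    matrix's ``n_zero_rows``.
    """
    if W.normalized:
        raise ValueError("weight matrix is already row-normalized")
    sums = W.row_sums()
    zero_rows = sums == 0.0
    if W.is_sparse:
        inv = np.where(zero_rows, 0.0, 1.0 / np.where(zero_rows, 1.0, sums))
        mat = sp.diags(inv) @ W.matrix
    else:
        mat = W.toarray().copy()
        nz = ~zero_rows
        mat[nz] = mat[nz] / sums[nz, None]
    return SpatialWeights(mat, W.alpha, W.unit_order, normalized=True,
                          zero_policy=W.zero_policy,
                          n_zero_rows=int(zero_rows.sum()))


def cluster_centroid_matrix(dataset, alpha: float = 1.0,
                            zero_policy: str = "error",
                            epsilon: float = 1e-6) -> SpatialWeights:
    """Inverse-distance matrix over the unique per-cluster coordinates.

    One row/column per cluster, ordered by sorted cluster id.  Because every
    member of a cluster carries the cluster's coordinates, this matrix equals
    the inverse-distance matrix of ANY one-per-cluster subsample, entrywise —
    the constancy that makes the bootstrap's replicate matrix reusable.

    Raises if any cluster's members disagree on their coordinates.
    """
    coords = dataset.cluster_coordinates()  # verifies within-cluster consistency
    return build_inverse_distance_matrix(coords, alpha=alpha,
                                         zero_policy=zero_policy, epsilon=epsilon)
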