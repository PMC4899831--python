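"""Generalized Mahalanobis distance to cluster centroids.

The similarity between a patient vector x and a cluster with centroid mu
is d_S(x, C) = sqrt((x - mu)^T S (x - mu)) for a symmetric positive
semi-definite (SPSD) matrix S.  With S = I this is the Euclidean
distance; the default S is the pseudo-inverse of the shrunk pooled
within-cluster covariance.  Because sqrt is monotone, rankings are
identical whether the radical is applied or not.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.linalg import pinvh

__all__ = ["SPSDMatrix", "SPSDError", "estimate_S", "mahalanobis_distance"]

PROVENANCES = ("identity", "pooled_inverse_covariance", "per_cluster_inverse_covariance")

_SYM_TOL = 1e-10
_EIG_TOL = -1e-8


class SPSDError(ValueError):
    """Raised when a matrix violates the SPSD contract."""


class SPSDMatrix:
    """A validated symmetric positive semi-definite d x d matrix.

    Raises :class:`SPSDError` if ``max|M - M^T| > 1e-10`` or the smallest
    eigenvalue is below ``-1e-8``.
    """

    def __init__(
        self,
        matrix: np.ndarray,
        provenance: str = "identity",
        shrinkage_lambda: float = 0.0,
    ):
        matrix = np.asarray(matrix, dtype=float)
        if matrix.ndim != 2 or matrix.shape[0] != matrix.shape[1]:
            raise SPSDError("S must be a square matrix")
        asym = float(np.abs(matrix - matrix.T).max())
        if asym > _SYM_TOL:
            raise SPSDError(f"S is not symmetric (max asymmetry {asym:.3g})")
        eigmin = float(np.linalg.eigvalsh(matrix).min())
        if eigmin < _EIG_TOL:
            raise SPSDError(f"S is not PSD (smallest eigenvalue {eigmin:.3g})")
        if provenance not in PROVENANCES:
            raise SPSDError(f"provenance must be one of {PROVENANCES}")
        if not 0.0 <= shrinkage_lambda <= 1.0:
            raise SPSDError("shrinkage_lambda must be in [0, 1]")
        self.matrix = matrix
        self.provenance = provenance
        self.shrinkage_lambda = shrinkage_lambda
        self.eigmin_ = eigmin

    @property
    def dim(self) -> int:
        return self.matrix.shape[0]


def _pooled_within_covariance(X: np.ndarray, labels: np.ndarray) -> np.ndarray:
    resid = X.copy()
    k = 0
    for cid in np.unique(labels):
        mask = labels == cid
        resid[mask] -= X[mask].mean(axis=0)
        k += 1
    dof = max(len(X) - k, 1)
    return resid.T @ resid / dof


def estimate_S(
    X: np.ndarray,
    labels: np.ndarray | None = None,
    provenance: str = "pooled_inverse_covariance",
    shrinkage_lambda: float = 0.1,
) -> SPSDMatrix:
    """Estimate the metric matrix S from training data.

    ``identity`` returns I_d.  ``pooled_inverse_covariance`` returns the
    pseudo-inverse of the shrunk pooled within-cluster covariance
    ``(1 - lambda) * Sigma + lambda * diag(Sigma)``; when fewer than d + 1
    training points are available it falls back to the identity with a
    warning.  Singularity is handled by the pseudo-inverse.
    """
    X = np.asarray(X, dtype=float)
    d = X.shape[1]
    if provenance == "identity":
        return SPSDMatrix(np.eye(d), "identity", 0.0)
    if provenance not in PROVENANCES:
        raise SPSDError(f"provenance must be one of {PROVENANCES}")
    if len(X) < d + 1:
        warnings.warn(
            "fewer than d+1 training points: falling back to the identity metric",
            stacklevel=2,
        )
        return SPSDMatrix(np.eye(d), "identity", 0.0)
    if labels is None:
        labels = np.zeros(len(X), dtype=int)
    sigma = _pooled_within_covariance(X, np.asarray(labels))
    shrunk = (1.0 - shrinkage_lambda) * sigma + shrinkage_lambda * np.diag(
        np.diag(sigma)
    )
    S = pinvh(shrunk)
    S = (S + S.T) / 2.0  # pinvh is symmetric up to rounding
    return SPSDMatrix(S, provenance, shrinkage_lambda)


def mahalanobis_distance(x: np.ndarray, cluster, S: SPSDMatrix) -> float:
    """d_S(x, C) = sqrt((x - mu)^T S (x - mu)) to a cluster's centroid.

    ``cluster`` may be a :class:`~simrec.cluster.Cluster` or a bare
    centroid vector.  Tiny negative quadratic forms from floating error
    (> -1e-10) are clamped to zero; anything below that raises
    :class:`SPSDError`.
    """
    mu = getattr(cluster, "centroid", cluster)
    x = np.asarray(x, dtype=float)
    mu = np.asarray(mu, dtype=float)
    if x.shape != mu.shape or x.shape[0] != S.dim:
        raise ValueError(
            f"dimension mismatch: x {x.shape}, mu {mu.shape}, S {S.matrix.shape}"
        )
    diff = x - mu
    q = float(diff @ S.matrix @ diff)
    if q < -1e-10:
        raise SPSDError(f"quadratic form is negative ({q:.3g}); S violates SPSD")
    return float(np.sqrt(max(q, 0.0)))
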