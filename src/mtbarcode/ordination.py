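"""Principal-coordinates analysis (PCoA) of genetic distance matrices.

The distance matrix is converted to the Gower-centered cross-product matrix
B = -1/2 * J D2 J (D2 element-wise squared distances, J the centering
projector), and eigendecomposed; coordinates are eigenvectors scaled by the
square root of their (positive) eigenvalues.  Genetic distances (K2P,
aa-Kimura) are generally non-Euclidean, so negative eigenvalues occur; they
are reported in full and simply excluded from the variance fractions (no
Lingoes/Cailliez correction by default).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .distances import DistanceMatrix

__all__ = ["OrdinationResult", "pcoord", "grouping_separation"]


@dataclass
class OrdinationResult:
    """PCoA embedding with the full eigenvalue spectrum."""

    labels: list[str]
    coordinates: np.ndarray      # (n objects, retained dims)
    eigenvalues: np.ndarray      # full spectrum, descending (may be negative)
    variance_fractions: np.ndarray  # lambda_i / sum positive lambda
    group_labels: dict[str, str] | None = None

    def to_frame(self) -> pd.DataFrame:
        cols = {f"axis{i + 1}": self.coordinates[:, i]
                for i in range(self.coordinates.shape[1])}
        df = pd.DataFrame({"label": self.labels, **cols})
        if self.group_labels:
            df["group"] = [self.group_labels.get(l) for l in self.labels]
        return df


def pcoord(dm: DistanceMatrix, dims: int = 3,
           correction: str | None = None,
           group_labels: dict[str, str] | None = None) -> OrdinationResult:
    """Principal coordinates of a symmetric distance matrix.

    ``dims`` requests the number of retained axes; when fewer positive
    eigenvalues exist the result is truncated with a warning.
    ``correction='lingoes'`` adds the smallest constant to off-diagonal
    squared distances that makes the configuration Euclidean.
    """
    D = np.asarray(dm.values, dtype=float)
    if np.isnan(D).any():
        raise ValueError("distance matrix contains undefined entries")
    if not np.allclose(D, D.T) or not np.allclose(np.diag(D), 0.0):
        raise ValueError("input must be symmetric with zero diagonal")
    n = D.shape[0]
    D2 = D ** 2
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ D2 @ J
    eigval, eigvec = np.linalg.eigh((B + B.T) / 2.0)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]

    if correction == "lingoes" and eigval[-1] < -1e-12:
        c = -eigval[-1]
        D2c = D2 + 2.0 * c * (1.0 - np.eye(n))
        B = -0.5 * J @ D2c @ J
        eigval, eigvec = np.linalg.eigh((B + B.T) / 2.0)
        order = np.argsort(eigval)[::-1]
        eigval, eigvec = eigval[order], eigvec[:, order]

    tol = max(abs(eigval[0]), 1.0) * 1e-10
    n_pos = int((eigval > tol).sum())
    keep = min(dims, n_pos)
    if keep < dims:
        warnings.warn(
            f"only {n_pos} positive eigenvalues; returning {keep} dimensions"
        )
    coords = eigvec[:, :keep] * np.sqrt(eigval[:keep])
    pos_sum = eigval[eigval > tol].sum()
    fractions = np.where(eigval > tol, eigval / pos_sum, 0.0) if pos_sum > 0 \
        else np.zeros_like(eigval)
    return OrdinationResult(
        list(dm.labels), coords, eigval, fractions, group_labels
    )


def grouping_separation(result: OrdinationResult, dims: int = 2):
    """Per-group separation summary in the first ``dims`` embedding axes.

    Reports group centroids, the fraction of objects whose nearest centroid
    is their own group's ("own-centroid fraction", a simple overlap
    indicator), and the cumulative variance fraction of the retained axes.
    """
    if not result.group_labels:
        raise ValueError("ordination result carries no group labels")
    dims = min(dims, result.coordinates.shape[1])
    X = result.coordinates[:, :dims]
    groups = np.array([result.group_labels[l] for l in result.labels])
    names = sorted(set(groups))
    if len(names) < 2:
        raise ValueError("overlap undefined for a single group")
    centroids = {g: X[groups == g].mean(axis=0) for g in names}
    C = np.vstack([centroids[g] for g in names])
    d2 = ((X[:, None, :] - C[None, :, :]) ** 2).sum(axis=2)
    nearest = np.array(names)[np.argmin(d2, axis=1)]
    own_fraction = float((nearest == groups).mean())
    cum_var = float(result.variance_fractions[:dims].sum())
    return {
        "centroids": centroids,
        "own_centroid_fraction": own_fraction,
        "cumulative_variance_fraction": cum_var,
        "n_dims": dims,
    }
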