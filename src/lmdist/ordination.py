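"""Principal coordinates analysis and distance-distribution diagnostics.

Classical PCoA (metric multidimensional scaling): square the distances,
double-center, eigendecompose, and scale eigenvectors by the square roots
of the positive eigenvalues. Dissimilarities that are not Euclidean-
embeddable (Bray-Curtis, Jaccard) produce negative eigenvalues; those
axes are dropped and variance fractions are computed over the positive
spectrum only.

Also provides the oversaturation diagnostic: a strongly left-skewed
distribution of pairwise values means the measure has lost dynamic range
at the far end of a gradient — the regime in which geodesic adjustment
helps.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.linalg import eigh
from sklearn.base import BaseEstimator

from .io import check_distance_matrix

__all__ = [
    "PCoA",
    "Ordination",
    "pcoa",
    "dims_for_variance",
    "axis_gradient_correlation",
    "oversaturation_check",
]

#: Relative cutoff below which an eigenvalue is treated as numerically zero.
_EIG_TOL = 1e-12

#: Skewness below which a distance distribution is flagged oversaturated.
DEFAULT_SKEW_CUTOFF = -0.1


class PCoA(BaseEstimator):
    """Principal coordinates analysis of a precomputed distance matrix.

    scikit-learn style decomposition: ``fit_transform(D)`` returns the
    sample coordinates; only positive-eigenvalue axes are kept.

    Parameters
    ----------
    n_components : int or None
        Number of leading axes to return; ``None`` keeps every positive
        axis.

    Attributes
    ----------
    coordinates_ : ndarray of shape (n, k)
        Embedded sample coordinates; column j has squared norm equal to
        ``eigenvalues_[j]``.
    eigenvalues_ : ndarray of shape (k,)
        Positive eigenvalues of the double-centered Gram matrix, sorted
        descending.
    explained_variance_ratio_ : ndarray of shape (k,)
        Eigenvalues over their sum (positive spectrum only); sums to 1.
    labels_ : list of str or None
    """

    def __init__(self, n_components: int | None = None):
        self.n_components = n_components

    def fit(self, X, y=None):
        labels = list(X.index) if isinstance(X, pd.DataFrame) else None
        D = check_distance_matrix(X)
        n = D.shape[0]
        if n < 3:
            raise ValueError(f"PCoA needs at least 3 samples, got {n}")
        B = D**2
        B -= B.mean(axis=0)
        B -= B.mean(axis=1, keepdims=True)
        B *= -0.5
        w, V = eigh(B)
        order = np.argsort(w)[::-1]
        w, V = w[order], V[:, order]
        keep = w > _EIG_TOL * max(abs(w[0]), abs(w[-1]), 1e-300)
        w, V = w[keep], V[:, keep]
        if w.size == 0:
            # all points coincide: a single degenerate axis of zeros
            w = np.array([0.0])
            V = np.zeros((n, 1))
        # deterministic sign: largest-magnitude loading positive
        flip = V[np.argmax(np.abs(V), axis=0), np.arange(V.shape[1])] < 0
        V[:, flip] *= -1
        coords = V * np.sqrt(np.maximum(w, 0.0))
        total = w.sum()
        ratio = w / total if total > 0 else np.zeros_like(w)
        if self.n_components is not None:
            coords = coords[:, : self.n_components]
        self.coordinates_ = coords
        self.eigenvalues_ = w
        self.explained_variance_ratio_ = ratio
        self.labels_ = labels
        return self

    def fit_transform(self, X, y=None) -> np.ndarray:
        return self.fit(X).coordinates_

    def transform(self, X=None):
        """Coordinates of the fitted samples (no out-of-sample mapping)."""
        return self.coordinates_


@dataclass(frozen=True)
class Ordination:
    """Labeled PCoA result: coordinates, eigenvalues, variance fractions."""

    labels: list
    coordinates: np.ndarray
    eigenvalues: np.ndarray
    variance_explained: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        cols = [f"axis{k + 1}" for k in range(self.coordinates.shape[1])]
        return pd.DataFrame(self.coordinates, index=self.labels, columns=cols)


def pcoa(D) -> Ordination:
    """Run classical PCoA on a distance matrix; thin wrapper over PCoA()."""
    est = PCoA().fit(D)
    labels = est.labels_ or [f"s{i}" for i in range(est.coordinates_.shape[0])]
    return Ordination(
        labels, est.coordinates_, est.eigenvalues_, est.explained_variance_ratio_
    )


def dims_for_variance(ordination, threshold: float = 0.80, cap: int = 10) -> int:
    """Smallest axis count whose cumulative variance fraction exceeds
    ``threshold``, capped at ``min(cap, available axes)``; at least 1."""
    if isinstance(ordination, Ordination):
        ratio = ordination.variance_explained
    elif isinstance(ordination, PCoA):
        ratio = ordination.explained_variance_ratio_
    else:
        ratio = np.asarray(ordination, dtype=float)
    k = len(ratio)
    cum = np.cumsum(ratio)
    over = np.nonzero(cum > threshold)[0]
    n = int(over[0]) + 1 if over.size else k
    return max(1, min(n, cap, k))


def axis_gradient_correlation(ordination, axis: int, gradient) -> float:
    """|Pearson r| between one ordination axis and an external gradient.

    The absolute value is taken because the sign of a PCoA axis is
    arbitrary.
    """
    coords = (
        ordination.coordinates
        if isinstance(ordination, Ordination)
        else ordination.coordinates_
        if isinstance(ordination, PCoA)
        else np.asarray(ordination, dtype=float)
    )
    g = np.asarray(gradient, dtype=float)
    if coords.shape[0] != g.shape[0]:
        raise ValueError("gradient length must match sample count")
    if axis < 1 or axis > coords.shape[1]:
        raise ValueError(f"axis {axis} out of range 1..{coords.shape[1]}")
    if np.ptp(g) == 0:
        raise ValueError("gradient is constant; correlation undefined")
    x = coords[:, axis - 1]
    if np.ptp(x) == 0:
        return 0.0
    return float(abs(stats.pearsonr(x, g)[0]))


def oversaturation_check(
    D, skew_cutoff: float = DEFAULT_SKEW_CUTOFF
) -> tuple[float, bool]:
    """Skewness of the pairwise-distance distribution and an
    oversaturation verdict.

    Returns the adjusted Fisher-Pearson sample skewness of the upper-
    triangle values and ``True`` when it falls below ``skew_cutoff``
    (distances piled up near the measure's ceiling, thin left tail).
    A zero-variance distribution has undefined skewness and returns
    ``(0.0, False)`` with a warning.
    """
    M = check_distance_matrix(D)
    n = M.shape[0]
    if n < 4:
        raise ValueError("need at least 4 samples for a skewness estimate")
    vals = M[np.triu_indices(n, k=1)]
    if np.ptp(vals) == 0:
        warnings.warn("all pairwise distances equal; skewness undefined")
        return 0.0, False
    skew = float(stats.skew(vals, bias=False))
    return skew, bool(skew < skew_cutoff)
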