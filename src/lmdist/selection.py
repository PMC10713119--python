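"""Radius auto-selection machinery: the candidate grid, the degree
filter, the embedding-fidelity objective, the largest-radius selection
rule, and Gaussian smoothing across radii.

The selection trades off two things. A large radius trusts almost all
original values and barely adjusts anything; a small radius rebuilds
long distances from many short hops and risks overfitting a sparse
graph. Candidate radii are screened by a minimum average graph degree
(``phi`` as a fraction of the sample count) and scored by how faithfully
the adjusted matrix embeds into PCoA space. The largest screened radius
wins unless a smaller one beats the incumbent's score by more than
``epsilon``, which biases the choice toward trusting more of the data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy import stats

from .graph import NeighborGraph
from .io import check_distance_matrix
from .ordination import PCoA, dims_for_variance

__all__ = [
    "LMdistParams",
    "RadiusDiagnostics",
    "LMdistResult",
    "candidate_radii",
    "average_degree",
    "objective_correlation",
    "gaussian_smooth",
]


@dataclass(frozen=True)
class LMdistParams:
    """Tuning parameters of the radius auto-selection.

    phi : minimum average degree, as a fraction of the sample count, for
        a radius to be eligible (default 0.10).
    epsilon : score margin a smaller radius must exceed the incumbent by
        (default 0.05).
    n_radii : number of candidate radii evaluated (default 50).
    smooth / smooth_sigma : optional Gaussian averaging of the adjusted
        matrices across eligible radii, centered at the chosen radius;
        ``smooth_sigma=None`` defaults to one tenth of the grid span.
    variance_threshold / max_dims : how many PCoA axes the objective
        uses — the fewest covering > ``variance_threshold`` of the
        positive-eigenvalue variance, at most ``max_dims``.
    """

    phi: float = 0.10
    epsilon: float = 0.05
    n_radii: int = 50
    smooth: bool = False
    smooth_sigma: float | None = None
    variance_threshold: float = 0.80
    max_dims: int = 10

    def __post_init__(self):
        if not 0 < self.phi < 1:
            raise ValueError("phi must lie in (0, 1)")
        if self.epsilon < 0:
            raise ValueError("epsilon must be nonnegative")
        if self.n_radii < 1:
            raise ValueError("n_radii must be at least 1")
        if not 0 < self.variance_threshold < 1:
            raise ValueError("variance_threshold must lie in (0, 1)")
        if self.max_dims < 1:
            raise ValueError("max_dims must be at least 1")
        if self.smooth_sigma is not None and not self.smooth_sigma > 0:
            raise ValueError("smooth_sigma must be positive")


@dataclass(frozen=True)
class RadiusDiagnostics:
    """Per-radius record produced during auto-selection."""

    radius: float
    average_degree: float
    degree_valid: bool
    objective_correlation: float  # NaN when the radius failed the screen
    n_mst_edges: int


@dataclass(frozen=True)
class LMdistResult:
    """Outcome of an adjustment run.

    ``chosen_radius`` of ``None`` means no radius passed the screen (or
    the input was too small to score) and ``adjusted`` echoes the input.
    """

    adjusted: pd.DataFrame
    chosen_radius: float | None
    diagnostics: list = field(default_factory=list)
    smoothed: bool = False

    def diagnostics_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "radius": d.radius,
                    "average_degree": d.average_degree,
                    "degree_valid": d.degree_valid,
                    "objective_correlation": d.objective_correlation,
                    "n_mst_edges": d.n_mst_edges,
                }
                for d in self.diagnostics
            ]
        )


def candidate_radii(D, n_radii: int = 50) -> np.ndarray:
    """Evenly spaced candidate radii over the data's distance range.

    ``n_radii`` values spanning the half-open interval (min positive
    off-diagonal distance, max distance], endpoint included. A single
    candidate degenerates to the maximum distance.
    """
    M = check_distance_matrix(D)
    if n_radii < 1:
        raise ValueError("n_radii must be at least 1")
    off = M[np.triu_indices(M.shape[0], k=1)]
    pos = off[off > 0]
    if pos.size == 0:
        raise ValueError("matrix has no positive off-diagonal entries")
    lo, hi = float(pos.min()), float(off.max())
    return np.linspace(lo, hi, n_radii + 1)[1:]


def average_degree(G: NeighborGraph) -> float:
    """Mean number of trusted (non-borrowed) edges per node."""
    n = G.n_nodes
    n_trusted = len(G.edges) - len(G.mst_borrowed)
    return 2.0 * n_trusted / n if n else 0.0


def objective_correlation(
    adjusted, variance_threshold: float = 0.80, max_dims: int = 10
) -> float:
    """Embedding fidelity of an adjusted matrix in PCoA space.

    Embeds the matrix with PCoA, keeps the fewest axes (at most
    ``max_dims``) covering more than ``variance_threshold`` of the
    positive-eigenvalue variance, and returns the Pearson correlation
    between the adjusted distances and the Euclidean distances among the
    embedded points, over the strict upper triangle. Degenerate inputs
    (all points coincident) score 0 with a warning.
    """
    M = check_distance_matrix(adjusted)
    if M.shape[0] < 3:
        raise ValueError("objective needs at least 3 samples")
    est = PCoA().fit(M)
    ndim = dims_for_variance(
        est.explained_variance_ratio_, threshold=variance_threshold, cap=max_dims
    )
    emb = pdist(est.coordinates_[:, :ndim])
    orig = squareform(M, checks=False)
    if np.ptp(orig) == 0:
        # equidistant designs embed exactly (regular simplex) and deserve a
        # perfect score; coincident points have no embedding to speak of
        if orig.max() == 0 or not np.allclose(orig, emb, rtol=1e-8, atol=1e-10):
            warnings.warn("degenerate embedding; objective correlation undefined")
            return 0.0
        return 1.0
    if np.ptp(emb) == 0:
        warnings.warn("degenerate embedding; objective correlation undefined")
        return 0.0
    return float(stats.pearsonr(orig, emb)[0])


def _selection_rule(correlations, epsilon: float) -> int | None:
    """Index of the winning radius among eligible candidates.

    ``correlations`` are the objective scores of the eligible radii in
    *descending radius order*. The first entry (largest radius) starts as
    the incumbent; each subsequent entry replaces the incumbent only if
    it exceeds the incumbent's score by more than ``epsilon``. Returns
    ``None`` for an empty list.
    """
    winner = None
    best = -np.inf
    for k, c in enumerate(correlations):
        if winner is None or c > best + epsilon:
            winner, best = k, c
    return winner


def gaussian_smooth(per_radius, chosen: float, sigma: float) -> np.ndarray:
    """Gaussian-weighted elementwise average of adjusted matrices.

    ``per_radius`` is a sequence of ``(radius, matrix)`` pairs covering
    the eligible radii; weights are ``exp(-(r - chosen)^2 / (2 sigma^2))``
    normalized to sum 1, so the output is a convex combination bounded
    between the elementwise min and max of the inputs.
    """
    if len(per_radius) == 0:
        raise ValueError("no matrices to smooth")
    if not sigma > 0:
        raise ValueError("sigma must be positive")
    radii = np.array([r for r, _ in per_radius], dtype=float)
    mats = np.stack([check_distance_matrix(m) for _, m in per_radius])
    z = -((radii - chosen) ** 2) / (2.0 * sigma**2)
    z -= z.max()  # sigma -> 0 stays well-defined: mass collapses on chosen
    w = np.exp(z)
    w /= w.sum()
    return np.tensordot(w, mats, axes=1)
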