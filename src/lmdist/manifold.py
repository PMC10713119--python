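"""The LMDist estimator: geodesic adjustment of a beta-diversity matrix
with optional automatic radius selection.

Fits in the scikit-learn mold of the manifold learners (MDS, Isomap):
``fit_transform`` operates on the training set's pairwise matrix and
there is no out-of-sample mapping — the adjusted matrix is the product.
Unlike the embedding learners, the output is itself a distance matrix
and can flow into any downstream distance-based analysis.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .graph import build_neighbor_graph, connect_graph, geodesic_distances
from .io import check_distance_matrix, _as_labeled_frame
from .metrics import bray_curtis, jaccard
from .selection import (
    LMdistParams,
    LMdistResult,
    RadiusDiagnostics,
    _selection_rule,
    average_degree,
    candidate_radii,
    gaussian_smooth,
    objective_correlation,
)

__all__ = ["LMDist", "select_radius", "lmdist_auto"]

#: Fewest samples for which the PCoA-based objective is meaningful.
_MIN_SAMPLES_AUTO = 4


class LMDist(BaseEstimator):
    """Correct oversaturated pairwise dissimilarities via graph geodesics.

    Pairwise values below a neighborhood radius are trusted as graph
    edges; every pairwise value is then recomputed as the shortest-path
    length through that graph (with minimal spanning-tree edges borrowed
    if the graph fragments). Long-range values that had saturated the
    measure's ceiling are thereby rebuilt as sums of short, trustworthy
    hops, which straightens gradient arches in ordination.

    Parameters
    ----------
    radius : "auto" or positive float
        Fixed neighborhood radius, or "auto" to screen ``n_radii``
        candidates (largest radius wins unless a smaller one improves
        the embedding-fidelity objective by more than ``epsilon``).
    phi : float
        Minimum average trusted-edge degree for a candidate radius, as a
        fraction of the sample count.
    epsilon : float
        Objective margin a smaller radius must beat the incumbent by.
    n_radii : int
        Number of candidate radii.
    smooth : bool
        Average the adjusted matrices of all eligible radii with a
        Gaussian weight centered at the chosen radius.
    smooth_sigma : float or None
        Width of that Gaussian in radius units; ``None`` means one tenth
        of the candidate-grid span.
    variance_threshold, max_dims :
        PCoA axis budget of the objective (fewest axes covering more
        than ``variance_threshold`` of positive-eigenvalue variance, at
        most ``max_dims``).
    metric : {"precomputed", "braycurtis", "jaccard"}
        With "precomputed", ``X`` is a square distance matrix; otherwise
        ``X`` is a samples x features abundance table and the named
        dissimilarity is computed first.

    Attributes
    ----------
    adjusted_ : DataFrame of shape (n, n)
        The adjusted distance matrix.
    chosen_radius_ : float or None
        Radius actually used; ``None`` means no eligible radius existed
        and the input was passed through unadjusted.
    diagnostics_ : list of RadiusDiagnostics
        Per-candidate degree and objective records (ascending radius).
    smoothed_ : bool
    labels_ : list of str

    Examples
    --------
    >>> import numpy as np
    >>> from lmdist import LMDist
    >>> D = np.abs(np.subtract.outer(np.arange(5.), np.arange(5.))) / 10
    >>> LMDist(radius=0.15).fit_transform(D).to_numpy()[0, -1]
    0.4
    """

    def __init__(
        self,
        radius="auto",
        phi: float = 0.10,
        epsilon: float = 0.05,
        n_radii: int = 50,
        smooth: bool = False,
        smooth_sigma: float | None = None,
        variance_threshold: float = 0.80,
        max_dims: int = 10,
        metric: str = "precomputed",
    ):
        self.radius = radius
        self.phi = phi
        self.epsilon = epsilon
        self.n_radii = n_radii
        self.smooth = smooth
        self.smooth_sigma = smooth_sigma
        self.variance_threshold = variance_threshold
        self.max_dims = max_dims
        self.metric = metric

    # -- internals ---------------------------------------------------------

    def _resolve_distance(self, X) -> pd.DataFrame:
        if self.metric == "precomputed":
            return _as_labeled_frame(X)
        if self.metric == "braycurtis":
            return bray_curtis(X)
        if self.metric == "jaccard":
            return jaccard(X)
        raise ValueError(
            f"metric must be 'precomputed', 'braycurtis' or 'jaccard', got {self.metric!r}"
        )

    def _params(self) -> LMdistParams:
        return LMdistParams(
            phi=self.phi,
            epsilon=self.epsilon,
            n_radii=self.n_radii,
            smooth=self.smooth,
            smooth_sigma=self.smooth_sigma,
            variance_threshold=self.variance_threshold,
            max_dims=self.max_dims,
        )

    def _evaluate_radius(self, M, labels, r, force_adjust=False):
        """Build, repair and score the graph at one radius."""
        G = connect_graph(build_neighbor_graph(M, r, labels=labels), M)
        deg = average_degree(G)
        valid = deg >= self.phi * len(labels)
        adj = corr = None
        if valid or force_adjust:
            adj = geodesic_distances(G, return_frame=False)
        if valid and len(labels) >= 3:
            corr = objective_correlation(adj, self.variance_threshold, self.max_dims)
        diag = RadiusDiagnostics(
            radius=float(r),
            average_degree=float(deg),
            degree_valid=bool(valid),
            objective_correlation=float(corr) if corr is not None else float("nan"),
            n_mst_edges=len(G.mst_borrowed),
        )
        return diag, adj

    # -- estimator API -----------------------------------------------------

    def fit(self, X, y=None):
        params = self._params()  # validates early
        D = self._resolve_distance(X)
        labels = list(D.index)
        M = D.to_numpy()
        n = len(labels)
        self.labels_ = labels
        self.smoothed_ = False

        if self.radius != "auto":
            r = float(self.radius)
            if not r > 0:
                raise ValueError("radius must be positive")
            # a fixed radius is honored even below the degree screen
            diag, adj = self._evaluate_radius(M, labels, r, force_adjust=True)
            self.adjusted_ = _as_labeled_frame(adj, labels=labels)
            self.chosen_radius_ = r
            self.diagnostics_ = [diag]
            return self

        if n < _MIN_SAMPLES_AUTO:
            warnings.warn(
                f"only {n} samples; radius selection needs at least "
                f"{_MIN_SAMPLES_AUTO}, returning the input unadjusted"
            )
            self.adjusted_ = D.copy()
            self.chosen_radius_ = None
            self.diagnostics_ = []
            return self

        grid = candidate_radii(M, params.n_radii)
        diags: list[RadiusDiagnostics] = []
        eligible: list[tuple[float, float, np.ndarray]] = []  # (r, corr, adj)
        for r in grid[::-1]:
            diag, adj = self._evaluate_radius(M, labels, r)
            diags.append(diag)
            if diag.degree_valid:
                eligible.append((diag.radius, diag.objective_correlation, adj))
        self.diagnostics_ = diags[::-1]  # ascending radius

        winner = _selection_rule([c for _, c, _ in eligible], params.epsilon)
        if winner is None:
            self.adjusted_ = D.copy()
            self.chosen_radius_ = None
            return self

        chosen_r, _, chosen_adj = eligible[winner]
        if params.smooth and len(eligible) > 1:
            sigma = params.smooth_sigma
            if sigma is None:
                span = float(grid[-1] - grid[0])
                sigma = span / 10.0 if span > 0 else 1.0
            chosen_adj = gaussian_smooth(
                [(r, a) for r, _, a in eligible], chosen_r, sigma
            )
            self.smoothed_ = True
        self.adjusted_ = _as_labeled_frame(chosen_adj, labels=labels)
        self.chosen_radius_ = chosen_r
        return self

    def fit_transform(self, X, y=None) -> pd.DataFrame:
        """Fit on ``X`` and return the adjusted distance matrix."""
        return self.fit(X).adjusted_

    def result_(self) -> LMdistResult:
        """Fitted state bundled as an LMdistResult."""
        return LMdistResult(
            adjusted=self.adjusted_,
            chosen_radius=self.chosen_radius_,
            diagnostics=list(self.diagnostics_),
            smoothed=self.smoothed_,
        )


def select_radius(D, params: LMdistParams | None = None) -> LMdistResult:
    """Screen candidate radii on ``D`` and return the selected adjustment.

    Smoothing is not applied here even if ``params.smooth`` is set; use
    :func:`lmdist_auto` for the full pipeline.
    """
    params = params or LMdistParams()
    est = LMDist(
        radius="auto",
        phi=params.phi,
        epsilon=params.epsilon,
        n_radii=params.n_radii,
        smooth=False,
        variance_threshold=params.variance_threshold,
        max_dims=params.max_dims,
    )
    est.fit(D)
    return est.result_()


def lmdist_auto(D, params: LMdistParams | None = None) -> LMdistResult:
    """Full automatic adjustment: radius selection plus optional smoothing."""
    params = params or LMdistParams()
    est = LMDist(
        radius="auto",
        phi=params.phi,
        epsilon=params.epsilon,
        n_radii=params.n_radii,
        smooth=params.smooth,
        smooth_sigma=params.smooth_sigma,
        variance_threshold=params.variance_threshold,
        max_dims=params.max_dims,
    )
    est.fit(D)
    return est.result_()
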