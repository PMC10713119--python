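"""Pairwise dissimilarity measures computed from abundance tables.

Two measures are provided, the ones most commonly fed into ordination of
community data: Bray-Curtis on relative abundances and binary Jaccard on
presence/absence. Both are bounded in [0, 1] and returned as labeled
square DataFrames satisfying the distance-matrix invariants.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .io import check_abundance_table, _as_labeled_frame

__all__ = ["bray_curtis", "jaccard"]


def bray_curtis(table) -> pd.DataFrame:
    """Bray-Curtis dissimilarity, BC(x, y) = sum|x_k - y_k| / sum(x_k + y_k).

    Rows are normalized to relative abundances first, so the measure
    compares compositions rather than absolute yields.
    """
    T = check_abundance_table(table)
    M = T.to_numpy(dtype=float)
    M = M / M.sum(axis=1, keepdims=True)
    D = squareform(pdist(M, metric="braycurtis"))
    return _as_labeled_frame(D, labels=list(T.index))


def jaccard(table) -> pd.DataFrame:
    """Binary Jaccard dissimilarity, 1 - |A & B| / |A | B| on presence sets.

    Presence is abundance strictly greater than zero; abundance magnitudes
    are otherwise ignored.
    """
    T = check_abundance_table(table)
    P = T.to_numpy(dtype=float) > 0
    D = squareform(pdist(P, metric="jaccard"))
    return _as_labeled_frame(D, labels=list(T.index))
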