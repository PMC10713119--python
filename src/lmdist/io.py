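"""Reading, writing and validation of distance matrices and abundance tables.

Both formats are plain tab-separated text. A distance matrix carries the same
sample labels as its first row and first column; an abundance table has
samples as rows and features as columns. Labels are kept on
:class:`pandas.DataFrame` containers throughout, which is the in-memory
currency of the package.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "check_distance_matrix",
    "check_abundance_table",
    "read_distance_matrix",
    "write_distance_matrix",
    "read_abundance_table",
    "write_abundance_table",
]

#: Maximum tolerated asymmetry before a matrix is rejected. Matrices within
#: this tolerance are symmetrized as (M + M.T) / 2.
ASYMMETRY_TOL = 1e-8


class DistanceMatrixError(ValueError):
    """Raised when a distance matrix violates its invariants."""


class AbundanceTableError(ValueError):
    """Raised when an abundance table violates its invariants."""


def check_distance_matrix(X, *, tol: float = ASYMMETRY_TOL) -> np.ndarray:
    """Validate a square dissimilarity matrix and return it as a float array.

    Requirements: square, finite, nonnegative, symmetric within ``tol``
    (then symmetrized exactly), zero diagonal within ``tol`` (then zeroed).

    Parameters
    ----------
    X : array-like or DataFrame of shape (n, n)
    tol : float
        Largest absolute asymmetry or diagonal deviation accepted.

    Returns
    -------
    ndarray of shape (n, n)
        Exactly symmetric, hollow, nonnegative copy of ``X``.
    """
    if isinstance(X, pd.DataFrame):
        labels = list(X.index)
        if list(X.columns) != labels:
            raise DistanceMatrixError("row and column labels differ")
        X = X.to_numpy()
    M = np.asarray(X, dtype=float)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise DistanceMatrixError(f"matrix must be square, got shape {M.shape}")
    if not np.all(np.isfinite(M)):
        raise DistanceMatrixError("matrix contains non-finite entries")
    if M.min() < 0:
        raise DistanceMatrixError("matrix contains negative entries")
    asym = np.abs(M - M.T).max() if M.size else 0.0
    if asym > tol:
        raise DistanceMatrixError(f"matrix asymmetric beyond tolerance ({asym:.3g} > {tol:.3g})")
    M = (M + M.T) / 2.0
    if M.size and np.abs(np.diag(M)).max() > tol:
        raise DistanceMatrixError("diagonal entries must be zero")
    np.fill_diagonal(M, 0.0)
    return M


def check_abundance_table(T) -> pd.DataFrame:
    """Validate a samples x features abundance table.

    Entries must be finite and nonnegative; no sample row may sum to zero
    (an empty sample has no defined composition).
    """
    T = pd.DataFrame(T)
    M = T.to_numpy(dtype=float)
    if not np.all(np.isfinite(M)):
        raise AbundanceTableError("table contains non-finite entries")
    if M.size and M.min() < 0:
        raise AbundanceTableError("table contains negative entries")
    sums = M.sum(axis=1)
    if np.any(sums == 0):
        bad = list(T.index[sums == 0])
        raise AbundanceTableError(f"sample rows sum to zero: {bad}")
    if T.index.has_duplicates:
        raise AbundanceTableError("duplicate sample labels")
    return T.astype(float)


def _as_labeled_frame(D, labels=None) -> pd.DataFrame:
    """Wrap a validated matrix in a DataFrame with the given labels."""
    M = check_distance_matrix(D)
    if isinstance(D, pd.DataFrame) and labels is None:
        labels = list(D.index)
    if labels is None:
        labels = [f"s{i}" for i in range(M.shape[0])]
    if len(set(labels)) != M.shape[0]:
        raise DistanceMatrixError("labels must be unique and match matrix size")
    return pd.DataFrame(M, index=list(labels), columns=list(labels))


def read_distance_matrix(path) -> pd.DataFrame:
    """Read a labeled square distance matrix from a tab-separated file.

    The first row and first column must carry identical sample labels.
    Asymmetry within 1e-8 is symmetrized; anything beyond is an error.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if df.shape[0] != df.shape[1]:
        raise DistanceMatrixError(
            f"file body is not square: {df.shape[0]} rows x {df.shape[1]} columns"
        )
    if list(df.index) != list(df.columns):
        raise DistanceMatrixError("row labels do not match column labels")
    try:
        values = df.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise DistanceMatrixError(f"non-numeric body: {exc}") from None
    return _as_labeled_frame(pd.DataFrame(values, index=df.index, columns=df.columns))


def write_distance_matrix(D, path, labels=None) -> None:
    """Write a distance matrix as labeled tab-separated text.

    Values are printed with 17 significant digits so a read/write round
    trip is lossless for double precision.
    """
    frame = _as_labeled_frame(D, labels)
    frame.to_csv(path, sep="\t", float_format="%.17g")


def read_abundance_table(path) -> pd.DataFrame:
    """Read a samples x features abundance table from tab-separated text."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    return check_abundance_table(df)


def write_abundance_table(T, path) -> None:
    """Write an abundance table as labeled tab-separated text."""
    check_abundance_table(T).to_csv(path, sep="\t", float_format="%.17g")
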