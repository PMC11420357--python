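"""Patient-to-patient distance and the two MDS lens coordinates.

The distance between two patients is the normalized correlation distance
1 - r, with r the Pearson correlation of their feature vectors taken across
features (each row centred by its own mean). The two lens values per
patient are the leading coordinates of classical (Torgerson) metric MDS on
that distance matrix: double-centre -D^2/2, eigendecompose, and scale the
top non-negative eigenvectors by sqrt(eigenvalue). Classical MDS is
deterministic, which keeps the whole pipeline seed-free from here on.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

__all__ = ["normalized_correlation_distance", "classical_mds", "MDSLens"]


def normalized_correlation_distance(features) -> np.ndarray:
    """n x n matrix of 1 - Pearson r between patients' feature rows.

    Rows with zero variance across features are maximally uninformative:
    their correlation with every other row is taken as 0 (distance 1),
    and 0 to themselves. Values lie in [0, 2].
    """
    X = np.asarray(features, dtype=float)
    if X.ndim != 2:
        raise ValueError("expected a 2-D patients x features array")
    n, p = X.shape
    if p < 2:
        raise ValueError("correlation distance needs at least 2 features")
    if not np.all(np.isfinite(X)):
        raise ValueError("missing/non-finite entries; impute before distances")

    centred = X - X.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centred, axis=1)
    degenerate = norms == 0
    safe = np.where(degenerate, 1.0, norms)
    U = centred / safe[:, None]
    r = np.clip(U @ U.T, -1.0, 1.0)
    r[degenerate, :] = 0.0
    r[:, degenerate] = 0.0
    D = 1.0 - r
    np.fill_diagonal(D, 0.0)
    return D


def classical_mds(D: np.ndarray, n_components: int = 2) -> np.ndarray:
    """Torgerson MDS coordinates for a symmetric distance matrix.

    Missing positive-semidefinite directions (fewer than ``n_components``
    non-negative eigenvalues) are padded with zero columns. Each column's
    sign is fixed so its largest-magnitude entry is positive, making the
    output reproducible across linear-algebra backends.
    """
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    if D.shape != (n, n):
        raise ValueError("distance matrix must be square")
    if not np.allclose(D, D.T, atol=1e-10):
        raise ValueError("distance matrix must be symmetric")
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D * D) @ J
    # symmetric eigenproblem; eigh returns ascending order
    vals, vecs = np.linalg.eigh((B + B.T) / 2.0)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]

    coords = np.zeros((n, n_components))
    usable = 0
    for j in range(min(n_components, n)):
        if vals[j] > 0:
            coords[:, j] = vecs[:, j] * np.sqrt(vals[j])
            usable += 1
    if usable < n_components:
        warnings.warn(
            f"only {usable} positive MDS directions; remaining lens "
            "coordinates padded with zeros"
        )
    for j in range(n_components):
        col = coords[:, j]
        if col.any() and col[np.argmax(np.abs(col))] < 0:
            coords[:, j] = -col
    return coords


class MDSLens(BaseEstimator, TransformerMixin):
    """Transformer: feature matrix -> (distance matrix, 2 lens columns).

    ``fit`` computes and stores ``distance_`` and ``lens_``;
    ``transform`` returns the lens coordinates (as a DataFrame when the
    input carried a patient index).
    """

    def __init__(self, n_lenses: int = 2):
        self.n_lenses = n_lenses

    def fit(self, X, y=None):
        index = X.index if isinstance(X, pd.DataFrame) else None
        self.distance_ = normalized_correlation_distance(X)
        coords = classical_mds(self.distance_, self.n_lenses)
        if index is not None:
            self.lens_ = pd.DataFrame(
                coords, index=index, columns=[f"lens{i+1}" for i in range(self.n_lenses)]
            )
        else:
            self.lens_ = pd.DataFrame(
                coords, columns=[f"lens{i+1}" for i in range(self.n_lenses)]
            )
        return self

    def transform(self, X=None):
        check_is_fitted(self, "lens_")
        return self.lens_

    def fit_transform(self, X, y=None):
        return self.fit(X).transform()
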