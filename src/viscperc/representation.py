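"""Representational analyses: RDMs in factor space and PCA of pixel vs
feature spaces.

A representational dissimilarity matrix (RDM) holds the pairwise Euclidean
distances between stimuli in the 4-D factor space; two representations are
compared by regressing one RDM's strictly-lower-triangle entries on the
other's.  Pixel-space PCA flattens each stimulus video into one very long
vector (width × height × frames) and extracts components through the Gram
matrix (samples ≪ dimensions); feature-space PCA operates on standardized
mean feature ratings, with PC1's sign anchored to log viscosity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from sklearn.decomposition import PCA

from .report import FitReport, ols_report
from .synth import RatingsTable

__all__ = [
    "RDM",
    "PCAResult",
    "compute_rdm",
    "compare_rdms",
    "pixel_pca",
    "feature_pca",
    "viscosity_alignment",
    "downscale_and_gray",
]

#: grayscale conversion weights (ITU-R BT.601)
GRAY_WEIGHTS = np.array([0.2989, 0.5870, 0.1140])


@dataclass
class RDM:
    """Symmetric, zero-diagonal, non-negative dissimilarity matrix."""

    values: np.ndarray
    labels: list = field(default=None)

    def __post_init__(self) -> None:
        d = np.asarray(self.values, dtype=float)
        if d.ndim != 2 or d.shape[0] != d.shape[1]:
            raise ValueError("RDM must be square")
        if not np.allclose(d, d.T, atol=1e-10):
            raise ValueError("RDM must be symmetric")
        if not np.allclose(np.diag(d), 0.0, atol=1e-10):
            raise ValueError("RDM diagonal must be zero")
        if (d < -1e-12).any():
            raise ValueError("RDM entries must be non-negative")
        self.values = d
        if self.labels is None:
            self.labels = list(range(len(d)))

    @property
    def n(self) -> int:
        return len(self.values)

    def lower_triangle(self) -> np.ndarray:
        """Strictly-lower-triangle entries (diagonal and upper excluded)."""
        i, j = np.tril_indices(self.n, k=-1)
        return self.values[i, j]

    def satisfies_triangle_inequality(self, atol: float = 1e-9) -> bool:
        d = self.values
        # d[i,j] <= min_k d[i,k] + d[k,j]
        through = (d[:, :, None] + d[None, :, :]).min(axis=1)
        return bool(np.all(d <= through + atol))


def compute_rdm(scores, labels: Sequence | None = None) -> RDM:
    """Pairwise Euclidean distances between stimuli in factor space."""
    X = np.asarray(scores, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a 2-D score matrix with at least 2 rows")
    if labels is None and isinstance(scores, pd.DataFrame):
        labels = list(scores.index)
    return RDM(squareform(pdist(X, metric="euclidean")), labels)


def compare_rdms(a: RDM, b: RDM) -> FitReport:
    """OLS of b's strictly-lower-triangle entries on a's.

    With n stimuli the regression uses n(n−1)/2 pairs and df2 = pairs − 2.
    R² is symmetric in the roles of a and b.
    """
    if a.n != b.n:
        raise ValueError("RDMs have different sizes")
    if list(a.labels) != list(b.labels):
        raise ValueError("RDM labels do not match")
    rep, _ = ols_report(a.lower_triangle(), b.lower_triangle())
    return rep


@dataclass
class PCAResult:
    """PCA scores, explained-variance fractions, and (optionally) loadings."""

    scores: np.ndarray  # (n_samples, n_components)
    explained_variance_ratio: np.ndarray
    components: np.ndarray | None = None  # (n_components, n_dims); may be huge

    def __post_init__(self) -> None:
        evr = np.asarray(self.explained_variance_ratio, dtype=float)
        if (np.diff(evr) > 1e-10).any():
            raise ValueError("explained-variance fractions must be non-increasing")
        if evr.sum() > 1 + 1e-8:
            raise ValueError("explained-variance fractions must sum to <= 1")


def downscale_and_gray(frames_rgb: np.ndarray) -> np.ndarray:
    """Halve each RGB frame and convert to grayscale (BT.601 weights)."""
    frames_rgb = np.asarray(frames_rgb, dtype=float)
    gray = frames_rgb @ GRAY_WEIGHTS
    return 0.25 * (gray[:, 0::2, 0::2] + gray[:, 1::2, 0::2]
                   + gray[:, 0::2, 1::2] + gray[:, 1::2, 1::2])


def pixel_pca(videos: Sequence[np.ndarray], n_components: int | None = None,
              return_components: bool = False) -> PCAResult:
    """PCA across stimuli of flattened pixel-space video vectors.

    Each stimulus video (frames × H × W, already grayscale) is flattened to
    one vector; every pixel dimension is centred across stimuli and the
    eigendecomposition runs on the n × n Gram matrix, which is exact and
    avoids materialising a covariance over millions of pixel dimensions.
    All videos must share frame count and resolution.  At most n − 1
    components are non-trivial.
    """
    shapes = {np.asarray(v).shape for v in videos}
    if len(shapes) != 1:
        raise ValueError(f"videos differ in shape/frame count: {sorted(shapes)}")
    X = np.stack([np.asarray(v, dtype=float).ravel() for v in videos])
    n = X.shape[0]
    k = min(n_components or n - 1, n - 1)
    Xc = X - X.mean(axis=0, keepdims=True)
    G = Xc @ Xc.T
    evals, evecs = np.linalg.eigh(G)
    order = np.argsort(evals)[::-1][:k]
    evals = np.maximum(evals[order], 0.0)
    evecs = evecs[:, order]
    scores = evecs * np.sqrt(evals)  # = U S, the PCA projections
    total = np.trace(G)
    evr = evals / total if total > 0 else np.zeros(k)
    components = None
    if return_components:
        nz = evals > 1e-12
        components = np.zeros((k, X.shape[1]))
        components[nz] = (Xc.T @ (evecs[:, nz] / np.sqrt(evals[nz]))).T
    return PCAResult(scores, evr, components)


def feature_pca(table, viscosities: np.ndarray | None = None,
                n_components: int = 4) -> PCAResult:
    """PCA of the standardized (repetition-averaged) feature ratings.

    When physical viscosities are supplied, PC1's sign is fixed so that it
    correlates positively with log10 viscosity.
    """
    if isinstance(table, RatingsTable):
        values = table.average_repetitions().values
    else:
        values = pd.DataFrame(table)
    X = values.to_numpy(dtype=float)
    Z = (X - X.mean(axis=0)) / X.std(axis=0)
    k = min(n_components, Z.shape[1], Z.shape[0] - 1)
    pca = PCA(n_components=k)
    scores = pca.fit_transform(Z)
    comps = pca.components_.copy()
    if viscosities is not None:
        lv = np.log10(np.asarray(viscosities, dtype=float))
        if np.corrcoef(scores[:, 0], lv)[0, 1] < 0:
            scores[:, 0] *= -1
            comps[0] *= -1
    return PCAResult(scores, pca.explained_variance_ratio_, comps)


def viscosity_alignment(pca: PCAResult, viscosities: np.ndarray,
                        axis: str = "log10") -> FitReport:
    """OLS of the PC1 score on the physical viscosity axis.

    ``axis`` may be "log10" (stimuli are log-spaced; default) or "ordinal"
    (rank of the viscosity step).
    """
    v = np.asarray(viscosities, dtype=float)
    if len(v) != len(pca.scores):
        raise ValueError("scores and viscosities are not aligned")
    if axis == "log10":
        x = np.log10(v)
    elif axis == "ordinal":
        x = np.argsort(np.argsort(v)).astype(float)
    else:
        raise ValueError(f"unknown axis {axis!r}")
    rep, _ = ols_report(x, pca.scores[:, 0])
    return rep
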