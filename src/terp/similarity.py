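"""Neighborhood similarity weights from a supervised 1-d projection.

Plain Euclidean distance in the design space is fragile: adding a
redundant or pure-noise column changes every pairwise distance even
though no information was added.  Instead, the neighborhood is first
binarized into in-class / not-in-class samples by thresholding the
black-box probabilities, then projected onto the two-class Fisher
discriminant direction.  Distances along that single coordinate feed a
Gaussian kernel ``Pi_i = exp(-d_i^2 / sigma^2)``.

The projection is normalized so the pooled within-class variance of
the projected coordinates equals 1, which is what makes the fixed
kernel width ``sigma = 1`` a meaningful default rather than a tunable
hyperparameter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigError, DegenerateNeighborhoodError

__all__ = [
    "ClassLabels",
    "SimilarityWeights",
    "binarize_predictions",
    "fisher_projection",
    "euclidean_distances",
    "gaussian_weights",
    "similarity_error",
]


@dataclass(frozen=True)
class ClassLabels:
    """Binary in-class labels derived from black-box probabilities."""

    labels: np.ndarray
    threshold: float = 0.5


@dataclass(frozen=True)
class SimilarityWeights:
    """1-d coordinates, distances to the anchor, and Gaussian weights."""

    projected: np.ndarray
    d: np.ndarray
    Pi: np.ndarray
    sigma: float = 1.0


def binarize_predictions(g: np.ndarray, threshold: float = 0.5) -> ClassLabels:
    """Label sample i as in-class (1) iff ``g_i >= threshold``."""
    g = np.asarray(g, dtype=float).ravel()
    if np.any(g < 0) or np.any(g > 1) or np.any(~np.isfinite(g)):
        raise ConfigError("predictions must lie in [0, 1]")
    if not 0.0 <= threshold <= 1.0:
        raise ConfigError("threshold must lie in [0, 1]")
    return ClassLabels(labels=(g >= threshold).astype(np.uint8), threshold=float(threshold))


def fisher_projection(
    design: np.ndarray,
    labels: ClassLabels | np.ndarray,
    ridge: float = 1e-6,
) -> tuple[np.ndarray, np.ndarray]:
    """Project the design matrix onto the two-class Fisher direction.

    The direction is the within-class-scatter-whitened mean difference
    ``S_w^{-1} (mu_1 - mu_0)``.  The scatter matrix is regularized by
    ``ridge * trace(S_w)/n`` on the diagonal so exactly duplicated or
    collinear columns do not break the solve — robustness to redundant
    features is the point of this projection.

    Returns ``(coords, direction)``.  Coordinates are centered on the
    grand mean, scaled to unit pooled within-class variance, and
    sign-fixed so the in-class mean is positive.
    """
    X = np.asarray(design, dtype=float)
    y = labels.labels if isinstance(labels, ClassLabels) else np.asarray(labels)
    y = y.ravel().astype(int)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ConfigError("design and labels are inconsistent")
    n0, n1 = int(np.sum(y == 0)), int(np.sum(y == 1))
    if n0 < 2 or n1 < 2:
        raise DegenerateNeighborhoodError(
            f"need >= 2 samples in each class, got {n0} not-in-class / {n1} in-class; "
            "widen the neighborhood or use the Euclidean similarity fallback"
        )
    X0, X1 = X[y == 0], X[y == 1]
    mu0, mu1 = X0.mean(axis=0), X1.mean(axis=0)
    D0, D1 = X0 - mu0, X1 - mu1
    Sw = D0.T @ D0 + D1.T @ D1
    n = X.shape[1]
    tr = np.trace(Sw)
    lam = ridge * (tr / n if tr > 0 else 1.0)
    w = np.linalg.solve(Sw + lam * np.eye(n), mu1 - mu0)

    c = X @ w
    c = c - c.mean()
    m0, m1 = c[y == 0].mean(), c[y == 1].mean()
    ss_within = np.sum((c[y == 0] - m0) ** 2) + np.sum((c[y == 1] - m1) ** 2)
    scale = np.sqrt(ss_within / (len(c) - 2))
    if scale > 0:
        c = c / scale
        w = w / scale
    if c[y == 1].mean() < c[y == 0].mean():
        c, w = -c, -w
    return c, w


def euclidean_distances(design: np.ndarray, anchor_index: int = 0) -> np.ndarray:
    """Standardized-Euclidean distances to the anchor, rescaled to unit
    variance.

    Fallback / baseline metric: each column is z-scored over the
    neighborhood, distances are Euclidean in that space and then
    divided by their own standard deviation so the Gaussian kernel with
    ``sigma = 1`` remains comparable to the Fisher-projected distances.
    """
    X = np.asarray(design, dtype=float)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    Z = (X - X.mean(axis=0)) / sd
    d = np.linalg.norm(Z - Z[anchor_index], axis=1)
    s = d.std()
    return d / s if s > 0 else d


def gaussian_weights(
    projected: np.ndarray,
    anchor_index: int = 0,
    sigma: float = 1.0,
) -> SimilarityWeights:
    """Gaussian kernel weights ``Pi_i = exp(-(c_i - c_0)^2 / sigma^2)``.

    The anchor (the instance being explained, row 0 by convention)
    always receives weight exactly 1.
    """
    if sigma <= 0:
        raise ConfigError("sigma must be positive")
    c = np.asarray(projected, dtype=float).ravel()
    d = np.abs(c - c[anchor_index])
    Pi = np.exp(-((d / sigma) ** 2))
    return SimilarityWeights(projected=c, d=d, Pi=Pi, sigma=float(sigma))


def similarity_error(Pi_original: np.ndarray, Pi_synthetic: np.ndarray) -> float:
    """Mean squared change in similarity weights, in [0, 1].

    Quantifies how much the weights move when uninformative (noise or
    correlated-copy) features are appended: since those features carry
    no information the weights *should* be unchanged, so any shift is
    error attributable to the similarity measure itself.
    """
    a = np.asarray(Pi_original, dtype=float).ravel()
    b = np.asarray(Pi_synthetic, dtype=float).ravel()
    if a.shape != b.shape:
        raise ConfigError("weight vectors differ in length")
    for v in (a, b):
        if np.any(v < 0) or np.any(v > 1):
            raise ConfigError("weights must lie in [0, 1]")
    return float(np.mean((a - b) ** 2))
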