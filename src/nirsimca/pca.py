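"""Mean-centered PCA by SVD, with the distance statistics one-class
classification builds on: Hotelling T² in the score space, Q residuals in its
orthogonal complement, and score-plot confidence ellipses."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import f as f_dist

__all__ = [
    "PCAModel",
    "ScoreStats",
    "ConfidenceEllipse",
    "fit_pca",
    "project",
    "explained_variance",
    "score_ellipse",
]

_RANK_RTOL = 1e-10


@dataclass(frozen=True)
class PCAModel:
    """center: training column means; loadings: (n_channels x A) orthonormal;
    component_variances: per-PC training score variances s_a^2/(n-1);
    residual_variances: variances of the components beyond A up to the rank
    (needed for Q confidence limits); total_variance: sum over all components.
    """

    center: np.ndarray
    loadings: np.ndarray
    component_variances: np.ndarray
    residual_variances: np.ndarray
    n_components: int
    n_training: int
    total_variance: float


@dataclass(frozen=True)
class ScoreStats:
    scores: np.ndarray  # (n x A)
    t2: np.ndarray      # Hotelling T² per sample
    q: np.ndarray       # squared orthogonal residual per sample


@dataclass(frozen=True)
class ConfidenceEllipse:
    pair: tuple[int, int]
    semi_axes: tuple[float, float]
    level: float


def fit_pca(X: np.ndarray, A: int) -> PCAModel:
    """SVD PCA of the mean-centered matrix, keeping A components.

    Sign convention: each loading column is flipped so its largest-magnitude
    element is positive, making fitted models platform- and run-stable.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be 2-D")
    n, p = X.shape
    if n < 2:
        raise ValueError("PCA needs at least 2 samples")
    if A < 1:
        raise ValueError("A must be >= 1")
    center = X.mean(axis=0)
    Xc = X - center
    _, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    if s[0] <= 0:
        raise ValueError("data matrix has zero variance; cannot fit PCA")
    rank = int(np.sum(s > s[0] * _RANK_RTOL))
    if A > rank:
        raise ValueError(f"A={A} exceeds data rank {rank}")
    variances = s**2 / (n - 1)
    loadings = Vt[:A].T.copy()
    for j in range(A):
        i = int(np.argmax(np.abs(loadings[:, j])))
        if loadings[i, j] < 0:
            loadings[:, j] = -loadings[:, j]
    return PCAModel(
        center=center,
        loadings=loadings,
        component_variances=variances[:A].copy(),
        residual_variances=variances[A:rank].copy(),
        n_components=A,
        n_training=n,
        total_variance=float(variances[: min(n - 1, p)].sum()),
    )


def project(model: PCAModel, X: np.ndarray) -> ScoreStats:
    """Scores, Hotelling T² and Q residual of new samples.

    T = (X - center) L;  q_i = ||(X_i - center) - T_i Lᵀ||²;
    t2_i = Σ_a T_ia² / λ_a with λ_a the training score variances.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.center.size:
        raise ValueError(
            f"X has {X.shape[1]} channels, model expects {model.center.size}"
        )
    Xc = X - model.center
    T = Xc @ model.loadings
    resid = Xc - T @ model.loadings.T
    q = np.einsum("ij,ij->i", resid, resid)
    t2 = ((T**2) / model.component_variances).sum(axis=1)
    return ScoreStats(scores=T, t2=t2, q=q)


def explained_variance(model: PCAModel) -> np.ndarray:
    """Fraction of total training variance carried by each kept component."""
    return model.component_variances / model.total_variance


def score_ellipse(
    model: PCAModel, pair: tuple[int, int] = (0, 1), level: float = 0.95
) -> ConfidenceEllipse:
    """Hotelling confidence ellipse for a pair of score axes.

    Semi-axes are sqrt(λ_i T²_lim) with the two-component limit
    T²_lim = 2(n-1)/(n-2) F_level(2, n-2).
    """
    i, j = pair
    if i == j:
        raise ValueError("ellipse needs two distinct components")
    n = model.n_training
    if n <= 2:
        raise ValueError("confidence ellipse needs n > 2 training samples")
    if not (0.0 < level < 1.0):
        raise ValueError("level must be in (0, 1)")
    A = model.n_components
    if not (0 <= i < A and 0 <= j < A):
        raise ValueError("component index out of range")
    t2_lim = 2.0 * (n - 1) / (n - 2) * f_dist.ppf(level, 2, n - 2)
    lam = model.component_variances
    return ConfidenceEllipse(
        pair=(i, j),
        semi_axes=(
            float(np.sqrt(lam[i] * t2_lim)),
            float(np.sqrt(lam[j] * t2_lim)),
        ),
        level=level,
    )
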