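"""Classical SIMCA one-class brand models.

Each brand is modelled by its own PCA on preprocessed training spectra.
Q residual and Hotelling T² confidence limits at 95% are turned into a
class-membership probability through the reduced distance

    d = sqrt[(q / Q_lim)² + (t2 / T²_lim)²],   p = exp(−d² ln2 / 2),

so p = 1 at the class center, p = 0.5 for a sample sitting exactly on both
limits (d = √2), and p decreases monotonically in both statistics. A sample is
attributed to every class with p ≥ 0.8 (class-modeling semantics: zero or
several assignments are possible). The probability map is this package's own
documented convention; commercial toolboxes do not publish theirs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2, f as f_dist, norm

from .pca import PCAModel, fit_pca, project
from .preprocess import MSCReference, PreprocessConfig, preprocess_pipeline
from .selection import venetian_blinds_select
from .synthetic import SpectrumSet

__all__ = [
    "SIMCAClassModel",
    "SIMCAPrediction",
    "q_confidence_limit",
    "t2_confidence_limit",
    "fit_simca_class",
    "simca_probability",
    "reduced_distance",
    "simca_assign",
]


def q_confidence_limit(residual_variances: np.ndarray, level: float = 0.95) -> float:
    """Jackson-Mudholkar confidence limit for the Q residual statistic.

    Uses the residual-component variances through their power sums
    theta_k = sum(lambda^k), k = 1..3. If the Wilson-Hilferty exponent
    degenerates (h0 <= 0 or negative base, possible for heavy-tailed residual
    spectra) the Box g*chi2(h) moment approximation is used instead.
    """
    lam = np.asarray(residual_variances, dtype=float)
    lam = lam[lam > 0]
    if not (0.0 < level < 1.0):
        raise ValueError("level must be in (0, 1)")
    if lam.size == 0:
        return 0.0
    th1 = float(lam.sum())
    th2 = float((lam**2).sum())
    th3 = float((lam**3).sum())
    h0 = 1.0 - 2.0 * th1 * th3 / (3.0 * th2**2)
    z = norm.ppf(level)
    if h0 > 0:
        base = (
            z * np.sqrt(2.0 * th2 * h0**2) / th1
            + 1.0
            + th2 * h0 * (h0 - 1.0) / th1**2
        )
        if base > 0:
            return float(th1 * base ** (1.0 / h0))
    # moment-matched scaled chi-squared fallback
    g = th2 / th1
    h = th1**2 / th2
    return float(g * chi2.ppf(level, h))


def t2_confidence_limit(A: int, n: int, level: float = 0.95) -> float:
    """Hotelling T² limit A(n-1)/(n-A) * F_level(A, n-A)."""
    if A < 1:
        raise ValueError("A must be >= 1")
    if n <= A:
        raise ValueError(f"need n > A (got n={n}, A={A})")
    if not (0.0 < level < 1.0):
        raise ValueError("level must be in (0, 1)")
    return float(A * (n - 1) / (n - A) * f_dist.ppf(level, A, n - A))


@dataclass(frozen=True)
class SIMCAClassModel:
    brand: str
    pca: PCAModel
    q_limit: float
    t2_limit: float
    confidence: float
    prob_threshold: float
    preprocess: PreprocessConfig | None
    msc_reference: MSCReference | None

    def __post_init__(self) -> None:
        if not (0.0 < self.prob_threshold < 1.0):
            raise ValueError("prob_threshold must be in (0, 1)")


@dataclass(frozen=True)
class SIMCAPrediction:
    """Long-form decision table: one row per (sample, class model) with
    columns sample_id, model_brand, q, t2, d, p, accepted."""

    table: pd.DataFrame

    def assignments(self) -> dict[str, set[str]]:
        """sample_id -> set of class brands with p >= threshold."""
        out: dict[str, set[str]] = {
            s: set() for s in self.table["sample_id"].unique()
        }
        acc = self.table[self.table["accepted"]]
        for s, b in zip(acc["sample_id"], acc["model_brand"]):
            out[s].add(b)
        return out


def _model_space(model, spectra: SpectrumSet) -> np.ndarray:
    """Preprocess raw spectra with the model's stored training state."""
    if model.preprocess is None:
        if spectra.n_channels != model.pca.center.size:
            raise ValueError("spectra channel count does not match model")
        return spectra.absorbance
    out, _ = preprocess_pipeline(spectra, model.preprocess, model.msc_reference)
    return out.absorbance


def fit_simca_class(
    training: SpectrumSet,
    brand: str,
    A: int | str = "auto",
    confidence: float = 0.95,
    prob_threshold: float = 0.8,
    preprocess: PreprocessConfig | None = PreprocessConfig(),
    max_A: int | None = None,
    cv_splits: int = 10,
) -> SIMCAClassModel:
    """Fit a one-class SIMCA model for one brand.

    ``training`` must contain only spectra of that brand. With ``A="auto"``
    the component count is chosen by venetian-blinds cross-validation over
    1..max_A; ``max_A`` defaults to min(10, n_training // 5), the usual
    five-samples-per-component rule of thumb, which also keeps the
    training-based Q limit calibrated for small classes. With
    ``preprocess=None`` the input is taken as already being in model space
    and no preprocessing state is stored.
    """
    labels = set(training.metadata["brand"])
    if labels != {brand}:
        raise ValueError(f"training set contains brands {sorted(labels)}, not only {brand!r}")
    if len(training) < 3:
        raise ValueError("need at least 3 training spectra")
    if preprocess is not None:
        prep, msc_ref = preprocess_pipeline(training, preprocess)
        X = prep.absorbance
    else:
        msc_ref = None
        X = training.absorbance
    if A == "auto":
        if max_A is None:
            max_A = max(1, min(10, len(training) // 5))
        A = venetian_blinds_select(X, max_A=max_A, n_splits=cv_splits)
    A = int(A)
    pca = fit_pca(X, A)
    q_lim = q_confidence_limit(pca.residual_variances, confidence)
    t2_lim = t2_confidence_limit(A, len(training), confidence)
    return SIMCAClassModel(
        brand=brand,
        pca=pca,
        q_limit=q_lim,
        t2_limit=t2_lim,
        confidence=confidence,
        prob_threshold=prob_threshold,
        preprocess=preprocess,
        msc_reference=msc_ref,
    )


def simca_probability(
    model: SIMCAClassModel, q: np.ndarray, t2: np.ndarray
) -> np.ndarray:
    """Class-membership probability from the reduced distance.

    d² = (q/Q_lim)² + (t2/T²_lim)²;  p = exp(−d² ln2 / 2). A degenerate
    Q_lim = 0 (perfect-fit class) treats q/Q_lim as 0 where q ≈ 0 and as
    infinite otherwise.
    """
    d = reduced_distance(model, q, t2)
    return np.exp(-(d**2) * np.log(2.0) / 2.0)


def reduced_distance(
    model: SIMCAClassModel, q: np.ndarray, t2: np.ndarray
) -> np.ndarray:
    """d = sqrt[(q/Q_lim)² + (t2/T²_lim)²], the limit-normalised distance."""
    q = np.asarray(q, dtype=float)
    t2 = np.asarray(t2, dtype=float)
    if model.q_limit > 0:
        qr = q / model.q_limit
    else:
        qr = np.where(q <= 1e-12, 0.0, np.inf)
    tr = t2 / model.t2_limit
    return np.sqrt(qr**2 + tr**2)


def simca_assign(
    models: list[SIMCAClassModel], spectra: SpectrumSet
) -> SIMCAPrediction:
    """Evaluate raw spectra against every class model.

    Each model preprocesses the spectra with its own stored training state,
    computes q, t2, the reduced distance d and probability p, and accepts the
    sample iff p >= its threshold. Samples may end up in no class (falsified
    or foreign products) or in several.
    """
    frames = []
    for model in models:
        X = _model_space(model, spectra)
        stats = project(model.pca, X)
        d = reduced_distance(model, stats.q, stats.t2)
        with np.errstate(over="ignore"):
            p = np.exp(-(d**2) * np.log(2.0) / 2.0)
        frames.append(
            pd.DataFrame(
                {
                    "sample_id": spectra.metadata["sample_id"],
                    "model_brand": model.brand,
                    "q": stats.q,
                    "t2": stats.t2,
                    "d": d,
                    "p": p,
                    "accepted": p >= model.prob_threshold,
                }
            )
        )
    return SIMCAPrediction(pd.concat(frames, ignore_index=True))
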