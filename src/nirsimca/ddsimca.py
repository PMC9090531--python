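"""Data-driven SIMCA (DD-SIMCA) one-class models.

After a per-brand PCA decomposition, each training sample yields a score
distance h (Mahalanobis distance inside the PC subspace) and an orthogonal
distance v (squared residual norm). Both are modelled as scaled chi-squared
variables whose scaling (the sample mean h0 or v0) and integer degrees of
freedom (N_h, N_v) are estimated by the method of moments. The total distance

    c = N_h * h / h0 + N_v * v / v0

is approximately chi-squared with N_h + N_v degrees of freedom, so the
acceptance region at significance level alpha is c <= c_crit with
c_crit the (1 - alpha) chi-squared quantile. Acceptance plots use the
coordinates (ln(1 + h/h0), ln(1 + v/v0)).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .pca import PCAModel, fit_pca, project
from .preprocess import MSCReference, PreprocessConfig, preprocess_pipeline
from .simca import _model_space
from .synthetic import SpectrumSet

__all__ = [
    "DDSIMCAModel",
    "DDDecision",
    "distances",
    "estimate_dof",
    "total_distance",
    "fit_ddsimca",
    "dd_decide",
]

DOF_CEILING = 250  # near-degenerate distributions are clipped here


def distances(pca: PCAModel, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Score distance h and orthogonal distance v of each row of X.

    h_i = sum_a t_ia^2 / lambda_a (training score variances), v_i = squared
    residual norm after reconstruction from the A kept components.
    """
    stats = project(pca, X)
    return stats.t2, stats.q


def estimate_dof(values: np.ndarray) -> tuple[float, int]:
    """Moment estimate of the scaled chi-squared parameters of a distance.

    For x ~ x0 * chi2(N) / N: E[x] = x0 and Var[x] = 2 x0^2 / N, so
    x0 = mean and N = round(2 mean^2 / variance), clipped to [1, DOF_CEILING].
    A zero-variance (degenerate) sample returns the ceiling.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 5:
        raise ValueError("need at least 5 distance values to estimate DoF")
    mean = float(v.mean())
    var = float(v.var(ddof=1))
    if var <= 0.0 or mean <= 0.0:
        return mean, DOF_CEILING
    dof = int(round(2.0 * mean**2 / var))
    return mean, int(np.clip(dof, 1, DOF_CEILING))


@dataclass(frozen=True)
class DDSIMCAModel:
    brand: str
    pca: PCAModel
    h0: float
    n_h: int
    v0: float
    n_v: int
    alpha: float
    c_crit: float
    preprocess: PreprocessConfig | None
    msc_reference: MSCReference | None

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must be in (0, 1)")
        if self.n_h < 1 or self.n_v < 1:
            raise ValueError("degrees of freedom must be >= 1")


@dataclass(frozen=True)
class DDDecision:
    """Per-sample table: sample_id, h, v, c, accepted, plot_x, plot_y."""

    table: pd.DataFrame
    model_brand: str


def fit_ddsimca(
    training: SpectrumSet,
    brand: str,
    A: int = 2,
    alpha: float = 1e-6,
    preprocess: PreprocessConfig | None = PreprocessConfig(),
) -> DDSIMCAModel:
    """Fit a DD-SIMCA model for one brand at significance level alpha.

    ``preprocess=None`` treats the input as already being in model space.
    """
    labels = set(training.metadata["brand"])
    if labels != {brand}:
        raise ValueError(
            f"training set contains brands {sorted(labels)}, not only {brand!r}"
        )
    n = len(training)
    if n <= A:
        raise ValueError(f"need more training samples than components (n={n}, A={A})")
    if preprocess is not None:
        prep, msc_ref = preprocess_pipeline(training, preprocess)
        X = prep.absorbance
    else:
        msc_ref = None
        X = training.absorbance
    pca = fit_pca(X, A)
    h, v = distances(pca, X)
    h0, n_h = estimate_dof(h)
    v0, n_v = estimate_dof(v)
    c_crit = float(chi2.ppf(1.0 - alpha, n_h + n_v))
    return DDSIMCAModel(
        brand=brand,
        pca=pca,
        h0=h0,
        n_h=n_h,
        v0=v0,
        n_v=n_v,
        alpha=alpha,
        c_crit=c_crit,
        preprocess=preprocess,
        msc_reference=msc_ref,
    )


def total_distance(model: DDSIMCAModel, h: np.ndarray, v: np.ndarray) -> np.ndarray:
    """c = N_h h/h0 + N_v v/v0, with degenerate scalings (h0 or v0 = 0)
    contributing 0 where the distance is ~0 and infinity otherwise."""
    h = np.asarray(h, dtype=float)
    v = np.asarray(v, dtype=float)
    hr = h / model.h0 if model.h0 > 0 else np.where(h <= 1e-12, 0.0, np.inf)
    vr = v / model.v0 if model.v0 > 0 else np.where(v <= 1e-12, 0.0, np.inf)
    return model.n_h * hr + model.n_v * vr


def dd_decide(model: DDSIMCAModel, spectra: SpectrumSet) -> DDDecision:
    """Accept or reject each spectrum for the model's target brand.

    Accepted iff c <= c_crit (boundary inclusive). Plot coordinates are the
    standard log-transformed distance ratios.
    """
    X = _model_space(model, spectra)
    h, v = distances(model.pca, X)
    c = total_distance(model, h, v)
    hr = h / model.h0 if model.h0 > 0 else np.zeros_like(h)
    vr = v / model.v0 if model.v0 > 0 else np.zeros_like(v)
    table = pd.DataFrame(
        {
            "sample_id": spectra.metadata["sample_id"],
            "h": h,
            "v": v,
            "c": c,
            "accepted": c <= model.c_crit,
            "plot_x": np.log1p(hr),
            "plot_y": np.log1p(vr),
        }
    )
    return DDDecision(table=table, model_brand=model.brand)
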