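"""Spectral preprocessing: crop, Savitzky-Golay derivative, MSC.

The pipeline order is crop -> SG second derivative -> multiplicative scatter
correction. Cropping first keeps the noisy spectral edges out of both the
derivative filter support and the MSC reference; the derivative removes
baseline offset and tilt; MSC removes the remaining multiplicative path-length
differences against a training-mean reference. Training state (the MSC
reference) is fitted once on training spectra and reused on test spectra.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter

from .synthetic import SpectrumSet, WavelengthGrid

__all__ = [
    "PreprocessConfig",
    "MSCReference",
    "crop",
    "savgol_derivative",
    "msc_fit",
    "msc_apply",
    "preprocess_pipeline",
]


@dataclass(frozen=True)
class PreprocessConfig:
    crop_low: float = 1085.0
    crop_high: float = 1601.0
    sg_window: int = 11
    sg_polyorder: int = 2
    sg_deriv: int = 2

    def __post_init__(self) -> None:
        if self.crop_low >= self.crop_high:
            raise ValueError("crop_low must be < crop_high")
        if self.sg_window % 2 == 0 or self.sg_window <= self.sg_polyorder:
            raise ValueError("sg_window must be odd and > sg_polyorder")
        if self.sg_deriv > self.sg_polyorder:
            raise ValueError("sg_deriv must be <= sg_polyorder")


@dataclass(frozen=True)
class MSCReference:
    """Reference spectrum for multiplicative scatter correction."""

    grid: WavelengthGrid
    values: np.ndarray
    provenance: str = "training-set mean"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.shape != (len(self.grid),):
            raise ValueError("MSC reference length must match its grid")
        if not np.all(np.isfinite(v)):
            raise ValueError("MSC reference contains non-finite values")
        if float(np.var(v)) <= 0.0:
            raise ValueError("MSC reference is constant (zero variance)")


def crop(spectra: SpectrumSet, low: float, high: float) -> SpectrumSet:
    """Keep channels with low <= lambda <= high (both ends inclusive)."""
    lam = spectra.grid.values
    keep = (lam >= low) & (lam <= high)
    n_keep = int(keep.sum())
    if n_keep == 0:
        raise ValueError(f"no channels fall in [{low}, {high}] nm")
    if n_keep < 8:
        raise ValueError(
            f"only {n_keep} channels fall in [{low}, {high}] nm; need at least 8"
        )
    return spectra.with_matrix(
        WavelengthGrid(lam[keep]), spectra.absorbance[:, keep]
    )


def savgol_derivative(
    spectra: SpectrumSet, window: int, polyorder: int, deriv: int
) -> SpectrumSet:
    """Savitzky-Golay derivative with respect to wavelength in nm.

    Each spectrum is replaced by the derivative of its moving-window
    least-squares polynomial fit, scaled by the channel spacing so the result
    is a d/d(nm) derivative independent of grid density. The half-window
    channels at each end, where the filter would have to invent data, are
    dropped from the output grid.
    """
    if window % 2 == 0:
        raise ValueError("window must be odd")
    if window <= polyorder:
        raise ValueError("window must exceed polyorder")
    if deriv > polyorder:
        raise ValueError("deriv must be <= polyorder")
    n = spectra.n_channels
    if window > n:
        raise ValueError(f"window {window} exceeds channel count {n}")
    half = window // 2
    out = savgol_filter(
        spectra.absorbance,
        window_length=window,
        polyorder=polyorder,
        deriv=deriv,
        delta=spectra.grid.spacing,
        axis=1,
        mode="interp",
    )
    sl = slice(half, n - half)
    return spectra.with_matrix(
        WavelengthGrid(spectra.grid.values[sl]), out[:, sl]
    )


def msc_fit(training: SpectrumSet) -> MSCReference:
    """Channelwise mean of the training spectra as MSC reference."""
    if len(training) < 2:
        raise ValueError("MSC reference needs at least 2 training spectra")
    ref = training.absorbance.mean(axis=0)
    return MSCReference(grid=training.grid, values=ref)


def msc_apply(
    spectra: SpectrumSet, ref: MSCReference, b_tol: float = 1e-10
) -> SpectrumSet:
    """Regress each spectrum on the reference and invert the fit.

    For each spectrum x the OLS fit x = a + b*ref is computed and the
    corrected spectrum is (x - a) / b, which removes additive offsets and
    multiplicative scatter relative to the reference.
    """
    if not np.allclose(spectra.grid.values, ref.grid.values, rtol=0, atol=1e-9):
        raise ValueError("spectra grid does not match MSC reference grid")
    r = ref.values
    rc = r - r.mean()
    denom = float(rc @ rc)
    X = spectra.absorbance
    b = (X - X.mean(axis=1, keepdims=True)) @ rc / denom
    a = X.mean(axis=1) - b * r.mean()
    bad = np.abs(b) < b_tol
    if bad.any():
        ids = spectra.metadata.loc[bad, "sample_id"].tolist()
        raise ValueError(
            f"MSC slope below tolerance for sample(s) {ids[:5]}; "
            "spectra uncorrelated with the reference"
        )
    corrected = (X - a[:, None]) / b[:, None]
    return spectra.with_matrix(spectra.grid, corrected)


def preprocess_pipeline(
    spectra: SpectrumSet,
    cfg: PreprocessConfig,
    ref: MSCReference | None = None,
) -> tuple[SpectrumSet, MSCReference]:
    """crop -> SG derivative -> MSC.

    With ``ref=None`` (training mode) the MSC reference is fitted on the input
    after crop+derivative and returned; otherwise (test mode) the supplied
    training reference is applied unchanged.
    """
    out = crop(spectra, cfg.crop_low, cfg.crop_high)
    out = savgol_derivative(out, cfg.sg_window, cfg.sg_polyorder, cfg.sg_deriv)
    if ref is None:
        ref = msc_fit(out)
    out = msc_apply(out, ref)
    return out, ref
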