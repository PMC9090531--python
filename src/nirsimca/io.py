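"""File formats: the spectra CSV dialect, model JSON files, run configs.

Spectra CSV dialect (version 1): a header row
``sample_id,brand,batch_id,channel,falsified,<wl1>,<wl2>,...`` where the
wavelength column names are printed in nm with 2 decimals and must be strictly
increasing and uniformly spaced; one data row per tablet with ``falsified``
as 0/1. Absorbance values are written with 12 significant digits so a
write/read round trip is lossless at that precision.

Model JSON files carry a format/version tag plus every field needed to make
identical decisions after reload (PCA, limits, preprocessing config and MSC
reference). Floats pass through Python's repr and are bit-exact on reload.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .ddsimca import DDSIMCAModel
from .pca import PCAModel
from .preprocess import MSCReference, PreprocessConfig
from .simca import SIMCAClassModel
from .synthetic import METADATA_COLUMNS, NoiseModel, SpectrumSet, WavelengthGrid

__all__ = [
    "read_spectra",
    "write_spectra",
    "save_model",
    "load_model",
    "RunConfig",
    "load_run_config",
    "noise_model_to_dict",
    "noise_model_from_dict",
]

MODEL_FORMAT = "nirsimca.model"
MODEL_VERSION = 1


def write_spectra(spectra: SpectrumSet, path: str | Path) -> None:
    """Write a SpectrumSet in the spectra CSV dialect."""
    wl_cols = [f"{w:.2f}" for w in spectra.grid.values]
    if len(set(wl_cols)) != len(wl_cols):
        raise ValueError("grid spacing below 0.01 nm cannot be represented")
    meta = spectra.metadata.copy()
    meta["falsified"] = meta["falsified"].astype(int)
    mat = pd.DataFrame(spectra.absorbance, columns=wl_cols)
    pd.concat([meta[list(METADATA_COLUMNS)], mat], axis=1).to_csv(
        path, index=False, float_format="%.12g"
    )


def read_spectra(path: str | Path) -> SpectrumSet:
    """Read a spectra CSV dialect file, validating grid and matrix."""
    df = pd.read_csv(path, dtype={"sample_id": str, "brand": str, "batch_id": str})
    head = list(df.columns[: len(METADATA_COLUMNS)])
    if head != list(METADATA_COLUMNS):
        raise ValueError(
            f"bad spectra CSV header: expected leading columns "
            f"{list(METADATA_COLUMNS)}, found {head}"
        )
    wl_cols = list(df.columns[len(METADATA_COLUMNS):])
    if not wl_cols:
        raise ValueError("spectra CSV has no wavelength columns")
    try:
        wavelengths = np.array([float(c) for c in wl_cols])
    except ValueError as exc:
        raise ValueError(f"non-numeric wavelength column name: {exc}") from None
    if np.any(np.diff(wavelengths) <= 0):
        bad = int(np.argmax(np.diff(wavelengths) <= 0))
        raise ValueError(
            f"wavelength columns not strictly increasing near column "
            f"{wl_cols[bad]!r}"
        )
    grid = WavelengthGrid(wavelengths)
    mat = df[wl_cols]
    numeric = mat.apply(pd.to_numeric, errors="coerce")
    if numeric.isna().any().any():
        row = int(numeric.isna().any(axis=1).idxmax())
        col = numeric.columns[numeric.isna().iloc[row].to_numpy().argmax()]
        raise ValueError(f"non-numeric absorbance at row {row}, column {col!r}")
    meta = df[list(METADATA_COLUMNS)].copy()
    if meta[["sample_id", "brand", "batch_id", "channel"]].isna().any().any():
        raise ValueError("missing metadata values in spectra CSV")
    meta["falsified"] = meta["falsified"].astype(int).astype(bool)
    return SpectrumSet(grid=grid, absorbance=numeric.to_numpy(float), metadata=meta)


def _pca_to_dict(pca: PCAModel) -> dict:
    return {
        "center": pca.center.tolist(),
        "loadings": pca.loadings.tolist(),
        "component_variances": pca.component_variances.tolist(),
        "residual_variances": pca.residual_variances.tolist(),
        "n_components": pca.n_components,
        "n_training": pca.n_training,
        "total_variance": pca.total_variance,
    }


def _pca_from_dict(d: dict) -> PCAModel:
    return PCAModel(
        center=np.array(d["center"], dtype=float),
        loadings=np.array(d["loadings"], dtype=float),
        component_variances=np.array(d["component_variances"], dtype=float),
        residual_variances=np.array(d["residual_variances"], dtype=float),
        n_components=int(d["n_components"]),
        n_training=int(d["n_training"]),
        total_variance=float(d["total_variance"]),
    )


def _prep_state_to_dict(model) -> dict:
    return {
        "preprocess": asdict(model.preprocess) if model.preprocess else None,
        "msc_reference": (
            {
                "grid": model.msc_reference.grid.values.tolist(),
                "values": model.msc_reference.values.tolist(),
                "provenance": model.msc_reference.provenance,
            }
            if model.msc_reference
            else None
        ),
    }


def _prep_state_from_dict(d: dict) -> tuple[PreprocessConfig | None, MSCReference | None]:
    cfg = PreprocessConfig(**d["preprocess"]) if d["preprocess"] else None
    ref = d["msc_reference"]
    msc = (
        MSCReference(
            grid=WavelengthGrid(np.array(ref["grid"], dtype=float)),
            values=np.array(ref["values"], dtype=float),
            provenance=ref["provenance"],
        )
        if ref
        else None
    )
    return cfg, msc


def save_model(model: SIMCAClassModel | DDSIMCAModel, path: str | Path) -> None:
    """Serialize a fitted class model to a versioned JSON file."""
    payload: dict = {
        "format": MODEL_FORMAT,
        "version": MODEL_VERSION,
        "brand": model.brand,
        "pca": _pca_to_dict(model.pca),
        **_prep_state_to_dict(model),
    }
    if isinstance(model, SIMCAClassModel):
        payload["type"] = "simca"
        payload.update(
            q_limit=model.q_limit,
            t2_limit=model.t2_limit,
            confidence=model.confidence,
            prob_threshold=model.prob_threshold,
        )
    elif isinstance(model, DDSIMCAModel):
        payload["type"] = "ddsimca"
        payload.update(
            h0=model.h0,
            n_h=model.n_h,
            v0=model.v0,
            n_v=model.n_v,
            alpha=model.alpha,
            c_crit=model.c_crit,
        )
    else:
        raise TypeError(f"cannot serialize {type(model).__name__}")
    Path(path).write_text(json.dumps(payload, sort_keys=True))


def load_model(path: str | Path) -> SIMCAClassModel | DDSIMCAModel:
    """Load a model JSON file; decisions after reload are bit-identical."""
    try:
        payload = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise ValueError(f"corrupt or truncated model file {path}: {exc}") from None
    if not isinstance(payload, dict) or payload.get("format") != MODEL_FORMAT:
        raise ValueError(f"{path} is not a {MODEL_FORMAT} file")
    if payload.get("version") != MODEL_VERSION:
        raise ValueError(
            f"model version {payload.get('version')} unsupported "
            f"(expected {MODEL_VERSION})"
        )
    cfg, msc = _prep_state_from_dict(payload)
    pca = _pca_from_dict(payload["pca"])
    if payload["type"] == "simca":
        return SIMCAClassModel(
            brand=payload["brand"],
            pca=pca,
            q_limit=float(payload["q_limit"]),
            t2_limit=float(payload["t2_limit"]),
            confidence=float(payload["confidence"]),
            prob_threshold=float(payload["prob_threshold"]),
            preprocess=cfg,
            msc_reference=msc,
        )
    if payload["type"] == "ddsimca":
        return DDSIMCAModel(
            brand=payload["brand"],
            pca=pca,
            h0=float(payload["h0"]),
            n_h=int(payload["n_h"]),
            v0=float(payload["v0"]),
            n_v=int(payload["n_v"]),
            alpha=float(payload["alpha"]),
            c_crit=float(payload["c_crit"]),
            preprocess=cfg,
            msc_reference=msc,
        )
    raise ValueError(f"unknown model type {payload['type']!r}")


def noise_model_to_dict(noise: NoiseModel) -> dict:
    d = asdict(noise)
    d["edge_boundaries"] = list(noise.edge_boundaries)
    return d


def noise_model_from_dict(d: dict) -> NoiseModel:
    known = {f.name for f in fields(NoiseModel)}
    unknown = set(d) - known
    if unknown:
        raise ValueError(f"unknown noise parameters: {sorted(unknown)}")
    d = dict(d)
    if "edge_boundaries" in d:
        d["edge_boundaries"] = tuple(d["edge_boundaries"])
    return NoiseModel(**d)


@dataclass(frozen=True)
class RunConfig:
    """Validated configuration for CLI runs; unknown keys are rejected."""

    seed: int = 42
    output_dir: str = "nirsimca_out"
    model: str = "simca"  # simca | ddsimca
    ncomp: int | str = "auto"
    alpha: float = 1e-6
    confidence: float = 0.95
    prob_threshold: float = 0.8
    crop_low: float = 1085.0
    crop_high: float = 1601.0
    sg_window: int = 11
    sg_polyorder: int = 2
    sg_deriv: int = 2

    def __post_init__(self) -> None:
        if self.model not in ("simca", "ddsimca"):
            raise ValueError("model must be 'simca' or 'ddsimca'")
        self.preprocess_config()  # validates the SG/crop fields

    def preprocess_config(self) -> PreprocessConfig:
        return PreprocessConfig(
            crop_low=self.crop_low,
            crop_high=self.crop_high,
            sg_window=self.sg_window,
            sg_polyorder=self.sg_polyorder,
            sg_deriv=self.sg_deriv,
        )


def load_run_config(path: str | Path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError("run config must be a YAML mapping")
    known = {f.name for f in fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**raw)
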