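"""Synthetic handheld-NIR tablet spectra.

Generates absorbance spectra with the statistical structure that derivative +
scatter-correction preprocessing and one-class PCA modelling assume: each
product brand is a sum of broad Gaussian overtone/combination bands (API bands
shared within a formulation family, excipient bands unique per brand), on top
of which tablet-to-tablet multiplicative scatter, additive offsets, baseline
tilt, a shared per-batch amplitude perturbation, and channel noise (larger at
the noisy spectral edges) are applied.

Falsified tablets carry no API bands at all: their signal comes from filler
bands at centers disjoint from every genuine API band, mimicking fakes that
contain excipient-like material but none of the declared active ingredients.

The default sampling design reproduces the field study layout this package
targets: eight product entries (six DP/SP brands plus a licit and an illicit
lot of the same sulfadoxine-pyrimethamine brand), 23 batches, ten tablets per
batch, 230 spectra, with the two illicit batches and one licit
dihydroartemisinin-piperaquine batch falsified.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "WavelengthGrid",
    "BandModel",
    "ProductRecipe",
    "DesignEntry",
    "SamplingDesign",
    "NoiseModel",
    "SpectrumSet",
    "default_recipe_library",
    "falsified_counterpart",
    "default_study_design",
    "simulate",
]

METADATA_COLUMNS = ("sample_id", "brand", "batch_id", "channel", "falsified")

#: filler bands used by every falsified recipe: centers are disjoint from all
#: genuine API band centers (>= 3.5 sigma away from the weakest API band of
#: each family so a missing API band is never masked by a filler tail).
FILLER_BANDS = (
    ("filler", 1105.0, 28.0, 0.40),
    ("filler", 1315.0, 30.0, 0.45),
    ("filler", 1670.0, 20.0, 0.30),
)


@dataclass(frozen=True)
class WavelengthGrid:
    """Strictly increasing, uniformly spaced wavelength axis in nm."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.ndim != 1 or v.size < 32:
            raise ValueError("wavelength grid needs at least 32 channels")
        d = np.diff(v)
        if np.any(d <= 0):
            raise ValueError("wavelength grid must be strictly increasing")
        # tolerate jitter at the 0.01 nm print resolution of the CSV dialect
        if not np.allclose(d, d.mean(), rtol=0, atol=0.011):
            raise ValueError("wavelength grid must be uniformly spaced")

    @property
    def spacing(self) -> float:
        return float((self.values[-1] - self.values[0]) / (self.values.size - 1))

    def __len__(self) -> int:
        return int(self.values.size)

    @classmethod
    def default(cls) -> "WavelengthGrid":
        """228 channels over 900-1700 nm (handheld dispersive NIR range)."""
        return cls(np.linspace(900.0, 1700.0, 228))


@dataclass(frozen=True)
class BandModel:
    """Gaussian absorption band: amplitude * exp(-(lam-center)^2 / (2 width^2))."""

    center: float
    width: float
    amplitude: float

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError("band width must be positive")
        if self.amplitude < 0:
            raise ValueError("band amplitude must be non-negative")

    def profile(self, lam: np.ndarray) -> np.ndarray:
        z = (np.asarray(lam, dtype=float) - self.center) / self.width
        return self.amplitude * np.exp(-0.5 * z * z)


@dataclass(frozen=True)
class ProductRecipe:
    brand_name: str
    api_bands: tuple[BandModel, ...]
    excipient_bands: tuple[BandModel, ...]
    falsified: bool = False

    @property
    def bands(self) -> tuple[BandModel, ...]:
        return tuple(self.api_bands) + tuple(self.excipient_bands)


@dataclass(frozen=True)
class DesignEntry:
    """One product row of the sampling design.

    ``falsified_batches`` flags individual batches of an otherwise licit
    recipe as falsified (a fake that infiltrated the licit supply chain);
    a recipe with ``falsified=True`` marks every batch of the entry.
    """

    recipe: ProductRecipe
    n_batches: int
    tablets_per_batch: int
    channel: str  # "licit" | "illicit"
    falsified_batches: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.n_batches < 1 or self.tablets_per_batch < 1:
            raise ValueError("n_batches and tablets_per_batch must be >= 1")
        if self.channel not in ("licit", "illicit"):
            raise ValueError("channel must be 'licit' or 'illicit'")
        if any(b < 0 or b >= self.n_batches for b in self.falsified_batches):
            raise ValueError("falsified batch index out of range")


@dataclass(frozen=True)
class SamplingDesign:
    entries: tuple[DesignEntry, ...]

    def __post_init__(self) -> None:
        names = [e.recipe.brand_name for e in self.entries]
        if len(self.entries) == 0:
            raise ValueError("sampling design must have at least one entry")
        # brand may repeat across sales channels but not within one channel
        keys = [(e.recipe.brand_name, e.channel) for e in self.entries]
        if len(set(keys)) != len(keys):
            raise ValueError(f"duplicate (brand, channel) entries in design: {names}")

    @property
    def n_batches(self) -> int:
        return sum(e.n_batches for e in self.entries)

    @property
    def n_spectra(self) -> int:
        return sum(e.n_batches * e.tablets_per_batch for e in self.entries)


@dataclass(frozen=True)
class NoiseModel:
    """Tablet/instrument noise parameters.

    multiplicative_scatter_sd   sigma of log-normal path-length factor m
    additive_offset_sd          sd of additive absorbance offset a [AU]
    baseline_slope_sd           sd of linear baseline tilt [AU/nm]
    batch_amplitude_sd          sd of the relative band-amplitude perturbation
                                shared by all tablets of a batch
    channel_noise_sd_core       per-channel noise sd inside edge_boundaries [AU]
    channel_noise_sd_edges      per-channel noise sd outside edge_boundaries [AU]
    edge_boundaries             (low, high) nm delimiting the repeatable range
    """

    multiplicative_scatter_sd: float = 0.08
    additive_offset_sd: float = 0.01
    baseline_slope_sd: float = 2e-5
    batch_amplitude_sd: float = 0.02
    channel_noise_sd_core: float = 8e-4
    channel_noise_sd_edges: float = 4e-3
    edge_boundaries: tuple[float, float] = (1085.0, 1601.0)

    def __post_init__(self) -> None:
        for name in (
            "multiplicative_scatter_sd",
            "additive_offset_sd",
            "baseline_slope_sd",
            "batch_amplitude_sd",
            "channel_noise_sd_core",
            "channel_noise_sd_edges",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.channel_noise_sd_edges < self.channel_noise_sd_core:
            raise ValueError("edge channel noise must be >= core channel noise")

    @classmethod
    def zero(cls) -> "NoiseModel":
        return cls(0.0, 0.0, 0.0, 0.0, 0.0, 0.0)


@dataclass
class SpectrumSet:
    """Wavelength grid + absorbance matrix + per-sample metadata.

    The universal currency between pipeline stages. ``metadata`` holds one row
    per spectrum with columns sample_id, brand, batch_id, channel, falsified.
    """

    grid: WavelengthGrid
    absorbance: np.ndarray
    metadata: pd.DataFrame

    def __post_init__(self) -> None:
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        if self.absorbance.ndim != 2:
            raise ValueError("absorbance must be a 2-D matrix")
        if self.absorbance.shape[1] != len(self.grid):
            raise ValueError(
                f"absorbance has {self.absorbance.shape[1]} columns but grid "
                f"has {len(self.grid)} channels"
            )
        if not np.all(np.isfinite(self.absorbance)):
            raise ValueError("absorbance contains non-finite values")
        missing = [c for c in METADATA_COLUMNS if c not in self.metadata.columns]
        if missing:
            raise ValueError(f"metadata missing columns: {missing}")
        if len(self.metadata) != self.absorbance.shape[0]:
            raise ValueError("metadata row count does not match absorbance")
        ids = self.metadata["sample_id"]
        if ids.duplicated().any():
            dup = ids[ids.duplicated()].iloc[0]
            raise ValueError(f"duplicate sample_id {dup!r}")
        self.metadata = self.metadata.reset_index(drop=True)

    def __len__(self) -> int:
        return self.absorbance.shape[0]

    @property
    def n_channels(self) -> int:
        return len(self.grid)

    def subset(self, mask) -> "SpectrumSet":
        """Row subset by boolean mask or integer positions (metadata travels)."""
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask.astype(int)
        return SpectrumSet(
            grid=self.grid,
            absorbance=self.absorbance[idx],
            metadata=self.metadata.iloc[idx].reset_index(drop=True),
        )

    def for_brand(self, brand: str) -> "SpectrumSet":
        return self.subset((self.metadata["brand"] == brand).to_numpy())

    def by_sample_ids(self, ids) -> "SpectrumSet":
        order = {s: i for i, s in enumerate(self.metadata["sample_id"])}
        missing = [s for s in ids if s not in order]
        if missing:
            raise KeyError(f"unknown sample ids: {missing[:3]}")
        return self.subset(np.array([order[s] for s in ids], dtype=int))

    def with_matrix(self, grid: WavelengthGrid, matrix: np.ndarray) -> "SpectrumSet":
        return SpectrumSet(grid=grid, absorbance=matrix, metadata=self.metadata.copy())


def default_recipe_library() -> dict[str, ProductRecipe]:
    """Band recipes for the eight studied brands.

    The three DP (dihydroartemisinin-piperaquine) brands share one API band
    triplet and the five SP (sulfadoxine-pyrimethamine) brands another; each
    brand adds its own excipient doublet, so brands within a family separate
    through excipient structure exactly as real formulations do.
    """
    dp_api = (
        BandModel(1160.0, 18.0, 0.45),
        BandModel(1395.0, 22.0, 0.60),
        BandModel(1520.0, 20.0, 0.35),
    )
    sp_api = (
        BandModel(1130.0, 20.0, 0.50),
        BandModel(1340.0, 24.0, 0.55),
        BandModel(1560.0, 18.0, 0.30),
    )
    excipients = {
        "Duo-Cotecxin": ((1210.0, 25.0, 0.30), (1470.0, 20.0, 0.25)),
        "Ridmal": ((1245.0, 22.0, 0.28), (1435.0, 26.0, 0.22)),
        "Malacur": ((1190.0, 20.0, 0.26), (1500.0, 24.0, 0.20)),
        "Maloxine": ((1225.0, 24.0, 0.32), (1455.0, 22.0, 0.24)),
        "Combimal": ((1260.0, 20.0, 0.27), (1415.0, 25.0, 0.21)),
        "Laridox": ((1175.0, 23.0, 0.25), (1530.0, 21.0, 0.23)),
        "Fansidar": ((1290.0, 22.0, 0.30), (1485.0, 23.0, 0.26)),
    }
    dp_brands = ("Duo-Cotecxin", "Ridmal", "Malacur")
    library = {}
    for brand, exc in excipients.items():
        api = dp_api if brand in dp_brands else sp_api
        library[brand] = ProductRecipe(
            brand_name=brand,
            api_bands=api,
            excipient_bands=tuple(BandModel(*e) for e in exc),
        )
    return library


def falsified_counterpart(recipe: ProductRecipe) -> ProductRecipe:
    """Fake tablet sold under the same brand name: API bands replaced by
    filler bands at disjoint centers, brand excipients absent."""
    if recipe.falsified:
        return recipe
    fillers = tuple(BandModel(c, w, a) for _, c, w, a in FILLER_BANDS)
    api_centers = {b.center for b in recipe.api_bands}
    if api_centers & {b.center for b in fillers}:
        raise ValueError("filler band centers collide with API band centers")
    return replace(recipe, api_bands=fillers, excipient_bands=(), falsified=True)


def default_study_design() -> SamplingDesign:
    """The field-study sampling layout: 8 entries, 23 batches, 230 spectra.

    Six DP/SP brands from licit drugstores (batch counts 6,2,2,5,2,2,2),
    plus two illicit street-vendor Maloxine batches (falsified), and one of
    the six licit Duo-Cotecxin batches falsified (a fake that reached the
    licit supply chain). Ten tablets per batch throughout.
    """
    lib = default_recipe_library()
    mk = DesignEntry
    entries = (
        mk(lib["Duo-Cotecxin"], 6, 10, "licit", falsified_batches=(5,)),
        mk(lib["Ridmal"], 2, 10, "licit"),
        mk(lib["Malacur"], 2, 10, "licit"),
        mk(lib["Maloxine"], 5, 10, "licit"),
        mk(falsified_counterpart(lib["Maloxine"]), 2, 10, "illicit"),
        mk(lib["Combimal"], 2, 10, "licit"),
        mk(lib["Laridox"], 2, 10, "licit"),
        mk(lib["Fansidar"], 2, 10, "licit"),
    )
    return SamplingDesign(entries)


def _entry_key(entry: DesignEntry) -> int:
    # stable per-(brand, channel) stream key: adding or reordering entries
    # does not perturb the draws of other entries
    return zlib.crc32(f"{entry.recipe.brand_name}|{entry.channel}".encode())


def simulate(
    design: SamplingDesign,
    noise: NoiseModel,
    grid: WavelengthGrid,
    seed: int,
) -> SpectrumSet:
    """Draw one spectrum per tablet of the design.

    Per tablet: absorbance(lam) = m * [sum_bands (1+delta_batch) * G_band(lam)
    + slope * (lam - lam_mid)] + a + eps(lam), with m log-normal (median 1),
    a and slope normal, delta_batch shared within a batch, and eps per-channel
    Gaussian with a larger sd outside ``noise.edge_boundaries``.

    Identical (design, noise, grid, seed) give bit-identical output; each
    batch and tablet has its own counter-based substream.
    """
    lam = grid.values
    lam_mid = float(lam.mean())
    lo, hi = noise.edge_boundaries
    channel_sd = np.where(
        (lam >= lo) & (lam <= hi),
        noise.channel_noise_sd_core,
        noise.channel_noise_sd_edges,
    )
    rows: list[np.ndarray] = []
    meta: list[dict] = []
    for entry in design.entries:
        key = _entry_key(entry)
        for b in range(entry.n_batches):
            batch_falsified = entry.recipe.falsified or b in entry.falsified_batches
            recipe = (
                falsified_counterpart(entry.recipe)
                if batch_falsified
                else entry.recipe
            )
            for band in recipe.bands:
                if not (lam[0] <= band.center <= lam[-1]):
                    raise ValueError(
                        f"band center {band.center} nm of {recipe.brand_name!r} "
                        f"falls outside the grid {lam[0]:.1f}-{lam[-1]:.1f} nm"
                    )
            rng_batch = np.random.default_rng(
                np.random.SeedSequence([seed, key, b, 0xB])
            )
            delta = rng_batch.normal(0.0, noise.batch_amplitude_sd)
            clean = (1.0 + delta) * sum(
                (band.profile(lam) for band in recipe.bands),
                start=np.zeros_like(lam),
            )
            batch_id = f"{entry.recipe.brand_name}_{entry.channel}_b{b:02d}"
            for t in range(entry.tablets_per_batch):
                rng = np.random.default_rng(
                    np.random.SeedSequence([seed, key, b, t, 0x7])
                )
                m = float(np.exp(rng.normal(0.0, noise.multiplicative_scatter_sd)))
                a = float(rng.normal(0.0, noise.additive_offset_sd))
                slope = float(rng.normal(0.0, noise.baseline_slope_sd))
                eps = rng.standard_normal(lam.size) * channel_sd
                rows.append(m * (clean + slope * (lam - lam_mid)) + a + eps)
                meta.append(
                    {
                        "sample_id": f"{batch_id}_t{t:02d}",
                        "brand": entry.recipe.brand_name,
                        "batch_id": batch_id,
                        "channel": entry.channel,
                        "falsified": bool(batch_falsified),
                    }
                )
    return SpectrumSet(
        grid=grid,
        absorbance=np.vstack(rows),
        metadata=pd.DataFrame(meta, columns=list(METADATA_COLUMNS)),
    )
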