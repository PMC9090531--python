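import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from nirsimca import (
    NoiseModel,
    PreprocessConfig,
    SpectrumSet,
    WavelengthGrid,
    default_study_design,
    simulate,
)
from nirsimca.study import split_study

settings.register_profile("suite", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("suite")


def make_spectrum_set(
    matrix,
    wavelengths=None,
    brand="TestBrand",
    batch_ids=None,
    falsified=False,
) -> SpectrumSet:
    """Wrap a plain matrix as a SpectrumSet with synthetic metadata."""
    matrix = np.atleast_2d(np.asarray(matrix, dtype=float))
    n, p = matrix.shape
    if wavelengths is None:
        wavelengths = np.linspace(900.0, 1700.0, p)
    if batch_ids is None:
        batch_ids = [f"{brand}_b00"] * n
    if np.isscalar(falsified):
        falsified = [bool(falsified)] * n
    meta = pd.DataFrame(
        {
            "sample_id": [f"{brand}_s{i:04d}" for i in range(n)],
            "brand": brand,
            "batch_id": batch_ids,
            "channel": "licit",
            "falsified": falsified,
        }
    )
    return SpectrumSet(grid=WavelengthGrid(wavelengths), absorbance=matrix, metadata=meta)


@pytest.fixture(scope="session")
def study_data() -> SpectrumSet:
    """The default 230-spectrum synthetic study, seed 42."""
    return simulate(
        default_study_design(), NoiseModel(), WavelengthGrid.default(), seed=42
    )


@pytest.fixture(scope="session")
def study_split(study_data):
    return split_study(study_data, PreprocessConfig())
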