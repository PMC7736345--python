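import numpy as np
import pytest

from gisthsi.cube_io import HyperspectralCube, instrument_grid
from gisthsi.pipeline_eval import PipelineConfig, SpecimenRecord, evaluate_cohort
from gisthsi.synthetic_data import SpecimenConfig, make_cohort


@pytest.fixture(scope="session")
def grid215() -> np.ndarray:
    return instrument_grid()


@pytest.fixture()
def small_cube() -> HyperspectralCube:
    """4x5 reflectance cube on the full instrument grid, deterministic."""
    rng = np.random.default_rng(42)
    wl = instrument_grid()
    values = rng.uniform(0.2, 0.6, size=(4, 5, wl.size))
    return HyperspectralCube(values, wl, {"calibrated": True,
                                          "domain": "reflectance"})


def tiny_specimen_config(**overrides) -> SpecimenConfig:
    """Desk-scale-down config usable on a 32x32 grid (thin boundary, 4px boxes)."""
    defaults = dict(shape=(32, 32), box_size=4, boundary_thickness_px=1.0,
                    lesion_axes_range=(16.0, 22.0))
    defaults.update(overrides)
    return SpecimenConfig(**defaults)


@pytest.fixture(scope="session")
def small_cohort():
    cfg = SpecimenConfig(shape=(32, 32), box_size=4, boundary_thickness_px=1.0)
    return make_cohort(n=4, config=cfg, seed=11, n_gist_only=1)


@pytest.fixture(scope="session")
def small_records(small_cohort):
    return [SpecimenRecord.from_synthetic(s) for s in small_cohort]


@pytest.fixture(scope="session")
def small_result(small_records):
    """One small end-to-end evaluation shared by the pipeline tests."""
    return evaluate_cohort(small_records, PipelineConfig())
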