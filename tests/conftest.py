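import numpy as np
import pytest

from parkzoning.catalog import default_catalog
from parkzoning.pipeline import load_config, run_pipeline
from parkzoning.raster import CORE, GENERAL, LandUseRaster, ZoneMask


@pytest.fixture(scope="session")
def catalog():
    return default_catalog()


@pytest.fixture(scope="session")
def small_results():
    """One fitted synthetic run shared by the integration-level tests."""
    cfg = load_config({"synthetic": {"n_rows": 140, "n_cols": 140}, "seed": 7})
    return run_pipeline(cfg)


def make_core_scene(values: np.ndarray, cell_size: float = 100.0):
    """Wrap a class-code array as (raster, all-CORE mask)."""
    values = np.asarray(values, dtype=np.int64)
    raster = LandUseRaster(values, cell_size)
    mask = ZoneMask(np.full(values.shape, CORE, dtype=np.int64), cell_size)
    return raster, mask


def make_general_scene(values: np.ndarray, cell_size: float = 100.0):
    values = np.asarray(values, dtype=np.int64)
    raster = LandUseRaster(values, cell_size)
    mask = ZoneMask(np.full(values.shape, GENERAL, dtype=np.int64), cell_size)
    return raster, mask
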