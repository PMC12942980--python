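import numpy as np
import pytest

from tickclim import hexgrid, hlz, records_qc, synthetic

WORLD_SEED = 7


@pytest.fixture(scope="session")
def world():
    """One synthetic study system shared by the whole suite."""
    return synthetic.make_world(seed=WORLD_SEED)


@pytest.fixture(scope="session")
def clean_annotated(world):
    """QC'd records annotated with climate triple and HLZ id."""
    qc = records_qc.run_qc(world.occurrences, land=world.land, min_records=200)
    base = world.climate[world.slices[0]]
    rec = hlz.extract_climate(qc.clean, base["monthly_temp"], base["precip"])
    return rec


@pytest.fixture(scope="session")
def hex_grid(world):
    return hexgrid.build_grid(world.land, circumradius_km=60.0)


@pytest.fixture(scope="session")
def baseline_hlz(world):
    base = world.climate[world.slices[0]]
    return hlz.classify_raster(base["monthly_temp"], base["precip"])


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
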