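import numpy as np
import pytest

from dvvrisk.grids import GridSpec, MonthlyClimateGrid
from dvvrisk.synthetic import ClimatologyParams, generate_climatology


@pytest.fixture(scope="session")
def coarse_grid() -> GridSpec:
    """1-degree European grid used for raster-level tests."""
    return GridSpec(resolution=1.0)


@pytest.fixture(scope="session")
def quiet_params() -> ClimatologyParams:
    """Noise-free climatology parameters (deterministic closed form)."""
    return ClimatologyParams(noise_sd=0.0, anomaly_sd=0.0)


@pytest.fixture(scope="session")
def quiet_climatology(coarse_grid, quiet_params) -> MonthlyClimateGrid:
    return generate_climatology(coarse_grid, quiet_params)


def constant_grid(spec: GridSpec, monthly_values) -> MonthlyClimateGrid:
    """Grid whose every cell carries the given 12 monthly means."""
    t = np.asarray(monthly_values, dtype=float)
    return MonthlyClimateGrid(
        grid=spec, tmean=np.broadcast_to(t[:, None, None], (12, spec.nlat, spec.nlon)).copy()
    )
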