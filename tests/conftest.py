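import pytest

from dlamino.profiles_io import ModelConstants, StationMetadata
from dlamino.racemization import default_calibration


@pytest.fixture(scope="session")
def constants():
    return ModelConstants()


@pytest.fixture(scope="session")
def calib():
    return default_calibration()


@pytest.fixture(scope="session")
def cold_station():
    """SO241-46-style metadata: 10 m core, 2.10 mm/yr, 8.83 degC at base."""
    return StationMetadata(
        station_id="SO241-46",
        latitude=27.7069,
        longitude=-111.2275,
        water_depth=664.0,
        core_recovery=1000.0,
        sedimentation_rate=2.10,
        temp_deepest=8.83,
        temp_gradient=0.13,
        location_type="Marine, OMZ",
    )


@pytest.fixture(scope="session")
def hot_station():
    """SO241-58-style metadata: ~5 m core, 0.79 mm/yr, 65.51 degC at base."""
    return StationMetadata(
        station_id="SO241-58",
        latitude=27.4081,
        longitude=-111.3896,
        water_depth=1845.0,
        core_recovery=498.0,
        sedimentation_rate=0.79,
        temp_deepest=65.51,
        temp_gradient=9.86,
        location_type="Hydrothermal",
    )
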