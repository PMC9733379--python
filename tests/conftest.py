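import numpy as np
import pytest

from uavcanopy.pipeline import PipelineConfig, run_pipeline
from uavcanopy.synthetic_field import FieldConfig, generate_field


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def field_config():
    # Moderate density keeps the session fixture fast while preserving the
    # full 32-plot / 128-quadrat layout.
    return FieldConfig(
        seed=1,
        points_per_plant=80,
        ground_density=25.0,
        plant_height_sd=0.01,
        stage=0.3,
        stage_spread=0.3,
    )


@pytest.fixture(scope="session")
def field(field_config):
    cloud, truth, measurements = generate_field(field_config)
    return cloud, truth, measurements


@pytest.fixture(scope="session")
def field_report(field):
    cloud, truth, measurements = field
    return run_pipeline(cloud, measurements, truth.layout, PipelineConfig())
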