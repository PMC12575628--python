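import numpy as np
import pytest

from habwatch.geo import GridTransform
from habwatch.scene_io import RadiometricMetadata, RasterField
from habwatch.synthetic_scene import BloomPatch, BloomScenario, build_truth, encode_scene


@pytest.fixture(scope="session")
def meta() -> RadiometricMetadata:
    return RadiometricMetadata()


@pytest.fixture(scope="session")
def scenario() -> BloomScenario:
    return BloomScenario(
        grid_shape=(32, 32),
        background_chla=14.4,
        patches=(BloomPatch(10, 12, 4.0, 57.1), BloomPatch(24, 24, 3.0, 30.0)),
        background_lsat=26.1,
        lsat_coupling=0.2,
        seed=7,
    )


@pytest.fixture(scope="session")
def truth(scenario):
    return build_truth(scenario)


@pytest.fixture(scope="session")
def scene(truth, scenario):
    return encode_scene(truth, scenario)


@pytest.fixture()
def random_field() -> RasterField:
    rng = np.random.default_rng(42)
    values = rng.uniform(-5, 40, size=(12, 9))
    mask = rng.random((12, 9)) > 0.2
    return RasterField(
        values=values, mask=mask, role="test",
        transform=GridTransform.north_up(1000.0, 2000.0, 30.0, 30.0),
        crs_id="EPSG:32736",
    )
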