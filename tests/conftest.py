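import numpy as np
import pytest

from coldscan import synthetic_data as sd


@pytest.fixture
def noiseless_footprint():
    """Zero-noise footprint dataset with exposed/buried/unchanged plants."""
    cfg = sd.FootprintSimConfig(
        sites_exposed=(137,), sites_buried=(520,),
        fc_planted={137: 1.25, 520: 0.80, 651: 0.87, 300: 1.0},
        noise_cv=0.0, seed=11)
    return sd.gen_footprint_dataset(cfg)


@pytest.fixture
def default_ramp():
    return sd.gen_current_ramp(sd.GatingSimConfig())


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
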