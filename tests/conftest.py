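import pytest

import synaptodetect as sd
from synaptodetect.synthetic import GeneratorParams


@pytest.fixture(scope="session")
def config():
    return sd.DetectionConfig()


@pytest.fixture(scope="session")
def family(config):
    return sd.build_template_family(config)


@pytest.fixture(scope="session")
def small_gt():
    """A small high-contrast ground-truth volume shared across tests."""
    params = GeneratorParams(amp_sigma_log=0.0)
    return sd.generate_volume((12, 128, 128), 12, params, seed=3)


@pytest.fixture(scope="session")
def small_detection(small_gt, family):
    cfg = sd.DetectionConfig(rng_seed=3)
    synapses, report = sd.detect_pipeline(small_gt.volume, cfg, family=family)
    return synapses, report
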