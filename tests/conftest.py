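from datetime import datetime

import numpy as np
import pytest

from n2osource import PipelineConfig, TrueScenario, generate_closure


@pytest.fixture
def config() -> PipelineConfig:
    return PipelineConfig()


@pytest.fixture
def noiseless_scenario() -> TrueScenario:
    return TrueScenario(flux_true=103.0, noise_conc=0.0, noise_delta=0.0,
                        source_d15a=5.0, source_d15b=-12.0, source_d18o=28.0)


@pytest.fixture
def noiseless_event(noiseless_scenario):
    return generate_closure(noiseless_scenario,
                            timestamp=datetime(2024, 5, 14, 8, 0))
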