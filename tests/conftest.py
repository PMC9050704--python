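import pytest
from hypothesis import HealthCheck, settings

from scmotormap.config import ModelConfig
from scmotormap.experiments import Model

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def cfg():
    """Stock configuration (ships pre-calibrated)."""
    return ModelConfig()


@pytest.fixture(scope="session")
def model(cfg):
    return Model(cfg)


@pytest.fixture(scope="session")
def motor_map(model):
    return model.motor_map


@pytest.fixture(scope="session")
def default_records(model):
    """Input/SC spike records for the default stimulus at T = 15 deg."""
    return model.run(model.default_spec())


@pytest.fixture(scope="session")
def default_metrics(model, default_records):
    return model.analyze(model.default_spec(), records=default_records)
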