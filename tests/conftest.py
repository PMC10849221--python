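import numpy as np
import pytest
from hypothesis import HealthCheck, settings

# Derandomized hypothesis profile so runs are reproducible everywhere.
settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_dataset():
    """A small synthetic dataset shared by pipeline-level tests."""
    from ribopred.synth import SynthConfig, generate_dataset

    config = SynthConfig(n_operons=120, seed=42)
    data = generate_dataset(config)
    data["config"] = config
    return data


@pytest.fixture(scope="session")
def small_pipeline(small_dataset):
    from ribopred.pipeline import run_pipeline

    return run_pipeline(
        small_dataset["records"],
        small_dataset["pa_table"],
        small_dataset["mrna_table"],
        small_dataset["grouping"],
        seed=42,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
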