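import pytest
from hypothesis import HealthCheck, settings

from il10pep.synthetic_data import GeneratorConfig, generate, make_benchmark

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def benchmark():
    """The standard synthetic benchmark (394 pos / 848 neg, planted motifs)."""
    return make_benchmark(seed=0)


@pytest.fixture(scope="session")
def small_ds():
    """A quick 60+60 biased dataset for cheap model tests."""
    ds, manifest = generate(GeneratorConfig(n_pos=60, n_neg=60, seed=11))
    return ds, manifest
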