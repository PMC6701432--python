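import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def benchmark_run():
    """One shared end-to-end benchmark run (suite generation, classifier
    training, segmentation of the test scenes)."""
    from fbseg.cli import run_benchmark

    return run_benchmark(benchmark_seed=7, train_seed=0)
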