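import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite", deadline=None, derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")

from asmpipe import simdata  # noqa: E402


@pytest.fixture(scope="session")
def small_genome():
    """2 x 50 kb diploid at 0.4% heterozygosity."""
    return simdata.simulate_diploid(2, 50_000, 0.004, seed=42)


@pytest.fixture(scope="session")
def fragmented(small_genome):
    """The small genome broken into 4 contigs/chromosome with 200-500 bp
    planted end overlaps."""
    return simdata.fragment_assembly(small_genome, 3, (200, 500), seed=43)
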