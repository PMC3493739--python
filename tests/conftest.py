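import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def target_fixture():
    from smallrna.synthetic_data import build_target_fixture

    return build_target_fixture(seed=11)


@pytest.fixture(scope="session")
def toy_genome():
    from smallrna.synthetic_data import generate_genome

    return generate_genome(n_chrom=1, length=10_000, seed=7)
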