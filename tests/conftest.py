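import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=60,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def toy_genome_genes():
    """Small deterministic genome with planted genes, shared across tests."""
    from radmut.synthetic_data import GeneratorConfig, gen_genome_and_genes

    config = GeneratorConfig(seed=42, genome_length=60_000, n_genes=20)
    return gen_genome_and_genes(config)
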