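import pytest

from venomscan import GeneratorConfig, generate_transcriptome, run_pipeline


@pytest.fixture(scope="session")
def default_config():
    return GeneratorConfig(seed=1)


@pytest.fixture(scope="session")
def dataset(default_config):
    """(contigs, annotations, truth) for the default 300-contig run."""
    return generate_transcriptome(default_config)


@pytest.fixture(scope="session")
def pipeline_result(default_config):
    """One full end-to-end run shared across tests."""
    return run_pipeline(default_config)
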