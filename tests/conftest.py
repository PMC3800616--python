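import pytest
from hypothesis import settings

settings.register_profile("suite", derandomize=True, deadline=None)
settings.load_profile("suite")

from exoseq.synth import SimConfig, generate_reads, generate_reference


@pytest.fixture(scope="session")
def sim_small():
    """A small deterministic simulated dataset shared across tests."""
    config = SimConfig(seed=11, read_count=400)
    references = generate_reference(config)
    reads, truth = generate_reads(config, references)
    return config, references, reads, truth
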