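import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import kmerlex as kx

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_genome():
    """Deterministic 5 kb order-0 genome, balanced composition."""
    return kx.markov_genome(np.array([0.25] * 4), order=0, length=5000, seed=7)


@pytest.fixture(scope="session")
def fasta_file(tmp_path_factory, small_genome):
    path = tmp_path_factory.mktemp("fasta") / "small.fa"
    kx.write_fasta(small_genome, path)
    return path
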