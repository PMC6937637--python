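import numpy as np
import pytest

from fcgrseq.benchmarks import prepare_features
from fcgrseq.config import PipelineConfig
from fcgrseq.synth import make_benchmark


@pytest.fixture(scope="session")
def config():
    return PipelineConfig()


@pytest.fixture(scope="session")
def bench20():
    """Reference benchmark: 6 species x 12 genomes x 20 kb, defaults."""
    return make_benchmark(seed=101)


@pytest.fixture(scope="session")
def feats20(bench20, config):
    return prepare_features(bench20.corpus, config)


@pytest.fixture(scope="session")
def tree_bench():
    """Compact 4-species corpus for tree/monophyly checks."""
    return make_benchmark(n_species=4, genomes_per_species=3, seed=303)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(42)
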