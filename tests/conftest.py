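import numpy as np
import pytest

from rehabminer.corpus_io import RelationInstance
from rehabminer.synth_corpus import GeneratorConfig, generate_corpus


@pytest.fixture(scope="session")
def small_corpus():
    """120 noiseless synthetic records with gold annotations."""
    return generate_corpus(GeneratorConfig(n_records=120, seed=11))


@pytest.fixture(scope="session")
def table3_instances():
    """Instances with the annotated-corpus class counts 901/3602/497/235."""
    counts = {"DS": 901, "SFD": 3602, "NSFD": 497, "UKN": 235}
    out = []
    for label, n in counts.items():
        for i in range(n):
            out.append(
                RelationInstance(label, "e1", "e2", f"# token{i} *")
            )
    return out


@pytest.fixture
def rng():
    return np.random.default_rng(42)
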