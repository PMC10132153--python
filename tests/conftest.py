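import numpy as np
import pytest

from transreg import SimulationConfig, generate_dataset
from transreg.simulate import GROUP4_CONSENSUS


@pytest.fixture(scope="session")
def small_dataset():
    """Mixed-group synthetic dataset shared by classification tests."""
    cfg = SimulationConfig(features_per_group={1: 60, 4: 60, 13: 60, 14: 60},
                           seed=11)
    return generate_dataset(cfg)


@pytest.fixture(scope="session")
def planted_sequences():
    """20 random 100-mers each carrying the exact planted 20-mer."""
    rng = np.random.default_rng(5)
    seqs = []
    for _ in range(20):
        s = "".join(rng.choice(list("ACGT"), size=100))
        j = int(rng.integers(0, 100 - len(GROUP4_CONSENSUS) + 1))
        seqs.append(s[:j] + GROUP4_CONSENSUS + s[j + len(GROUP4_CONSENSUS):])
    return seqs
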