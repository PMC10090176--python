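import numpy as np
import pytest

from neotadkit.sv_genome import GenomeModel, InsertionalDuplication
from neotadkit.synthetic import make_toy_case


@pytest.fixture(scope="session")
def toy_case():
    return make_toy_case(seed=0)


@pytest.fixture()
def tiny_genome():
    """Two short chromosomes with fixed sequences for per-base oracles."""
    rng = np.random.default_rng(7)
    seqs = {
        "acc": "".join(rng.choice(list("ACGT"), size=100)),
        "don": "".join(rng.choice(list("ACGT"), size=80)),
    }
    return GenomeModel.from_sequences(seqs)


@pytest.fixture()
def tiny_sv():
    return InsertionalDuplication("don", 20, 35, "acc", 60)
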