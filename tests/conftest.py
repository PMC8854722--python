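import numpy as np
import pytest

from cerna_forge.io_formats import SequenceSet
from cerna_forge.synthetic_data import ScenarioConfig, make_scenario

RNA = "ACGU"
DNA = "ACGT"


@pytest.fixture(scope="session")
def small_scenario():
    """A reduced planted scenario shared by unit tests (seed-fixed)."""
    cfg = ScenarioConfig(
        seed=11,
        n_mirnas=8,
        n_mrnas=40,
        n_lncrnas=6,
        n_circrnas=4,
        n_chromosomes=2,
    )
    return make_scenario(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(123)


def random_rna(rng, n):
    return "".join(RNA[i] for i in rng.integers(0, 4, n))


def random_dna(rng, n):
    return "".join(DNA[i] for i in rng.integers(0, 4, n))


def seqset(alphabet, **records):
    out = SequenceSet(alphabet=alphabet)
    for name, seq in records.items():
        out.add(name, seq)
    return out
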