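import numpy as np
import pytest

from mirthermo import MiRNA, UtrRecord
from mirthermo.thermo import ThermoEngineConfig, ToyEngine


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def example_mirna():
    # let-7-like 22-mer; seed positions 2-8 = GGAAUGU
    return MiRNA(id="mir-ex", sequence="UGGAAUGUAAAGAAGUAUGUAU")


@pytest.fixture
def toy_engine():
    return ToyEngine()


@pytest.fixture
def au_engine():
    return ToyEngine(unpaired_mode="au")


@pytest.fixture
def config():
    return ThermoEngineConfig()


def random_mirna_seq(rng, length=22):
    return "".join(rng.choice(list("ACGU"), size=length))


def random_rna(rng, length):
    return "".join(rng.choice(list("ACGU"), size=length))
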