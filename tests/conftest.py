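import pytest

from cleavemap import datasets


@pytest.fixture(scope="session")
def ex4c():
    """The 40-residue exendin4-cysteine parent peptide."""
    return datasets.ex4c()


@pytest.fixture(scope="session")
def tsme1():
    return datasets.analog_sequences()["TSME-1"]
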