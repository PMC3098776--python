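import numpy as np
import pytest

from fernbz.gene_order import load_catalog


@pytest.fixture(scope="session")
def catalog():
    return load_catalog()


@pytest.fixture()
def rng():
    return np.random.default_rng(20110413)


def random_dna(rng, n: int, gc: float = 0.5) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=n, p=p))
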