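import numpy as np
import pytest

from csvarc import simdata as sd


@pytest.fixture(scope="session")
def ref300k():
    """A 300-kb single-chromosome reference without a centromere."""
    return sd.make_reference(1, [300_000])


@pytest.fixture(scope="session")
def cen_ref():
    """A 1-Mb chromosome with a 400-kb annotated alpha-satellite array."""
    return sd.make_reference(2, [1_000_000], centromere_spec={"chr1": (400_000, 4, 0.8)})


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_seq(rng, n):
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=n)])
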