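import numpy as np
import pytest

from neocoda.composition import closure
from neocoda.io_tables import AbundanceTable, SampleMetadata


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def small_table():
    """3 taxa x 4 samples with one zero cell."""
    return AbundanceTable(
        ["Enterococcus", "Escherichia", "Bacteroides"],
        ["s1", "s2", "s3", "s4"],
        np.array([[10.0, 5.0, 0.0, 2.0],
                  [0.0, 5.0, 20.0, 3.0],
                  [5.0, 10.0, 5.0, 5.0]]),
    )


@pytest.fixture
def small_meta():
    return [
        SampleMetadata("s1", "A", "CHD", visit=1, delivery="vaginal", spo2=88.0),
        SampleMetadata("s2", "A", "CHD", visit=2, delivery="vaginal", spo2=88.0),
        SampleMetadata("s3", "B", "CHD", visit=1, delivery="cesarean", spo2=95.0),
        SampleMetadata("s4", "C", "HC", visit=1, delivery="vaginal"),
    ]


def random_composition(rng, n, d):
    """Strictly positive random compositions (Dirichlet draws)."""
    return closure(rng.dirichlet(np.ones(d) * 2.0, size=n) + 1e-9)
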