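import pytest

from sbirt.genome import Genome, Instance


@pytest.fixture
def unsigned_example() -> Instance:
    """Worked unsigned instance with two soft breakpoints (softly connected),
    one overcharged and one undercharged breakpoint (b1 = 4)."""
    source = Genome((0, 3, 2, 1, 4, 5, 6, 7), (4, 0, 3, 0, 5, 2, 0))
    return Instance(source, (1, 3, 0, 3, 1, 2, 4))


@pytest.fixture
def signed_example() -> Instance:
    """Worked signed instance with b2 = 4 and a known 3-operation solution."""
    source = Genome((0, -2, 1, -3, 4), (5, 3, 7, 2), signed=True)
    return Instance(source, (4, 4, 8, 1))
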