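import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")

from signetbench.network import Network, Node, Reaction


@pytest.fixture
def toy_network() -> Network:
    """A & !B => C with an input driving A; B basal off."""
    return Network(
        name="toy",
        phenotype="test",
        nodes=[Node("A"), Node("B"), Node("C")],
        reactions=[
            Reaction("=> A", weight=1.0),
            Reaction("=> B", weight=0.0),
            Reaction("A & !B => C"),
        ],
    )


@pytest.fixture
def chain_network() -> Network:
    """Linear stimulus -> receptor -> gene chain (all activating)."""
    return Network(
        name="chain",
        nodes=[Node("ISO"), Node("ADRB1"), Node("ANP")],
        reactions=[
            Reaction("=> ISO", weight=0.0),
            Reaction("ISO => ADRB1"),
            Reaction("ADRB1 => ANP"),
        ],
    )
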