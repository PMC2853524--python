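import pytest

from switchfba.model import MetabolicModel, Metabolite, Reaction
from switchfba.synth import SyntheticSpec, make_bundle


@pytest.fixture
def chain_model():
    """∅ ↔ A (uptake ≤ 10), A → B, biomass consumes 2 B: μ* = 5."""
    return MetabolicModel(
        metabolites=[Metabolite("A"), Metabolite("B")],
        reactions=[
            Reaction("EX_A", {"A": -1}, -10, 0, kind="exchange"),
            Reaction("R1", {"A": -1, "B": 1}, 0, 1000, kind="enzymatic"),
            Reaction("BM", {"B": -2}, 0, 1000, kind="biomass"),
        ],
    )


@pytest.fixture(scope="session")
def bundle():
    """The seeded 200-gene synthetic study used across integration tests."""
    return make_bundle(SyntheticSpec(seed=1))


@pytest.fixture(scope="session")
def spec1():
    return SyntheticSpec(seed=1)
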