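import pytest

from sdpscan.seqio import AlignedFamily
from sdpscan.synthetic_data import (
    FamilySpec,
    ToyStructureSpec,
    default_polymorphic_columns,
    simulate_family,
    simulate_structure,
)


@pytest.fixture(scope="session")
def planted_family():
    """Two clades x 10 sequences, 300 columns, 5 planted polymorphic
    columns, zero noise."""
    spec = FamilySpec(
        planted_polymorphisms=default_polymorphic_columns(5, 300), seed=42
    )
    return simulate_family(spec)


@pytest.fixture(scope="session")
def toy_pocket():
    return simulate_structure(ToyStructureSpec(seed=7))


@pytest.fixture
def tiny_family():
    """Hand-written 4-sequence alignment with gaps and two classes."""
    return AlignedFamily(
        records=[
            ("a1", "MKLV-TAAGS"),
            ("a2", "MKLV-TAAGS"),
            ("b1", "MKIVWTAAGS"),
            ("b2", "MKIVWTASGS"),
        ],
        class_of={"a1": "GA3OX", "a2": "GA3OX", "b1": "GA20OX", "b2": "GA20OX"},
        clade_of={"a1": "dicot", "a2": "dicot", "b1": "monocot", "b2": "monocot"},
    )
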