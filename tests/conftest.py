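"""Shared fixtures: hand-built micro-templates and one generated fold pair."""

import pytest

from foldswitch import (
    Embedding,
    FoldTemplate,
    SecondaryElement,
    ToyFoldSpec,
    make_fold_pair,
)


@pytest.fixture(scope="session")
def planted_pair():
    """One deterministic generated fold pair with a recoverable plant."""
    return make_fold_pair(ToyFoldSpec(seed=1))


@pytest.fixture
def micro_long():
    """12-residue long fold: helix 3-10, two contacts, hand-set burial."""
    return FoldTemplate(
        name="microL",
        length=12,
        elements=(SecondaryElement("helix", 3, 10, "α1"),),
        contacts=frozenset({(3, 6), (4, 8)}),
        ref_sequence="LLLLLLLLLLLL",
        burial=("surface",) * 12,
    )


@pytest.fixture
def micro_short():
    """12-residue short fold: strand 2-5, position 4 core, else surface."""
    burial = ["surface"] * 12
    burial[3] = "core"
    return FoldTemplate(
        name="microG",
        length=12,
        elements=(SecondaryElement("strand", 2, 5, "β1"),),
        contacts=frozenset({(2, 5), (4, 8)}),
        ref_sequence="LLLLLLLLLLLL",
        burial=tuple(burial),
    )


@pytest.fixture
def full_overlap_embedding():
    """Offset-0 embedding of a 12-mer into a 12-mer."""
    return Embedding(offset=0, short_len=12, anchor=("β1", "α1"))
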