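import numpy as np
import pytest

from esdfold import (
    BasePairProbMatrix,
    FixtureSpec,
    PlantedStem,
    RnaSequence,
    build_catalog,
    make_matrix,
)


@pytest.fixture
def fig1_sequence() -> RnaSequence:
    """The 14-nt worked-example sequence used throughout the docs."""
    return RnaSequence(id="example", residues="GUGCACGACGCCGU")


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture
def two_stem_spec() -> FixtureSpec:
    """Two mutually compatible planted stems (nested), n = 24."""
    return FixtureSpec(
        n=24,
        stems=(PlantedStem(1, 24, 4, 0.8), PlantedStem(7, 18, 3, 0.5)),
        seed=7,
    )


@pytest.fixture
def two_stem_matrix(two_stem_spec) -> BasePairProbMatrix:
    matrix, _ = make_matrix(two_stem_spec)
    return matrix


@pytest.fixture
def two_stem_catalog(two_stem_matrix):
    return build_catalog(two_stem_matrix, min_len=3)


def random_sequence(n: int, rng: np.random.Generator) -> RnaSequence:
    return RnaSequence(id=f"rand{n}", residues="".join(rng.choice(list("ACGU"), n)))
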