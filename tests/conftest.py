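import numpy as np
import pytest

from silkphylo.matrix import CharacterMatrix
from silkphylo.tree import parse_newick


@pytest.fixture
def quartet_tree():
    return parse_newick("((A,B),(C,D));")


@pytest.fixture
def six_taxa():
    return [f"t{i}" for i in range(6)]


def random_matrix(rng, taxa, nchar, symbols="012", missing_p=0.0):
    syms = list(symbols)
    rows = []
    for _ in taxa:
        chars = rng.choice(syms, size=nchar)
        if missing_p:
            mask = rng.random(nchar) < missing_p
            chars = np.where(mask, "?", chars)
        rows.append("".join(chars))
    return CharacterMatrix(list(taxa), rows, "standard")


@pytest.fixture
def make_random_matrix():
    return random_matrix
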