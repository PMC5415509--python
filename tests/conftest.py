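import io

import numpy as np
import pytest

from morphotrace import CharacterMatrix, load_fixture, parse_newick


@pytest.fixture(scope="session")
def fixture_data():
    return load_fixture()


@pytest.fixture
def quartet():
    return parse_newick("((A,B),(C,D));")


def matrix_from(states: dict[str, str]) -> CharacterMatrix:
    """Build a small matrix from {taxon: state-string}."""
    rows = "\n".join(f"{k},{','.join(v)}" for k, v in states.items())
    return CharacterMatrix.from_csv(io.StringIO(rows))


def random_tree_newick(rng: np.random.Generator, labels: list[str]) -> str:
    """Random binary topology over the given labels (no branch lengths)."""
    nodes = list(labels)
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        nodes.append(f"({a},{b})")
    return nodes[0] + ";"
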