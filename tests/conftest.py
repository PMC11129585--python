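import itertools

import pytest

import evoheritage as eh


@pytest.fixture
def cherry():
    """Two tips and a stem: (a:1,b:1):1."""
    return eh.parse_newick("(a:1,b:1):1;")


@pytest.fixture
def caterpillar_stem():
    """Three tips with a stem; the stem is ancestral to all three."""
    return eh.parse_newick("((a:1,b:1):1,c:1):1;")


@pytest.fixture
def imbalanced_dated():
    """Four tips, one sister to a three-tip clade; ultrametric with stem.

    Root at 3 My; stem top at 5 My.
    """
    return eh.parse_newick("(((c:1,d:1):1,b:2):1,a:3):2;")


@pytest.fixture
def star4():
    """Symmetric four-tip star with a stem."""
    return eh.parse_newick("(a:1,b:1,c:1,d:1):2;")


def all_vertex_subsets(tree, max_size=None):
    V = sorted(tree.vertices())
    n = len(V) if max_size is None else min(max_size, len(V))
    for r in range(n + 1):
        yield from (frozenset(c) for c in itertools.combinations(V, r))
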