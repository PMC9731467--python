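import numpy as np
import pytest

from signedcomm import (
    DirectedSignedNetwork,
    GeneratorParams,
    UndirectedSignedNetwork,
    generate,
)


def make_reciprocal(arcs, a, b, s):
    arcs[(a, b)] = s
    arcs[(b, a)] = s


@pytest.fixture
def fig2_network() -> DirectedSignedNetwork:
    """Worked balance-heuristic example: one-way enmity i->j; v1-v3 attach to
    i and j with one positive and one negative reciprocal edge each, v4 with
    two positives; making {i,j} reciprocal negative closes three balanced
    triads and one unbalanced."""
    arcs = {}
    make_reciprocal(arcs, "i", "v1", 1)
    make_reciprocal(arcs, "j", "v1", -1)
    make_reciprocal(arcs, "i", "v2", -1)
    make_reciprocal(arcs, "j", "v2", 1)
    make_reciprocal(arcs, "i", "v3", 1)
    make_reciprocal(arcs, "j", "v3", -1)
    make_reciprocal(arcs, "i", "v4", 1)
    make_reciprocal(arcs, "j", "v4", 1)
    arcs[("i", "j")] = -1
    return DirectedSignedNetwork(["i", "j", "v1", "v2", "v3", "v4"], arcs)


@pytest.fixture
def two_cliques() -> UndirectedSignedNetwork:
    """Two positive 4-cliques joined by a single positive edge; the optimal
    modularity partition is the two cliques."""
    nodes = [f"a{k}" for k in range(4)] + [f"b{k}" for k in range(4)]
    edges = {}
    for grp in ("a", "b"):
        for x in range(4):
            for y in range(x + 1, 4):
                edges[(f"{grp}{x}", f"{grp}{y}")] = 1
    edges[("a0", "b0")] = 1
    return UndirectedSignedNetwork(nodes, edges)


def random_directed(seed: int, n: int = 24) -> DirectedSignedNetwork:
    """Small random signed survey-style network for property checks."""
    params = GeneratorParams(
        n_nodes=n,
        community_sizes=[n // 2, n - n // 2],
        p_pos_in=0.4,
        p_neg_in=0.08,
        p_neg_out=0.15,
        censor_prob=0.2,
        seed=seed,
    )
    return generate(params)[0]


def random_undirected(seed: int, n: int = 16) -> UndirectedSignedNetwork:
    """Random undirected signed network (arbitrary signs, no planted order)."""
    rng = np.random.default_rng(seed)
    nodes = [f"n{k}" for k in range(n)]
    edges = {}
    for a in range(n):
        for b in range(a + 1, n):
            u = rng.random()
            if u < 0.25:
                edges[(nodes[a], nodes[b])] = 1
            elif u < 0.40:
                edges[(nodes[a], nodes[b])] = -1
    return UndirectedSignedNetwork(nodes, edges)
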