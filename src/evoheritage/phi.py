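"""The central EvoHeritage recursion and headline metrics.

phi(X) sums, over every edge, the features accumulated on that edge times
the proportion of them that survives attrition to be present on at least one
member of the query set X.  The survival proportion p(v, X) is computed by a
single postorder pass:

    p(v, X) = 1                                    if v in X
            = 0                                    if v is a terminal not in X
            = 1 - prod_children(1 - p(child) * beta(child edge))  otherwise

Interior vertices may be members of X (extinct ancestors count directly).
phi_rho expresses phi in standardized units (features on one disconnected
unit-length edge) and interpolates between PD (rho -> 0) and species
richness (rho -> infinity).
"""

from __future__ import annotations

from typing import Iterable

from .conditions import (
    EvoHeritageTree,
    StandardConditions,
    build_evoheritage_tree,
    standardized_unit,
)
from .treeio import PhyloTree

__all__ = [
    "survival_proportions",
    "phi",
    "phi_rho",
    "pd",
    "species_richness",
    "evolutionary_distinctiveness",
]


def survival_proportions(etree: EvoHeritageTree, X: Iterable[str]) -> dict[str, float]:
    """p(v, X) for every vertex: proportion of v's features surviving into X."""
    tree = etree.tree
    X = tree.validate_vertex_set(X)
    beta = etree.beta
    p: dict[str, float] = {}
    for v in tree.postorder():
        if v in X:
            p[v] = 1.0
            continue
        kids = tree.children(v)
        if not kids:
            p[v] = 0.0
            continue
        prod = 1.0
        for c in kids:
            prod *= 1.0 - p[c] * beta[c]
        p[v] = 1.0 - prod
    return p


def phi(etree: EvoHeritageTree, X: Iterable[str]) -> float:
    """Total surviving features of the vertex set X (raw EvoHeritage units)."""
    p = survival_proportions(etree, X)
    alpha = etree.alpha
    return sum(alpha[e] * p[e] for e in etree.edges())


def phi_rho(
    tree: PhyloTree,
    rho: float,
    X: Iterable[str],
    lam: float = 1.0,
) -> float:
    """phi of X under standard conditions, in standardized units.

    Depends only on rho, not on lam; converges to PD(X) as rho -> 0 and to
    |X| as rho -> infinity.
    """
    cond = StandardConditions(rho=rho, lam=lam)
    etree = build_evoheritage_tree(tree, cond)
    return phi(etree, X) / standardized_unit(cond)


def _spanning_edges(tree: PhyloTree, X: frozenset[str]) -> set[str]:
    """Edges on the union of root-to-v paths for v in X (stem included)."""
    used: set[str] = set()
    for x in X:
        v: str | None = x
        while v is not None and v not in used:
            if tree.has_ancestor_edge(v):
                used.add(v)
            v = tree.parent(v)
    return used


def pd(tree: PhyloTree, X: Iterable[str]) -> float:
    """Phylogenetic diversity: summed lengths of edges connecting X to the root.

    The stem edge is included when present.  Interior vertices in X are
    handled by the same path-union rule.
    """
    X = tree.validate_vertex_set(X)
    if not X:
        raise ValueError("PD is undefined for the empty set")
    return sum(tree.length(e) for e in _spanning_edges(tree, X))


def species_richness(X: Iterable[str]) -> int:
    """Number of vertices in X (the rho -> infinity limit of phi_rho)."""
    return len(frozenset(X))


def evolutionary_distinctiveness(tree: PhyloTree, X: Iterable[str]) -> dict[str, float]:
    """Fair-proportion ED: each edge length shared evenly among its members of X.

    For each x in X, sums L(e) / (number of X-members at or below e's
    descendant vertex) over all ancestral edges e, including the stem.
    Satisfies sum_x ED(x) = PD(X).
    """
    X = tree.validate_vertex_set(X)
    if not X:
        raise ValueError("ED is undefined for the empty set")
    # count X-members at or below each vertex in one postorder pass
    count: dict[str, int] = {}
    for v in tree.postorder():
        count[v] = (1 if v in X else 0) + sum(count[c] for c in tree.children(v))
    ed = {x: 0.0 for x in X}
    for x in X:
        v: str | None = x
        while v is not None:
            if tree.has_ancestor_edge(v):
                ed[x] += tree.length(v) / count[v]
            v = tree.parent(v)
    return ed
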