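"""Derived EvoHeritage metrics: unique-phi, diff-phi, expected future-phi,
and the Crozier genetic-diversity correspondence."""

from __future__ import annotations

from typing import Iterable, Mapping

from .conditions import EvoHeritageTree
from .phi import phi

__all__ = [
    "unique_phi",
    "diff_phi",
    "expected_future_phi",
    "crozier_gd",
]


def unique_phi(etree: EvoHeritageTree, X: Iterable[str], Y: Iterable[str]) -> float:
    """Features captured by X and by none of the vertices in Y.

    Defined as phi(X u Y) - phi(Y); non-negative by monotonicity of phi.
    """
    X = etree.tree.validate_vertex_set(X)
    Y = etree.tree.validate_vertex_set(Y)
    return phi(etree, X | Y) - phi(etree, Y)


def diff_phi(etree: EvoHeritageTree, X: Iterable[str], Y: Iterable[str]) -> float:
    """Symmetric difference in features between X and Y, as a proportion of
    the features of both together (a UniFrac analogue; in [0, 1]).

    Converges to unweighted UniFrac as rho -> 0 and to 1 for disjoint tip
    sets as rho -> infinity.
    """
    X = etree.tree.validate_vertex_set(X)
    Y = etree.tree.validate_vertex_set(Y)
    total = phi(etree, X | Y)
    if total <= 0.0:
        raise ValueError("diff_phi undefined: phi(X u Y) = 0")
    return (unique_phi(etree, X, Y) + unique_phi(etree, Y, X)) / total


def expected_future_phi(
    etree: EvoHeritageTree,
    X: Iterable[str],
    eps: Mapping[str, float],
    discount_terminal_alpha: bool = False,
) -> float:
    """Expected phi(X) at a future time given per-tip extinction probabilities.

    Extinction of a tip with probability eps(v) is cast as extra expected
    feature loss on its terminal edge: beta(e) is replaced by
    beta(e) * (1 - eps(v)) on terminal edges only, and phi is computed on
    the modified tree.  With that literal substitution the terminal edge's
    own accumulation still counts in full whenever its tip is in X; set
    ``discount_terminal_alpha=True`` to scale terminal alpha by (1 - eps(v))
    as well (treating a tip's own features as lost with it).
    """
    tree = etree.tree
    X = tree.validate_vertex_set(X)
    tips = set(tree.tips())
    for v, e in eps.items():
        if v not in tips:
            raise ValueError(f"extinction probability given for non-terminal vertex {v!r}")
        if not (0.0 <= e <= 1.0):
            raise ValueError(f"extinction probability for {v!r} outside [0, 1]: {e}")
    missing = [x for x in X if x in tips and x not in eps]
    if missing:
        raise ValueError(f"extinction probabilities missing for tips: {sorted(missing)}")
    beta = dict(etree.beta)
    alpha = dict(etree.alpha)
    for v in tips:
        if tree.has_ancestor_edge(v) and v in eps:
            beta[v] = beta[v] * (1.0 - eps[v])
            if discount_terminal_alpha:
                alpha[v] = alpha[v] * (1.0 - eps[v])
    modified = EvoHeritageTree(tree, alpha, beta)
    return phi(modified, X)


def crozier_gd(etree: EvoHeritageTree) -> float:
    """Crozier's genetic diversity: probability that a unit of ancestral
    (stem) heritage fails to be inherited identically by every tip.

    Equals 1 - prod_e beta(e), assuming every edge leads to at least one
    extant tip.
    """
    prod = 1.0
    for e in etree.edges():
        prod *= etree.beta[e]
    return 1.0 - prod
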