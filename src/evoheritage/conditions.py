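"""Standard conditions: from edge lengths to accumulation and attrition.

Under standard conditions, features ("EvoHeritage") accumulate along an edge
at a constant rate lambda per My, and each existing unit is lost by attrition
at rate rho per My.  Solving the resulting linear loss dynamics gives, for an
edge of length L,

    beta(e) = exp(-rho * L)                    (survival of ancestral units)
    alpha(e) = lambda/rho * (1 - exp(-rho*L))  (net accumulation; lambda*L at rho=0)

A *targeted* variant restricts accumulation to a geological window
[t1, t2] My ago while attrition still acts along the whole edge; this is the
basis of the living-fossil analysis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .treeio import PhyloTree, TreeError, derive_dates

__all__ = [
    "StandardConditions",
    "EvoHeritageTree",
    "AccumulationWindow",
    "edge_beta",
    "edge_alpha",
    "standardized_unit",
    "build_evoheritage_tree",
    "targeted_edge_alpha",
    "build_targeted_tree",
]

# beyond this, exp(-x) underflows meaningfully; clamp to the saturated values
_EXP_CUTOFF = 700.0


@dataclass(frozen=True)
class StandardConditions:
    """Attrition rate ``rho`` (1/My) and accumulation rate ``lam`` (units/My).

    ``lam`` defaults to 1: the standardized measure phi_rho depends only on
    rho, so lam matters only for raw-phi work.
    """

    rho: float = 0.0
    lam: float = 1.0

    def __post_init__(self) -> None:
        if not (self.rho >= 0):
            raise ValueError(f"attrition rate rho must be >= 0, got {self.rho}")
        if not (self.lam > 0):
            raise ValueError(f"accumulation rate lam must be > 0, got {self.lam}")


def edge_beta(cond: StandardConditions, length: float) -> float:
    """Proportion of ancestral features surviving attrition along an edge."""
    if length < 0:
        raise ValueError(f"negative edge length: {length}")
    x = cond.rho * length
    if x == 0.0:
        return 1.0
    if x > _EXP_CUTOFF:
        return 0.0
    return math.exp(-x)


def edge_alpha(cond: StandardConditions, length: float) -> float:
    """Net accumulation of features along an edge, attrition included.

    Monotone non-decreasing in length and saturating at lam/rho for rho > 0;
    exactly lam * length when rho = 0.
    """
    if length < 0:
        raise ValueError(f"negative edge length: {length}")
    if cond.rho == 0.0:
        return cond.lam * length
    x = cond.rho * length
    if x > _EXP_CUTOFF:
        return cond.lam / cond.rho
    return cond.lam / cond.rho * (-math.expm1(-x))


def standardized_unit(cond: StandardConditions) -> float:
    """Total features at the end of a single disconnected unit-length edge."""
    return edge_alpha(cond, 1.0)


@dataclass
class EvoHeritageTree:
    """A tree annotated per edge with accumulation ``alpha`` and survival ``beta``.

    Edges are keyed by descendant vertex, matching :class:`~evoheritage.treeio.PhyloTree`.
    """

    tree: PhyloTree
    alpha: dict[str, float] = field(repr=False)
    beta: dict[str, float] = field(repr=False)

    def __post_init__(self) -> None:
        edges = set(self.tree.edges())
        if set(self.alpha) != edges or set(self.beta) != edges:
            raise TreeError("alpha/beta must be defined on exactly the tree's edges")
        for e in edges:
            if self.alpha[e] < 0:
                raise TreeError(f"alpha({e!r}) must be >= 0")
            if not (0.0 <= self.beta[e] <= 1.0):
                raise TreeError(f"beta({e!r}) must lie in [0, 1]")

    def edges(self) -> list[str]:
        return self.tree.edges()


def build_evoheritage_tree(tree: PhyloTree, cond: StandardConditions) -> EvoHeritageTree:
    """Annotate every edge of ``tree`` with alpha and beta under ``cond``."""
    alpha = {e: edge_alpha(cond, tree.length(e)) for e in tree.edges()}
    beta = {e: edge_beta(cond, tree.length(e)) for e in tree.edges()}
    return EvoHeritageTree(tree, alpha, beta)


@dataclass(frozen=True)
class AccumulationWindow:
    """Geological interval [t1, t2] My ago in which accumulation is allowed.

    ``t2`` may be ``inf`` (accumulation arbitrarily far into the past).  The
    full window [0, inf) reproduces untargeted accumulation.
    """

    t1: float = 0.0
    t2: float = math.inf

    def __post_init__(self) -> None:
        if not (0 <= self.t1 < self.t2):
            raise ValueError(f"window requires 0 <= t1 < t2, got [{self.t1}, {self.t2}]")

    @classmethod
    def parse(cls, text: str) -> "AccumulationWindow":
        """Parse "t1,t2" with "inf" allowed for t2."""
        a, b = text.split(",")
        return cls(float(a), math.inf if b.strip().lower() == "inf" else float(b))


def targeted_edge_alpha(
    cond: StandardConditions,
    edge_interval: tuple[float, float],
    window: AccumulationWindow,
) -> float:
    """Net accumulation on an edge restricted to a geological window.

    ``edge_interval`` is ``(l1, l2)``: the edge spans from l2 My ago (old end)
    down to l1 My ago (recent end), l1 < l2.  Accumulation happens only at
    times within [t1, t2]; units then suffer attrition from their birth time
    down to the recent end of the edge, so accumulation older than the
    window start t1 carries an extra attrition factor exp(-rho*(t1 - l1)).
    Returns 0 when the edge lies wholly outside the window.  Attrition
    (beta) along the edge is unaffected by targeting.
    """
    l1, l2 = edge_interval
    if not (l1 < l2):
        raise ValueError(f"edge interval requires l1 < l2, got ({l1}, {l2})")
    a = max(l1, window.t1)
    b = min(l2, window.t2)
    if b <= a:
        return 0.0
    if cond.rho == 0.0:
        return cond.lam * (b - a)
    # integral over birth times t in [a, b] of lam * exp(-rho * (t - l1))
    xa = cond.rho * (a - l1)
    xb = cond.rho * (b - l1)
    ea = 0.0 if xa > _EXP_CUTOFF else math.exp(-xa)
    eb = 0.0 if xb > _EXP_CUTOFF else math.exp(-xb)
    return cond.lam / cond.rho * (ea - eb)


def build_targeted_tree(
    tree: PhyloTree, cond: StandardConditions, window: AccumulationWindow
) -> EvoHeritageTree:
    """EvoHeritage tree with window-targeted alpha and full-edge beta.

    Requires vertex dates (derived automatically for ultrametric trees).
    """
    tree = derive_dates(tree)
    assert tree.dates is not None
    beta = {e: edge_beta(cond, tree.length(e)) for e in tree.edges()}
    alpha: dict[str, float] = {}
    for e in tree.edges():
        l1 = tree.dates[e]
        l2 = l1 + tree.length(e)  # stem has no dated ancestor; use length
        if tree.parent(e) is not None:
            l2 = tree.dates[tree.parent(e)]
        if tree.length(e) == 0.0:
            alpha[e] = 0.0
            continue
        alpha[e] = targeted_edge_alpha(cond, (l1, l2), window)
    return EvoHeritageTree(tree, alpha, beta)
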