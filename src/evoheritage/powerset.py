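"""Power-set percolation and partitioned EvoHeritage.

An EvoHeritage tree with attrition can be viewed as a weighted mixture of
trees *without* attrition: each edge is independently retained with
probability beta(e) or removed with probability 1 - beta(e).  The operator
kappa sums a per-edge connection measure F over all 2^|E| retention
outcomes, weighted accordingly:

    kappa(F, ctx) = sum_{G subset of E} prod_{g in G} beta(g)
                     * prod_{g not in G} (1 - beta(g))
                     * sum_{e in E} alpha(e) * F(dV(e), G, ctx)

With F the reachability indicator, kappa reproduces phi exactly.  With F the
fair-share ratio c(v,G,X)/c(v,G,Y) it yields partitioned-phi: the fair share
of phi(Y) attributable to the subset X.  Exact enumeration is feasible for
small trees; a seeded Monte Carlo estimator handles the rest.  Targeting
accumulation to an ancient geological window and taking log10 of a tip's
partitioned share gives its living-fossil-ness.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Iterable

import numpy as np

from .conditions import (
    AccumulationWindow,
    EvoHeritageTree,
    StandardConditions,
    build_targeted_tree,
    standardized_unit,
)
from .phi import evolutionary_distinctiveness
from .treeio import PhyloTree

__all__ = [
    "MonteCarloConfig",
    "MCEstimate",
    "reachable_count",
    "indicator",
    "fair_share_ratio",
    "kappa_exact",
    "partitioned_phi_exact",
    "partitioned_phi_mc",
    "living_fossilness",
    "living_fossil_ranking",
]

#: Largest edge count for exact power-set enumeration (2^20 ~ 1e6 subsets).
DEFAULT_EXACT_CAP = 20


@dataclass(frozen=True)
class MonteCarloConfig:
    """Replicate count and seed for stochastic edge-removal estimation."""

    reps: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.reps < 1:
            raise ValueError(f"reps must be >= 1, got {self.reps}")


@dataclass(frozen=True)
class MCEstimate:
    """Monte Carlo point estimate with a replicate-based standard error."""

    value: float
    stderr: float
    reps: int

    def __float__(self) -> float:
        return self.value


# ---------------------------------------------------------------------------
# Connection measures on a fixed edge subset
# ---------------------------------------------------------------------------


def reachable_count(
    tree: PhyloTree, v: str, G: Iterable[str], X: Iterable[str]
) -> int:
    """Number of members of X reachable from v using only edges in G.

    Edges are directed away from the root, so reachable means "at or below v
    through retained edges"; v reaches itself with no edges at all.
    """
    G = frozenset(G)
    X = tree.validate_vertex_set(X)
    n = 0
    stack = [v]
    while stack:
        u = stack.pop()
        if u in X:
            n += 1
        for c in tree.children(u):
            if c in G:
                stack.append(c)
    return n


def indicator(tree: PhyloTree, v: str, G: Iterable[str], X: Iterable[str]) -> int:
    """1 iff at least one member of X is reachable from v within G."""
    return 1 if reachable_count(tree, v, G, X) >= 1 else 0


def fair_share_ratio(
    tree: PhyloTree,
    v: str,
    G: Iterable[str],
    X: Iterable[str],
    Y: Iterable[str],
) -> float:
    """c(v,G,X) / c(v,G,Y) for X a subset of Y; 0 when nothing in Y is reached."""
    X = tree.validate_vertex_set(X)
    Y = tree.validate_vertex_set(Y)
    if not X <= Y:
        raise ValueError("fair_share_ratio requires X to be a subset of Y")
    cy = reachable_count(tree, v, G, Y)
    if cy == 0:
        return 0.0
    return reachable_count(tree, v, G, X) / cy


# ---------------------------------------------------------------------------
# Exact enumeration
# ---------------------------------------------------------------------------


def _split_edges(etree: EvoHeritageTree) -> tuple[list[str], list[str], list[str]]:
    """Partition edges into always-kept (beta=1), always-removed (beta=0) and
    genuinely stochastic ones; only the last need enumerating."""
    kept, removed, stochastic = [], [], []
    for e in etree.edges():
        b = etree.beta[e]
        if b == 1.0:
            kept.append(e)
        elif b == 0.0:
            removed.append(e)
        else:
            stochastic.append(e)
    return kept, removed, stochastic


def _subtree_counts(
    tree: PhyloTree, G: frozenset[str], X: frozenset[str]
) -> dict[str, int]:
    """c(v, G, X) for every vertex, via one postorder pass."""
    cnt: dict[str, int] = {}
    for v in tree.postorder():
        n = 1 if v in X else 0
        for c in tree.children(v):
            if c in G:
                n += cnt[c]
        cnt[v] = n
    return cnt


def kappa_exact(
    etree: EvoHeritageTree,
    F: Callable,
    context,
    cap: int = DEFAULT_EXACT_CAP,
) -> float:
    """Exact power-set evaluation of kappa(F, context).

    ``F`` is called as ``F(tree, dV(e), G, *context)`` where ``context`` is a
    tuple of extra arguments (a single set may be passed bare).  The built-in
    measures :func:`indicator` and :func:`fair_share_ratio` are recognised
    and evaluated through a fast per-subset postorder count instead of
    per-edge graph searches.

    Raises if the number of edges with 0 < beta < 1 exceeds ``cap``
    (2^cap subsets); use :func:`partitioned_phi_mc` beyond that.
    """
    tree = etree.tree
    if not isinstance(context, tuple):
        context = (context,)
    kept, _removed, stochastic = _split_edges(etree)
    m = len(stochastic)
    if m > cap:
        raise ValueError(
            f"{m} stochastic edges exceed the exact enumeration cap ({cap}); "
            "use the Monte Carlo estimator instead"
        )
    edges = etree.edges()
    alpha = etree.alpha
    beta = etree.beta
    base = frozenset(kept)
    sets = tuple(tree.validate_vertex_set(S) for S in context)

    total = 0.0
    for mask in range(1 << m):
        weight = 1.0
        members = []
        for i in range(m):
            e = stochastic[i]
            if mask >> i & 1:
                weight *= beta[e]
                members.append(e)
            else:
                weight *= 1.0 - beta[e]
        G = base | frozenset(members)
        if F is indicator:
            cnt = _subtree_counts(tree, G, sets[0])
            inner = sum(alpha[e] for e in edges if cnt[e] >= 1)
        elif F is fair_share_ratio:
            X, Y = sets
            if not X <= Y:
                raise ValueError("fair_share_ratio requires X to be a subset of Y")
            cx = _subtree_counts(tree, G, X)
            cy = _subtree_counts(tree, G, Y)
            inner = sum(
                alpha[e] * (cx[e] / cy[e]) for e in edges if cy[e] >= 1
            )
        else:
            inner = sum(alpha[e] * F(tree, e, G, *context) for e in edges)
        total += weight * inner
    return total


def phi_via_powerset(
    etree: EvoHeritageTree, X: Iterable[str], cap: int = DEFAULT_EXACT_CAP
) -> float:
    """phi(X) computed through the percolation operator (kappa with the
    reachability indicator); an independent route to the postorder recursion."""
    return kappa_exact(etree, indicator, (etree.tree.validate_vertex_set(X),), cap=cap)


def partitioned_phi_exact(
    etree: EvoHeritageTree,
    X: Iterable[str],
    Y: Iterable[str],
    cap: int = DEFAULT_EXACT_CAP,
) -> float:
    """Fair share of phi(Y) attributed to the subset X, by exact enumeration.

    Summing over singletons x in Y recovers phi(Y) exactly; as rho -> 0 the
    per-tip shares converge to fair-proportion ED.
    """
    tree = etree.tree
    X = tree.validate_vertex_set(X)
    Y = tree.validate_vertex_set(Y)
    if not X <= Y:
        raise ValueError("partitioned phi requires X to be a subset of Y")
    return kappa_exact(etree, fair_share_ratio, (X, Y), cap=cap)


# ---------------------------------------------------------------------------
# Monte Carlo estimation
# ---------------------------------------------------------------------------


def _edge_ratios_mc(
    etree: EvoHeritageTree,
    focal: str,
    v: str,
    X: frozenset[str],
    reps: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Per-replicate fair-share ratios c(dV(e),G,{v})/c(dV(e),G,X) for one
    focal edge, sampling only its descendant edges (others cannot matter).

    Vectorized over replicates: every descendant edge with beta < 1 gets an
    independent Bernoulli(beta) retention draw per replicate, and counts are
    combined bottom-up with the draws masking each child's contribution.
    """
    tree = etree.tree
    beta = etree.beta
    sub = tree.subtree_vertices(focal)
    cnt: dict[str, np.ndarray] = {}
    reach: dict[str, np.ndarray] = {}
    for u in reversed(sub):  # children of u appear after u in preorder
        c_u = np.full(reps, 1 if u in X else 0, dtype=np.int64)
        r_u = np.full(reps, u == v, dtype=bool)
        for c in tree.children(u):
            b = beta[c]
            if b >= 1.0:
                c_u = c_u + cnt[c]
                r_u = r_u | reach[c]
            elif b > 0.0:
                keep = rng.random(reps) < b
                c_u = c_u + np.where(keep, cnt[c], 0)
                r_u = r_u | (keep & reach[c])
            # b == 0: edge never retained
        cnt[u] = c_u
        reach[u] = r_u
    cx = cnt[focal]
    with np.errstate(divide="ignore", invalid="ignore"):
        ratios = np.where(cx > 0, reach[focal] / np.maximum(cx, 1), 0.0)
    return ratios


def partitioned_phi_mc(
    etree: EvoHeritageTree,
    v: str,
    X: Iterable[str],
    mc: MonteCarloConfig,
) -> MCEstimate:
    """Monte Carlo partitioned-phi({v}, X) with a standard error.

    For each edge e with alpha(e) > 0, descendant edges are independently
    removed with probability 1 - beta and the fair-share ratio for v against
    X is averaged over replicates; the estimate is sum_e alpha(e) * mean
    ratio.  Each edge draws from its own RNG stream derived from
    (seed, edge index), so results are reproducible and independent of
    evaluation order.  The standard error comes from the replicate-level
    variance of the per-edge ratio sums.
    """
    tree = etree.tree
    X = tree.validate_vertex_set(X)
    if v not in X:
        raise ValueError(f"focal vertex {v!r} must be a member of X")
    alpha = etree.alpha
    reps = mc.reps
    totals = np.zeros(reps)
    point = 0.0
    for idx, e in enumerate(etree.edges()):
        a = alpha[e]
        if a == 0.0:
            continue
        rng = np.random.default_rng([mc.seed, idx])
        ratios = _edge_ratios_mc(etree, e, v, X, reps, rng)
        totals += a * ratios
        point += a * float(ratios.mean())
    if reps > 1:
        se = float(totals.std(ddof=1) / math.sqrt(reps))
    else:
        se = float("nan")
    return MCEstimate(value=point, stderr=se, reps=reps)


def partitioned_phi_mc_whole_tree(
    etree: EvoHeritageTree,
    v: str,
    X: Iterable[str],
    mc: MonteCarloConfig,
) -> MCEstimate:
    """Naive whole-tree sampler kept as a cross-check for the per-edge one:
    each replicate removes edges across the entire tree, then evaluates the
    inner kappa sum with per-edge graph searches."""
    tree = etree.tree
    X = tree.validate_vertex_set(X)
    if v not in X:
        raise ValueError(f"focal vertex {v!r} must be a member of X")
    rng = np.random.default_rng(mc.seed)
    edges = etree.edges()
    beta = etree.beta
    alpha = etree.alpha
    totals = np.empty(mc.reps)
    for r in range(mc.reps):
        G = frozenset(e for e in edges if rng.random() < beta[e])
        totals[r] = sum(
            alpha[e] * fair_share_ratio(tree, e, G, frozenset({v}), X)
            for e in edges
            if alpha[e] > 0.0
        )
    se = float(totals.std(ddof=1) / math.sqrt(mc.reps)) if mc.reps > 1 else float("nan")
    return MCEstimate(value=float(totals.mean()), stderr=se, reps=mc.reps)


# ---------------------------------------------------------------------------
# Living fossils
# ---------------------------------------------------------------------------


def living_fossilness(
    tree: PhyloTree,
    v: str,
    X: Iterable[str],
    window: AccumulationWindow,
    rho: float,
    mc: MonteCarloConfig | None = None,
    cap: int = DEFAULT_EXACT_CAP,
) -> float:
    """log10 of v's partitioned share of window-targeted features.

    Builds a targeted EvoHeritage tree (accumulation restricted to the
    geological window, attrition everywhere), partitions its phi among the
    extant set X, expresses v's share in standardized units, and returns
    log10 of it (-inf when the share is zero).  Attrition being an
    exponential decay process, log10 puts scores on a natural scale.

    Uses exact enumeration when the stochastic edge count fits under
    ``cap``, otherwise the Monte Carlo estimator (``mc`` required).
    """
    X = tree.validate_vertex_set(X)
    if v not in X:
        raise ValueError(f"focal vertex {v!r} must be a member of X")
    cond = StandardConditions(rho=rho)
    etree = build_targeted_tree(tree, cond, window)
    _kept, _removed, stochastic = _split_edges(etree)
    if len(stochastic) <= cap:
        share = partitioned_phi_exact(etree, frozenset({v}), X, cap=cap)
    else:
        if mc is None:
            raise ValueError(
                f"{len(stochastic)} stochastic edges exceed the exact cap; "
                "supply a MonteCarloConfig"
            )
        share = partitioned_phi_mc(etree, v, X, mc).value
    share_std = share / standardized_unit(cond)
    if share_std <= 0.0:
        return -math.inf
    return math.log10(share_std)


def living_fossil_ranking(
    tree: PhyloTree,
    window: AccumulationWindow,
    rho: float,
    X: Iterable[str] | None = None,
    mc: MonteCarloConfig | None = None,
    cap: int = DEFAULT_EXACT_CAP,
) -> list[tuple[str, float]]:
    """Living-fossil-ness of every tip in X (default: all tips), ranked.

    Sorted by descending score with ties broken by ascending tip label.
    """
    X = tree.validate_vertex_set(X if X is not None else tree.tips())
    scores = {
        x: living_fossilness(tree, x, X, window, rho, mc=mc, cap=cap) for x in X
    }
    return sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))


def ed_ranking(tree: PhyloTree, X: Iterable[str] | None = None) -> list[tuple[str, float]]:
    """Fair-proportion ED ranking with the same tie-break, for comparison
    (living-fossil-ness at rho = 0 with the full window reduces to this)."""
    X = tree.validate_vertex_set(X if X is not None else tree.tips())
    ed = evolutionary_distinctiveness(tree, X)
    return sorted(ed.items(), key=lambda kv: (-kv[1], kv[0]))
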