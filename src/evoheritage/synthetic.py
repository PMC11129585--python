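"""Synthetic trees, communities, the stochastic-unit simulator, and the
biodiversity-productivity attrition sweep.

The generators here define the study conditions for validation: dated Yule
(pure-birth) trees, exhaustive small tree topologies for oracle sweeps,
random communities on a tree with a pluggable response rule, and a
discrete-unit ("constant birth, linear death") simulator whose expectation
matches the deterministic phi.  The productivity sweep mirrors the workflow
of correlating per-community phi_rho with a response (e.g. biomass) across a
log grid of attrition rates, recovering the PD and species-richness
correlations at the two ends of the grid.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Iterable, Iterator

import numpy as np
import pandas as pd_lib
from scipy import stats

from .conditions import StandardConditions, build_evoheritage_tree, standardized_unit
from .phi import pd as pd_metric
from .phi import phi, phi_rho, species_richness
from .treeio import CommunityMatrix, PhyloTree, TreeError

__all__ = [
    "generate_yule_tree",
    "enumerate_tree_topologies",
    "simulate_stochastic_units",
    "generate_communities",
    "productivity_sweep",
    "make_ultrametric_and_date",
    "SweepResult",
    "default_rho_grid",
]


# ---------------------------------------------------------------------------
# Tree generation
# ---------------------------------------------------------------------------


def generate_yule_tree(
    n_tips: int,
    birth_rate: float = 1.0,
    seed: int | None = None,
) -> PhyloTree:
    """Dated ultrametric tree from a pure-birth (Yule) process, with a stem.

    A single stem lineage starts at time 0; each of k extant lineages splits
    at total rate k * birth_rate, and the simulation runs one extra
    inter-event time after the n-th lineage appears so pendant edges have
    positive length.  Internal vertices are labelled iv1.. and tips t1.. in
    preorder; deterministic for a given seed.
    """
    if n_tips < 2:
        raise ValueError(f"need at least 2 tips, got {n_tips}")
    if birth_rate <= 0:
        raise ValueError("birth rate must be positive")
    rng = np.random.default_rng(seed)
    start = {0: 0.0}  # creation time of each lineage (distance from origin)
    split: dict[int, float] = {}  # time at which a lineage split (internal only)
    children: dict[int, list[int]] = {0: []}
    active = [0]
    next_id = 1
    t = 0.0
    while len(active) < n_tips:
        k = len(active)
        t += float(rng.exponential(1.0 / (k * birth_rate)))
        v = active.pop(int(rng.integers(k)))
        split[v] = t
        for _ in range(2):
            children[v].append(next_id)
            children[next_id] = []
            start[next_id] = t
            active.append(next_id)
            next_id += 1
    present = t + float(rng.exponential(1.0 / (n_tips * birth_rate)))

    # deterministic relabelling in preorder
    label: dict[int, str] = {}
    order: list[int] = []
    stack = [0]
    while stack:
        v = stack.pop()
        order.append(v)
        stack.extend(reversed(children[v]))
    n_int = n_tip = 0
    for v in order:
        if children[v]:
            n_int += 1
            label[v] = f"iv{n_int}"
        else:
            n_tip += 1
            label[v] = f"t{n_tip}"

    end = {v: (split[v] if children[v] else present) for v in children}
    child_map = {label[v]: tuple(label[c] for c in children[v]) for v in children}
    lengths = {label[v]: end[v] - start[v] for v in children}  # root entry = stem
    dates = {label[v]: present - end[v] for v in children}
    return PhyloTree(child_map, lengths, label[0], dates=dates)


def make_ultrametric_and_date(tree: PhyloTree, crown_age: float, rtol: float = 1e-6) -> PhyloTree:
    """Linearly rescale an ultrametric tree so the crown sits at ``crown_age`` My.

    All edge lengths (stem included) are multiplied by crown_age / current
    crown depth and vertex dates are attached.  Raises for trees that are
    not ultrametric within ``rtol``; rate-smoothing is left to external
    tools.
    """
    depth = tree.depths()
    tip_depths = [depth[v] for v in tree.tips()]
    dmax = max(tip_depths)
    if dmax <= 0:
        raise TreeError("tree has zero depth; cannot rescale")
    if (dmax - min(tip_depths)) > rtol * dmax:
        raise TreeError(
            "tree is not ultrametric within tolerance; rate-smooth it "
            "externally before dating"
        )
    scale = crown_age / dmax
    lengths = {e: tree.length(e) * scale for e in tree.edges()}
    dates = {v: (dmax - d) * scale for v, d in depth.items()}
    return tree.copy(lengths=lengths, dates=dates)


# -- exhaustive small topologies --------------------------------------------


def _shapes(n_edges: int) -> Iterator[tuple]:
    """All rooted tree shapes below a vertex with exactly ``n_edges`` edges.

    A shape is a sorted tuple of child shapes; internal vertices have
    out-degree >= 2 (no unary chains), matching phylogenetic convention.
    """
    if n_edges == 0:
        yield ()
        return
    if n_edges == 1:
        yield ((),)  # single pendant edge
        return

    def partitions(total: int, max_part: int) -> Iterator[tuple[int, ...]]:
        if total == 0:
            yield ()
            return
        for part in range(min(total, max_part), 0, -1):
            for rest in partitions(total - part, part):
                yield (part,) + rest

    seen = set()
    for parts in partitions(n_edges, n_edges - 1):
        if len(parts) < 2:
            continue
        # each part p contributes one edge plus a subtree with p-1 edges
        def expand(idx: int, acc: tuple) -> Iterator[tuple]:
            if idx == len(parts):
                yield tuple(sorted(acc))
                return
            for sub in _shapes(parts[idx] - 1):
                yield from expand(idx + 1, acc + (sub,))

        for shape in expand(0, ()):
            if shape not in seen:
                seen.add(shape)
                yield shape


def enumerate_tree_topologies(
    max_edges: int,
    include_stem_variants: bool = True,
    length_cycle: tuple[float, ...] = (1.0, 0.5, 2.0, 0.75, 1.5),
) -> list[PhyloTree]:
    """Every rooted tree topology with at most ``max_edges`` edges.

    Internal vertices have out-degree >= 2; with ``include_stem_variants``
    each shape also appears with a stem edge (counted toward the edge
    budget).  Edge lengths cycle deterministically through ``length_cycle``
    so repeated runs yield identical trees.
    """
    trees: list[PhyloTree] = []
    for n in range(1, max_edges + 1):
        for shape in _shapes(n):
            for stem in (False, True) if include_stem_variants else (False,):
                if stem and n + 1 > max_edges:
                    continue
                trees.append(_shape_to_tree(shape, stem, length_cycle))
    return trees


def _shape_to_tree(shape: tuple, stem: bool, length_cycle: tuple[float, ...]) -> PhyloTree:
    children: dict[str, tuple[str, ...]] = {}
    lengths: dict[str, float] = {}
    counter = {"iv": 0, "t": 0, "e": 0}

    def next_length() -> float:
        val = length_cycle[counter["e"] % len(length_cycle)]
        counter["e"] += 1
        return val

    def build(node_shape: tuple) -> str:
        if not node_shape:
            counter["t"] += 1
            name = f"t{counter['t']}"
            children[name] = ()
            return name
        counter["iv"] += 1
        name = f"iv{counter['iv']}"
        kids = tuple(build(s) for s in node_shape)
        children[name] = kids
        for k in kids:
            lengths[k] = next_length()
        return name

    if not shape:  # a bare leaf needs a root above it
        root = "iv1"
        children[root] = ("t1",)
        children["t1"] = ()
        lengths["t1"] = next_length()
    else:
        root = build(shape)
    if stem:
        lengths[root] = next_length()
    return PhyloTree(children, lengths, root)


# ---------------------------------------------------------------------------
# Stochastic discrete-unit simulator
# ---------------------------------------------------------------------------


def simulate_stochastic_units(
    tree: PhyloTree,
    cond: StandardConditions,
    reps: int,
    seed: int | None = None,
    X: Iterable[str] | None = None,
) -> np.ndarray:
    """Simulate discrete feature units under constant birth / linear death.

    On each edge, new units are born at rate lam and each existing unit dies
    at rate rho; the number of *newly created* units still alive at the edge
    end is Poisson with mean alpha(e) (Poisson births thinned by exponential
    survival), and each inherited unit survives the edge independently with
    probability beta(e).  Units are copied to all descendants at vertices.

    Returns, per replicate, the number of distinct units present on at least
    one member of the query set X (default: all tips).  The sample mean
    converges to the deterministic phi(X).
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    X = tree.validate_vertex_set(X if X is not None else tree.tips())
    etree = build_evoheritage_tree(tree, cond)
    rng = np.random.default_rng(seed)
    beta = etree.beta
    alpha = etree.alpha

    def reach(v: str, m: int) -> np.ndarray:
        """For m units sitting at v, whether each reaches some member of X."""
        if v in X:
            return np.ones(m, dtype=bool)
        out = np.zeros(m, dtype=bool)
        todo = np.arange(m)
        for c in tree.children(v):
            if not todo.size:
                break
            alive = todo[rng.random(todo.size) < beta[c]]
            if alive.size:
                hit = reach(c, alive.size)
                out[alive[hit]] = True
                todo = todo[~out[todo]]
        return out

    counts = np.zeros(reps, dtype=np.int64)
    for e in etree.edges():
        a = alpha[e]
        if a == 0.0:
            continue
        births = rng.poisson(a, size=reps)
        total = int(births.sum())
        if total == 0:
            continue
        survived = reach(e, total)
        # slice per-replicate segments back out of the flat unit array
        idx = np.repeat(np.arange(reps), births)
        counts += np.bincount(idx[survived], minlength=reps)
    return counts


# ---------------------------------------------------------------------------
# Communities and the productivity sweep
# ---------------------------------------------------------------------------


def generate_communities(
    tree: PhyloTree,
    n_communities: int,
    occupancy_model: str = "uniform",
    seed: int | None = None,
    occupancy_p: float = 0.5,
    response: str | Callable[[frozenset[str]], float] = "richness",
    response_rho: float | None = None,
    noise_sd_frac: float = 0.0,
) -> CommunityMatrix:
    """Random presence/absence communities on a tree plus a response value.

    ``occupancy_model`` is "uniform" (each tip present independently with
    probability ``occupancy_p``) or "clade" (a random internal vertex is
    drawn per community; tips inside its subtree are present with
    probability 0.8, others with 0.2 * ``occupancy_p``).  The response is
    computed from each community's tip set by the named rule - "richness",
    "pd", or "phi_rho" (with ``response_rho``) - or by a callable; Gaussian
    noise with sd ``noise_sd_frac`` times the response sd is then added.
    Empty communities are retained (their diversity is 0 downstream).
    """
    if occupancy_model not in ("uniform", "clade"):
        raise ValueError(f"unknown occupancy model {occupancy_model!r}")
    rng = np.random.default_rng(seed)
    tips = tree.tips()
    internals = [v for v in tree.vertices() if not tree.is_tip(v)]
    rows = np.zeros((n_communities, len(tips)), dtype=np.int8)
    for i in range(n_communities):
        if occupancy_model == "uniform":
            rows[i] = rng.random(len(tips)) < occupancy_p
        else:
            focus = internals[int(rng.integers(len(internals)))]
            inside = {v for v in tree.subtree_vertices(focus) if tree.is_tip(v)}
            p = np.where(
                np.fromiter((t in inside for t in tips), bool, len(tips)),
                0.8,
                0.2 * occupancy_p,
            )
            rows[i] = rng.random(len(tips)) < p

    def response_fn(tip_set: frozenset[str]) -> float:
        if callable(response):
            return float(response(tip_set))
        if response == "richness":
            return float(species_richness(tip_set))
        if response == "pd":
            return float(pd_metric(tree, tip_set)) if tip_set else 0.0
        if response == "phi_rho":
            if response_rho is None:
                raise ValueError("response='phi_rho' requires response_rho")
            return float(phi_rho(tree, response_rho, tip_set)) if tip_set else 0.0
        raise ValueError(f"unknown response rule {response!r}")

    ids = [f"c{i + 1}" for i in range(n_communities)]
    presence = pd_lib.DataFrame(rows, index=ids, columns=tips)
    values = np.array(
        [response_fn(frozenset(np.array(tips)[rows[i] == 1])) for i in range(n_communities)]
    )
    if noise_sd_frac > 0:
        values = values + rng.normal(0.0, noise_sd_frac * values.std(), n_communities)
    return CommunityMatrix(presence, pd_lib.Series(values, index=ids))


def default_rho_grid(
    rho_min: float = 1e-4, rho_max: float = 1e4, points: int = 25
) -> np.ndarray:
    """Log-spaced attrition grid spanning the PD-to-richness continuum."""
    return np.logspace(math.log10(rho_min), math.log10(rho_max), points)


@dataclass
class SweepResult:
    """Per-rho correlation between community phi_rho and the response."""

    rho: np.ndarray
    r: np.ndarray  # Pearson r per grid point; NaN where phi_rho has no variance
    argmax_rho: float
    pd_r: float
    richness_r: float

    def summary(self) -> str:
        return (
            f"optimal rho = {self.argmax_rho:.6g} "
            f"(r = {np.nanmax(self.r):.4f}); "
            f"PD r = {self.pd_r:.4f}, richness r = {self.richness_r:.4f}"
        )


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    if np.std(x) == 0.0:
        return float("nan")
    return float(stats.pearsonr(x, y).statistic)


def productivity_sweep(
    tree: PhyloTree,
    communities: CommunityMatrix,
    rho_grid: np.ndarray | None = None,
    clade: str | Iterable[str] | None = None,
    require_clades: tuple | None = None,
) -> SweepResult:
    """Correlate per-community phi_rho with the response across a rho grid.

    For every rho, phi_rho of each community's tip set is correlated
    (Pearson) with the community response; the rho maximizing r is reported
    together with the correlations obtained from PD and species richness
    directly (the two limits of phi_rho).  ``clade`` restricts the measured
    tip sets to a named subtree (internal vertex label) or explicit tip
    list; ``require_clades=(A, B)`` first drops communities lacking a
    representative of either clade.
    """
    communities.validate_against(tree)
    if require_clades is not None:
        communities = communities.filter_requiring_clades(tree, *require_clades)
    if len(communities.communities) < 3:
        raise ValueError("need at least 3 communities")
    resp = communities.response.to_numpy()
    if np.std(resp) == 0.0:
        raise ValueError("response has zero variance")
    if rho_grid is None:
        rho_grid = default_rho_grid()
    rho_grid = np.asarray(rho_grid, dtype=float)
    if not np.all(np.diff(rho_grid) > 0):
        raise ValueError("rho grid must be strictly increasing")

    restrict: set[str] | None = None
    if clade is not None:
        if isinstance(clade, str):
            if clade not in tree:
                raise ValueError(f"clade vertex {clade!r} not in tree")
            restrict = {v for v in tree.subtree_vertices(clade) if tree.is_tip(v)}
        else:
            restrict = set(clade)

    tip_sets = []
    for c in communities.communities:
        s = communities.tips_present(c)
        tip_sets.append(frozenset(s & restrict) if restrict is not None else s)

    r = np.empty(len(rho_grid))
    for i, rho in enumerate(rho_grid):
        cond = StandardConditions(rho=float(rho))
        etree = build_evoheritage_tree(tree, cond)
        su = standardized_unit(cond)
        values = np.array([phi(etree, s) / su if s else 0.0 for s in tip_sets])
        r[i] = _pearson(values, resp)

    pd_vals = np.array([pd_metric(tree, s) if s else 0.0 for s in tip_sets])
    sr_vals = np.array([float(len(s)) for s in tip_sets])
    pd_r = _pearson(pd_vals, resp)
    sr_r = _pearson(sr_vals, resp)
    best = int(np.nanargmax(r))
    return SweepResult(
        rho=rho_grid, r=r, argmax_rho=float(rho_grid[best]), pd_r=pd_r, richness_r=sr_r
    )
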