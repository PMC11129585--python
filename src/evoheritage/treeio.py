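"""Rooted directed trees and community data.

This module provides the directed-tree data model that the rest of the
package consumes: a :class:`PhyloTree` is a rooted tree with a non-negative
length on every edge, optional vertex dates (millions of years before
present, increasing into the past) and an optional *stem* edge hanging above
the root.  The stem is modelled as an edge from a synthetic origin point down
to the root vertex, so that metrics which sum over "all edges" naturally
include it; the origin point itself is not a member of the vertex set.

Newick and Nexus parsing is delegated to dendropy; serialization is a small
purpose-built writer so that branch lengths round-trip exactly.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import dendropy
import pandas as pd

__all__ = [
    "PhyloTree",
    "CommunityMatrix",
    "TreeError",
    "NewickParseError",
    "parse_newick",
    "write_newick",
    "read_tree_set",
    "extend_stem_to_origin",
    "derive_dates",
    "read_community_matrix",
]

#: Age of the origin of life used when extending stems, in My.
ORIGIN_OF_LIFE_MY = 4025.0

_DATE_RTOL = 1e-6


class TreeError(ValueError):
    """Invalid tree structure or tree-related input."""


class NewickParseError(TreeError):
    """Malformed Newick/Nexus input."""


class PhyloTree:
    """Rooted directed tree with edge lengths.

    Edges are identified by their descendant vertex: every non-root vertex
    has exactly one ancestor edge, and the root may additionally carry a stem
    edge (an ancestor edge coming from outside the vertex set).

    Parameters
    ----------
    children
        Mapping from each vertex label to the tuple of its child labels
        (leaves may be omitted or map to an empty tuple).
    lengths
        Mapping from vertex label to the length of the edge above it, in My.
        Contains every non-root vertex; contains the root iff a stem edge is
        present.
    root
        Label of the (biological) root vertex.
    dates
        Optional mapping from vertex label to its date in My before present.
    """

    __slots__ = ("_children", "_parent", "_length", "root", "dates")

    def __init__(
        self,
        children: Mapping[str, Sequence[str]],
        lengths: Mapping[str, float],
        root: str,
        dates: Mapping[str, float] | None = None,
    ) -> None:
        self._children: dict[str, tuple[str, ...]] = {}
        self._parent: dict[str, str] = {}
        seen: set[str] = set()
        stack = [root]
        while stack:
            v = stack.pop()
            if v in seen:
                raise TreeError(f"vertex {v!r} reachable twice (cycle or duplicate label)")
            seen.add(v)
            kids = tuple(children.get(v, ()))
            self._children[v] = kids
            for c in kids:
                self._parent[c] = v
                stack.append(c)
        extra = set(children) - seen
        if extra:
            raise TreeError(f"vertices not reachable from root: {sorted(extra)}")
        self.root = root
        self._length: dict[str, float] = {}
        for v, length in lengths.items():
            if v not in seen:
                raise TreeError(f"edge length given for unknown vertex {v!r}")
            length = float(length)
            if length < 0:
                raise TreeError(f"negative edge length {length} on edge above {v!r}")
            self._length[v] = length
        missing = seen - set(self._length) - {root}
        if missing:
            raise TreeError(f"missing edge lengths above vertices: {sorted(missing)}")
        self.dates: dict[str, float] | None = None
        if dates is not None:
            self.dates = {v: float(dates[v]) for v in seen}
            self._check_dates()

    def _check_dates(self) -> None:
        assert self.dates is not None
        for v in self.edges():
            p = self._parent.get(v)
            if p is None:
                continue  # stem: no dated ancestor inside V
            span = self.dates[p] - self.dates[v]
            tol = _DATE_RTOL * max(1.0, abs(self._length[v]))
            if abs(span - self._length[v]) > tol:
                raise TreeError(
                    f"dates inconsistent with edge length above {v!r}: "
                    f"span {span} vs length {self._length[v]}"
                )

    # -- structure ---------------------------------------------------------

    def vertices(self) -> list[str]:
        return list(self._children)

    def edges(self) -> list[str]:
        """Edges, each named by its descendant vertex (stem included)."""
        return [v for v in self._children if v in self._length]

    def children(self, v: str) -> tuple[str, ...]:
        return self._children[v]

    def parent(self, v: str) -> str | None:
        """Ancestor vertex, or None for the root (even if a stem exists)."""
        return self._parent.get(v)

    def length(self, v: str) -> float:
        """Length of the edge above vertex ``v``."""
        return self._length[v]

    @property
    def has_stem(self) -> bool:
        return self.root in self._length

    @property
    def stem_length(self) -> float | None:
        return self._length.get(self.root)

    def has_ancestor_edge(self, v: str) -> bool:
        """True iff an edge lies above ``v`` (true for the root only with a stem)."""
        return v in self._length

    def is_tip(self, v: str) -> bool:
        return not self._children[v]

    def tips(self) -> list[str]:
        return [v for v, kids in self._children.items() if not kids]

    def n_vertices(self) -> int:
        return len(self._children)

    def n_edges(self) -> int:
        return len(self._length)

    def __contains__(self, v: str) -> bool:
        return v in self._children

    def postorder(self) -> Iterator[str]:
        """Vertices with every child before its parent (deterministic)."""
        out: list[str] = []
        stack = [self.root]
        while stack:
            v = stack.pop()
            out.append(v)
            stack.extend(self._children[v])
        return reversed(out)

    def preorder(self) -> Iterator[str]:
        stack = [self.root]
        while stack:
            v = stack.pop()
            yield v
            stack.extend(reversed(self._children[v]))

    def subtree_vertices(self, v: str) -> list[str]:
        """All vertices at or below ``v`` in preorder."""
        out = []
        stack = [v]
        while stack:
            u = stack.pop()
            out.append(u)
            stack.extend(reversed(self._children[u]))
        return out

    def depths(self, include_stem: bool = False) -> dict[str, float]:
        """Path length from the root (or stem top) down to each vertex."""
        d0 = self._length.get(self.root, 0.0) if include_stem else 0.0
        depth = {self.root: d0}
        for v in self.preorder():
            for c in self._children[v]:
                depth[c] = depth[v] + self._length[c]
        return depth

    # -- derived copies ----------------------------------------------------

    def copy(
        self,
        lengths: Mapping[str, float] | None = None,
        dates: Mapping[str, float] | None = None,
    ) -> "PhyloTree":
        return PhyloTree(
            {v: k for v, k in self._children.items()},
            dict(self._length) if lengths is None else dict(lengths),
            self.root,
            dates if dates is not None else (dict(self.dates) if self.dates else None),
        )

    def validate_vertex_set(self, X: Iterable[str]) -> frozenset[str]:
        X = frozenset(X)
        unknown = [x for x in X if x not in self._children]
        if unknown:
            raise TreeError(f"vertices not in tree: {sorted(unknown)}")
        return X

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return (
            f"<PhyloTree {len(self.tips())} tips, {self.n_edges()} edges"
            f"{', stem' if self.has_stem else ''}>"
        )


# ---------------------------------------------------------------------------
# Newick / Nexus
# ---------------------------------------------------------------------------


def _from_dendropy(dtree: dendropy.Tree) -> PhyloTree:
    children: dict[str, list[str]] = {}
    lengths: dict[str, float] = {}
    labels: dict[int, str] = {}
    counter = 0
    tip_labels: set[str] = set()
    for node in dtree.preorder_node_iter():
        label = None
        if node.taxon is not None:
            label = node.taxon.label
        elif node.label:
            label = node.label
        if label is None:
            counter += 1
            label = f"iv{counter}"
        if node.is_leaf():
            if label in tip_labels:
                raise TreeError(f"duplicate tip label {label!r}")
            tip_labels.add(label)
        if label in children:
            raise TreeError(f"duplicate vertex label {label!r}")
        labels[id(node)] = label
        children[label] = []
        parent = node.parent_node
        if parent is not None:
            children[labels[id(parent)]].append(label)
        edge_len = node.edge.length
        if parent is None:
            if edge_len is not None:  # root edge -> stem
                lengths[label] = edge_len
        else:
            if edge_len is None:
                raise TreeError(f"missing branch length on edge above {label!r}")
            lengths[label] = edge_len
    root = labels[id(dtree.seed_node)]
    return PhyloTree(children, lengths, root)


def parse_newick(text: str) -> PhyloTree:
    """Parse a single Newick string into a :class:`PhyloTree`.

    Branch lengths are required on all edges; a length on the root branch
    becomes the stem edge.  Unlabelled internal vertices receive
    deterministic preorder labels ``iv1``, ``iv2``, ...
    """
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as err:  # dendropy raises several error classes
        raise NewickParseError(f"malformed Newick: {err}") from err
    return _from_dendropy(dtree)


def _format_length(x: float) -> str:
    s = repr(float(x))
    return s[:-2] if s.endswith(".0") else s


def write_newick(tree: PhyloTree) -> str:
    """Serialize to Newick, preserving lengths exactly (shortest round-trip)."""

    def render(v: str) -> str:
        kids = tree.children(v)
        label = v if (not kids or not v.startswith("iv")) else ""
        body = label if not kids else "(" + ",".join(render(c) for c in kids) + ")" + label
        if v == tree.root:
            if tree.has_stem:
                body += ":" + _format_length(tree.length(v))
            return body
        return body + ":" + _format_length(tree.length(v))

    return render(tree.root) + ";"


def read_tree_set(source: str | Path) -> list[PhyloTree]:
    """Read one or more trees from a Nexus or multi-line Newick source.

    ``source`` may be a path to a file or the file content itself.  Nexus
    TREES blocks (with optional translate table) are resolved by dendropy.
    """
    text: str
    if isinstance(source, Path) or (isinstance(source, str) and os.path.exists(source)):
        text = Path(source).read_text(encoding="utf-8")
    else:
        text = str(source)
    schema = "nexus" if text.lstrip().upper().startswith("#NEXUS") else "newick"
    try:
        tlist = dendropy.TreeList.get(
            data=text,
            schema=schema,
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as err:
        raise NewickParseError(f"could not parse tree set: {err}") from err
    if len(tlist) == 0:
        raise TreeError("no trees found in input")
    return [_from_dendropy(t) for t in tlist]


# ---------------------------------------------------------------------------
# Dates and stem extension
# ---------------------------------------------------------------------------


def derive_dates(tree: PhyloTree, rtol: float = _DATE_RTOL) -> PhyloTree:
    """Attach vertex dates to an ultrametric tree (tips anchored at 0 My).

    Raises :class:`TreeError` if tip depths differ by more than ``rtol``
    relative to the crown depth, or if dates are already present (they are
    kept as-is in that case).
    """
    if tree.dates is not None:
        return tree
    depth = tree.depths()
    tip_depths = [depth[t] for t in tree.tips()]
    dmax = max(tip_depths)
    if dmax > 0 and (dmax - min(tip_depths)) > rtol * dmax:
        raise TreeError(
            "tree is not ultrametric; supply explicit vertex dates or "
            "rate-smooth the tree externally"
        )
    return tree.copy(dates={v: dmax - d for v, d in depth.items()})


def extend_stem_to_origin(tree: PhyloTree, origin_age: float = ORIGIN_OF_LIFE_MY) -> PhyloTree:
    """Lengthen (or create) the stem so its top sits at ``origin_age`` My.

    The path from the deepest tip up through the stem then equals
    ``origin_age``; by default this is the origin of life at 4025 My.
    """
    tree = derive_dates(tree)
    assert tree.dates is not None
    root_age = tree.dates[tree.root]
    if origin_age < root_age - _DATE_RTOL * max(1.0, root_age):
        raise TreeError(
            f"origin_age {origin_age} is younger than the root age {root_age}"
        )
    lengths = {v: tree.length(v) for v in tree.edges()}
    lengths[tree.root] = origin_age - root_age
    return tree.copy(lengths=lengths)


# ---------------------------------------------------------------------------
# Community data
# ---------------------------------------------------------------------------


@dataclass
class CommunityMatrix:
    """Communities x tips presence/absence with a per-community response.

    ``presence`` has community identifiers as the index and tip labels as
    columns, cells in {0, 1}.  ``response`` is one numeric value per
    community (e.g. plot biomass), aligned with ``presence.index``.
    """

    presence: pd.DataFrame
    response: pd.Series = field(repr=False)

    def __post_init__(self) -> None:
        if self.presence.index.has_duplicates:
            dups = self.presence.index[self.presence.index.duplicated()].tolist()
            raise ValueError(f"duplicate community ids: {dups}")
        vals = self.presence.to_numpy()
        if not ((vals == 0) | (vals == 1)).all():
            raise ValueError("presence matrix cells must be 0 or 1")
        missing = self.presence.index.difference(self.response.index)
        if len(missing):
            raise ValueError(f"communities missing a response value: {list(missing)}")
        self.response = self.response.loc[self.presence.index].astype(float)
        self.presence = self.presence.astype("int8")

    @property
    def communities(self) -> list:
        return list(self.presence.index)

    @property
    def tip_labels(self) -> list[str]:
        return list(self.presence.columns)

    def tips_present(self, community) -> frozenset[str]:
        row = self.presence.loc[community]
        return frozenset(row.index[row == 1])

    def validate_against(self, tree: PhyloTree) -> None:
        tip_set = set(tree.tips())
        offenders = [c for c in self.presence.columns if c not in tip_set]
        if offenders:
            raise ValueError(f"tip labels absent from tree: {offenders}")

    def filter_requiring_clades(
        self, tree: PhyloTree, clade_a: str | Iterable[str], clade_b: str | Iterable[str]
    ) -> "CommunityMatrix":
        """Drop communities lacking a representative of either clade.

        A clade may be named by an internal vertex label or given as an
        explicit collection of tip labels.
        """

        def clade_tips(clade) -> set[str]:
            if isinstance(clade, str):
                if clade not in tree:
                    raise ValueError(f"clade vertex {clade!r} not in tree")
                return {v for v in tree.subtree_vertices(clade) if tree.is_tip(v)}
            return set(clade)

        ta, tb = clade_tips(clade_a), clade_tips(clade_b)
        keep = [
            c
            for c in self.presence.index
            if (self.tips_present(c) & ta) and (self.tips_present(c) & tb)
        ]
        return CommunityMatrix(self.presence.loc[keep], self.response.loc[keep])


def read_community_matrix(
    csv_presence: str | Path,
    csv_response: str | Path,
    tree: PhyloTree | None = None,
) -> CommunityMatrix:
    """Read presence/absence and response CSVs into a :class:`CommunityMatrix`.

    The presence CSV has one header row of tip labels and one row per
    community (first column = community id); the response CSV has two
    columns: community id and value.  If ``tree`` is given, tip labels are
    validated against it and column order is harmonized with the tree's tip
    order.
    """
    presence = pd.read_csv(csv_presence, index_col=0)
    resp = pd.read_csv(csv_response, index_col=0)
    if resp.shape[1] != 1:
        raise ValueError("response CSV must have exactly two columns: id,value")
    response = resp.iloc[:, 0]
    vals = presence.to_numpy()
    if not ((vals == 0) | (vals == 1)).all():
        raise ValueError("presence matrix cells must be 0 or 1")
    cm = CommunityMatrix(presence, response)
    if tree is not None:
        cm.validate_against(tree)
        order = [t for t in tree.tips() if t in set(cm.presence.columns)]
        cm = CommunityMatrix(cm.presence[order], cm.response)
    return cm
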