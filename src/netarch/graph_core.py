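"""Core data types shared across the package.

A network snapshot is an undirected simple :class:`networkx.Graph` whose
nodes carry opaque string labels.  Growth histories record the forward
process that produced a graph; reconstruction results record the inferred
reverse process.  Node/anchor (duplication) relationships are encoded in a
rooted binary *anchor tree* whose leaves are the extant node labels: each
node arrival conceptually splits its anchor's leaf in two, so the tree's
clades summarise which groups of nodes share duplication history.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx

__all__ = [
    "LabeledGraph",
    "NEG_INF",
    "GraphValidationError",
    "UnsupportedModelError",
    "ForwardEvent",
    "GrowthHistory",
    "ReverseEvent",
    "ReconstructionResult",
    "AnchorTree",
    "new_graph",
    "validate_graph",
    "replay_history",
    "build_anchor_tree",
    "clades",
    "restrict_tree",
]

#: Type of every graph handled by this package: undirected, simple, string labels.
LabeledGraph = nx.Graph

#: Sentinel for a log-likelihood of an impossible event (probability zero).
NEG_INF = float("-inf")


class GraphValidationError(ValueError):
    """A graph, history, or tree violates a structural invariant."""


class UnsupportedModelError(ValueError):
    """An operation was requested for a model that cannot support it."""


def new_graph(edges: Iterable[tuple[str, str]] = (), nodes: Iterable[str] = ()) -> LabeledGraph:
    """Build a validated undirected simple graph from edges and extra nodes."""
    g = nx.Graph()
    g.add_nodes_from(str(n) for n in nodes)
    for a, b in edges:
        a, b = str(a), str(b)
        if a == b:
            raise GraphValidationError(f"self-loop on node {a!r}")
        if g.has_edge(a, b):
            raise GraphValidationError(f"duplicate edge ({a!r}, {b!r})")
        g.add_edge(a, b)
    return g


def validate_graph(g: LabeledGraph) -> LabeledGraph:
    """Check the simple/undirected invariants, returning ``g`` unchanged."""
    if g.is_directed() or g.is_multigraph():
        raise GraphValidationError("graph must be undirected and simple")
    loops = list(nx.selfloop_edges(g))
    if loops:
        raise GraphValidationError(f"self-loops present: {loops[:3]}")
    return g


# ---------------------------------------------------------------------------
# Histories
# ---------------------------------------------------------------------------


@dataclass
class ForwardEvent:
    """One forward growth step: a node arrival plus its edge changes.

    ``anchor`` is ``None`` for models without link copying (PA).
    ``deleted_node`` is set only by the node-deletion DMC variant; the
    deleted node's incident edges are removed implicitly on replay.
    """

    arriving: str
    anchor: str | None
    edges_added: list[tuple[str, str]] = field(default_factory=list)
    edges_removed: list[tuple[str, str]] = field(default_factory=list)
    deleted_node: str | None = None


@dataclass
class GrowthHistory:
    """Ordered forward record of a simulated growth process."""

    seed_nodes: list[str]
    seed_edges: list[tuple[str, str]]
    events: list[ForwardEvent]
    model: str = ""
    params: dict = field(default_factory=dict)

    def arrival_order(self) -> list[str]:
        """All nodes ever added, oldest first (seed nodes precede arrivals)."""
        order = list(self.seed_nodes)
        order.extend(e.arriving for e in self.events)
        if len(set(order)) != len(order):
            raise GraphValidationError("arriving node labels are not unique")
        return order


def replay_history(history: GrowthHistory) -> LabeledGraph:
    """Re-apply a growth history from its seed graph; returns the final graph."""
    g = new_graph(history.seed_edges, nodes=history.seed_nodes)
    for ev in history.events:
        g.add_node(ev.arriving)
        for a, b in ev.edges_added:
            if a == b or g.has_edge(a, b):
                raise GraphValidationError(f"invalid edge addition ({a!r}, {b!r})")
            g.add_edge(a, b)
        for a, b in ev.edges_removed:
            if not g.has_edge(a, b):
                raise GraphValidationError(f"cannot remove missing edge ({a!r}, {b!r})")
            g.remove_edge(a, b)
        if ev.deleted_node is not None:
            if ev.deleted_node not in g:
                raise GraphValidationError(f"cannot delete missing node {ev.deleted_node!r}")
            g.remove_node(ev.deleted_node)
    return g


@dataclass
class ReverseEvent:
    """One reverse step: removal of the inferred most-recent arrival.

    ``anchor`` is the inferred duplication partner (the kept node for DMC
    merges, the fire anchor for FF); ``None`` for PA.  ``fallback`` marks
    steps where no candidate had positive likelihood and a random removal
    was used instead.  ``removed_edges`` are the edges incident to the
    removed node at removal time; ``edges_added_to_predecessor`` are edges
    the kept node gained in the inferred ancestor (DMC merges only).
    """

    removed: str
    anchor: str | None
    log_likelihood: float
    fallback: bool = False
    removed_edges: list[tuple[str, str]] = field(default_factory=list)
    edges_added_to_predecessor: list[tuple[str, str]] = field(default_factory=list)


@dataclass
class ReconstructionResult:
    """Ordered reverse record produced by the greedy reversal engine."""

    events: list[ReverseEvent]
    root: str
    model: str = ""
    params: dict = field(default_factory=dict)
    ancestral_edges: set[frozenset] = field(default_factory=set)
    snapshots: dict[int, LabeledGraph] = field(default_factory=dict)

    def node_set(self) -> set[str]:
        return {self.root} | {e.removed for e in self.events}

    def arrival_order(self) -> list[str]:
        """Inferred arrival order, oldest first (later-removed = older)."""
        return [self.root] + [e.removed for e in reversed(self.events)]


# ---------------------------------------------------------------------------
# Anchor trees
# ---------------------------------------------------------------------------


class AnchorTree:
    """Rooted binary tree over extant node labels.

    A node is either a leaf (``label`` set) or an internal node with
    exactly two ``children``.  Internal nodes are duplication/merge events.
    """

    __slots__ = ("label", "children")

    def __init__(self, label: str | None = None,
                 children: tuple["AnchorTree", "AnchorTree"] | None = None):
        if (label is None) == (children is None):
            raise GraphValidationError("an AnchorTree node is a leaf xor an internal node")
        if children is not None and len(children) != 2:
            raise GraphValidationError("internal nodes must have exactly two children")
        self.label = label
        self.children = children

    @property
    def is_leaf(self) -> bool:
        return self.label is not None

    def leaves(self) -> frozenset:
        """Leaf label set under this node (iterative; trees can be deep)."""
        out, stack = [], [self]
        while stack:
            t = stack.pop()
            if t.is_leaf:
                out.append(t.label)
            else:
                stack.extend(t.children)
        labels = frozenset(out)
        if len(labels) != len(out):
            raise GraphValidationError("duplicate leaf labels in anchor tree")
        return labels

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"AnchorTree<{len(self.leaves())} leaves>"


def clades(tree: AnchorTree) -> set[frozenset]:
    """Leaf sets under each internal node (root included, singletons excluded)."""
    out: set[frozenset] = set()
    # Post-order accumulation of leaf sets without recursion.
    sets: dict[int, frozenset] = {}
    stack: list[tuple[AnchorTree, bool]] = [(tree, False)]
    while stack:
        node, expanded = stack.pop()
        if node.is_leaf:
            sets[id(node)] = frozenset([node.label])
        elif not expanded:
            stack.append((node, True))
            stack.extend((c, False) for c in node.children)
        else:
            left, right = (sets[id(c)] for c in node.children)
            if left & right:
                raise GraphValidationError("leaf label appears in both subtrees")
            s = left | right
            sets[id(node)] = s
            out.add(s)
    return out


def _merge_sequence(pairs: Sequence[tuple[str, str]], all_labels: Iterable[str]) -> AnchorTree:
    """Join leaf trees bottom-up: each (kept, removed) pair merges the two
    current subtrees under a new internal node owned by the kept label."""
    current = {lab: AnchorTree(label=lab) for lab in all_labels}
    root_key = None
    for kept, removed in pairs:
        if kept not in current or removed not in current:
            raise GraphValidationError(f"unknown label in merge ({kept!r}, {removed!r})")
        current[kept] = AnchorTree(children=(current[kept], current[removed]))
        del current[removed]
        root_key = kept
    if len(current) != 1:
        raise GraphValidationError(
            f"merge sequence leaves {len(current)} trees; expected a single root")
    return current[root_key]


def build_anchor_tree(history: GrowthHistory | ReconstructionResult) -> AnchorTree:
    """Encode node/anchor relationships of a history as a binary tree.

    Forward histories are processed newest-arrival-first: each arrival
    joins the arriving node's current subtree under its anchor's, which is
    the bottom-up equivalent of splitting the anchor's leaf on arrival.
    Reverse histories join (anchor, removed) in removal order.  Models
    without anchors (PA) are unsupported.
    """
    if isinstance(history, GrowthHistory):
        if any(e.anchor is None for e in history.events):
            raise UnsupportedModelError("history has events without anchors (PA model?)")
        if len(history.seed_nodes) != 2:
            raise UnsupportedModelError(
                "anchor trees require a two-node seed; clique-seeded (PA) histories "
                "carry no anchor information")
        labels = history.arrival_order()
        pairs = [(e.anchor, e.arriving) for e in reversed(history.events)]
        # The two seed nodes form the final (oldest) cherry.
        pairs.append((history.seed_nodes[0], history.seed_nodes[1]))
        return _merge_sequence(pairs, labels)
    if isinstance(history, ReconstructionResult):
        if any(e.anchor is None for e in history.events):
            raise UnsupportedModelError("reconstruction has events without anchors (PA model?)")
        labels = history.node_set()
        pairs = [(e.anchor, e.removed) for e in history.events]
        return _merge_sequence(pairs, labels)
    raise TypeError(f"cannot build an anchor tree from {type(history).__name__}")


def restrict_tree(tree: AnchorTree, keep: Iterable[str]) -> AnchorTree:
    """Prune leaves outside ``keep``, suppressing unary internal nodes.

    Needed when comparing trees from node-deletion runs, where the true
    tree contains leaves for nodes that no longer exist.
    """
    keep = set(keep)

    def prune(node: AnchorTree) -> AnchorTree | None:
        if node.is_leaf:
            return node if node.label in keep else None
        kids = [c for c in map(prune, node.children) if c is not None]
        if len(kids) == 2:
            return AnchorTree(children=(kids[0], kids[1]))
        if len(kids) == 1:
            return kids[0]
        return None

    out = prune(tree)
    if out is None:
        raise GraphValidationError("restriction removed every leaf")
    return out


def to_newick(tree: AnchorTree) -> str:
    """Render a tree as a Newick string (no branch lengths)."""

    def quote(label: str) -> str:
        if any(c in label for c in "()[]{}:;,'\t\n ") or label == "":
            return "'" + label.replace("'", "''") + "'"
        return label

    parts: list[str] = []
    # Iterative post-order rendering.
    rendered: dict[int, str] = {}
    stack: list[tuple[AnchorTree, bool]] = [(tree, False)]
    while stack:
        node, expanded = stack.pop()
        if node.is_leaf:
            rendered[id(node)] = quote(node.label)
        elif not expanded:
            stack.append((node, True))
            stack.extend((c, False) for c in node.children)
        else:
            a, b = (rendered[id(c)] for c in node.children)
            rendered[id(node)] = f"({a},{b})"
    parts.append(rendered[id(tree)])
    return "".join(parts) + ";"


def total_clade_count(tree: AnchorTree) -> int:
    """Number of internal nodes = number of clades for a binary tree."""
    return len(clades(tree))
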