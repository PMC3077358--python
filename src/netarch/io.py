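"""Readers and writers for the package's text formats.

Formats (all line-oriented, deterministic output):

* **Edge list** — one edge per line, two whitespace-separated labels.
  Lines starting with ``#`` are comments, except the directive
  ``#node <label>`` which declares an isolated node (needed after
  node deletion or noise).  Blank lines are ignored.  Self-loops and
  duplicate edges are rejected with the offending line number.
* **History TSV** — one growth or reverse event per line with columns
  ``step``, ``node``, ``anchor`` (``-`` if none), ``log-likelihood``
  (``-`` if not applicable) and semicolon-separated edge changes
  (``+u,v`` added, ``-u,v`` removed, ``!w`` node deleted).  Header
  comment lines carry the kind (growth/reconstruction), model, params
  (JSON), and the seed graph or root.
* **Newick** — anchor trees with quoted labels where needed, no branch
  lengths.

Every reader/writer pair is a semantic round trip: graphs come back with
identical labels and edges, trees with identical clade sets, histories
with identical replays.  Labels may not contain whitespace or the
delimiter characters ``, ; ' " #``.
"""

from __future__ import annotations

import json
from pathlib import Path

from .graph_core import (
    AnchorTree,
    ForwardEvent,
    GraphValidationError,
    GrowthHistory,
    LabeledGraph,
    ReconstructionResult,
    ReverseEvent,
    new_graph,
    to_newick,
    validate_graph,
)

__all__ = [
    "read_edge_list",
    "write_edge_list",
    "read_history",
    "write_history",
    "read_newick",
    "write_newick",
    "read_class_map",
    "read_annotations",
]

_FORBIDDEN = set(" \t\n,;'\"#")


def _check_label(label: str) -> str:
    if not label or any(c in _FORBIDDEN for c in label):
        raise GraphValidationError(
            f"label {label!r} is empty or contains whitespace or a delimiter "
            "character (one of , ; ' \" #), which the text formats cannot carry")
    return label


# ---------------------------------------------------------------------------
# Edge lists
# ---------------------------------------------------------------------------


def read_edge_list(path) -> LabeledGraph:
    """Parse an edge-list file; see the module docstring for the dialect."""
    g = new_graph()
    text = Path(path).read_text()
    for ln, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            parts = line[1:].split()
            if parts and parts[0] == "node":
                if len(parts) != 2:
                    raise GraphValidationError(
                        f"{path}:{ln}: '#node' directive needs exactly one label")
                g.add_node(parts[1])
            continue
        parts = line.split()
        if len(parts) != 2:
            raise GraphValidationError(
                f"{path}:{ln}: expected two whitespace-separated labels, "
                f"got {len(parts)}")
        a, b = parts
        if a == b:
            raise GraphValidationError(f"{path}:{ln}: self-loop on node {a!r}")
        if g.has_edge(a, b):
            raise GraphValidationError(f"{path}:{ln}: duplicate edge ({a!r}, {b!r})")
        g.add_edge(a, b)
    return g


def write_edge_list(g: LabeledGraph, path) -> None:
    """Write a graph deterministically: sorted edges, then isolated nodes."""
    validate_graph(g)
    for v in g.nodes:
        _check_label(v)
    lines = [f"{a}\t{b}" for a, b in sorted(tuple(sorted(e)) for e in g.edges)]
    lines.extend(f"#node {v}" for v in sorted(g.nodes) if g.degree(v) == 0)
    Path(path).write_text("\n".join(lines) + "\n" if lines else "")


# ---------------------------------------------------------------------------
# Histories
# ---------------------------------------------------------------------------


def _fmt_changes(added, removed, deleted=None) -> str:
    items = [f"+{a},{b}" for a, b in added]
    items += [f"-{a},{b}" for a, b in removed]
    if deleted is not None:
        items.append(f"!{deleted}")
    return ";".join(items) if items else "-"


def _parse_changes(field: str, where: str):
    added, removed, deleted = [], [], None
    if field == "-":
        return added, removed, deleted
    for item in field.split(";"):
        if item.startswith("!"):
            deleted = item[1:]
            continue
        if len(item) < 2 or item[0] not in "+-" or "," not in item:
            raise GraphValidationError(f"{where}: malformed edge change {item!r}")
        a, b = item[1:].split(",", 1)
        (added if item[0] == "+" else removed).append((a, b))
    return added, removed, deleted


def _fmt_loglik(x: float) -> str:
    return "-inf" if x == float("-inf") else repr(float(x))


def write_history(history: GrowthHistory | ReconstructionResult, path) -> None:
    """Serialize a history as line-oriented TSV (see module docstring).

    Snapshots of a reconstruction are not serialized; everything else
    round-trips (ancestral edges are recomputed on read).
    """
    lines = []
    if isinstance(history, GrowthHistory):
        for v in history.arrival_order():
            _check_label(v)
        lines.append("#kind growth")
        lines.append(f"#model {history.model}")
        lines.append(f"#params {json.dumps(history.params, sort_keys=True)}")
        lines.append("#seed-nodes " + " ".join(history.seed_nodes))
        for a, b in history.seed_edges:
            lines.append(f"#seed-edge {a} {b}")
        for step, ev in enumerate(history.events):
            lines.append("\t".join([
                str(step), ev.arriving, ev.anchor if ev.anchor else "-", "-",
                _fmt_changes(ev.edges_added, ev.edges_removed, ev.deleted_node)]))
    elif isinstance(history, ReconstructionResult):
        for v in history.node_set():
            _check_label(v)
        lines.append("#kind reconstruction")
        lines.append(f"#model {history.model}")
        lines.append(f"#params {json.dumps(history.params, sort_keys=True)}")
        lines.append(f"#root {history.root}")
        for step, ev in enumerate(history.events):
            lines.append("\t".join([
                str(step), ev.removed, ev.anchor if ev.anchor else "-",
                _fmt_loglik(ev.log_likelihood),
                _fmt_changes(ev.edges_added_to_predecessor, ev.removed_edges)]))
    else:
        raise TypeError(f"cannot serialize {type(history).__name__}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_history(path) -> GrowthHistory | ReconstructionResult:
    """Parse a history TSV; the ``#kind`` header selects the result type."""
    meta: dict[str, str] = {}
    seed_nodes: list[str] = []
    seed_edges: list[tuple[str, str]] = []
    rows: list[tuple[int, list[str]]] = []
    for ln, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.rstrip("\n")
        if not line.strip():
            continue
        if line.startswith("#"):
            parts = line[1:].split(None, 1)
            key = parts[0]
            val = parts[1] if len(parts) > 1 else ""
            if key == "seed-nodes":
                seed_nodes = val.split()
            elif key == "seed-edge":
                a, b = val.split()
                seed_edges.append((a, b))
            else:
                meta[key] = val
            continue
        fields = line.split("\t")
        if len(fields) != 5:
            raise GraphValidationError(f"{path}:{ln}: expected 5 tab-separated "
                                       f"columns, got {len(fields)}")
        rows.append((ln, fields))
    kind = meta.get("kind")
    model = meta.get("model", "")
    params = json.loads(meta["params"]) if "params" in meta else {}
    if kind == "growth":
        events = []
        for ln, (_, node, anchor, _lik, changes) in rows:
            added, removed, deleted = _parse_changes(changes, f"{path}:{ln}")
            events.append(ForwardEvent(node, None if anchor == "-" else anchor,
                                       added, removed, deleted))
        return GrowthHistory(seed_nodes, seed_edges, events, model, params)
    if kind == "reconstruction":
        if "root" not in meta:
            raise GraphValidationError(f"{path}: reconstruction without a #root line")
        events = []
        for ln, (_, node, anchor, lik, changes) in rows:
            gained, removed_edges, _ = _parse_changes(changes, f"{path}:{ln}")
            loglik = float("-inf") if lik == "-inf" else float(lik)
            events.append(ReverseEvent(node, None if anchor == "-" else anchor,
                                       loglik, fallback=(loglik == float("-inf")),
                                       removed_edges=removed_edges,
                                       edges_added_to_predecessor=gained))
        result = ReconstructionResult(events, meta["root"], model, params)
        result.ancestral_edges = _recompute_ancestral(result)
        return result
    raise GraphValidationError(f"{path}: missing or unknown '#kind' header {kind!r}")


def _recompute_ancestral(result: ReconstructionResult) -> set[frozenset]:
    """Ancestral edges = edges gained by predecessors minus extant edges,
    where the extant graph is the forward replay of the reconstruction."""
    import networkx as nx

    g = nx.Graph()
    g.add_node(result.root)
    gained: set[frozenset] = set()
    for ev in reversed(result.events):
        for e in ev.edges_added_to_predecessor:
            gained.add(frozenset(e))
            g.remove_edge(*e)
        g.add_node(ev.removed)
        g.add_edges_from(ev.removed_edges)
    return gained - {frozenset(e) for e in g.edges}


# ---------------------------------------------------------------------------
# Newick trees
# ---------------------------------------------------------------------------


def write_newick(tree: AnchorTree, path) -> None:
    """Write an anchor tree as a Newick string (no branch lengths)."""
    Path(path).write_text(to_newick(tree) + "\n")


def read_newick(text_or_path) -> AnchorTree:
    """Parse a binary Newick string (or file) back into an :class:`AnchorTree`.

    Supports the subset :func:`write_newick` emits: binary topology, quoted
    or plain leaf labels, no branch lengths or internal labels.
    """
    p = Path(str(text_or_path))
    text = p.read_text() if p.is_file() else str(text_or_path)
    s = text.strip()
    if not s.endswith(";"):
        raise GraphValidationError("Newick string must end with ';'")
    s = s[:-1]
    pos = 0

    def parse() -> AnchorTree:
        nonlocal pos
        if pos >= len(s):
            raise GraphValidationError("unexpected end of Newick string")
        if s[pos] == "(":
            pos += 1
            left = parse()
            if pos >= len(s) or s[pos] != ",":
                raise GraphValidationError(f"expected ',' at position {pos}")
            pos += 1
            right = parse()
            if pos >= len(s) or s[pos] != ")":
                raise GraphValidationError(f"expected ')' at position {pos}")
            pos += 1
            return AnchorTree(children=(left, right))
        if s[pos] == "'":
            pos += 1
            out = []
            while pos < len(s):
                if s[pos] == "'":
                    if pos + 1 < len(s) and s[pos + 1] == "'":  # escaped quote
                        out.append("'")
                        pos += 2
                        continue
                    pos += 1
                    return AnchorTree(label="".join(out))
                out.append(s[pos])
                pos += 1
            raise GraphValidationError("unterminated quoted label")
        start = pos
        while pos < len(s) and s[pos] not in "(),":
            pos += 1
        label = s[start:pos]
        if not label:
            raise GraphValidationError(f"empty label at position {start}")
        return AnchorTree(label=label)

    tree = parse()
    if pos != len(s):
        raise GraphValidationError(f"trailing characters after position {pos}")
    return tree


# ---------------------------------------------------------------------------
# Annotation tables
# ---------------------------------------------------------------------------


def read_class_map(path) -> dict[str, int]:
    """Node age classes: one ``label<TAB>integer-class`` per line
    ('#' comments and blank lines ignored); larger class = older."""
    out: dict[str, int] = {}
    for ln, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t") if "\t" in line else line.split()
        if len(parts) != 2:
            raise GraphValidationError(f"{path}:{ln}: expected 'label<TAB>class'")
        try:
            out[parts[0]] = int(parts[1])
        except ValueError:
            raise GraphValidationError(
                f"{path}:{ln}: class {parts[1]!r} is not an integer") from None
    return out


def read_annotations(path) -> dict[str, set]:
    """Functional labels: one ``label<TAB>comma-separated-annotations`` per
    line ('#' comments and blank lines ignored)."""
    out: dict[str, set] = {}
    for ln, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t") if "\t" in line else line.split(None, 1)
        if len(parts) != 2:
            raise GraphValidationError(
                f"{path}:{ln}: expected 'label<TAB>annotation[,annotation...]'")
        labels = {a.strip() for a in parts[1].split(",") if a.strip()}
        if not labels:
            raise GraphValidationError(f"{path}:{ln}: empty annotation set")
        out[parts[0]] = labels
    return out
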