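import pytest

from netarch import (
    AnchorTree,
    ForwardEvent,
    GraphValidationError,
    GrowthHistory,
    ReconstructionResult,
    ReverseEvent,
    UnsupportedModelError,
    build_anchor_tree,
    clades,
    new_graph,
    replay_history,
    restrict_tree,
    to_newick,
    validate_graph,
)
from netarch.graph_core import total_clade_count


def test_new_graph_rejects_self_loop():
    with pytest.raises(GraphValidationError):
        new_graph([("a", "a")])


def test_new_graph_rejects_duplicate_edge():
    with pytest.raises(GraphValidationError):
        new_graph([("a", "b"), ("b", "a")])


def test_new_graph_isolated_nodes():
    g = new_graph([("a", "b")], nodes=["c"])
    assert set(g.nodes) == {"a", "b", "c"}
    assert g.degree("c") == 0


def test_validate_graph_rejects_directed():
    import networkx as nx

    with pytest.raises(GraphValidationError):
        validate_graph(nx.DiGraph())


def test_replay_simple_history():
    h = GrowthHistory(["n0", "n1"], [("n0", "n1")],
                      [ForwardEvent("n2", "n0", [("n2", "n1"), ("n0", "n2")])])
    g = replay_history(h)
    assert sorted(map(tuple, map(sorted, g.edges))) == [
        ("n0", "n1"), ("n0", "n2"), ("n1", "n2")]


def test_replay_with_deletion():
    h = GrowthHistory(["n0", "n1"], [("n0", "n1")],
                      [ForwardEvent("n2", "n0", [("n2", "n1")],
                                    deleted_node="n0")])
    g = replay_history(h)
    assert set(g.nodes) == {"n1", "n2"}
    assert g.has_edge("n1", "n2")


def test_replay_rejects_removing_missing_edge():
    h = GrowthHistory(["n0", "n1"], [("n0", "n1")],
                      [ForwardEvent("n2", "n0", [], [("n2", "n1")])])
    with pytest.raises(GraphValidationError):
        replay_history(h)


def test_anchor_tree_leaf_xor_internal():
    with pytest.raises(GraphValidationError):
        AnchorTree()
    with pytest.raises(GraphValidationError):
        AnchorTree(label="a", children=(AnchorTree(label="b"),
                                        AnchorTree(label="c")))


def test_cherry_tree_from_single_event_history():
    # 2-node seed, one arrival anchored at n1 -> ((n0,n1),n2) shape
    h = GrowthHistory(["n0", "n1"], [("n0", "n1")],
                      [ForwardEvent("n2", "n1", [("n2", "n0")])])
    t = build_anchor_tree(h)
    assert t.leaves() == frozenset({"n0", "n1", "n2"})
    assert clades(t) == {frozenset({"n1", "n2"}),
                         frozenset({"n0", "n1", "n2"})}


def test_forward_tree_clades_worked_example():
    # arrivals: 2<-1, 3<-1, 4<-3, 5<-2 from seed (0, 1)
    evs = [ForwardEvent("2", "1", []), ForwardEvent("3", "1", []),
           ForwardEvent("4", "3", []), ForwardEvent("5", "2", [])]
    t = build_anchor_tree(GrowthHistory(["0", "1"], [("0", "1")], evs))
    got = clades(t)
    assert frozenset({"3", "4"}) in got
    assert frozenset({"1", "3", "4"}) in got
    assert frozenset({"2", "5"}) in got
    assert frozenset({"0", "1", "2", "3", "4", "5"}) in got
    assert len(got) == 5  # binary tree over 6 leaves


def test_forward_and_exact_reverse_trees_match():
    evs = [ForwardEvent("2", "1", []), ForwardEvent("3", "1", []),
           ForwardEvent("4", "3", []), ForwardEvent("5", "2", [])]
    h = GrowthHistory(["0", "1"], [("0", "1")], evs)
    # exactly-correct reverse: remove newest first with its true anchor,
    # finishing with the seed cherry
    rev_events = [ReverseEvent("5", "2", 0.0), ReverseEvent("4", "3", 0.0),
                  ReverseEvent("3", "1", 0.0), ReverseEvent("2", "1", 0.0),
                  ReverseEvent("1", "0", 0.0)]
    r = ReconstructionResult(rev_events, "0")
    assert clades(build_anchor_tree(h)) == clades(build_anchor_tree(r))
    assert r.arrival_order() == ["0", "1", "2", "3", "4", "5"]


def test_build_anchor_tree_rejects_pa():
    h = GrowthHistory(["n0", "n1"], [("n0", "n1")],
                      [ForwardEvent("n2", None, [("n2", "n0")])])
    with pytest.raises(UnsupportedModelError):
        build_anchor_tree(h)


def test_restrict_tree_suppresses_unary():
    t = AnchorTree(children=(
        AnchorTree(children=(AnchorTree(label="a"), AnchorTree(label="b"))),
        AnchorTree(label="c")))
    r = restrict_tree(t, {"a", "c"})
    assert r.leaves() == frozenset({"a", "c"})
    assert clades(r) == {frozenset({"a", "c"})}
    with pytest.raises(GraphValidationError):
        restrict_tree(t, set())


def test_to_newick_cherry_and_quoting():
    t = AnchorTree(children=(AnchorTree(label="a"), AnchorTree(label="b")))
    assert to_newick(t) == "(a,b);"
    q = AnchorTree(children=(AnchorTree(label="a b"), AnchorTree(label="c's")))
    assert to_newick(q) == "('a b','c''s');"


def test_total_clade_count():
    t = AnchorTree(children=(
        AnchorTree(children=(AnchorTree(label="a"), AnchorTree(label="b"))),
        AnchorTree(label="c")))
    assert total_clade_count(t) == 2
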