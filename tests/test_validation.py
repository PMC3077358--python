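import math

import numpy as np
import pytest

from netarch import (
    AnchorTree,
    DMCParams,
    ReconstructionResult,
    ReverseEvent,
    anchor_pair_annotation_agreement,
    anchor_similarity,
    build_anchor_tree,
    class_kendall,
    edge_arrival_stamps,
    edge_arrival_summary,
    footrule,
    grow_dmc,
    kendall_tau,
    network_stats,
    new_graph,
    restrict_order,
    reverse,
)

ORDER = [f"n{i}" for i in range(6)]


def test_kendall_identical_and_reversed():
    assert kendall_tau(ORDER, ORDER) == 1.0
    assert kendall_tau(ORDER, ORDER[::-1]) == -1.0


def test_footrule_identical_and_reversed():
    assert footrule(ORDER, ORDER) == 1.0
    # exactly opposite orders displace sum = floor(n^2/2) for even n
    assert footrule(ORDER, ORDER[::-1]) == 0.0


def test_footrule_hand_example():
    truth = ["a", "b", "c", "d"]
    pred = ["b", "a", "c", "d"]  # displacement 1+1 = 2; max = 8
    assert footrule(truth, pred) == pytest.approx(1 - 2 / 8)


def test_rank_measures_require_same_node_set():
    with pytest.raises(ValueError):
        kendall_tau(["a", "b"], ["a", "c"])
    with pytest.raises(ValueError):
        footrule(["a", "b"], ["b", "c"])
    with pytest.raises(ValueError):
        kendall_tau(["a", "a"], ["a", "a"])


def test_restrict_order():
    assert restrict_order(ORDER, {"n4", "n1"}) == ["n1", "n4"]


def test_anchor_similarity_self_is_100(grown):
    g, h, model = grown
    if model == "pa":
        return  # PA carries no anchors
    t = build_anchor_tree(h)
    assert anchor_similarity(t, t) == 100.0


def test_anchor_similarity_partial():
    # ((a,b),(c,d)) vs ((a,c),(b,d)): only the root clade is shared -> 1/3
    ab = AnchorTree(children=(AnchorTree(label="a"), AnchorTree(label="b")))
    cd = AnchorTree(children=(AnchorTree(label="c"), AnchorTree(label="d")))
    t1 = AnchorTree(children=(ab, cd))
    ac = AnchorTree(children=(AnchorTree(label="a"), AnchorTree(label="c")))
    bd = AnchorTree(children=(AnchorTree(label="b"), AnchorTree(label="d")))
    t2 = AnchorTree(children=(ac, bd))
    assert anchor_similarity(t1, t2) == pytest.approx(100 / 3)
    with pytest.raises(ValueError):
        anchor_similarity(t1, ab)


def test_class_kendall_oracle():
    # classes: larger = older.  prediction lists oldest first.
    classes = {"a": 3, "b": 2, "c": 1}
    assert class_kendall(["a", "b", "c"], classes) == 1.0
    assert class_kendall(["c", "b", "a"], classes) == -1.0
    # one same-class pair is ignored
    classes2 = {"a": 2, "b": 1, "c": 1}
    assert class_kendall(["b", "a", "c"], classes2) == pytest.approx(0.0)
    with pytest.raises(ValueError):
        class_kendall(["a", "b"], {"a": 1, "b": 1})


def test_random_order_baselines_monte_carlo():
    """Methods baselines: over random permutations at n=100, mean Kendall
    tends to 0.00 and mean normalized footrule to 1/3."""
    rng = np.random.default_rng(123)
    n = 100
    base = [f"n{i}" for i in range(n)]
    taus, foots = [], []
    for _ in range(2000):
        perm = [base[i] for i in rng.permutation(n)]
        taus.append(kendall_tau(base, perm))
        foots.append(footrule(base, perm))
    assert abs(np.mean(taus)) < 0.01
    assert abs(np.mean(foots) - 1 / 3) < 0.01


def _toy_reconstruction():
    # forward: root a; b arrives on a; c arrives on b (edge to a too);
    # reverse order: c (anchor b), b (anchor a)
    events = [
        ReverseEvent("c", "b", -0.1, removed_edges=[("c", "a"), ("c", "b")],
                     edges_added_to_predecessor=[]),
        ReverseEvent("b", "a", -0.2, removed_edges=[("b", "a")],
                     edges_added_to_predecessor=[]),
    ]
    return ReconstructionResult(events, "a", "ff", {})


def test_edge_arrival_stamps_toy():
    stamps, g = edge_arrival_stamps(_toy_reconstruction())
    assert set(g.nodes) == {"a", "b", "c"}
    assert stamps[frozenset(("a", "b"))] == 1
    assert stamps[frozenset(("a", "c"))] == 2
    assert stamps[frozenset(("b", "c"))] == 2


def test_edge_arrival_summary_toy():
    labels = {"a": {"x"}, "b": {"x"}, "c": {"y"}}
    s = edge_arrival_summary(_toy_reconstruction(), labels, k=1)
    # oldest edge (a,b) shares 'x'; newest (one of the step-2 edges) does not
    assert s.oldest_fraction == 1.0
    assert s.newest_fraction == 0.0
    assert s.extant_baseline == pytest.approx(1 / 3)
    assert math.isnan(s.ancestral_fraction)  # no ancestral edges inferred
    with pytest.raises(ValueError):
        edge_arrival_summary(_toy_reconstruction(), labels, k=10)
    with pytest.raises(ValueError):
        edge_arrival_summary(_toy_reconstruction(), {}, k=1)


def test_edge_arrival_stamps_respects_dmc_merges():
    # stamps must replay gained-edge removals; run on a real DMC reversal
    g, _ = grow_dmc(25, DMCParams(0.3, 0.7), 19)
    r = reverse(g, "dmc", DMCParams(0.3, 0.7), 5)
    stamps, replayed = edge_arrival_stamps(r)
    assert {frozenset(e) for e in replayed.edges} == {frozenset(e) for e in g.edges}
    assert set(stamps) == {frozenset(e) for e in g.edges}


def test_annotation_agreement():
    g = new_graph([("a", "b"), ("b", "c")])
    labels = {"a": {"x"}, "b": {"x"}, "c": {"y"}}
    r = ReconstructionResult(
        [ReverseEvent("c", "b", -0.1), ReverseEvent("b", "a", -0.2)], "a")
    agg = anchor_pair_annotation_agreement(r, labels, g)
    assert agg.n_pairs == 2
    assert agg.pair_fraction == pytest.approx(0.5)   # (b,a) share, (c,b) don't
    assert agg.edge_baseline == pytest.approx(0.5)
    with pytest.raises(ValueError):
        anchor_pair_annotation_agreement(r, {}, g)


def test_network_stats_known_graph():
    # path a-b-c: density 2/3, clustering 0, mean SPL (1+1+2)/3, cores all 1
    g = new_graph([("a", "b"), ("b", "c")])
    s = network_stats(g)
    assert s.density == pytest.approx(2 / 3)
    assert s.clustering == 0.0
    assert s.mean_shortest_path == pytest.approx(4 / 3)
    assert s.mean_core_number == 1.0
    with pytest.raises(ValueError):
        network_stats(new_graph())


def test_network_stats_disconnected():
    g = new_graph([("a", "b")], nodes=["z"])
    s = network_stats(g)
    assert s.mean_shortest_path == 1.0  # only the connected pair counts
    assert s.mean_core_number == pytest.approx(2 / 3)
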