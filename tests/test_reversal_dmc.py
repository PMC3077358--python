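import math

import numpy as np
import pytest

from netarch import (
    NEG_INF,
    DMCParams,
    DMCScoreTable,
    FFParams,
    PAParams,
    apply_dmc_merge,
    dmc_pair_score,
    grow_dmc,
    grow_ff,
    grow_pa,
    new_graph,
    reverse,
    total_log_likelihood,
)

P = DMCParams(0.1, 0.9)


def test_pair_score_triangle_oracle(triangle):
    # adjacent pair with one common neighbor, no asymmetric neighbors:
    # 1/(N-1) * q_con * (1-q_mod)^1 = 0.5 * 0.9 * 0.9 = 0.405
    assert dmc_pair_score(triangle, "u", "v", P) == pytest.approx(math.log(0.405))


def test_pair_score_path_oracle(path3):
    # adjacent pair, zero common, one asymmetric neighbor:
    # 0.5 * 0.9 * (0.1/2)^1 = 0.0225
    assert dmc_pair_score(path3, "u", "v", P) == pytest.approx(math.log(0.0225))


def test_pair_score_symmetry_and_nonedge(triangle):
    assert dmc_pair_score(triangle, "u", "v", P) == \
        dmc_pair_score(triangle, "v", "u", P)
    g = new_graph([("u", "a"), ("a", "v")])
    # non-adjacent pair uses gamma = 1 - q_con
    expected = math.log(0.5 * 0.1 * 0.9)  # 1/(N-1)=0.5, 1-q_con=0.1, (1-q_mod)^1
    assert dmc_pair_score(g, "u", "v", P) == pytest.approx(expected)


def test_pair_score_neg_inf_sentinel():
    g = new_graph([("u", "v")])
    # q_con = 0 makes an adjacent pair impossible
    assert dmc_pair_score(g, "u", "v", DMCParams(0.5, 0.0)) == NEG_INF
    # q_mod = 0 makes any asymmetric neighbor impossible
    g2 = new_graph([("u", "v"), ("u", "a")])
    assert dmc_pair_score(g2, "u", "v", DMCParams(0.0, 0.9)) == NEG_INF


def test_pair_score_input_validation(triangle):
    with pytest.raises(ValueError):
        dmc_pair_score(triangle, "u", "u", P)
    with pytest.raises(ValueError):
        dmc_pair_score(triangle, "u", "zzz", P)


def test_apply_dmc_merge(triangle):
    triangle.add_edge("v", "w")
    pred, gained = apply_dmc_merge(triangle, "u", "v")
    assert "v" not in pred
    assert gained == [("u", "w")]
    assert pred.has_edge("u", "w") and pred.has_edge("u", "a")
    # original graph untouched
    assert "v" in triangle


def test_score_table_matches_reference(grown):
    g, _, _ = grown
    table = DMCScoreTable(g, P)
    ref = {frozenset((u, v)): dmc_pair_score(g, u, v, P)
           for i, u in enumerate(sorted(g.nodes))
           for v in sorted(g.nodes)[i + 1:]}
    got = table.as_dict()
    assert got.keys() == ref.keys()
    for k in ref:
        assert got[k] == pytest.approx(ref[k]), k


def test_score_table_incremental_equals_scratch(grown):
    """Criterion-6 property: the incrementally maintained table equals a
    from-scratch recomputation after every merge, on graphs from all
    simulators (<= 50 nodes)."""
    g, _, _ = grown
    rng = np.random.default_rng(77)
    table = DMCScoreTable(g, DMCParams(0.3, 0.7))
    current = g.copy()
    for _ in range(g.number_of_nodes() - 2):
        i, j, _ = table.best_pair(rng)
        keep, remove = (i, j) if rng.random() < 0.5 else (j, i)
        gained = table.merge(keep, remove)
        current.remove_node(table.labels[remove])
        current.add_edges_from((table.labels[a], table.labels[b])
                               for a, b in gained)
        scratch = DMCScoreTable(current, DMCParams(0.3, 0.7))
        inc = table.as_dict()
        ref = scratch.as_dict()
        assert inc.keys() == ref.keys()
        for k in ref:
            if ref[k] == NEG_INF:
                assert inc[k] == NEG_INF
            else:
                assert inc[k] == pytest.approx(ref[k], abs=1e-9), k


def test_reverse_dmc_reproducible_and_complete():
    g, _ = grow_dmc(40, P, 4)
    r1 = reverse(g, "dmc", P, 9)
    r2 = reverse(g, "dmc", P, 9)
    assert [e.removed for e in r1.events] == [e.removed for e in r2.events]
    assert [e.anchor for e in r1.events] == [e.anchor for e in r2.events]
    assert r1.node_set() == set(g.nodes)
    assert len(r1.events) == g.number_of_nodes() - 1
    # a different seed changes tie-breaking / keep-remove choices
    r3 = reverse(g, "dmc", P, 10)
    assert [e.removed for e in r3.events] != [e.removed for e in r1.events]


def test_reverse_clique_closed_form_likelihood():
    """DMC with q_mod=0, q_con=1 grows cliques; reversing a clique has a
    closed-form total likelihood: at size k every adjacent pair scores
    log(1/(k-1) * 1 * 1), so the greedy total is -log((N-1)!)."""
    params = DMCParams(0.0, 1.0)
    g, _ = grow_dmc(10, params, 6)
    n = g.number_of_nodes()
    assert g.number_of_edges() == n * (n - 1) // 2
    r = reverse(g, "dmc", params, 1)
    expected = -sum(math.log(k - 1) for k in range(2, n + 1))
    assert total_log_likelihood(r) == pytest.approx(expected)
    assert not any(e.fallback for e in r.events)


def test_reverse_dmc_ancestral_edges_disjoint_from_extant():
    g, _ = grow_dmc(40, DMCParams(0.3, 0.7), 8)
    r = reverse(g, "dmc", DMCParams(0.3, 0.7), 2)
    extant = {frozenset(e) for e in g.edges}
    assert not (r.ancestral_edges & extant)


def test_reverse_dmc_snapshots():
    g, _ = grow_dmc(30, P, 5)
    r = reverse(g, "dmc", P, 3, snapshot_sizes=[10, 20])
    assert set(r.snapshots) == {10, 20}
    assert r.snapshots[10].number_of_nodes() == 10
    assert set(r.snapshots[10].nodes) <= set(r.snapshots[20].nodes)


def test_reverse_random_policy_dmc_only():
    g, _ = grow_dmc(20, P, 5)
    r = reverse(g, "dmc", P, 3, policy="random")
    assert len(r.events) == g.number_of_nodes() - 1
    with pytest.raises(ValueError):
        reverse(g, "ff", FFParams(0.3), 3, policy="random")
    with pytest.raises(ValueError):
        reverse(g, "dmc", P, 3, policy="bogus")


def test_random_policy_likelihood_below_greedy():
    # the greedy reconstruction should out-score the random-merge null
    g, _ = grow_dmc(40, P, 14)
    greedy = total_log_likelihood(reverse(g, "dmc", P, 1))
    rand = total_log_likelihood(reverse(g, "dmc", P, 1, policy="random"))
    assert greedy > rand


def test_reverse_validates_inputs():
    with pytest.raises(ValueError):
        reverse(new_graph(nodes=["a"]), "dmc", P, 0)
    g = new_graph([("a", "b")])
    with pytest.raises(TypeError):
        reverse(g, "dmc", FFParams(0.3), 0)
    with pytest.raises(TypeError):
        reverse(g, "ff", P, 0)
    with pytest.raises(ValueError):
        reverse(g, "bogus", None, 0)
    with pytest.raises(ValueError):
        reverse(g, "pa", PAParams(2), 0, snapshot_sizes=None, policy="random")
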