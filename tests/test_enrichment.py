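"""Over-representation, topology impact and FDR adjustment."""

from math import comb

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from metabscreen.enrichment import (
    Pathway,
    PathwayDb,
    enrich,
    fdr_adjust,
    load_toy_pathway_db,
    ora_test,
    pathway_impact,
)


# ---------------------------------------------------------------- ORA


def test_ora_zero_hits_is_one():
    assert ora_test(0, 5, 5, 20) == 1.0


def test_ora_pathway_equals_universe_is_one():
    assert ora_test(5, 20, 5, 20) == pytest.approx(1.0)


def test_ora_matches_combinatorial_enumeration():
    """N=20, m=5, n=5, k=3: tail equals the exact sum of hypergeometric
    terms C(5,j) C(15,5-j) / C(20,5) for j >= 3."""
    expected = sum(comb(5, j) * comb(15, 5 - j) for j in range(3, 6)) / comb(20, 5)
    assert ora_test(3, 5, 5, 20) == pytest.approx(expected, rel=1e-12)


def test_ora_rejects_impossible_overlap():
    with pytest.raises(ValueError):
        ora_test(6, 5, 5, 20)


@settings(deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=4))
def test_ora_monotone_in_k(k):
    assert ora_test(k + 1, 5, 5, 20) <= ora_test(k, 5, 5, 20)


# ---------------------------------------------------------------- impact


def path_pathway():
    nodes = list("abcde")
    return Pathway(
        id="P", name="path", members=set(nodes),
        edges=[("a", "b"), ("b", "c"), ("c", "d"), ("d", "e")],
    )


def brute_force_betweenness(pw: Pathway) -> dict:
    """All-pairs shortest-path enumeration (O(V^3) Floyd-Warshall style)."""
    g = pw.graph()
    nodes = sorted(pw.members)
    bc = dict.fromkeys(nodes, 0.0)
    for s in nodes:
        for t in nodes:
            if s == t:
                continue
            try:
                paths = list(nx.all_shortest_paths(g, s, t))
            except nx.NetworkXNoPath:
                continue
            for node in nodes:
                if node in (s, t):
                    continue
                through = sum(node in p for p in paths)
                bc[node] += through / len(paths)
    return bc


def test_impact_no_hits_zero_and_all_hits_one():
    pw = path_pathway()
    assert pathway_impact([], pw) == 0.0
    assert pathway_impact(list("abcde"), pw) == pytest.approx(1.0)


def test_impact_matches_all_pairs_enumeration():
    pw = path_pathway()
    bc = brute_force_betweenness(pw)
    total = sum(bc.values())
    expected = bc["c"] / total
    assert pathway_impact({"c"}, pw) == pytest.approx(expected, rel=1e-12)
    # interior of a directed path concentrates centrality: c is maximal
    assert bc["c"] == max(bc.values())


def test_impact_on_random_graph_matches_enumeration():
    rng = np.random.default_rng(8)
    nodes = [f"n{i}" for i in range(8)]
    edges = [
        (a, b)
        for a in nodes
        for b in nodes
        if a != b and rng.random() < 0.25
    ]
    pw = Pathway(id="R", name="rand", members=set(nodes), edges=edges)
    bc = brute_force_betweenness(pw)
    total = sum(bc.values())
    hits = set(rng.choice(nodes, size=3, replace=False))
    expected = 0.0 if total == 0 else sum(bc[h] for h in hits) / total
    assert pathway_impact(hits, pw) == pytest.approx(expected, rel=1e-10)


def test_symmetrized_graph_equals_bidirectional_directed():
    nodes = list("abcdef")
    rng = np.random.default_rng(9)
    undirected = [(a, b) for i, a in enumerate(nodes) for b in nodes[i + 1:]
                  if rng.random() < 0.4]
    both = [(a, b) for a, b in undirected] + [(b, a) for a, b in undirected]
    pw = Pathway(id="U", name="sym", members=set(nodes), edges=both)
    g_und = nx.Graph(undirected)
    g_und.add_nodes_from(nodes)
    bc_und = nx.betweenness_centrality(g_und, normalized=False)
    total = sum(bc_und.values())
    hits = {"a", "c"}
    if total > 0:
        # undirected counts each pair once; the ratio is unchanged
        expected = sum(bc_und[h] for h in hits) / total
        assert pathway_impact(hits, pw) == pytest.approx(expected, rel=1e-10)


def test_edge_to_non_member_rejected():
    with pytest.raises(ValueError, match="non-member"):
        Pathway(id="X", name="bad", members={"a"}, edges=[("a", "z")])


# ---------------------------------------------------------------- FDR


def test_fdr_single_p_unchanged():
    assert fdr_adjust([0.03])[0] == pytest.approx(0.03)


def test_fdr_step_up_arithmetic():
    q = fdr_adjust([0.01, 0.02, 0.03, 0.04])
    np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.04], rtol=1e-12)


def test_fdr_all_ones_stay_one():
    np.testing.assert_allclose(fdr_adjust([1.0, 1.0, 1.0]), 1.0)


@settings(deadline=None, derandomize=True)
@given(st.lists(st.floats(min_value=0, max_value=1), min_size=2, max_size=30))
def test_fdr_preserves_p_value_ordering(ps):
    q = fdr_adjust(ps)
    order = np.argsort(ps)
    assert all(q[a] <= q[b] + 1e-12 for a, b in zip(order, order[1:]))
    assert (q <= 1.0 + 1e-12).all()


# ---------------------------------------------------------------- enrich


def test_enrich_planted_pathway_ranks_first():
    """80% of a 10-member pathway inside a 15-hit list (N=200): that
    pathway tops the ranking by p in >= 95% of seeds."""
    universe = [f"M{i:03d}" for i in range(200)]
    target = set(universe[:10])
    others = {
        f"P{j}": set(np.random.default_rng(j).choice(universe, 12, replace=False))
        for j in range(2, 8)
    }
    db = PathwayDb(
        pathways={
            "P1": Pathway(id="P1", name="target", members=target),
            **{
                k: Pathway(id=k, name=k, members=v) for k, v in others.items()
            },
        }
    )
    wins = 0
    n_seeds = 40
    for seed in range(n_seeds):
        rng = np.random.default_rng(1000 + seed)
        hits = set(rng.choice(sorted(target), 8, replace=False)) | set(
            rng.choice(universe[10:], 7, replace=False)
        )
        res = enrich(hits, db, universe)
        wins += res.iloc[0]["pathway_id"] == "P1"
    assert wins >= 0.95 * n_seeds


def test_enrich_null_calibration():
    """Uniformly random hit lists: ~5% of pathway tests fall below 0.05."""
    db = load_toy_pathway_db()
    universe = sorted(db.all_members())
    flags = total = 0
    for seed in range(200):
        rng = np.random.default_rng(seed)
        hits = rng.choice(universe, size=15, replace=False)
        res = enrich(hits, db, universe)
        flags += int((res["p_hyper"] < 0.05).sum())
        total += len(res)
    rate = flags / total
    # hypergeometric discreteness makes the test conservative; the rate
    # must sit near alpha and never above it by more than binomial noise
    assert rate < 0.05 + 3 * np.sqrt(0.05 * 0.95 / total)
    assert rate > 0.005


def test_enrich_ignores_pathways_outside_universe():
    db = PathwayDb(
        pathways={
            "IN": Pathway(id="IN", name="in", members={"a", "b", "c"}),
            "OUT": Pathway(id="OUT", name="out", members={"x", "y"}),
        }
    )
    res = enrich({"a"}, db, {"a", "b", "c", "d"})
    assert list(res["pathway_id"]) == ["IN"]


def test_toy_db_structure():
    db = load_toy_pathway_db()
    assert len(db) == 12
    for pw in db.pathways.values():
        assert 5 <= len(pw.members) <= 20
        for u, v in pw.edges:
            assert u in pw.members and v in pw.members
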