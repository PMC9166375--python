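"""Path enumeration against an exhaustive oracle; span filtering; merging."""

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from docsubre.corpus_io import ParsedSentence, Token
from docsubre.doc_graph import (SYNTACTIC, VIRTUAL, DocumentSubgraph,
                                GraphEdge, WindowSpec)
from docsubre.errors import DocsubreError
from docsubre.path_miner import (CID, Cooccurrence, Path, TraversedEdge,
                                 find_paths, merge_instances,
                                 minimal_span_filter, path_signature,
                                 select_top_k)


def _graph(n_nodes, edge_list):
    """edge_list: (u, v, category, label); nodes are (0, i)."""
    nodes = {(0, i) for i in range(n_nodes)}
    edges = [GraphEdge((0, u), (0, v), cat, lab, directed=(cat == SYNTACTIC))
             for u, v, cat, lab in edge_list]
    return DocumentSubgraph(WindowSpec(1, 1), nodes, edges)


def _oracle_paths(sub, source, target, md):
    """Independent enumerator: networkx simple edge paths with a length cap."""
    g = sub.to_networkx()
    out = []
    for ep in nx.all_simple_edge_paths(g, source, target, cutoff=md - 1):
        out.append(tuple([source] + [e[1] for e in ep]))
    return sorted(out)


def _random_graph(rng):
    n = int(rng.integers(2, 9))
    edges = []
    for u in range(n):
        for v in range(u + 1, n):
            if rng.random() < 0.45:
                cat = SYNTACTIC if rng.random() < 0.7 else VIRTUAL
                lab = ["amod", "nsubj", "dobj", "TITLE", "NEXT-SENT"][int(rng.integers(5))]
                edges.append((u, v, cat, lab))
    return _graph(n, edges), n


def test_adjacent_nodes_yield_single_edge_path_first():
    sub = _graph(3, [(0, 1, SYNTACTIC, "nsubj"), (1, 2, SYNTACTIC, "dobj"),
                     (0, 2, VIRTUAL, "TITLE")])
    paths = find_paths(sub, (0, 0), (0, 1), md=15, kmax=100)
    assert paths[0].nodes == ((0, 0), (0, 1))
    assert paths[0].edges[0].direction == "with"  # traversed head -> dependent


def test_find_paths_matches_exhaustive_oracle_on_random_graphs():
    rng = np.random.default_rng(7)
    for _ in range(60):
        sub, n = _random_graph(rng)
        src, tgt = (0, 0), (0, n - 1)
        got = sorted(p.nodes for p in find_paths(sub, src, tgt, md=15, kmax=10000))
        assert got == _oracle_paths(sub, src, tgt, 15)


def test_find_paths_ordering_is_bfs_with_lexicographic_ties():
    rng = np.random.default_rng(8)
    for _ in range(20):
        sub, n = _random_graph(rng)
        paths = find_paths(sub, (0, 0), (0, n - 1), md=15, kmax=10000)
        keys = [(len(p.nodes), p.nodes) for p in paths]
        assert keys == sorted(keys)


def test_find_paths_caps_at_kmax_with_prefix_stability():
    # complete graph on 7 nodes: far more than 150 simple paths
    edges = [(u, v, SYNTACTIC, "dep") for u in range(7) for v in range(u + 1, 7)]
    sub = _graph(7, edges)
    all_paths = find_paths(sub, (0, 0), (0, 6), md=15, kmax=100000)
    assert len(all_paths) > 150
    capped = find_paths(sub, (0, 0), (0, 6), md=15, kmax=150)
    assert len(capped) == 150
    assert [p.nodes for p in capped] == [p.nodes for p in all_paths[:150]]


def test_find_paths_enforces_md_node_bound():
    chain = [(i, i + 1, SYNTACTIC, "dep") for i in range(19)]
    sub = _graph(20, chain)
    assert find_paths(sub, (0, 0), (0, 19), md=15, kmax=10) == []
    assert len(find_paths(sub, (0, 0), (0, 14), md=15, kmax=10)) == 1
    rng = np.random.default_rng(9)
    for _ in range(20):
        sub, n = _random_graph(rng)
        for p in find_paths(sub, (0, 0), (0, n - 1), md=4, kmax=1000):
            assert len(p.nodes) <= 4
            assert all(x not in ((0, 0), (0, n - 1)) for x in p.nodes[1:-1])


def test_find_paths_degenerate_and_missing_nodes():
    sub = _graph(2, [(0, 1, SYNTACTIC, "dep")])
    with pytest.raises(DocsubreError, match="degenerate"):
        find_paths(sub, (0, 0), (0, 0))
    with pytest.raises(DocsubreError, match="not in subgraph"):
        find_paths(sub, (0, 0), (0, 9))


def _cooc(lo, hi):
    return Cooccurrence(0, 1, WindowSpec(1, 1), (lo, hi))


def test_minimal_span_filter_cases():
    assert minimal_span_filter([_cooc(1, 4)]) == [_cooc(1, 4)]
    kept = minimal_span_filter([_cooc(1, 4), _cooc(2, 3)])
    assert [c.span for c in kept] == [(2, 3)]
    kept = minimal_span_filter([_cooc(1, 2), _cooc(4, 5)])
    assert len(kept) == 2  # disjoint spans: rule is vacuous


@settings(max_examples=60, deadline=None, derandomize=True)
@given(st.lists(st.tuples(st.integers(0, 6), st.integers(0, 6)), min_size=1, max_size=8))
def test_minimal_span_filter_matches_pairwise_containment_oracle(raw):
    coocs = [_cooc(min(a, b), max(a, b)) for a, b in raw]
    spans = {c.span for c in coocs}
    expect = [c for c in coocs
              if not any(o != c.span and o[0] >= c.span[0] and o[1] <= c.span[1]
                         for o in spans)]
    assert minimal_span_filter(coocs) == expect


def _parses_for_merge():
    toks = [Token(s, "NN") for s in ("alpha", "beta", "gamma", "delta")]
    return [ParsedSentence(toks, [(0, 1, "dep"), (0, 2, "dep"), (0, 3, "dep")], 0)]


def _path(nodes, labels):
    return Path(tuple((0, i) for i in nodes),
                tuple(TraversedEdge(l, SYNTACTIC, "with") for l in labels))


def test_merge_collapses_identical_patterns_and_counts_multiplicity():
    parses = _parses_for_merge()
    p = _path([0, 1], ["dep"])
    inst = merge_instances("d", "C", "D", [p, p, p], parses, CID)
    assert len(inst.paths) == 1 and inst.multiplicities == [3]
    assert inst.label == CID
    # lexically distinct paths are both kept
    q = _path([0, 2], ["dep"])
    inst2 = merge_instances("d", "C", "D", [p, q], parses)
    assert len(inst2.paths) == 2 and inst2.multiplicities == [1, 1]


def test_merge_dedup_key_is_the_surface_pattern():
    # same surfaces at different node positions collapse too
    toks = [Token("x", "NN"), Token("y", "NN"), Token("x", "NN"), Token("y", "NN")]
    parses = [ParsedSentence(toks, [(0, 1, "dep"), (0, 2, "dep"), (0, 3, "dep")], 0)]
    a = _path([0, 1], ["dep"])
    b = _path([2, 3], ["dep"])
    assert path_signature(a, parses) == path_signature(b, parses)
    inst = merge_instances("d", "C", "D", [a, b], parses)
    assert len(inst.paths) == 1 and inst.multiplicities == [2]


def test_merge_is_idempotent():
    parses = _parses_for_merge()
    paths = [_path([0, 1], ["dep"]), _path([0, 2], ["dep"])]
    once = merge_instances("d", "C", "D", paths, parses)
    twice = merge_instances("d", "C", "D", once.paths, parses)
    assert twice.paths == once.paths
    assert twice.multiplicities == [1, 1]


def test_select_top_k_shortest_and_frequency_strategies():
    parses = [ParsedSentence([Token(f"t{i}", "NN") for i in range(7)],
                             [(0, i, "dep") for i in range(1, 7)], 0)]
    paths = [_path([0, 1, 2], ["dep"] * 2), _path([0, 3, 4], ["dep"] * 2),
             _path([0, 1, 2, 3], ["dep"] * 3), _path([0, 1, 2, 3, 4], ["dep"] * 4),
             _path([0, 1, 2, 3, 4, 5], ["dep"] * 5)]  # lengths 3,3,4,5,6
    inst = merge_instances("d", "C", "D", paths, parses)
    short = select_top_k(inst, 3, "shortest")
    assert sorted(len(p) for p in short.paths) == [3, 3, 4]
    # frequency strategy: multiplicities {4,2,2,1} -> the 4 plus one 2 by tie rule
    raw = [paths[0]] * 4 + [paths[2]] * 2 + [paths[3]] * 2 + [paths[4]]
    inst2 = merge_instances("d", "C", "D", raw, parses)
    freq = select_top_k(inst2, 2, "most_frequent")
    assert freq.multiplicities == [4, 2]
    assert len(freq.paths[1]) == 4  # tie between the 2s broken by shorter length


def test_select_top_k_keeps_all_when_fewer_and_is_identity_at_infinity():
    parses = _parses_for_merge()
    inst = merge_instances("d", "C", "D",
                           [_path([0, 1], ["dep"]), _path([0, 2], ["dep"])], parses)
    assert select_top_k(inst, 3).paths == inst.paths
    assert select_top_k(inst, 10**9).paths == inst.paths
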