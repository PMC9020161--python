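"""Pathway parsing, graph union, and shortest-path node enumeration."""

import networkx as nx
import numpy as np
import pytest

from ddnscreen import (
    PathwayParseError,
    PathwayRecord,
    build_ughp,
    parse_pathway_file,
    shortest_path_nodes,
)
from ddnscreen.synthetic import generate_pathways


def write(tmp_path, text, name="pw.tsv"):
    p = tmp_path / name
    p.write_text(text, encoding="utf-8")
    return p


class TestParseEdgeTsv:
    def test_reads_edges_back(self, tmp_path):
        p = write(tmp_path, "A\tB\t+1\nB\tC\t-1\n")
        rec = parse_pathway_file(p)
        assert rec.pathway_id == "pw"
        assert rec.edges == (("A", "B", 1), ("B", "C", -1))

    def test_duplicate_rows_collapse(self, tmp_path):
        p = write(tmp_path, "A\tB\t+1\nA\tB\t+1\n")
        assert len(parse_pathway_file(p).edges) == 1

    def test_comments_and_blank_lines_skipped(self, tmp_path):
        p = write(tmp_path, "# header\n\nA\tB\t1\n")
        assert len(parse_pathway_file(p).edges) == 1

    def test_bad_sign_names_line(self, tmp_path):
        p = write(tmp_path, "A\tB\t+1\nA\tB\t2\n")
        with pytest.raises(PathwayParseError, match=":2"):
            parse_pathway_file(p)

    def test_self_loops_dropped(self, tmp_path):
        p = write(tmp_path, "A\tA\t+1\nA\tB\t+1\n")
        assert parse_pathway_file(p).edges == (("A", "B", 1),)

    def test_empty_file_rejected(self, tmp_path):
        p = write(tmp_path, "# only comments\n")
        with pytest.raises(PathwayParseError):
            parse_pathway_file(p)

    def test_wrong_column_count_rejected(self, tmp_path):
        p = write(tmp_path, "A\tB\n")
        with pytest.raises(PathwayParseError, match=":1"):
            parse_pathway_file(p)


# hand-written synthetic KGML snippet (gene entries + one activation,
# one inhibition, one ignored binding relation)
_KGML = """<?xml version="1.0"?>
<pathway name="path:syn001" title="synthetic kgml fixture">
  <entry id="1" name="hsa:10" type="gene"/>
  <entry id="2" name="hsa:20" type="gene"/>
  <entry id="3" name="hsa:30" type="gene"/>
  <entry id="4" name="cpd:C00001" type="compound"/>
  <relation entry1="1" entry2="2" type="PPrel">
    <subtype name="activation" value="--&gt;"/>
  </relation>
  <relation entry1="2" entry2="3" type="PPrel">
    <subtype name="inhibition" value="--|"/>
  </relation>
  <relation entry1="1" entry2="4" type="PCrel">
    <subtype name="binding/association" value="---"/>
  </relation>
</pathway>
"""


def test_kgml_subset_reads_gene_relations_only(tmp_path):
    p = tmp_path / "syn001.xml"
    p.write_text(_KGML, encoding="utf-8")
    rec = parse_pathway_file(p, dialect="kgml_subset")
    assert rec.edges == (("hsa:10", "hsa:20", 1), ("hsa:20", "hsa:30", -1))
    assert rec.name == "synthetic kgml fixture"


def pw(pid, *edges):
    return PathwayRecord(pathway_id=pid, name=pid, edges=tuple(edges))


class TestBuildUghp:
    def test_disjoint_union(self):
        g = build_ughp([pw("p1", ("A", "B", 1)), pw("p2", ("B", "C", -1))])
        assert g.nodes == {"A", "B", "C"}
        assert g.n_edges == 2
        assert not g.conflict_edges

    def test_union_is_idempotent(self):
        g = build_ughp([pw("p1", ("A", "B", 1)), pw("p2", ("A", "B", 1))])
        assert g.n_nodes == 2 and g.n_edges == 1

    def test_sign_conflict_keeps_edge_with_plus_one(self):
        g = build_ughp([pw("p1", ("A", "B", 1)), pw("p2", ("A", "B", -1))])
        assert g.signed_adjacency[("A", "B")] == 1
        assert g.conflict_edges == {("A", "B")}

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            build_ughp([])

    def test_edge_count_bounded_by_sum_over_pathways(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            pathways = generate_pathways(
                n_genes=30, n_pathways=int(rng.integers(1, 5)),
                mean_edges=10, seed=int(rng.integers(1000)),
            )
            g = build_ughp(pathways)
            total = sum(len(p.edges) for p in pathways)
            assert g.n_edges <= total
            shared = total - len({(s, t) for p in pathways for s, t, _ in p.edges})
            if shared == 0:
                assert g.n_edges == total

    def test_export_roundtrips_through_parser(self, tmp_path):
        g = build_ughp([pw("p1", ("A", "B", 1), ("B", "C", -1))])
        out = tmp_path / "ughp.tsv"
        g.write_edge_tsv(out)
        lines = out.read_text().splitlines()
        assert lines[0] == "source\ttarget\tsign\tconflict"
        assert lines[1] == "A\tB\t1\t0"


class TestShortestPathNodes:
    def test_unique_chain(self):
        g = build_ughp([pw("p", ("A", "B", 1), ("B", "C", 1))])
        res = shortest_path_nodes(g, "A", "C", directed=True)
        assert res.nodes == {"A", "B", "C"} and res.reachable

    def test_diamond_unions_both_paths(self):
        g = build_ughp([pw("p", ("A", "B", 1), ("B", "D", 1), ("A", "C", 1), ("C", "D", 1))])
        assert shortest_path_nodes(g, "A", "D", directed=True).nodes == {"A", "B", "C", "D"}

    def test_longer_detour_excluded(self):
        # A->B->D is minimal; A->C->E->D is longer and must not contribute
        g = build_ughp([pw("p", ("A", "B", 1), ("B", "D", 1),
                           ("A", "C", 1), ("C", "E", 1), ("E", "D", 1))])
        assert shortest_path_nodes(g, "A", "D", directed=True).nodes == {"A", "B", "D"}

    def test_unreachable_returns_endpoints_flagged(self):
        g = build_ughp([pw("p", ("A", "B", 1), ("Y", "Z", 1))])
        res = shortest_path_nodes(g, "A", "Z", directed=True)
        assert res.nodes == {"A", "Z"} and not res.reachable

    def test_source_equals_target(self):
        g = build_ughp([pw("p", ("A", "B", 1))])
        assert shortest_path_nodes(g, "A", "A").nodes == {"A"}

    def test_missing_node_raises(self):
        g = build_ughp([pw("p", ("A", "B", 1))])
        with pytest.raises(KeyError):
            shortest_path_nodes(g, "A", "Q")

    def test_undirected_mode_is_symmetric(self):
        g = build_ughp(generate_pathways(n_genes=30, n_pathways=3, mean_edges=15, seed=5))
        order = g.node_order
        rng = np.random.default_rng(6)
        for _ in range(30):
            a, b = (order[i] for i in rng.integers(0, len(order), 2))
            assert (
                shortest_path_nodes(g, a, b, directed=False).nodes
                == shortest_path_nodes(g, b, a, directed=False).nodes
            )


def _oracle_nodes(nxg, s, t):
    """Independent oracle: exhaustive enumeration of all shortest paths."""
    try:
        return frozenset(n for path in nx.all_shortest_paths(nxg, s, t) for n in path)
    except nx.NetworkXNoPath:
        return frozenset({s, t})


@pytest.mark.parametrize("directed", [True, False])
def test_matches_exhaustive_enumeration_on_random_graphs(directed):
    """Distance-sum membership equals union over all enumerated paths."""
    rng = np.random.default_rng(42 if directed else 43)
    for trial in range(50):
        n = int(rng.integers(5, 51))
        genes = [f"N{i}" for i in range(n)]
        m = int(rng.integers(n, 3 * n))
        edges = []
        for _ in range(m):
            i, j = rng.integers(0, n, 2)
            if i != j:
                edges.append((genes[i], genes[j], 1))
        if not edges:
            continue
        g = build_ughp([pw("p", *dict.fromkeys(edges))])
        nxg = g.to_networkx()
        if not directed:
            nxg = nxg.to_undirected()
        order = g.node_order
        for _ in range(10):
            s, t = (order[i] for i in rng.integers(0, len(order), 2))
            res = shortest_path_nodes(g, s, t, directed=directed)
            assert res.nodes == _oracle_nodes(nxg, s, t) | {s, t}
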