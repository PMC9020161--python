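"""Signed pathway graphs and their union.

A pathway is a list of signed directed gene--gene relations
(+1 activation, -1 suppression).  Merging many pathways by node and
edge union yields a single unified pathway graph whose adjacency takes
values in {-1, 0, +1}, 0 meaning "no direct signal".  Unweighted
shortest-path queries on that union are the backbone of the
drug--disease subnetworks built in :mod:`ddnscreen.scoring`.

Sign convention: +1 = activation, -1 = suppression.  Scoring downstream
uses topology only; signs are carried for reporting and visualisation.
"""

from __future__ import annotations

import logging
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import shortest_path as _apsp

logger = logging.getLogger(__name__)

_SIGN_TOKENS = {"1": 1, "+1": 1, "-1": -1, "−1": -1}


class PathwayParseError(ValueError):
    """Raised for malformed pathway files; message names file and line."""


@dataclass(frozen=True)
class PathwayRecord:
    """One pathway: an id, a display name and deduplicated signed edges."""

    pathway_id: str
    name: str
    edges: tuple[tuple[str, str, int], ...]

    def __post_init__(self) -> None:
        if not self.pathway_id:
            raise ValueError("pathway_id must be nonempty")
        for s, t, sign in self.edges:
            if s == t:
                raise ValueError(f"self-loop {s!r} in pathway {self.pathway_id}")
            if sign not in (-1, 1):
                raise ValueError(f"sign {sign!r} not in {{-1, +1}}")


def parse_pathway_file(path: str | Path, dialect: str = "edge_tsv") -> PathwayRecord:
    """Read one pathway file into a :class:`PathwayRecord`.

    ``edge_tsv`` rows are ``source<TAB>target<TAB>sign`` with ``#`` comments;
    ``kgml_subset`` reads only gene--gene KGML relations whose subtype is
    ``activation`` or ``inhibition``.  Self-loops are dropped (logged),
    duplicate edges collapse to one, and the pathway id is the file stem.
    """
    path = Path(path)
    if dialect == "edge_tsv":
        edges = _parse_edge_tsv(path)
        name = path.stem
    elif dialect == "kgml_subset":
        edges, name = _parse_kgml_subset(path)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    if not edges:
        raise PathwayParseError(f"{path}: no usable edges")
    return PathwayRecord(pathway_id=path.stem, name=name, edges=tuple(edges))


def _parse_edge_tsv(path: Path) -> list[tuple[str, str, int]]:
    edges: list[tuple[str, str, int]] = []
    seen: set[tuple[str, str, int]] = set()
    n_self = 0
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 3:
                raise PathwayParseError(
                    f"{path}:{lineno}: expected 3 tab-separated fields, got {len(fields)}"
                )
            src, tgt, tok = (f.strip() for f in fields)
            if not src or not tgt:
                raise PathwayParseError(f"{path}:{lineno}: empty gene symbol")
            if tok not in _SIGN_TOKENS:
                raise PathwayParseError(f"{path}:{lineno}: bad sign token {tok!r}")
            sign = _SIGN_TOKENS[tok]
            if src == tgt:
                n_self += 1
                continue
            edge = (src, tgt, sign)
            if edge not in seen:
                seen.add(edge)
                edges.append(edge)
    if n_self:
        logger.info("%s: dropped %d self-loop(s)", path, n_self)
    return edges


_KGML_SIGNS = {"activation": 1, "inhibition": -1}


def _parse_kgml_subset(path: Path) -> tuple[list[tuple[str, str, int]], str]:
    # Only gene entries and activation/inhibition relations; everything else
    # (compounds, groups, maplinks) is out of scope and skipped.
    tree = ET.parse(path)
    root = tree.getroot()
    name = root.get("title") or path.stem
    gene_of: dict[str, str] = {}
    for entry in root.iter("entry"):
        if entry.get("type") == "gene":
            label = (entry.get("name") or "").split()
            if label:
                gene_of[entry.get("id", "")] = label[0]
    edges: list[tuple[str, str, int]] = []
    seen: set[tuple[str, str, int]] = set()
    for rel in root.iter("relation"):
        src = gene_of.get(rel.get("entry1", ""))
        tgt = gene_of.get(rel.get("entry2", ""))
        if src is None or tgt is None or src == tgt:
            continue
        for sub in rel.iter("subtype"):
            sign = _KGML_SIGNS.get(sub.get("name", ""))
            if sign is None:
                continue
            edge = (src, tgt, sign)
            if edge not in seen:
                seen.add(edge)
                edges.append(edge)
    return edges, name


@dataclass
class UnifiedPathwayGraph:
    """Union of signed pathways: nodes, signed adjacency, conflict log.

    ``signed_adjacency`` maps an ordered gene pair to its sign; absent
    pairs are 0.  Pairs asserted with both signs across pathways keep the
    edge with sign +1 and are recorded in ``conflict_edges``.
    """

    nodes: frozenset[str]
    signed_adjacency: dict[tuple[str, str], int]
    conflict_edges: frozenset[tuple[str, str]]
    _cache: dict = field(default_factory=dict, repr=False, compare=False)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.signed_adjacency)

    @property
    def node_order(self) -> list[str]:
        if "order" not in self._cache:
            self._cache["order"] = sorted(self.nodes)
            self._cache["index"] = {g: i for i, g in enumerate(self._cache["order"])}
        return self._cache["order"]

    @property
    def node_index(self) -> dict[str, int]:
        self.node_order
        return self._cache["index"]

    def distance_matrix(self, directed: bool = False) -> np.ndarray:
        """All-pairs unweighted (hop-count) distances, cached per direction.

        Dense ``n x n`` float array with ``inf`` for unreachable pairs.
        Intended for pathway unions up to a few thousand genes.
        """
        key = ("dist", directed)
        if key not in self._cache:
            order, index = self.node_order, self.node_index
            n = len(order)
            rows = [index[s] for s, _ in self.signed_adjacency]
            cols = [index[t] for _, t in self.signed_adjacency]
            adj = sp.csr_matrix(
                (np.ones(len(rows)), (rows, cols)), shape=(n, n), dtype=np.int8
            )
            self._cache[key] = _apsp(adj, directed=directed, unweighted=True)
        return self._cache[key]

    def to_networkx(self):
        import networkx as nx

        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        for (s, t), sign in self.signed_adjacency.items():
            g.add_edge(s, t, sign=sign, conflict=(s, t) in self.conflict_edges)
        return g

    def write_edge_tsv(self, path: str | Path) -> None:
        """Export as 4-column TSV: source, target, sign, conflict."""
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("source\ttarget\tsign\tconflict\n")
            for (s, t) in sorted(self.signed_adjacency):
                sign = self.signed_adjacency[(s, t)]
                fh.write(f"{s}\t{t}\t{sign}\t{int((s, t) in self.conflict_edges)}\n")


def build_ughp(pathways: list[PathwayRecord]) -> UnifiedPathwayGraph:
    """Union a list of pathways into one unified pathway graph.

    Nodes are the union of all genes on any edge; an ordered pair carries
    an edge iff some pathway asserts it.  A sign conflict (same pair seen
    with +1 and -1) keeps the edge with sign +1 and logs the pair.
    """
    if not pathways:
        raise ValueError("need at least one pathway")
    adjacency: dict[tuple[str, str], int] = {}
    conflicts: set[tuple[str, str]] = set()
    for pw in pathways:
        for s, t, sign in pw.edges:
            prev = adjacency.get((s, t))
            if prev is None:
                adjacency[(s, t)] = sign
            elif prev != sign:
                adjacency[(s, t)] = 1
                conflicts.add((s, t))
                logger.warning(
                    "sign conflict on edge %s->%s (pathway %s); keeping +1",
                    s, t, pw.pathway_id,
                )
    nodes = frozenset(g for edge in adjacency for g in edge)
    return UnifiedPathwayGraph(
        nodes=nodes, signed_adjacency=adjacency, conflict_edges=frozenset(conflicts)
    )


@dataclass(frozen=True)
class ShortestPathResult:
    """Node union over all minimum-hop paths, plus a reachability flag."""

    nodes: frozenset[str]
    reachable: bool


def shortest_path_nodes(
    graph: UnifiedPathwayGraph, source: str, target: str, directed: bool = False
) -> ShortestPathResult:
    """Union of nodes on *all* minimum-hop paths from source to target.

    A node v lies on some shortest path iff d(s,v) + d(v,t) = d(s,t),
    which is read off the cached distance matrix.  If the target is
    unreachable the result is {source, target} flagged unreachable;
    source == target gives {source}.
    """
    for g in (source, target):
        if g not in graph.nodes:
            raise KeyError(f"gene {g!r} not in graph")
    if source == target:
        return ShortestPathResult(frozenset({source}), True)
    D = graph.distance_matrix(directed)
    idx = graph.node_index
    i, j = idx[source], idx[target]
    d = D[i, j]
    if not np.isfinite(d):
        return ShortestPathResult(frozenset({source, target}), False)
    on_path = D[i, :] + D[:, j] == d
    order = graph.node_order
    return ShortestPathResult(
        frozenset(order[k] for k in np.flatnonzero(on_path)), True
    )
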