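"""Union signed pathways into one graph and query shortest-path nodes.

Generates a small synthetic pathway collection, merges it, and shows
the node set a drug-gene/disease-gene pair would contribute to a
drug--disease network.
"""

from ddnscreen import build_ughp, shortest_path_nodes
from ddnscreen.synthetic import generate_pathways

pathways = generate_pathways(n_genes=60, n_pathways=5, mean_edges=25, seed=0)
ughp = build_ughp(pathways)
print(f"unified graph: {ughp.n_nodes} genes, {ughp.n_edges} signed edges, "
      f"{len(ughp.conflict_edges)} sign conflicts")

source, target = ughp.node_order[0], ughp.node_order[-1]
res = shortest_path_nodes(ughp, source, target, directed=False)
print(f"genes on all shortest paths {source} .. {target}: {sorted(res.nodes)}")
print("(these are the nodes such a pair contributes to a drug-disease network;")
print(" an unreachable pair would contribute only its two endpoints)")
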