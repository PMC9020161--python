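"""Drug--disease networks and the Pearson repurposing score.

For one drug condition and one disease subtype: map the drug's top
genes and the subtype's candidate genes onto the unified pathway graph,
take the union of all nodes lying on minimum-hop paths between every
(drug gene, disease gene) pair, and correlate the drug and disease
z-scores over the resulting node set.  The node count N of that network
is bounded by N <= G_dr + G_di + G_i (drug, disease and intermediate
gene counts), with equality when no gene plays two roles.

A strongly negative Pearson r means the drug pushes the network's genes
in the opposite direction to the disease -- the favourable case -- so
rankings sort ascending by r.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .pathway import UnifiedPathwayGraph
from .perturbation import (
    CombinedProfile,
    DiseaseSignature,
    PerturbationProfile,
    ProfileKey,
)

logger = logging.getLogger(__name__)


@dataclass
class DrugDiseaseNetwork:
    """Shortest-path subnetwork between mapped drug and disease genes.

    ``drug_genes`` and ``disease_genes`` are the mapped (graph-member)
    inputs and may overlap; ``intermediate_genes`` is disjoint from
    both.  ``roles`` exposes the disjoint partition with the overlap
    labelled "both".  Pairs with no connecting path contribute only
    their endpoints and are counted in ``unreachable_pairs``.
    """

    drug_genes: frozenset[str]
    disease_genes: frozenset[str]
    intermediate_genes: frozenset[str]
    nodes: frozenset[str]
    unreachable_pairs: int = 0
    dropped_drug_genes: int = 0
    dropped_disease_genes: int = 0

    @property
    def roles(self) -> dict[str, str]:
        roles = {}
        for g in self.nodes:
            dr, di = g in self.drug_genes, g in self.disease_genes
            roles[g] = "both" if dr and di else "drug" if dr else "disease" if di else "intermediate"
        return roles

    @property
    def node_bound(self) -> int:
        """Upper bound on |nodes|: G_dr + G_di + G_i."""
        return len(self.drug_genes) + len(self.disease_genes) + len(self.intermediate_genes)


def build_ddn(
    ughp: UnifiedPathwayGraph,
    drug_genes: Iterable[str],
    disease_genes: Iterable[str],
    directed: bool = False,
) -> DrugDiseaseNetwork:
    """Union all shortest-path node sets between drug and disease genes.

    Input genes absent from the graph are dropped (counts kept on the
    result).  A node v is on a shortest path for pair (s, t) iff
    d(s,v) + d(v,t) = d(s,t); the check is vectorised over all pairs on
    the graph's cached distance matrix.  If either side maps to nothing
    the network is degenerate and downstream scores come out undefined.
    """
    if not ughp.nodes:
        raise ValueError("empty pathway graph")
    drug_in = sorted(set(drug_genes) & ughp.nodes)
    dis_in = sorted(set(disease_genes) & ughp.nodes)
    dropped_dr = len(set(drug_genes)) - len(drug_in)
    dropped_di = len(set(disease_genes)) - len(dis_in)
    if dropped_dr or dropped_di:
        logger.debug(
            "dropped %d drug / %d disease gene(s) absent from graph",
            dropped_dr, dropped_di,
        )
    if not drug_in or not dis_in:
        nodes = frozenset(drug_in) | frozenset(dis_in)
        return DrugDiseaseNetwork(
            frozenset(drug_in), frozenset(dis_in), frozenset(), nodes,
            unreachable_pairs=0,
            dropped_drug_genes=dropped_dr, dropped_disease_genes=dropped_di,
        )
    D = ughp.distance_matrix(directed)
    idx = ughp.node_index
    dr_idx = np.array([idx[g] for g in drug_in])
    di_idx = np.array([idx[g] for g in dis_in])
    d_pair = D[np.ix_(dr_idx, di_idx)]  # (kd, ki)
    finite = np.isfinite(d_pair)
    unreachable = int((~finite).sum())
    # d(s, v) + d(v, t) == d(s, t) over all pairs at once
    M = D[dr_idx][:, None, :] + D[:, di_idx].T[None, :, :]
    with np.errstate(invalid="ignore"):
        on_path = (M == d_pair[:, :, None]) & finite[:, :, None]
    mask = on_path.any(axis=(0, 1))
    order = ughp.node_order
    nodes = {order[k] for k in np.flatnonzero(mask)}
    nodes.update(drug_in)
    nodes.update(dis_in)
    endpoint = set(drug_in) | set(dis_in)
    return DrugDiseaseNetwork(
        drug_genes=frozenset(drug_in),
        disease_genes=frozenset(dis_in),
        intermediate_genes=frozenset(nodes - endpoint),
        nodes=frozenset(nodes),
        unreachable_pairs=unreachable,
        dropped_drug_genes=dropped_dr,
        dropped_disease_genes=dropped_di,
    )


@dataclass(frozen=True)
class RepurposingScore:
    """Pearson r between drug and disease z over the network's genes.

    ``r`` is None (undefined) when fewer than 3 genes carry both
    z-scores or either array has zero variance; undefined scores are
    excluded from rankings rather than coerced to 0.
    """

    drug_key: ProfileKey | tuple[ProfileKey, ProfileKey]
    subtype_id: str
    r: float | None
    n_genes_scored: int

    @property
    def defined(self) -> bool:
        return self.r is not None


def score(
    ddn: DrugDiseaseNetwork,
    drug_profile: PerturbationProfile | CombinedProfile,
    disease_signature: DiseaseSignature,
) -> RepurposingScore:
    """Correlate drug vs disease z-scores over the network's genes.

    Only genes with a z-score in both the profile and the signature
    enter the paired arrays (identical, sorted gene order).
    """
    genes = sorted(
        g for g in ddn.nodes if g in drug_profile.z and g in disease_signature.z
    )
    n = len(genes)
    key = drug_profile.key
    subtype = disease_signature.subtype_id
    if n < 3:
        return RepurposingScore(key, subtype, None, n)
    x = np.array([drug_profile.z[g] for g in genes])
    y = np.array([disease_signature.z[g] for g in genes])
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return RepurposingScore(key, subtype, None, n)
    r = float(np.corrcoef(x, y)[0, 1])
    return RepurposingScore(key, subtype, r, n)


def score_profile(
    ughp: UnifiedPathwayGraph,
    profile: PerturbationProfile | CombinedProfile,
    signature: DiseaseSignature,
    disease_genes: Iterable[str],
    k: int = 50,
    directed: bool = False,
) -> RepurposingScore:
    """Convenience: top-k drug genes -> network -> score, in one call."""
    from .perturbation import select_drug_genes

    drug_genes = select_drug_genes(profile, k)
    ddn = build_ddn(ughp, drug_genes, disease_genes, directed=directed)
    return score(ddn, profile, signature)


def rank_drugs(scores: Sequence[RepurposingScore]) -> list[RepurposingScore]:
    """Defined scores sorted most-negative first; ties by drug key."""
    defined = [s for s in scores if s.defined]
    return sorted(defined, key=lambda s: (s.r, s.drug_key))


def score_distribution(scores: Sequence[RepurposingScore]) -> dict[str, float]:
    """Five-number summary (min, q1, median, q3, max) of defined scores."""
    rs = np.array([s.r for s in scores if s.defined])
    if rs.size == 0:
        raise ValueError("no defined scores to summarise")
    q1, med, q3 = np.percentile(rs, [25, 50, 75])
    return {
        "min": float(rs.min()),
        "q1": float(q1),
        "median": float(med),
        "q3": float(q3),
        "max": float(rs.max()),
        "n": int(rs.size),
    }


def write_ranking_tsv(ranked: Sequence[RepurposingScore], path) -> None:
    """Ranked table: rank, drug_id, dose, time_h, score, n_genes_scored."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("rank\tdrug_id\tdose\ttime_h\tscore\tn_genes_scored\n")
        for i, s in enumerate(ranked, start=1):
            drug_id, dose, time_h = s.drug_key
            fh.write(
                f"{i}\t{drug_id}\t{dose:g}\t{time_h:g}\t{s.r:.6f}\t{s.n_genes_scored}\n"
            )


def write_ddn_tables(ddn: DrugDiseaseNetwork, ughp: UnifiedPathwayGraph, prefix) -> None:
    """Export a network as node TSV (role column) and induced-edge TSV."""
    roles = ddn.roles
    with open(f"{prefix}.nodes.tsv", "w", encoding="utf-8") as fh:
        fh.write("gene\trole\n")
        for g in sorted(ddn.nodes):
            fh.write(f"{g}\t{roles[g]}\n")
    with open(f"{prefix}.edges.tsv", "w", encoding="utf-8") as fh:
        fh.write("source\ttarget\tsign\n")
        for (s, t), sign in sorted(ughp.signed_adjacency.items()):
            if s in ddn.nodes and t in ddn.nodes:
                fh.write(f"{s}\t{t}\t{sign}\n")
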