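"""Drug--disease network construction and the Pearson repurposing score."""

import numpy as np
import pytest

from ddnscreen import (
    DiseaseSignature,
    PathwayRecord,
    PerturbationProfile,
    build_ddn,
    build_ughp,
    rank_drugs,
    score,
    score_distribution,
)
from ddnscreen.scoring import RepurposingScore
from ddnscreen.synthetic import generate_pathways


def graph(*edges):
    return build_ughp([PathwayRecord("p", "p", tuple((s, t, 1) for s, t in edges))])


def profile(**z):
    return PerturbationProfile("d", 1.0, 24.0, z)


def signature(**z):
    return DiseaseSignature("S", z)


class TestBuildDdn:
    def test_chain_hits_node_count_bound_exactly(self):
        g = graph(("D", "M"), ("M", "S"))
        ddn = build_ddn(g, {"D"}, {"S"})
        assert ddn.nodes == {"D", "M", "S"}
        assert ddn.intermediate_genes == {"M"}
        assert len(ddn.nodes) == ddn.node_bound == 3

    def test_adjacent_pair_has_no_intermediates(self):
        g = graph(("D", "S"), ("S", "Q"))
        ddn = build_ddn(g, {"D"}, {"S"})
        assert ddn.nodes == {"D", "S"} and not ddn.intermediate_genes
        assert len(ddn.nodes) < 3

    def test_shared_intermediate_counted_once(self):
        # two drug genes reach one disease gene through the same hub
        g = graph(("D1", "M"), ("D2", "M"), ("M", "S"))
        ddn = build_ddn(g, {"D1", "D2"}, {"S"})
        assert ddn.intermediate_genes == {"M"}
        assert len(ddn.nodes) == 4  # < 2 + 1 + (1 per pair) = 4 naive, hub deduped
        assert len(ddn.nodes) <= ddn.node_bound

    def test_overlapping_drug_disease_gene_counted_once(self):
        g = graph(("A", "B"))
        ddn = build_ddn(g, {"A", "B"}, {"B"})
        assert ddn.roles["B"] == "both"
        assert len(ddn.nodes) == 2 < ddn.node_bound

    def test_unmapped_genes_dropped_and_counted(self):
        g = graph(("D", "S"))
        ddn = build_ddn(g, {"D", "QQ"}, {"S", "ZZ"})
        assert ddn.dropped_drug_genes == 1 and ddn.dropped_disease_genes == 1
        assert ddn.nodes == {"D", "S"}

    def test_fully_unmapped_side_gives_degenerate_network(self):
        g = graph(("D", "S"))
        ddn = build_ddn(g, {"QQ"}, {"S"})
        assert ddn.nodes == {"S"}
        assert score(ddn, profile(S=1.0), signature(S=1.0)).r is None

    def test_unreachable_pairs_contribute_endpoints_only(self):
        g = graph(("D", "M"), ("Y", "S"))  # D cannot reach S even undirected
        ddn = build_ddn(g, {"D"}, {"S"})
        assert ddn.nodes == {"D", "S"}
        assert ddn.unreachable_pairs == 1

    def test_node_count_bound_on_random_networks(self):
        rng = np.random.default_rng(12)
        g = build_ughp(generate_pathways(n_genes=60, n_pathways=4, mean_edges=30, seed=8))
        order = g.node_order
        for _ in range(25):
            dr = {order[i] for i in rng.integers(0, len(order), 5)}
            di = {order[i] for i in rng.integers(0, len(order), 4)}
            ddn = build_ddn(g, dr, di)
            assert len(ddn.nodes) <= ddn.node_bound
            assert ddn.intermediate_genes.isdisjoint(ddn.drug_genes | ddn.disease_genes)


def pearson_oracle(x, y):
    """Direct closed-form evaluation of the correlation formula."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    dx, dy = x - x.mean(), y - y.mean()
    return float((dx * dy).sum() / np.sqrt((dx**2).sum() * (dy**2).sum()))


class TestScore:
    def _score_arrays(self, x, y):
        genes = [f"g{i}" for i in range(len(x))]
        g = graph(*[(genes[i], genes[i + 1]) for i in range(len(genes) - 1)])
        ddn = build_ddn(g, set(genes), set(genes))
        return score(ddn, profile(**dict(zip(genes, x))), signature(**dict(zip(genes, y))))

    def test_exact_reversal_scores_minus_one(self):
        s = self._score_arrays([1, 2, 3], [-1, -2, -3])
        assert s.r == pytest.approx(-1.0)

    def test_identity_scores_plus_one(self):
        s = self._score_arrays([1, 2, 3], [1, 2, 3])
        assert s.r == pytest.approx(1.0)

    def test_hand_case_gives_point_eight(self):
        s = self._score_arrays([1, 2, 3, 4], [1, 3, 2, 4])
        assert s.r == pytest.approx(0.8, abs=1e-12)

    def test_matches_closed_form_oracle(self):
        rng = np.random.default_rng(17)
        for _ in range(100):
            n = int(rng.integers(3, 40))
            x = rng.normal(0, 3, n)
            y = rng.normal(0, 3, n)
            s = self._score_arrays(np.clip(x, -10, 10), np.clip(y, -10, 10))
            assert s.r == pytest.approx(
                pearson_oracle(np.clip(x, -10, 10), np.clip(y, -10, 10)), abs=1e-12
            )
            assert s.n_genes_scored == n

    def test_invariant_to_gene_order(self):
        genes = [f"g{i}" for i in range(6)]
        g = graph(*[(genes[i], genes[i + 1]) for i in range(5)])
        ddn = build_ddn(g, set(genes), set(genes))
        z1 = dict(zip(genes, [1.0, -2, 3, 0.5, 2, -1]))
        z2 = dict(zip(genes, [0.3, 1, -2, 4, -3, 2]))
        shuffled = dict(sorted(z1.items(), reverse=True))
        assert score(ddn, profile(**z1), signature(**z2)).r == pytest.approx(
            score(ddn, profile(**shuffled), signature(**z2)).r, abs=1e-15
        )

    def test_fewer_than_three_genes_is_undefined(self):
        s = self._score_arrays([1, 2], [2, 1])
        assert s.r is None and not s.defined and s.n_genes_scored == 2

    def test_zero_variance_is_undefined(self):
        s = self._score_arrays([1, 1, 1], [1, 2, 3])
        assert s.r is None

    def test_genes_missing_a_z_value_are_dropped(self):
        g = graph(("a", "b"), ("b", "c"), ("c", "d"))
        ddn = build_ddn(g, {"a", "b", "c", "d"}, {"a", "b", "c", "d"})
        s = score(ddn, profile(a=1.0, b=2.0, c=3.0), signature(a=3.0, b=2.0, c=1.0, d=9.0))
        assert s.n_genes_scored == 3
        assert s.r == pytest.approx(-1.0)


def rs(key, r):
    return RepurposingScore(drug_key=(key, 1.0, 24.0), subtype_id="S", r=r, n_genes_scored=10)


class TestRanking:
    def test_most_negative_first(self):
        ranked = rank_drugs([rs("d1", -0.5), rs("d2", 0.3), rs("d3", -0.9)])
        assert [s.drug_key[0] for s in ranked] == ["d3", "d1", "d2"]

    def test_undefined_excluded(self):
        assert rank_drugs([rs("d1", None), rs("d2", None)]) == []

    def test_ties_broken_by_drug_key(self):
        ranked = rank_drugs([rs("zz", -0.5), rs("aa", -0.5)])
        assert [s.drug_key[0] for s in ranked] == ["aa", "zz"]


class TestScoreDistribution:
    def test_five_number_summary(self):
        summary = score_distribution([rs("a", -0.2), rs("b", 0.0), rs("c", 0.2)])
        assert summary["median"] == 0.0
        assert summary["min"] == -0.2 and summary["max"] == 0.2

    def test_single_score_collapses_summary(self):
        summary = score_distribution([rs("a", -0.4)])
        assert {summary[k] for k in ("min", "q1", "median", "q3", "max")} == {-0.4}

    def test_no_defined_scores_rejected(self):
        with pytest.raises(ValueError):
            score_distribution([rs("a", None)])

    def test_negatively_biased_library_has_negative_median(self, run0):
        # library in which every drug partially reverses the signature
        from ddnscreen import score_profile

        sig = run0.signature
        rng = np.random.default_rng(99)
        scores = []
        for i in range(20):
            z = {
                g: float(np.clip(-0.5 * sig.z[g] + rng.normal(0, 1), -10, 10))
                for g in sig.z
            }
            p = PerturbationProfile(f"b{i:02d}", 1.0, 24.0, z)
            scores.append(score_profile(run0.ughp, p, sig, run0.candidates.genes))
        assert score_distribution(scores)["median"] < 0
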