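import math
from fractions import Fraction
from math import comb

import networkx as nx
import numpy as np
import pytest
from scipy import stats

from csn.analysis import (
    AnnotationTable,
    cai_degree_regression,
    compute_cai,
    degree_expression_correlation,
    degree_frequency_fit,
    hypergeom_upper_tail,
    interaction_overlap,
    neighborhood_enrichment,
    predict_annotations,
    read_expression_table,
    read_reference_network,
    roc_over_densities,
)
from csn.network import CorrelationMatrix
from csn.sequence_io import GeneRecord

from .test_network import corr_from_rhos


def exact_hypergeom_tail(k, N, K, n):
    """Big-integer binomial-coefficient oracle for P(X >= k)."""
    if k <= 0:
        return Fraction(1)
    num = sum(comb(K, j) * comb(N - K, n - j)
              for j in range(k, min(n, K) + 1) if n - j <= N - K)
    return Fraction(num, comb(N, n))


class TestDegreeFrequencyFit:
    def test_star_two_points_perfectly_negative(self):
        g = nx.star_graph(4)
        out = degree_frequency_fit(g)
        assert out["pearson_rho"] == pytest.approx(-1.0)
        assert len(out["points"]) == 2

    def test_regular_graph_undefined(self):
        out = degree_frequency_fit(nx.cycle_graph(6))
        assert math.isnan(out["spearman_rho"])

    def test_matches_rank_oracle_on_scale_free_graph(self):
        g = nx.barabasi_albert_graph(300, 2, seed=0)
        out = degree_frequency_fit(g)
        deg = np.array([d for _, d in g.degree()])
        vals, counts = np.unique(deg, return_counts=True)
        expected = stats.pearsonr(stats.rankdata(np.log10(vals)),
                                  stats.rankdata(np.log10(counts))).statistic
        assert out["spearman_rho"] == pytest.approx(expected, abs=1e-12)
        assert out["spearman_rho"] < 0  # scale-free signature

    def test_isolated_nodes_rejected(self):
        g = nx.Graph()
        g.add_nodes_from("abc")
        g.add_edge("a", "b")
        with pytest.raises(ValueError):
            degree_frequency_fit(g)


class TestDegreeExpression:
    def test_monotone_expression_gives_rho_one(self):
        g = nx.Graph([("a", "b"), ("b", "c"), ("c", "a"), ("c", "d")])
        expr = {n: float(g.degree(n)) * 10 for n in g.nodes}
        out = degree_expression_correlation(g, expr)
        assert out["spearman_rho"] == pytest.approx(1.0)

    def test_constant_expression_undefined(self):
        g = nx.path_graph(5)
        out = degree_expression_correlation(g, {n: 1.0 for n in g.nodes})
        assert math.isnan(out["spearman_rho"])

    def test_missing_genes_dropped_and_counted(self):
        g = nx.path_graph(6)
        expr = {n: float(n) for n in list(g.nodes)[:4]}
        assert degree_expression_correlation(g, expr)["n_used"] == 4

    def test_permutation_null_centred_on_zero(self):
        g = nx.barabasi_albert_graph(40, 2, seed=1)
        rng = np.random.default_rng(0)
        base = np.arange(40, dtype=float) + 1
        rhos = []
        for _ in range(300):
            expr = dict(zip(g.nodes, rng.permutation(base)))
            rhos.append(degree_expression_correlation(g, expr)["spearman_rho"])
        assert abs(np.mean(rhos)) < 0.05

    def test_too_small_intersection_rejected(self):
        g = nx.path_graph(5)
        with pytest.raises(ValueError):
            degree_expression_correlation(g, {0: 1.0, 1: 2.0})


class TestComputeCai:
    def test_class_maximal_codons_give_unity(self):
        # 6 leucine codons, gene uses only the set-wide most frequent one
        genes = [GeneRecord("a", "CTGCTGCTG"), GeneRecord("b", "CTGCTACTG")]
        cai = compute_cai(genes)
        assert cai["a"] == pytest.approx(1.0)

    def test_geometric_mean_of_two_weights(self):
        # set-wide GGT:GGC usage 8:2 -> w = 1 and 0.25; one of each -> sqrt(0.25)
        genes = [GeneRecord("bg", "GGT" * 7 + "GGC"), GeneRecord("x", "GGTGGC")]
        cai = compute_cai(genes)
        assert cai["x"] == pytest.approx(0.5)

    def test_single_codon_classes_excluded(self):
        # Met and Trp carry no synonymous choice; a gene of only those is NaN
        genes = [GeneRecord("m", "ATGTGG"), GeneRecord("n", "GCTGCC"),
                 GeneRecord("o", "GCTGCT")]
        cai = compute_cai(genes)
        assert math.isnan(cai["m"])

    def test_invariant_under_gene_order(self):
        rng = np.random.default_rng(0)
        from .conftest import CODONS
        genes = [GeneRecord(f"g{i}", "".join(rng.choice(CODONS, size=30)))
                 for i in range(10)]
        a = compute_cai(genes)
        b = compute_cai(genes[::-1])
        for g in a:
            assert a[g] == pytest.approx(b[g], abs=1e-15)


class TestCaiDegreeRegression:
    def test_degree_driven_abundance_prefers_combined(self):
        rng = np.random.default_rng(1)
        g = nx.barabasi_albert_graph(60, 3, seed=2)
        g = nx.relabel_nodes(g, {i: f"g{i}" for i in g.nodes})
        expr = {n: math.exp(0.3 * g.degree(n)) for n in g.nodes}
        cai = {n: float(rng.uniform(0.2, 1.0)) for n in g.nodes}
        out = cai_degree_regression(g, expr, cai)
        assert out["rho_combined"] > out["rho_cai"]

    def test_cai_driven_abundance_keeps_combined_at_least_equal(self):
        rng = np.random.default_rng(2)
        g = nx.barabasi_albert_graph(60, 3, seed=3)
        g = nx.relabel_nodes(g, {i: f"g{i}" for i in g.nodes})
        cai = {n: float(rng.uniform(0.2, 1.0)) for n in g.nodes}
        expr = {n: math.exp(3 * cai[n]) for n in g.nodes}
        out = cai_degree_regression(g, expr, cai)
        assert out["rho_combined"] >= out["rho_cai"] - 1e-9

    def test_small_noise_design_stays_bounded(self):
        rng = np.random.default_rng(3)
        g = nx.path_graph(10)
        g = nx.relabel_nodes(g, {i: f"g{i}" for i in g.nodes})
        expr = {n: float(rng.lognormal()) for n in g.nodes}
        cai = {n: float(rng.uniform(0.2, 1)) for n in g.nodes}
        out = cai_degree_regression(g, expr, cai)
        assert -1 <= out["rho_combined"] <= 1

    def test_too_few_genes_rejected(self):
        g = nx.path_graph(4)
        with pytest.raises(ValueError):
            cai_degree_regression(g, {n: 1.0 for n in g.nodes},
                                  {n: 0.5 for n in g.nodes})


class TestInteractionOverlap:
    def test_half_recovered(self):
        g = nx.Graph([("A", "B"), ("B", "C")])
        g.add_node("D")
        out = interaction_overlap(g, {("A", "B"), ("C", "D")})
        assert out["sensitivity"] == 0.5
        assert out["tp"] == 1

    def test_reference_subset_gives_one(self):
        g = nx.Graph([("A", "B"), ("B", "C"), ("A", "C")])
        assert interaction_overlap(g, {("A", "B")})["sensitivity"] == 1.0

    def test_disjoint_gives_zero(self):
        g = nx.Graph([("A", "B")])
        g.add_nodes_from("CD")
        assert interaction_overlap(g, {("C", "D")})["sensitivity"] == 0.0

    def test_empty_restricted_reference_rejected(self):
        g = nx.Graph([("A", "B")])
        with pytest.raises(ValueError):
            interaction_overlap(g, {("X", "Y")})


class TestRoc:
    def make_corr(self, n, seed):
        rng = np.random.default_rng(seed)
        import itertools
        pairs = {p: float(rng.uniform(-1, 1))
                 for p in itertools.combinations(range(n), 2)}
        return corr_from_rhos([f"g{i}" for i in range(n)], pairs)

    def test_perfect_separation_auc_one(self):
        c = corr_from_rhos("ABCD", {(0, 1): 0.9, (0, 2): 0.8, (0, 3): 0.1,
                                    (1, 2): 0.2, (1, 3): 0.15, (2, 3): 0.7})
        out = roc_over_densities(c, {("A", "B"), ("A", "C"), ("C", "D")})
        assert out["auc"] == 1.0

    def test_auc_equals_mann_whitney_oracle(self):
        rng = np.random.default_rng(4)
        for seed in range(5):
            c = self.make_corr(10, seed)
            all_pairs = [(x, y) for x, y, _ in c.iter_pairs()]
            ref = {all_pairs[i] for i in rng.choice(len(all_pairs), 12, replace=False)}
            out = roc_over_densities(c, ref)
            # oracle over the same gene universe: genes covered by the reference
            universe = {g for p in ref for g in p}
            pairs = [p for p in all_pairs if p[0] in universe and p[1] in universe]
            scores = {(x, y): r for x, y, r in c.iter_pairs()}
            pos = [scores[p] for p in pairs if p in ref]
            neg = [scores[p] for p in pairs if p not in ref]
            ranks = stats.rankdata(pos + neg)
            u = ranks[: len(pos)].sum() - len(pos) * (len(pos) + 1) / 2
            assert out["auc"] == pytest.approx(u / (len(pos) * len(neg)), abs=1e-12)

    def test_auc_invariant_under_monotone_transform(self):
        c = self.make_corr(9, seed=7)
        all_pairs = [(x, y) for x, y, _ in c.iter_pairs()]
        ref = set(all_pairs[::3])
        base = roc_over_densities(c, ref)["auc"]
        c2 = CorrelationMatrix(c.gene_ids, np.tanh(3 * c.values))
        assert roc_over_densities(c2, ref)["auc"] == pytest.approx(base, abs=1e-12)

    def test_degenerate_labels_rejected(self):
        c = self.make_corr(4, seed=0)
        with pytest.raises(ValueError):
            roc_over_densities(c, set())


class TestNeighborhoodEnrichment:
    def test_hypergeometric_worked_example(self):
        assert hypergeom_upper_tail(3, 50, 10, 5) == pytest.approx(
            102252 / 2118760, abs=1e-12)

    def test_zero_hits_tail_is_one(self):
        assert hypergeom_upper_tail(0, 50, 10, 5) == 1.0

    def test_universal_term_tail_is_one(self):
        assert hypergeom_upper_tail(5, 50, 50, 5) == pytest.approx(1.0, abs=1e-12)

    def test_exact_oracle_random_sample(self):
        rng = np.random.default_rng(8)
        for _ in range(100):
            N = int(rng.integers(2, 201))
            K = int(rng.integers(0, N + 1))
            n = int(rng.integers(1, N + 1))
            k = int(rng.integers(0, min(n, K) + 1))
            assert hypergeom_upper_tail(k, N, K, n) == pytest.approx(
                float(exact_hypergeom_tail(k, N, K, n)), abs=1e-12)

    def test_bh_properties(self):
        # q >= p, q monotone in p-rank, rejections form a prefix
        g = nx.complete_graph(6)
        g = nx.relabel_nodes(g, {i: f"g{i}" for i in g.nodes})
        ann = AnnotationTable({"g0": {"T1"}, "g1": {"T1"}, "g2": {"T2"},
                               "g3": {"T2", "T1"}, "g4": {"T3"}})
        recs = neighborhood_enrichment(g, ann, alpha=0.5)
        assert recs, "expected some tests"
        by_p = sorted(recs, key=lambda r: r.p)
        qs = [r.q for r in by_p]
        assert all(r.q >= r.p - 1e-15 for r in recs)
        assert all(q2 >= q1 - 1e-15 for q1, q2 in zip(qs, qs[1:]))
        flags = [r.enriched for r in by_p]
        assert flags == sorted(flags, reverse=True)

    def test_no_annotations_empty_result(self):
        g = nx.path_graph(4)
        assert neighborhood_enrichment(g, AnnotationTable({})) == []

    def test_clique_term_enriched_at_radius_one(self):
        g = nx.disjoint_union(nx.complete_graph(5), nx.complete_graph(5))
        g = nx.relabel_nodes(g, {i: f"g{i}" for i in g.nodes})
        g.add_edge("g0", "g5")
        ann = AnnotationTable({f"g{i}": {"A" if i < 5 else "B"} for i in range(10)})
        recs = neighborhood_enrichment(g, ann, radius=1, alpha=0.05)
        enriched = {(r.gene_id, r.term_id) for r in recs if r.enriched}
        assert ("g1", "A") in enriched
        assert ("g6", "B") in enriched
        assert ("g1", "B") not in enriched

    def test_layout_radius_mode(self):
        g = nx.path_graph(4)
        g = nx.relabel_nodes(g, {i: f"g{i}" for i in g.nodes})
        layout = {"g0": (0, 0), "g1": (0.01, 0), "g2": (1, 1), "g3": (0.99, 1)}
        ann = AnnotationTable({"g0": {"T"}, "g1": {"T"}})
        recs = neighborhood_enrichment(g, ann, radius=0.05, mode="layout",
                                       layout=layout)
        sizes = {r.gene_id: r.n for r in recs}
        assert sizes["g0"] == 2  # g0+g1 cluster only


class TestPredictAnnotations:
    def make_enriched(self, pairs):
        from csn.analysis import EnrichmentRecord
        return [EnrichmentRecord(g, t, 5, 3, 50, 10, 0.01, 0.02, True)
                for g, t in pairs]

    def test_known_annotation_counts_toward_success(self):
        ann = AnnotationTable({"g1": {"T"}})
        out = predict_annotations(self.make_enriched([("g1", "T"), ("g2", "T")]), ann)
        assert out["success_rate"] == 0.5
        assert out["novel"] == [("g2", "T")]

    def test_empty_enrichment(self):
        out = predict_annotations([], AnnotationTable({"g": {"T"}}))
        assert math.isnan(out["success_rate"])
        assert out["predictions"] == []


class TestTableReaders:
    def test_expression_tsv(self, tmp_path):
        p = tmp_path / "expr.tsv"
        p.write_text("g1\t2.5\ng2\t0\n")
        assert read_expression_table(p) == {"g1": 2.5, "g2": 0.0}

    def test_reference_tsv_dedup_and_self_pairs(self, tmp_path):
        p = tmp_path / "ref.tsv"
        p.write_text("a\tb\nb\ta\nc\tc\n")
        assert read_reference_network(p) == {("a", "b")}

    def test_annotation_tsv_roundtrip(self, tmp_path):
        p = tmp_path / "ann.tsv"
        ann = AnnotationTable({"g1": {"T1", "T2"}, "g2": {"T1"}})
        ann.to_tsv(p)
        back = AnnotationTable.from_tsv(p)
        assert back.gene_to_terms == ann.gene_to_terms
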