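"""20/20 classification, enrichment permutation and modular scores."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from cisrec.driver_modules import (classify_2020, interaction_enrichment,
                                   modular_scores, rewire_degree_preserving,
                                   roc_auc, roc_curve, roc_evaluate)


def _coding(gene_rows):
    return pd.DataFrame(gene_rows, columns=["gene", "sample", "position",
                                            "consequence"])


class TestClassify2020:
    def test_recurrent_positions_make_oncogene(self):
        rows = [("g", f"s{i}", 100, "missense") for i in range(3)]
        rows += [("g", f"s{i+3}", 200 + i, "missense") for i in range(7)]
        res = classify_2020(_coding(rows), min_variants=7)
        assert res.loc["g", "driver_class"] == "oncogene"
        assert res.loc["g", "recurrent_fraction"] == pytest.approx(0.3)

    def test_truncating_fraction_makes_tsg(self):
        rows = [("g", f"s{i}", i, "nonsense") for i in range(3)]
        rows += [("g", f"s{i+3}", 100 + i, "missense") for i in range(7)]
        res = classify_2020(_coding(rows), min_variants=7)
        assert res.loc["g", "driver_class"] == "TSG"

    def test_exact_twenty_percent_is_none(self):
        rows = [("g", "sa", 100, "missense"), ("g", "sb", 100, "missense")]
        rows += [("g", f"s{i}", 200 + i, "nonsense") for i in range(2)]
        rows += [("g", f"t{i}", 300 + i, "missense") for i in range(6)]
        res = classify_2020(_coding(rows), min_variants=7)
        assert res.loc["g", "recurrent_fraction"] == pytest.approx(0.2)
        assert res.loc["g", "truncating_fraction"] == pytest.approx(0.2)
        assert res.loc["g", "driver_class"] == "none"

    def test_below_min_variants_unclassified(self):
        rows = [("g", "s1", 100, "nonsense"), ("g", "s2", 100, "nonsense")]
        res = classify_2020(_coding(rows), min_variants=7)
        assert res.loc["g", "driver_class"] == "none"

    def test_unknown_consequence_rejected(self):
        with pytest.raises(ValueError, match="consequence"):
            classify_2020(_coding([("g", "s", 1, "weird")] * 8))

    def test_planted_cds_recovered(self, small_cohort):
        res = classify_2020(small_cohort.coding_variants)
        for cd in small_cohort.truth["planted_cds"]:
            assert res.loc[cd["gene"], "driver_class"] == cd["style"]


class TestInteractionEnrichment:
    def test_saturated_sets_are_invariant_under_node_permutation(self):
        g = nx.gnp_random_graph(30, 0.2, seed=1)
        nodes = set(g.nodes)
        er = interaction_enrichment(g, nodes, nodes, mode="node", reps=50,
                                    seed=0)
        assert er.ratio == pytest.approx(1.0)
        assert er.empirical_p == pytest.approx(1.0)

    def test_disjoint_sets_rejected(self):
        g = nx.path_graph(4)
        with pytest.raises(ValueError, match="intersect"):
            interaction_enrichment(g, {"zz"}, {0, 1}, reps=5)

    def test_link_mode_preserves_degrees(self):
        g = nx.gnp_random_graph(50, 0.1, seed=2)
        nodes = sorted(g.nodes)
        edges = np.array(list(g.edges))
        rng = np.random.default_rng(0)
        for _ in range(10):
            u, v = rewire_degree_preserving(edges[:, 0], edges[:, 1],
                                            len(nodes), rng)
            assert np.array_equal(
                np.bincount(np.concatenate([u, v]), minlength=len(nodes)),
                np.bincount(edges.ravel(), minlength=len(nodes)))
            # stays a simple graph
            keys = np.minimum(u, v) * len(nodes) + np.maximum(u, v)
            assert len(np.unique(keys)) == len(keys)
            assert np.all(u != v)

    def test_rewiring_moves_edges(self):
        g = nx.gnp_random_graph(50, 0.1, seed=3)
        edges = np.array(list(g.edges))
        u, v = rewire_degree_preserving(edges[:, 0], edges[:, 1], 50,
                                        np.random.default_rng(1))
        orig = set(map(tuple, np.sort(edges, axis=1)))
        new = set(zip(np.minimum(u, v), np.maximum(u, v)))
        assert orig != new

    def test_planted_cd_td_links_enriched(self, small_cohort):
        cds = {c["gene"] for c in small_cohort.truth["planted_cds"]}
        tds = {t["gene"] for t in small_cohort.truth["planted_tds"]}
        er = interaction_enrichment(small_cohort.ppi, cds, tds, mode="node",
                                    reps=300, seed=0)
        assert er.ratio > 1.5
        assert er.empirical_p < 0.05


class TestModularScores:
    def test_worked_neighborhood(self):
        g = nx.Graph([("v", "u1"), ("v", "u2"), ("u1", "w")])
        M = {"v": 2, "u1": 4, "u2": 0, "w": 0}
        res = modular_scores(g, M)
        assert res.loc["v", "score_average"] == pytest.approx(4.0)
        assert res.loc["v", "score_max"] == pytest.approx(6.0)
        assert res.loc["v", "score_sum"] == pytest.approx(4.0)

    def test_isolated_node_collapses_to_M(self):
        g = nx.Graph()
        g.add_node("v")
        res = modular_scores(g, {"v": 3})
        assert (res.loc["v", ["score_average", "score_max", "score_sum"]]
                == 3.0).all()

    def test_all_zero_M_gives_zero_scores(self):
        g = nx.cycle_graph(5)
        res = modular_scores(g, {v: 0 for v in g.nodes})
        assert (res[["score_average", "score_max", "score_sum"]] == 0).all().all()

    def test_average_equals_sum_on_regular_graphs(self):
        g = nx.random_regular_graph(4, 12, seed=0)
        rng = np.random.default_rng(0)
        M = {v: int(rng.integers(0, 9)) for v in g.nodes}
        res = modular_scores(g, M)
        assert np.allclose(res["score_average"], res["score_sum"])

    def test_matches_brute_force_on_random_graphs(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            g = nx.gnp_random_graph(15, 0.3, seed=int(rng.integers(2 ** 31)))
            M = {v: int(rng.integers(0, 7)) for v in g.nodes}
            res = modular_scores(g, M)
            for v in g.nodes:
                nbrs = list(g.neighbors(v))
                if nbrs:
                    avg = M[v] + sum(M[u] for u in nbrs) / len(nbrs)
                    mx = M[v] + max(M[u] for u in nbrs)
                    sm = M[v] + sum(M[u] / g.degree(u) for u in nbrs)
                else:
                    avg = mx = sm = M[v]
                assert res.loc[v, "score_average"] == pytest.approx(avg)
                assert res.loc[v, "score_max"] == pytest.approx(mx)
                assert res.loc[v, "score_sum"] == pytest.approx(sm)

    def test_monotone_in_neighbor_M(self):
        g = nx.Graph([("v", "u1"), ("v", "u2")])
        base = modular_scores(g, {"v": 1, "u1": 2, "u2": 3}).loc["v"]
        more = modular_scores(g, {"v": 1, "u1": 5, "u2": 3}).loc["v"]
        for col in ("score_average", "score_max", "score_sum"):
            assert more[col] >= base[col]

    def test_weighted_max_uses_normalized_weights(self):
        g = nx.Graph()
        g.add_edge("v", "u1", weight=4.0)
        g.add_edge("v", "u2", weight=2.0)
        res = modular_scores(g, {"v": 0, "u1": 2, "u2": 10})
        # weights normalized by max (4.0): W(v,u1)=1, W(v,u2)=0.5
        assert res.loc["v", "score_max"] == pytest.approx(5.0)


class TestRoc:
    def test_perfect_separation_gives_auc_one(self):
        scores = np.r_[np.ones(5), np.zeros(5)]
        labels = scores > 0.5
        assert roc_auc(scores, labels) == pytest.approx(1.0)

    def test_matches_sklearn_on_random_scores(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(0)
        scores = rng.normal(size=300)
        labels = rng.random(300) < 0.3
        assert roc_auc(scores, labels) == pytest.approx(
            roc_auc_score(labels, scores))

    def test_curve_endpoints(self):
        rng = np.random.default_rng(1)
        fpr, tpr, thr = roc_curve(rng.normal(size=50), rng.random(50) < 0.5)
        assert fpr[0] == tpr[0] == 0.0
        assert fpr[-1] == tpr[-1] == 1.0

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            roc_auc(np.arange(4), np.ones(4, bool))

    def test_evaluate_returns_auc_per_scorer(self):
        scores = {"a": {"g1": 1.0, "g2": 0.0}, "b": {"g1": 0.0, "g2": 1.0}}
        res = roc_evaluate(scores, {"g1"})
        assert res.loc["a", "auc"] == 1.0
        assert res.loc["b", "auc"] == 0.0
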