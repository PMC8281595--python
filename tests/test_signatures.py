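"""Differential features, pan-dataset ranking and consensus networks."""

import numpy as np
import pytest
from scipy.stats import norm, rankdata

from omicsurv.data_model import OmicsMatrix, SurvivalTable
from omicsurv.errors import OmicsurvError
from omicsurv.signatures import (
    CoexpressionGraph,
    DifferentialFeature,
    DifferentialFeatureSet,
    _prune_edges,
    build_coexpression_network,
    consensus_network,
    detect_communities,
    differential_features,
    pan_dataset_rank,
)


def ranksum_oracle(a, b):
    """Two-sided Wilcoxon rank-sum p via the normal approximation
    (no tie correction, no continuity correction) — independent of scipy."""
    n1, n2 = len(a), len(b)
    ranks = rankdata(np.concatenate([a, b]))
    s = ranks[:n1].sum()
    expected = n1 * (n1 + n2 + 1) / 2.0
    sd = np.sqrt(n1 * n2 * (n1 + n2 + 1) / 12.0)
    z = (s - expected) / sd
    return 2 * norm.sf(abs(z))


def layer(values, tag="RNA"):
    values = np.asarray(values, dtype=float)
    return OmicsMatrix(
        tag,
        [f"g{i}" for i in range(values.shape[0])],
        [f"s{i}" for i in range(values.shape[1])],
        values,
    )


class TestDifferentialFeatures:
    def test_indicator_feature_retained_over(self):
        rng = np.random.default_rng(0)
        labels = np.repeat([0, 1], 50)
        vals = rng.standard_normal((5, 100))
        vals[2] = (labels == 0) * 3.0 + rng.normal(0, 0.01, 100)
        de = differential_features(layer(vals), labels, p_threshold=1e-3)
        ids = {f.feature_id: f for f in de.features}
        assert "g2" in ids and ids["g2"].direction == "over"

    def test_flat_feature_not_retained(self):
        rng = np.random.default_rng(1)
        labels = np.repeat([0, 1], 20)
        vals = np.vstack([np.ones(40), rng.standard_normal(40)])
        de = differential_features(layer(vals), labels, p_threshold=0.9)
        assert "g0" not in de.feature_ids

    def test_pvalues_match_independent_ranksum(self):
        rng = np.random.default_rng(2)
        labels = np.repeat([0, 1], 25)
        vals = rng.standard_normal((8, 50))  # continuous -> tie-free
        de = differential_features(layer(vals), labels, p_threshold=1.0)
        by_id = {f.feature_id: f.wilcoxon_p for f in de.features}
        for i in range(8):
            a, b = vals[i][labels == 0], vals[i][labels == 1]
            assert by_id[f"g{i}"] == pytest.approx(ranksum_oracle(a, b), abs=1e-10)

    def test_small_group_rejected(self):
        labels = np.array([0, 0, 1, 1, 1])
        with pytest.raises(OmicsurvError):
            differential_features(layer(np.ones((2, 5))), labels)


class TestPanRank:
    def de(self, pairs, tag="RNA"):
        return DifferentialFeatureSet(
            tag,
            [DifferentialFeature(f, "over", 1e-5, cox_p=p) for f, p in pairs],
            1e-3,
        )

    def test_two_point_minmax(self):
        scores = pan_dataset_rank({"d1": self.de([("gA", 1e-6), ("gB", 1e-2)])})
        assert scores["gA"] == pytest.approx(1.0)
        assert scores["gB"] == pytest.approx(0.0)

    def test_always_best_sums_across_datasets(self):
        per = {
            f"d{k}": self.de([("gA", 1e-8), ("gB", 1e-3), ("gC", 1e-2)])
            for k in range(3)
        }
        scores = pan_dataset_rank(per)
        assert scores["gA"] == pytest.approx(3.0)
        assert all(0 <= v <= 3 for v in scores.values())

    def test_single_feature_dataset_scores_one(self):
        scores = pan_dataset_rank({"d1": self.de([("gX", 1e-4)])})
        assert scores["gX"] == pytest.approx(1.0)

    def test_matches_brute_force_ordering(self):
        rng = np.random.default_rng(3)
        per = {}
        for k in range(4):
            feats = [(f"g{i}", float(10 ** -rng.uniform(1, 9))) for i in range(6)]
            per[f"d{k}"] = self.de(feats)
        scores = pan_dataset_rank(per)
        brute = {}
        for de in per.values():
            lv = np.array([-np.log10(f.cox_p) for f in de.features])
            normalized = (lv - lv.min()) / (lv.max() - lv.min())
            for f, r in zip(de.features, normalized):
                brute[f.feature_id] = brute.get(f.feature_id, 0.0) + r
        for g in brute:
            assert scores[g] == pytest.approx(brute[g], abs=1e-12)


class TestNetwork:
    def de_for(self, lay, p=1e-6):
        return DifferentialFeatureSet(
            lay.omic_tag,
            [DifferentialFeature(f, "over", p) for f in lay.feature_ids],
            1e-3,
        )

    def test_perfectly_correlated_pair_weight_one(self):
        rng = np.random.default_rng(4)
        x = rng.standard_normal(50)
        vals = np.vstack([x, 2 * x + 1, rng.standard_normal(50)])
        lay = layer(vals)
        g = build_coexpression_network(lay, self.de_for(lay))
        w = {frozenset((u, v)): w for u, v, w in g.edges}
        assert w[frozenset(("g0", "g1"))] == pytest.approx(1.0)

    def test_node_score_is_sum_of_incident_weights(self):
        rng = np.random.default_rng(5)
        lay = layer(rng.standard_normal((6, 80)))
        g = build_coexpression_network(lay, self.de_for(lay))
        for node, score in g.nodes.items():
            incident = sum(w for u, v, w in g.edges if node in (u, v))
            assert score == pytest.approx(incident, abs=1e-9)

    def test_constant_gene_dropped(self, caplog):
        rng = np.random.default_rng(6)
        vals = rng.standard_normal((4, 30))
        vals[1] = 5.0
        lay = layer(vals)
        with caplog.at_level("WARNING"):
            g = build_coexpression_network(lay, self.de_for(lay))
        assert "g1" not in g.nodes


class TestConsensus:
    def planted_graph(self, shift=0, within=1.0, between=0.02):
        nodes = [f"n{i+shift}" for i in range(8)]
        g = CoexpressionGraph(nodes={n: 1.0 for n in nodes}, edges=[])
        for i in range(8):
            for j in range(i + 1, 8):
                same_block = (i < 4) == (j < 4)
                g.edges.append((nodes[i], nodes[j], within if same_block else between))
        return g

    def test_identity_transform_plus_communities(self):
        g = self.planted_graph()
        out = consensus_network([g], top_nodes=100, max_edges_per_node=100)
        assert set(out.nodes) == set(g.nodes)
        assert len(out.edges) == len(g.edges)
        assert out.communities is not None

    def test_two_identical_graphs_double_weights(self):
        g = self.planted_graph()
        out = consensus_network([g, g], top_nodes=100, max_edges_per_node=100)
        assert out.nodes["n0"] == pytest.approx(2.0)
        w = {frozenset((u, v)): wt for u, v, wt in out.edges}
        assert w[frozenset(("n0", "n1"))] == pytest.approx(2.0)

    def test_walktrap_recovers_planted_blocks(self):
        from sklearn.metrics import adjusted_rand_score

        g = self.planted_graph()
        out = consensus_network([g], top_nodes=8, max_edges_per_node=10)
        planted = [0 if int(n[1:]) < 4 else 1 for n in sorted(out.communities)]
        found = [out.communities[n] for n in sorted(out.communities)]
        assert adjusted_rand_score(planted, found) == 1.0

    def test_pruning_respects_either_endpoint_rule(self):
        # hub with many spokes: spokes keep their only (hence top-1) edge
        # even when the hub's own top list is exhausted
        nodes = {f"v{i}": 1.0 for i in range(12)}
        edges = [("v0", f"v{i}", 1.0 / i) for i in range(1, 12)]
        g = CoexpressionGraph(nodes=nodes, edges=edges)
        pruned = _prune_edges(list(g.edges), max_edges_per_node=3)
        # every spoke's single edge survives via the spoke endpoint
        assert len(pruned) == 11

    def test_pruning_removes_edges_outside_both_top_lists(self):
        # clique of 6: with max 2 per node, kept edges are each in some
        # endpoint's top-2; weights chosen so the weakest edges vanish
        rng = np.random.default_rng(7)
        nodes = {f"v{i}": 1.0 for i in range(6)}
        edges = []
        for i in range(6):
            for j in range(i + 1, 6):
                edges.append((f"v{i}", f"v{j}", float(rng.random())))
        pruned = _prune_edges(edges, max_edges_per_node=2)
        assert len(pruned) < len(edges)
        by_node = {}
        for u, v, w in edges:
            by_node.setdefault(u, []).append((w, (u, v, w)))
            by_node.setdefault(v, []).append((w, (u, v, w)))
        for e in pruned:
            u, v, _ = e
            tops = []
            for node in (u, v):
                lst = sorted(by_node[node], key=lambda t: -t[0])[:2]
                tops.extend(edge for _, edge in lst)
            assert e in tops
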