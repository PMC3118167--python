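"""Worked examples and properties of the 24 network parameters."""

import igraph as ig
import numpy as np
import pytest

from hairpinnet import FEATURE_NAMES, build_graph, compute_features
from hairpinnet.features import (NetworkFeaturizer, articulation_points,
                                 betweenness, burt_constraint, closeness,
                                 cocitation_coupling, community_partition,
                                 coreness, degree_stats, density, girth,
                                 hub_score, modularity, motif4_census,
                                 path_metrics, transitivity)
from hairpinnet.records import HairpinError, RnaRecord

import _oracles as oracle

P3 = ig.Graph(3, [(0, 1), (1, 2)])
STAR = ig.Graph(4, [(0, 1), (0, 2), (0, 3)])
TRIANGLE = ig.Graph(3, [(0, 1), (1, 2), (0, 2)])
K3 = TRIANGLE
C4 = ig.Graph(4, [(0, 1), (1, 2), (2, 3), (3, 0)])


class TestIndividualParameters:
    def test_degree_stats_hairpin(self, hairpin9_graph):
        mean, _ = degree_stats(hairpin9_graph)
        assert mean == pytest.approx(22 / 9)

    def test_betweenness_star_and_path(self):
        node_b, _ = betweenness(STAR)
        assert list(node_b) == [3.0, 0.0, 0.0, 0.0]
        node_b, edge_b = betweenness(P3)
        assert list(node_b) == [0.0, 1.0, 0.0]
        assert list(edge_b) == [2.0, 2.0]

    def test_closeness_path_and_complete(self):
        assert list(closeness(P3)) == pytest.approx([2 / 3, 1.0, 2 / 3])
        assert list(closeness(K3)) == pytest.approx([1.0, 1.0, 1.0])

    def test_burt_constraint_star_and_triangle(self):
        con = burt_constraint(STAR)
        assert con[0] == pytest.approx(1 / 3)
        assert list(con[1:]) == pytest.approx([1.0, 1.0, 1.0])
        assert list(burt_constraint(TRIANGLE)) == pytest.approx([1.125] * 3)

    def test_hub_score_path_and_cycle(self):
        assert list(hub_score(P3)) == pytest.approx(
            [2 ** -0.5, 1.0, 2 ** -0.5], abs=1e-10)
        assert list(hub_score(C4)) == pytest.approx([1.0] * 4)

    def test_coreness_hairpin_and_dangling_end(self):
        assert list(coreness(build_graph("(((...)))"))) == [2.0] * 9
        core = coreness(build_graph(".((...))"))
        assert core[0] == 1.0 and list(core[1:]) == [2.0] * 7
        assert core.mean() == pytest.approx(15 / 8)

    def test_cocitation_star_mean(self):
        pairs = cocitation_coupling(STAR)
        assert pairs.mean() == pytest.approx(0.5)  # 3 leaf pairs share 1

    def test_path_metrics_examples(self, hairpin9_graph):
        mean, var, diam = path_metrics(P3)
        assert (mean, diam) == (pytest.approx(4 / 3), 2.0)
        assert path_metrics(hairpin9_graph)[2] == 4.0
        mean, var, diam = path_metrics(K3)
        assert (mean, var, diam) == (1.0, 0.0, 1.0)

    def test_girth_conventions(self):
        assert girth(build_graph("." * 9)) == 0.0      # acyclic sentinel
        assert girth(build_graph("(...)")) == 5.0      # backbone loop
        assert girth(build_graph("(((...)))")) == 4.0  # stacked pairs

    def test_transitivity_examples(self, hairpin9_graph):
        assert transitivity(TRIANGLE) == 1.0
        assert transitivity(STAR) == 0.0
        assert transitivity(hairpin9_graph) == 0.0

    def test_density_examples(self, hairpin9_graph):
        assert density(hairpin9_graph) == pytest.approx(22 / 72)
        assert density(K3) == 1.0

    def test_modularity_single_edge_and_barbell(self):
        assert modularity(ig.Graph(2, [(0, 1)])) == 0.0
        barbell = ig.Graph(6, [(0, 1), (1, 2), (0, 2),
                               (3, 4), (4, 5), (3, 5), (2, 3)])
        part, q = community_partition(barbell)
        assert sorted(sorted(c) for c in part) == [[0, 1, 2], [3, 4, 5]]
        assert q == pytest.approx(oracle.modularity_q(
            6, barbell.get_edgelist(), part))
        assert q == pytest.approx(5 / 14)

    def test_modularity_internally_consistent(self, hairpin9_graph):
        part, q = community_partition(hairpin9_graph)
        edges = hairpin9_graph.graph.get_edgelist()
        assert q == pytest.approx(oracle.modularity_q(9, edges, part))

    def test_articulation_examples(self):
        assert articulation_points(build_graph("(((...)))")) == 0
        assert articulation_points(build_graph(".((...))")) == 1
        assert articulation_points(build_graph("." * 9)) == 7

    def test_motif_census_examples(self, hairpin9_graph):
        path, star, cycle = motif4_census(hairpin9_graph)
        assert (star, cycle) == (4, 2)
        assert motif4_census(ig.Graph(4, [(0, 1), (1, 2), (2, 3)])) == (1, 0, 0)


class TestFeatureVector:
    def test_worked_hairpin_values(self):
        vec = compute_features("(((...)))")
        assert vec["degree_mean"] == pytest.approx(22 / 9)
        assert vec["transitivity"] == 0.0
        assert vec["girth"] == 4.0
        assert vec["diameter"] == 4.0
        assert vec["density"] == pytest.approx(22 / 72)
        assert vec["n_articulation_points"] == 0.0
        assert vec["motif4_star"] == 4.0
        assert vec["motif4_cycle"] == 2.0

    def test_canonical_order_and_finiteness(self):
        vec = compute_features("((((....))))...")
        assert list(vec.index) == list(FEATURE_NAMES) and len(vec) == 24
        assert np.isfinite(vec.to_numpy()).all()

    def test_structure_only_and_deterministic(self):
        a = RnaRecord("a", "GGGAAACCC", "(((...)))")
        b = RnaRecord("b", "CCCUUUGGG", "(((...)))")
        va, vb = compute_features(a), compute_features(b)
        assert (va.to_numpy() == vb.to_numpy()).all()
        assert (va.to_numpy() == compute_features(a).to_numpy()).all()

    def test_cocitation_equals_bibcoupling(self, small_features):
        X = small_features.X
        assert (X["cocitation_mean"] == X["bibcoupling_mean"]).all()

    def test_too_short_rejected(self):
        with pytest.raises(HairpinError):
            compute_features(build_graph("...."))


class TestNetworkFeaturizer:
    def test_transform_matches_compute_features(self, small_records):
        frame = NetworkFeaturizer().fit_transform(small_records[:5])
        assert list(frame.columns) == list(FEATURE_NAMES)
        direct = compute_features(small_records[0])
        assert frame.iloc[0].to_numpy() == pytest.approx(direct.to_numpy())

    def test_sklearn_pipeline_composition(self, small_records):
        from sklearn.pipeline import Pipeline

        from hairpinnet import HairpinForestClassifier

        labels = [r.label for r in small_records]
        pipe = Pipeline([
            ("featurize", NetworkFeaturizer()),
            ("forest", HairpinForestClassifier(ntree=60, random_state=0)),
        ])
        pipe.fit(small_records, labels)
        assert pipe.score(small_records, labels) > 0.9
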