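"""SOM training, consensus metaclustering, rule annotation, k selection."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

import senocyto as sc
from senocyto import resources


def blob_matrix(panel, centers, n_per_blob, channels, rng, sd=0.3):
    """Gaussian blobs on the named channels, background noise elsewhere."""
    rows = []
    labels = []
    for i, center in enumerate(centers):
        block = pd.DataFrame(
            rng.normal(0.2, 0.25, size=(n_per_blob, len(panel.markers))),
            columns=panel.markers,
        )
        for ch, mean in zip(channels, center):
            block[ch] = rng.normal(mean, sd, n_per_blob)
        rows.append(block)
        labels += [i] * n_per_blob
    values = pd.concat(rows, ignore_index=True)
    m = sc.EventMatrix(values=values, panel=panel, transformed=True)
    return m, np.array(labels)


class TestSOM:
    def test_single_node_grid_collapses_to_mean(self, panel, rng):
        m, _ = blob_matrix(panel, [(0, 4), (4, 0)], 200, ["CD24", "Sca-1"], rng)
        model = sc.train_som(m, channels=["CD24", "Sca-1"], grid=(1, 1), epochs=5, seed=0)
        assert model.n_nodes == 1
        expected = m.values[["CD24", "Sca-1"]].mean().to_numpy()
        np.testing.assert_allclose(model.code_vectors[0], expected, atol=1e-6)

    def test_three_blobs_perfectly_assigned(self, panel, rng):
        m, truth = blob_matrix(
            panel, [(0, 0), (5, 0), (0, 5)], 300, ["CD24", "Sca-1"], rng
        )
        model = sc.train_som(m, channels=["CD24", "Sca-1"], grid=(3, 1), epochs=10, seed=1)
        nodes = model.assign_events(m)
        assert adjusted_rand_score(truth, nodes) == pytest.approx(1.0)

    def test_same_seed_reproduces_codes(self, panel, rng):
        m, _ = blob_matrix(panel, [(0, 0), (5, 5)], 300, ["CD24", "Sca-1"], rng)
        a = sc.train_som(m, channels=["CD24", "Sca-1"], grid=(4, 4), epochs=5, seed=7)
        b = sc.train_som(m, channels=["CD24", "Sca-1"], grid=(4, 4), epochs=5, seed=7)
        np.testing.assert_array_equal(a.code_vectors, b.code_vectors)

    def test_quantization_error_settles(self, panel, rng):
        m, _ = blob_matrix(panel, [(0, 0), (5, 0), (0, 5)], 500, ["CD24", "Sca-1"], rng)
        model = sc.train_som(m, channels=["CD24", "Sca-1"], grid=(5, 5), epochs=10, seed=2)
        trace = model.quantization_errors
        second_half = trace[len(trace) // 2 :]
        assert all(b <= a * 1.01 for a, b in zip(second_half, second_half[1:]))

    def test_fewer_events_than_nodes_rejected(self, panel, rng):
        m, _ = blob_matrix(panel, [(0, 0)], 10, ["CD24"], rng)
        with pytest.raises(ValueError, match="smaller grid"):
            sc.train_som(m, channels=["CD24"], grid=(10, 10), epochs=2, seed=0)


class TestConsensus:
    def test_k1_single_metacluster(self, panel, rng):
        m, _ = blob_matrix(panel, [(0, 0), (5, 5)], 200, ["CD24", "Sca-1"], rng)
        model = sc.train_som(m, channels=["CD24", "Sca-1"], grid=(3, 3), epochs=5, seed=0)
        res = sc.consensus_metacluster(model, m, k=1, iterations=5, seed=0)
        assert set(res.metacluster_of_event) == {0}

    def test_consensus_matrix_symmetric_unit_diagonal(self, panel, rng):
        m, _ = blob_matrix(panel, [(0, 0), (5, 0), (0, 5)], 300, ["CD24", "Sca-1"], rng)
        model = sc.train_som(m, channels=["CD24", "Sca-1"], grid=(4, 4), epochs=5, seed=3)
        res = sc.consensus_metacluster(model, m, k=3, iterations=10, seed=3)
        c = res.consensus
        np.testing.assert_allclose(c, c.T)
        np.testing.assert_allclose(np.diag(c), 1.0)
        assert c.min() >= 0 and c.max() <= 1

    def test_separated_blobs_recovered_with_high_ari(self, panel, rng):
        m, truth = blob_matrix(
            panel,
            [(0, 0, 0), (4, 0, 0), (0, 4, 0), (0, 0, 4)],
            400,
            ["CD24", "Sca-1", "LeptinR"],
            rng,
        )
        model = sc.train_som(m, channels=["CD24", "Sca-1", "LeptinR"], grid=(6, 6), epochs=10, seed=4)
        res = sc.consensus_metacluster(model, m, k=4, iterations=10, seed=4)
        assert adjusted_rand_score(truth, res.metacluster_of_event) >= 0.9

    def test_event_order_invariance(self, panel, rng):
        m, _ = blob_matrix(panel, [(0, 0), (5, 0), (0, 5)], 200, ["CD24", "Sca-1"], rng)
        model = sc.train_som(m, channels=["CD24", "Sca-1"], grid=(3, 1), epochs=10, seed=5)
        res = sc.consensus_metacluster(model, m, k=3, iterations=10, seed=5)
        perm = rng.permutation(m.n_events)
        m2 = m.take(perm)
        res2 = sc.consensus_metacluster(model, m2, k=3, iterations=10, seed=5)
        # same partition up to label names
        assert adjusted_rand_score(res.metacluster_of_event[perm], res2.metacluster_of_event) == 1.0

    def test_k_above_node_count_rejected(self, panel, rng):
        m, _ = blob_matrix(panel, [(0, 0)], 100, ["CD24"], rng)
        model = sc.train_som(m, channels=["CD24"], grid=(2, 2), epochs=2, seed=0)
        with pytest.raises(ValueError, match="exceeds"):
            sc.consensus_metacluster(model, m, k=5, iterations=2, seed=0)


class TestAnnotation:
    def test_cd24high_profile_matches_rule(self, panel, rng):
        rules = resources.table2_rules()
        centers = {
            "CD24high Osteolineage": {"CD24": 5.5, "Osterix": 4.0, "Runx2": 4.0},
            "CD24low Osteolineage": {"CD24": 1.8, "Osterix": 4.0, "Runx2": 4.0},
            "Early Osteoblasts": {"Runx2": 4.0, "Osterix": 4.0},
            "background": {},
        }
        blocks, sizes = [], [300, 400, 400, 1200]
        for (name, markers), n in zip(centers.items(), sizes):
            block = pd.DataFrame(
                rng.normal(0.2, 0.25, size=(n, len(panel.markers))), columns=panel.markers
            )
            for ch, mean in markers.items():
                block[ch] = rng.normal(mean, 0.4, n)
            blocks.append(block)
        m = sc.EventMatrix(values=pd.concat(blocks, ignore_index=True), panel=panel, transformed=True)
        model = sc.train_som(m, channels=panel.identity_markers, grid=(4, 4), epochs=10, seed=6)
        res = sc.consensus_metacluster(model, m, k=4, iterations=10, seed=6)
        res = sc.annotate_clusters(res, rules, m)
        labels = set(res.annotation.values())
        assert {
            "CD24high Osteolineage",
            "CD24low Osteolineage",
            "Early Osteoblasts",
            "unlabeled",
        } == labels

    def test_unknown_rule_marker_is_config_error(self, panel, rng):
        from senocyto.cluster import AnnotationRule, AnnotationRuleSet

        m, _ = blob_matrix(panel, [(0, 0), (5, 5)], 200, ["CD24", "Sca-1"], rng)
        model = sc.train_som(m, channels=["CD24", "Sca-1"], grid=(2, 2), epochs=3, seed=0)
        res = sc.consensus_metacluster(model, m, k=2, iterations=3, seed=0)
        rules = AnnotationRuleSet(
            rules=[AnnotationRule("x", 1, ("NotAMarker",), ())]
        )
        with pytest.raises(sc.PanelError, match="NotAMarker"):
            sc.annotate_clusters(res, rules, m)

    def test_abundances_sum_to_one_per_sample(self, panel, rng):
        m, _ = blob_matrix(panel, [(0, 0), (5, 0), (0, 5)], 300, ["CD24", "Sca-1"], rng)
        model = sc.train_som(m, channels=["CD24", "Sca-1"], grid=(3, 3), epochs=5, seed=1)
        res = sc.consensus_metacluster(model, m, k=3, iterations=5, seed=1)
        samples = np.array(["a", "b", "c"] * (m.n_events // 3))
        ab = res.abundance(samples)
        np.testing.assert_allclose(ab.sum(axis=1), 1.0)


class TestSelectK:
    def test_recovers_true_blob_count(self, panel, rng):
        m, _ = blob_matrix(
            panel,
            [(0, 0, 0), (5, 0, 0), (0, 5, 0), (0, 0, 5), (5, 5, 0)],
            400,
            ["CD24", "Sca-1", "LeptinR"],
            rng,
        )
        model = sc.train_som(m, channels=["CD24", "Sca-1", "LeptinR"], grid=(6, 6), epochs=10, seed=8)
        best, table = sc.select_k(model, m, (2, 8), iterations=5, seed=8)
        assert best == 5
        assert not table["no_structure"].iloc[0]

    def test_single_blob_flags_no_structure(self, panel, rng):
        m, _ = blob_matrix(panel, [(2, 2)], 800, ["CD24", "Sca-1"], rng)
        model = sc.train_som(m, channels=["CD24", "Sca-1"], grid=(4, 4), epochs=5, seed=9)
        _, table = sc.select_k(model, m, (2, 5), iterations=5, seed=9)
        assert table["no_structure"].iloc[0]

    def test_choice_invariant_to_event_order(self, panel, rng):
        m, _ = blob_matrix(panel, [(0, 0), (5, 0), (0, 5)], 300, ["CD24", "Sca-1"], rng)
        model = sc.train_som(m, channels=["CD24", "Sca-1"], grid=(4, 4), epochs=5, seed=10)
        best1, _ = sc.select_k(model, m, (2, 6), iterations=5, seed=10)
        m2 = m.take(rng.permutation(m.n_events))
        best2, _ = sc.select_k(model, m2, (2, 6), iterations=5, seed=10)
        assert best1 == best2 == 3
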