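"""Preprocessing: drift normalization, arcsinh, cleanup gate, subsampling."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import senocyto as sc
from senocyto.preprocess import CleanupParams


class TestBeadNormalize:
    def test_constant_bead_signal_is_identity(self, small_config):
        cfg = small_config.replace(drift_slope=0.0)
        m = sc.simulate_sample(cfg, "old", [1])
        # an exactly constant bead signal: every bin median equals the global
        # median, so every correction factor is exactly 1
        beads = sc.detect_beads(m)
        m.values.loc[beads, "Bead"] = 400.0
        out = sc.bead_normalize(m)
        np.testing.assert_array_equal(out.values.to_numpy(), m.values.to_numpy())

    def test_injected_drift_equalizes_bin_medians(self, small_config):
        cfg = small_config.replace(drift_slope=-0.20, events_per_sample=20000)
        m = sc.simulate_sample(cfg, "old", [2])
        out = sc.bead_normalize(m, n_bins=20)

        def bin_medians(matrix):
            bead = matrix.values["Bead"].to_numpy()
            sel = sc.detect_beads(matrix)
            edges = np.linspace(0, len(bead), 21).astype(int)
            return np.array(
                [np.median(bead[lo:hi][sel[lo:hi]]) for lo, hi in zip(edges, edges[1:])]
            )

        before, after = bin_medians(m), bin_medians(out)
        assert np.ptp(before) / np.median(before) > 0.10  # drift clearly present
        assert np.ptp(after) / np.median(after) < 0.01

    def test_no_bead_events_passes_through_with_warning(self, small_config, caplog):
        cfg = small_config.replace(
            contamination={**small_config.contamination, "beads": 0.0}
        )
        m = sc.simulate_sample(cfg, "old", [3])
        with caplog.at_level("WARNING"):
            out = sc.bead_normalize(m)
        assert out.values.equals(m.values)
        assert "bead" in caplog.text.lower()

    def test_preserves_event_count_and_order(self, small_config):
        m = sc.simulate_sample(small_config, "young", [4])
        out = sc.bead_normalize(m)
        assert out.n_events == m.n_events
        # per-event correction is multiplicative, so zero stays zero and the
        # event-length channel is untouched
        pd.testing.assert_series_equal(out.values["Event_length"], m.values["Event_length"])


class TestArcsinh:
    def test_closed_form_values(self, panel):
        values = pd.DataFrame(
            np.zeros((2, len(panel.markers))), columns=panel.markers
        )
        values.iloc[1] = 5.0
        m = sc.EventMatrix(values=values, panel=panel)
        out = sc.arcsinh_transform(m, cofactor=5.0)
        assert out.values.iloc[0, 0] == 0.0
        assert out.values.iloc[1, 0] == pytest.approx(0.8814, abs=1e-4)
        assert out.transformed

    def test_double_transform_rejected(self, panel):
        m = sc.EventMatrix(
            values=pd.DataFrame(np.ones((3, len(panel.markers))), columns=panel.markers),
            panel=panel,
        )
        once = sc.arcsinh_transform(m)
        with pytest.raises(ValueError, match="already"):
            sc.arcsinh_transform(once)

    @settings(max_examples=50, deadline=None)
    @given(
        x1=st.floats(0, 1e6, allow_nan=False),
        delta=st.floats(1e-6, 1e6, allow_nan=False),
        cofactor=st.floats(0.5, 50),
    )
    def test_strictly_monotone(self, x1, delta, cofactor):
        a = np.arcsinh(x1 / cofactor)
        b = np.arcsinh((x1 + delta) / cofactor)
        assert b > a


class TestCleanupGate:
    def test_all_clean_input_keeps_99_percent(self, small_config):
        cfg = small_config.replace(
            contamination={k: 0.0 for k in small_config.contamination}
        )
        m = sc.simulate_sample(cfg, "young", [5])
        mt = sc.arcsinh_transform(sc.bead_normalize(m), cfg.cofactor)
        clean, qc = sc.cleanup_gate(mt, CleanupParams.from_dict(cfg.cleanup))
        assert clean.n_events >= 0.99 * m.n_events
        assert qc.stage_counts["input"] == m.n_events

    def test_precision_recall_per_contamination_class(self, config):
        cfg = config.replace(
            events_per_sample=20000,
            contamination={"beads": 0.05, "doublets": 0.05, "dead": 0.05,
                           "debris": 0.02, "cd45pos": 0.03},
        )
        m = sc.simulate_sample(cfg, "old", [6])
        mt = sc.arcsinh_transform(sc.bead_normalize(m), cfg.cofactor)
        _, qc = sc.cleanup_gate(mt, CleanupParams.from_dict(cfg.cleanup))
        truth = m.truth["contamination_class"]
        pred = qc.removed_class
        for cls in ("bead", "doublet", "dead", "debris", "cd45pos"):
            tp = int(((truth == cls) & (pred == cls)).sum())
            fp = int(((truth != cls) & (pred == cls)).sum())
            fn = int(((truth == cls) & (pred != cls)).sum())
            assert tp / (tp + fp) >= 0.95, f"{cls} precision"
            assert tp / (tp + fn) >= 0.95, f"{cls} recall"

    def test_cd45_carryover_removed(self, small_cohort):
        """Lin-CD45- selection removes simulated hematopoietic carryover."""
        for m in small_cohort["matrices"].values():
            kept = m.truth["contamination_class"]
            assert (kept == "cd45pos").mean() < 0.005

    def test_stage_counts_reconcile_and_nonincreasing(self, small_config):
        m = sc.simulate_sample(small_config, "old", [7])
        mt = sc.arcsinh_transform(sc.bead_normalize(m), small_config.cofactor)
        clean, qc = sc.cleanup_gate(mt, CleanupParams.from_dict(small_config.cleanup))
        counts = list(qc.stage_counts.values())
        assert counts == sorted(counts, reverse=True)
        removed = (qc.removed_class != "kept").sum()
        assert counts[0] - counts[-1] == removed
        assert clean.n_events == counts[-1]

    def test_idempotent(self, small_config):
        m = sc.simulate_sample(small_config, "old", [8])
        mt = sc.arcsinh_transform(sc.bead_normalize(m), small_config.cofactor)
        params = CleanupParams.from_dict(small_config.cleanup)
        once, _ = sc.cleanup_gate(mt, params)
        twice, qc2 = sc.cleanup_gate(once, params)
        pd.testing.assert_frame_equal(once.values, twice.values)
        assert (qc2.removed_class == "kept").all()

    def test_missing_instrument_channel_named_in_error(self, small_config):
        from senocyto.panel import PanelDefinition

        m = sc.simulate_sample(small_config, "old", [9])
        mt = sc.arcsinh_transform(m, small_config.cofactor)
        broken_panel = PanelDefinition(
            tuple(c for c in mt.panel.channels if c.category != "instrument_viability")
        )
        broken = sc.EventMatrix(
            values=mt.values.drop(columns=["Viability"]),
            panel=broken_panel,
            transformed=True,
        )
        with pytest.raises(sc.PanelError, match="instrument_viability"):
            sc.cleanup_gate(broken, CleanupParams.from_dict(small_config.cleanup))

    def test_malformed_params_rejected(self):
        with pytest.raises(ValueError, match="dna_bounds"):
            CleanupParams(
                dna_bounds=(5.0, 4.0), event_length_max=1, viability_max=1,
                bead_min=1, cd45_max=1, lineage_max=1,
            )


class TestSubsample:
    def test_zero_and_oversized_requests(self, small_cohort):
        m = next(iter(small_cohort["matrices"].values()))
        assert sc.subsample_events(m, 0, seed=1).n_events == 0
        assert sc.subsample_events(m, 10**7, seed=1).n_events == m.n_events

    def test_deterministic_given_seed(self, small_cohort):
        m = next(iter(small_cohort["matrices"].values()))
        a = sc.subsample_events(m, 500, seed=42)
        b = sc.subsample_events(m, 500, seed=42)
        pd.testing.assert_frame_equal(a.values, b.values)
        c = sc.subsample_events(m, 500, seed=43)
        assert not a.values.equals(c.values)

    def test_pooling_count_is_exact(self, small_cohort):
        """n samples x 2,000 events pool to exactly 2,000 n events."""
        parts = [
            sc.subsample_events(m, 2000, seed=i)
            for i, m in enumerate(small_cohort["matrices"].values())
        ]
        total = sum(p.n_events for p in parts)
        assert total == 2000 * len(small_cohort["matrices"])
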