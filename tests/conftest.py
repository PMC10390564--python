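"""Shared fixtures: the default panel, a desk-scale simulation config, and a
fully preprocessed small cohort reused across gating/profile tests."""

from __future__ import annotations

import numpy as np
import pytest

import senocyto as sc


@pytest.fixture(scope="session")
def panel():
    return sc.default_panel()


@pytest.fixture(scope="session")
def config():
    return sc.SimulationConfig.default()


@pytest.fixture(scope="session")
def small_config(config):
    return config.replace(events_per_sample=4000)


def preprocess_sample(cfg, group, seed, master=1, ko=False, sample_id=None):
    """Simulate -> bead-normalize -> arcsinh -> cleanup one sample."""
    m = sc.simulate_sample(
        cfg, group, [master, seed], sample_id=sample_id or f"{group}_{seed}", ko_control=ko
    )
    m = sc.arcsinh_transform(sc.bead_normalize(m), cfg.cofactor)
    clean, _ = sc.cleanup_gate(m, sc.CleanupParams.from_dict(cfg.cleanup))
    return clean


@pytest.fixture(scope="session")
def small_cohort(small_config):
    """5 young + 5 old cleaned samples plus a KO control, with thresholds."""
    young = {f"y{i}": preprocess_sample(small_config, "young", i) for i in range(1, 6)}
    old = {f"o{i}": preprocess_sample(small_config, "old", 100 + i) for i in range(1, 6)}
    ko = preprocess_sample(small_config, "young", 999, ko=True, sample_id="ko")

    thresholds = sc.ThresholdSet()
    thresholds.add(sc.derive_threshold(ko, "p16", 0.999))
    for marker, spec in small_config.thresholds.items():
        if spec["source"] == "quantile_of_pooled":
            thresholds.add(
                sc.pooled_quantile_threshold(list(young.values()), marker, float(spec["quantile"]))
            )
    matrices = {**young, **old}
    calls = {sid: sc.call_markers(m, thresholds) for sid, m in matrices.items()}
    groups = {sid: ("young" if sid.startswith("y") else "old") for sid in matrices}
    return {
        "matrices": matrices,
        "ko": ko,
        "thresholds": thresholds,
        "calls": calls,
        "groups": groups,
        "config": small_config,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
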