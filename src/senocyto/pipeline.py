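"""End-to-end pipeline orchestration with provenance.

One YAML run config drives the fixed stage order simulate -> preprocess ->
gate -> cluster -> diff -> citrus -> report. Every written artifact is
digested (sha256) into a run manifest so regenerated outputs can be checked
byte-for-byte; the master seed is recorded in the manifest and threaded into
every stochastic stage.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import resources
from .cluster import annotate_clusters, consensus_metacluster
from .events import EventMatrix, write_events
from .gating import (
    ThresholdSet,
    call_markers,
    derive_threshold,
    pooled_quantile_threshold,
    summarize_calls,
)
from .panel import CohortDesign, PanelDefinition, PanelError, load_design, load_panel
from .preprocess import CleanupParams, arcsinh_transform, bead_normalize, cleanup_gate, subsample_events
from .profiles import clearance_report
from .simulate import SimulationConfig, simulate_cohort
from .som import train_som
from .stats import compare_table

logger = logging.getLogger(__name__)

STAGES = ("simulate", "preprocess", "gate", "cluster", "diff", "citrus", "report")


class PipelineValidationError(ValueError):
    pass


class StageFailure(RuntimeError):
    def __init__(self, stage: str, cause: Exception) -> None:
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclasses.dataclass
class RunConfig:
    output_dir: Path
    seed: int = 0
    panel_path: Path | None = None
    design_path: Path | None = None
    cohort_config_path: Path | None = None
    enabled: dict[str, bool] = dataclasses.field(default_factory=dict)
    params: dict[str, Any] = dataclasses.field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        base = Path(path).parent
        def resolve(key):
            return (base / raw[key]).resolve() if raw.get(key) else None
        cfg = cls(
            output_dir=(base / raw["output_dir"]).resolve(),
            seed=int(raw.get("seed", 0)),
            panel_path=resolve("panel"),
            design_path=resolve("design"),
            cohort_config_path=resolve("cohort_config"),
            enabled={s: bool(v) for s, v in raw.get("stages", {}).items()},
            params=raw.get("params", {}),
        )
        cfg.validate()
        return cfg

    def validate(self) -> None:
        for key in self.enabled:
            if key not in STAGES:
                raise PipelineValidationError(f"unknown stage {key!r}")
        for p in (self.panel_path, self.design_path, self.cohort_config_path):
            if p is not None and not Path(p).exists():
                raise PipelineValidationError(f"referenced file {p} does not exist")
        if not self.stage_enabled("simulate") and self.design_path is None:
            raise PipelineValidationError("need a design with file paths when simulate is disabled")
        if self.stage_enabled("diff") and not self.stage_enabled("gate"):
            raise PipelineValidationError("diff stage requires the gate stage")
        if self.stage_enabled("report") and not self.stage_enabled("cluster"):
            raise PipelineValidationError("report stage requires the cluster stage")

    def stage_enabled(self, stage: str) -> bool:
        return self.enabled.get(stage, True)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclasses.dataclass
class RunManifest:
    seed: int
    stages: dict[str, dict[str, Any]] = dataclasses.field(default_factory=dict)

    def record(self, stage: str, status: str, outputs: list[Path] | None = None, **extra: Any) -> None:
        self.stages[stage] = {
            "status": status,
            "outputs": {str(p): _sha256(Path(p)) for p in (outputs or [])},
            **extra,
        }

    def write(self, path: Path) -> Path:
        with open(path, "w") as fh:
            json.dump({"seed": self.seed, "stages": self.stages}, fh, indent=2, sort_keys=True)
        return path


def _default_design() -> CohortDesign:
    rows = [(f"young_{i:02d}", "young", "none", "wildtype", "") for i in range(1, 16)]
    rows += [(f"old_{i:02d}", "old", "vehicle", "wildtype", "") for i in range(1, 13)]
    rows += [(f"senolytic_{i:02d}", "old", "senolytic", "wildtype", "") for i in range(1, 14)]
    rows += [("ko_control", "young", "none", "ko_control", "")]
    return CohortDesign.from_rows(rows)


def run_pipeline(config: RunConfig) -> RunManifest:
    """Execute the enabled stages in fixed order; abort on the first failure."""
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(seed=config.seed)

    panel = load_panel(config.panel_path) if config.panel_path else resources.default_panel()
    design = load_design(config.design_path) if config.design_path else _default_design()
    sim_config = (
        SimulationConfig.from_yaml(config.cohort_config_path)
        if config.cohort_config_path
        else SimulationConfig.default()
    )
    sim_config = sim_config.replace(seed=config.seed, **config.params.get("simulate", {}))

    state: dict[str, Any] = {"panel": panel, "design": design}
    for stage in STAGES:
        if not config.stage_enabled(stage):
            manifest.record(stage, "skipped")
            continue
        try:
            outputs = _STAGE_FUNCS[stage](config, sim_config, state, out)
            manifest.record(stage, "complete", outputs)
        except Exception as exc:  # noqa: BLE001 - manifest must name the stage
            manifest.record(stage, "failed", error=str(exc))
            manifest.write(out / "manifest.json")
            raise StageFailure(stage, exc) from exc

    manifest.write(out / "manifest.json")
    return manifest


# --------------------------------------------------------------------------
# stage implementations
# --------------------------------------------------------------------------


def _stage_simulate(config, sim_config, state, out) -> list[Path]:
    matrices = simulate_cohort(sim_config, state["design"], state["panel"])
    state["raw"] = matrices
    qc_dir = out / "events"
    qc_dir.mkdir(exist_ok=True)
    paths = []
    if config.params.get("simulate", {}).get("write_events", False):
        for sid, m in matrices.items():
            paths.append(write_events(m, qc_dir / f"{sid}.tsv", format="tsv"))
    return paths


def _stage_preprocess(config, sim_config, state, out) -> list[Path]:
    if "raw" not in state:
        from .events import read_events

        state["raw"] = {
            r["sample_id"]: read_events(r["file_path"], state["panel"], r["sample_id"])
            for _, r in state["design"].samples.iterrows()
        }
    params = CleanupParams.from_dict(sim_config.cleanup)
    cleaned, reports = {}, []
    for sid, m in state["raw"].items():
        normalized = bead_normalize(m, state["panel"])
        transformed = arcsinh_transform(normalized, sim_config.cofactor)
        clean, qc = cleanup_gate(transformed, params, state["panel"])
        cleaned[sid] = clean
        reports.append(qc.to_frame().assign(sample_id=sid))
    state["clean"] = cleaned
    qc_path = out / "qc_report.tsv"
    pd.concat(reports, ignore_index=True).to_csv(qc_path, sep="\t", index=False)
    return [qc_path]


def _stage_gate(config, sim_config, state, out) -> list[Path]:
    clean = state["clean"]
    design: CohortDesign = state["design"]
    thresholds = ThresholdSet()
    gate_params = config.params.get("gate", {})

    ko_ids = list(design.samples.loc[design.samples["genotype"] == "ko_control", "sample_id"])
    for marker, spec in sim_config.thresholds.items():
        if spec["source"] == "ko_control":
            if not ko_ids:
                raise PanelError(f"marker {marker} needs a ko_control sample in the design")
            thresholds.add(derive_threshold(clean[ko_ids[0]], marker, float(spec["quantile"])))
        else:
            young = [clean[s] for s in design.sample_ids("young")]
            thresholds.add(pooled_quantile_threshold(young, marker, float(spec["quantile"])))

    analysis_ids = design.sample_ids()
    calls = {sid: call_markers(clean[sid], thresholds) for sid in analysis_ids}
    state["thresholds"] = thresholds
    state["calls"] = calls
    summary = summarize_calls(calls, design, {s: clean[s] for s in analysis_ids})
    state["summary"] = summary

    t_path = thresholds.to_yaml(out / "thresholds.yaml")
    s_path = out / "senescence_summary.tsv"
    summary.to_csv(s_path, sep="\t", index=False)
    return [t_path, s_path]


def _stage_cluster(config, sim_config, state, out) -> list[Path]:
    clean = state["clean"]
    design: CohortDesign = state["design"]
    p = config.params.get("cluster", {})
    n_sub = int(p.get("events_per_sample", 2000))
    ids = design.sample_ids()
    pooled_parts, owners = [], []
    for sid in ids:
        sub = subsample_events(clean[sid], n_sub, seed=config.seed)
        pooled_parts.append(sub.values)
        owners.append(np.repeat(sid, sub.n_events))
    pooled_values = pd.concat(pooled_parts, ignore_index=True)
    pooled = EventMatrix(
        values=pooled_values, panel=state["panel"], sample_id="pooled", transformed=True
    )
    model = train_som(
        pooled,
        channels=state["panel"].identity_markers,
        grid=tuple(p.get("grid", (10, 10))),
        epochs=int(p.get("epochs", 10)),
        seed=config.seed,
    )
    result = consensus_metacluster(
        model, pooled, k=int(p.get("k", 11)), iterations=int(p.get("iterations", 10)),
        seed=config.seed,
    )
    rules = resources.table2_rules()
    result = annotate_clusters(result, rules, pooled)
    state["pooled"] = pooled
    state["pooled_owner"] = np.concatenate(owners)
    state["metaclusters"] = result

    prof_path = out / "cluster_profiles.tsv"
    result.profiles.assign(
        annotation=[result.annotation[m] for m in result.profiles.index]
    ).to_csv(prof_path, sep="\t")
    assign_path = out / "cluster_assignments.tsv"
    pd.DataFrame(
        {
            "sample_id": state["pooled_owner"],
            "node": result.node_of_event,
            "metacluster": result.metacluster_of_event,
            "label": result.labels_of_event,
        }
    ).to_csv(assign_path, sep="\t", index=False)
    return [prof_path, assign_path]


def _stage_diff(config, sim_config, state, out) -> list[Path]:
    summary = state["summary"]
    contrast = tuple(config.params.get("diff", {}).get("contrast", ("young", "old")))
    metrics = [c for c in summary.columns if c.startswith(("pct_", "mean_"))]
    table = compare_table(
        summary.set_index("sample_id")[metrics], summary.set_index("sample_id")["group"],
        contrast,
    )
    path = out / f"diff_{contrast[0]}_vs_{contrast[1]}.tsv"
    table.to_csv(path, sep="\t", index=False)
    state["diff"] = table
    return [path]


def _stage_citrus(config, sim_config, state, out) -> list[Path]:
    from .citrus import build_hierarchy, extract_features, sam_association

    design: CohortDesign = state["design"]
    p = config.params.get("citrus", {})
    contrast = tuple(p.get("contrast", ("old", "old_senolytic")))
    ids = [s for s in design.sample_ids() if design.group_of(s) in contrast]
    if len(ids) < 6:
        raise PipelineValidationError("citrus stage needs >= 3 samples per arm")
    hierarchy = build_hierarchy(
        {s: state["clean"][s] for s in ids},
        n_per_sample=int(p.get("events_per_sample", 500)),
        min_fraction=float(p.get("min_cluster_frac", 0.02)),
        channels=state["panel"].identity_markers,
        seed=config.seed,
    )
    groups = {s: design.group_of(s) for s in ids}
    features = extract_features(hierarchy, "abundance", groups)
    assoc = sam_association(
        features,
        target_fdr=float(p.get("fdr", 0.05)),
        n_permutations=int(p.get("permutations", 500)),
        seed=config.seed,
    )
    state["citrus"] = (hierarchy, features, assoc)
    path = out / "citrus_associations.tsv"
    assoc.features.to_csv(path, sep="\t")
    return [path]


def _stage_report(config, sim_config, state, out) -> list[Path]:
    design: CohortDesign = state["design"]
    result = state["metaclusters"]
    owner = state["pooled_owner"]
    labels = result.labels_of_event

    # per-sample abundance of each annotated cluster on the pooled events
    rows = []
    for sid in design.sample_ids():
        mask = owner == sid
        if not mask.any():
            continue
        lab = labels[mask]
        total = mask.sum()
        for name in sorted(set(labels)):
            rows.append(
                {
                    "sample_id": sid,
                    "group": design.group_of(sid),
                    "cluster": name,
                    "fraction": float((lab == name).sum()) / float(total),
                }
            )
    abundances = pd.DataFrame(rows)
    outputs = []
    a_path = out / "cluster_abundances.tsv"
    abundances.to_csv(a_path, sep="\t", index=False)
    outputs.append(a_path)

    arms = set(abundances["group"])
    if {"old", "old_senolytic"} <= arms:
        clearance = clearance_report(abundances, ("old", "old_senolytic"))
        c_path = out / "clearance_report.tsv"
        clearance.to_csv(c_path, sep="\t", index=False)
        outputs.append(c_path)

    run_summary = {
        "seed": config.seed,
        "n_samples": len(design.sample_ids()),
        "clusters": sorted(set(labels)),
        "citrus_included": "citrus" in state,
    }
    if "citrus" in state:
        run_summary["n_significant_citrus_features"] = int(
            state["citrus"][2].features["significant"].sum()
        )
    j_path = out / "run_summary.json"
    with open(j_path, "w") as fh:
        json.dump(run_summary, fh, indent=2, sort_keys=True)
    outputs.append(j_path)
    return outputs


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "preprocess": _stage_preprocess,
    "gate": _stage_gate,
    "cluster": _stage_cluster,
    "diff": _stage_diff,
    "citrus": _stage_citrus,
    "report": _stage_report,
}
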