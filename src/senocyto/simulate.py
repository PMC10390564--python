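"""Synthetic CyTOF cohort generator with full ground truth.

Emulates the statistical structure of a bone/marrow mesenchymal mass-cytometry
cohort: 11 identity-marker-defined populations, age- and treatment-dependent
p16+/p21+ prevalences with conditional BCL-2/Ki67 rates (so that combinatorial
p16KB = p16+/Ki67-/BCL-2+ calls are recoverable), senescence archetypes that
shift SASP/DNA-damage channels, bead/doublet/dead-cell/debris/CD45+
contamination, and slow multiplicative signal drift over acquisition order.

Marker noise is normal on the arcsinh scale (cofactor 5), inverse-transformed
to ion counts and truncated at zero. Every event carries truth labels
(population, contamination class, senescence flags, archetype) so downstream
gating and clustering can be validated against known answers.
"""

from __future__ import annotations

import dataclasses
import zlib
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from .events import EventMatrix
from .panel import CohortDesign, PanelDefinition, PanelError, default_panel

__all__ = [
    "SimulationConfig",
    "simulate_sample",
    "simulate_cohort",
    "truth_summary",
    "GROUPS",
]

GROUPS = ("young", "old", "old_senolytic")

#: contamination classes; 'cell' marks clean analysis events
CONTAMINATION_CLASSES = ("cell", "bead", "doublet", "dead", "debris", "cd45pos")

TRUTH_COLUMNS = [
    "population",
    "contamination_class",
    "archetype",
    "p16_true",
    "p21_true",
    "ki67_true",
    "bcl2_true",
    "p16kb_true",
    "p21kb_true",
]


@dataclasses.dataclass
class PopulationSpec:
    name: str
    weight: dict[str, float]
    senescence_enrichment: dict[str, float]
    markers: dict[str, float]


@dataclasses.dataclass
class SenescenceArchetype:
    name: str
    family: str  # bcl2 | ki67 | other — the flag combination it is compatible with
    weight: float
    shifts: dict[str, float]


@dataclasses.dataclass
class SimulationConfig:
    """Full simulator calibration; see ``config/default_cohort.yaml``."""

    events_per_sample: int
    cofactor: float
    seed: int
    baseline_mean: float
    baseline_sd: float
    positive_cv: float
    contamination: dict[str, float]
    drift_slope: float
    between_animal_cv: float
    prevalence: dict[str, dict[str, float]]
    conditional: dict[str, Any]
    marker_positive_means: dict[str, float]
    instrument: dict[str, Any]
    cleanup: dict[str, Any]
    thresholds: dict[str, dict[str, Any]]
    populations: list[PopulationSpec]
    archetypes: list[SenescenceArchetype]

    def __post_init__(self) -> None:
        if self.events_per_sample < 1:
            raise PanelError("events_per_sample must be >= 1")
        for frac in self.contamination.values():
            if not 0.0 <= frac <= 1.0:
                raise PanelError("contamination fractions must lie in [0, 1]")
        if sum(self.contamination.values()) > 1.0:
            raise PanelError("contamination fractions sum above 1")
        for marker, by_group in self.prevalence.items():
            for g, p in by_group.items():
                if not 0.0 <= p <= 1.0:
                    raise PanelError(f"prevalence {marker}/{g} outside [0, 1]")
        for group in GROUPS:
            total = sum(p.weight.get(group, 0.0) for p in self.populations)
            if abs(total - 1.0) > 1e-6:
                raise PanelError(f"population weights for group {group!r} sum to {total}, not 1")
        for family in ("bcl2", "ki67", "other"):
            wsum = sum(a.weight for a in self.archetypes if a.family == family)
            if wsum and abs(wsum - 1.0) > 1e-6:
                raise PanelError(f"archetype weights in family {family!r} sum to {wsum}, not 1")

    # -- construction ------------------------------------------------------
    @classmethod
    def from_dict(cls, raw: Mapping[str, Any]) -> "SimulationConfig":
        pops = [
            PopulationSpec(
                name=p["name"],
                weight={k: float(v) for k, v in p["weight"].items()},
                senescence_enrichment={k: float(v) for k, v in p.get("senescence_enrichment", {}).items()},
                markers={k: float(v) for k, v in p.get("markers", {}).items()},
            )
            for p in raw["populations"]
        ]
        archs = [
            SenescenceArchetype(
                name=a["name"],
                family=a["family"],
                weight=float(a["weight"]),
                shifts={k: float(v) for k, v in a.get("shifts", {}).items()},
            )
            for a in raw.get("archetypes", [])
        ]
        return cls(
            events_per_sample=int(raw["events_per_sample"]),
            cofactor=float(raw.get("cofactor", 5.0)),
            seed=int(raw.get("seed", 0)),
            baseline_mean=float(raw.get("baseline_mean", 0.2)),
            baseline_sd=float(raw.get("baseline_sd", 0.25)),
            positive_cv=float(raw.get("positive_cv", 0.12)),
            contamination={k: float(v) for k, v in raw.get("contamination", {}).items()},
            drift_slope=float(raw.get("drift_slope", 0.0)),
            between_animal_cv=float(raw.get("between_animal_cv", 0.0)),
            prevalence={m: dict(v) for m, v in raw["prevalence"].items()},
            conditional=dict(raw["conditional"]),
            marker_positive_means=dict(raw["marker_positive_means"]),
            instrument=dict(raw["instrument"]),
            cleanup=dict(raw.get("cleanup", {})),
            thresholds={m: dict(v) for m, v in raw.get("thresholds", {}).items()},
            populations=pops,
            archetypes=archs,
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    @classmethod
    def default(cls, **overrides: Any) -> "SimulationConfig":
        from . import resources

        cfg = resources.default_cohort_config()
        for key, value in overrides.items():
            if not hasattr(cfg, key):
                raise AttributeError(f"unknown config field {key!r}")
            setattr(cfg, key, value)
        return cfg

    def replace(self, **overrides: Any) -> "SimulationConfig":
        return dataclasses.replace(self, **overrides)


# ---------------------------------------------------------------------------
# sampling helpers
# ---------------------------------------------------------------------------


def _marker_sd(config: SimulationConfig, mean: np.ndarray) -> np.ndarray:
    return np.maximum(config.positive_cv * mean, config.baseline_sd)


def _draw_cells(
    config: SimulationConfig,
    panel: PanelDefinition,
    group: str,
    n: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw n clean-cell events: arcsinh-scale antibody matrix + population idx."""
    markers = panel.markers
    n_chan = len(markers)
    weights = np.array([p.weight[group] for p in config.populations])
    pop_idx = rng.choice(len(config.populations), size=n, p=weights / weights.sum())

    mean_table = np.full((len(config.populations), n_chan), config.baseline_mean)
    for i, pop in enumerate(config.populations):
        for marker, mean in pop.markers.items():
            if marker in markers:
                mean_table[i, markers.index(marker)] = mean
    means = mean_table[pop_idx]
    values = rng.normal(means, _marker_sd(config, means))
    return values, pop_idx


def _assign_flags(
    config: SimulationConfig,
    group: str,
    pop_idx: np.ndarray,
    rng: np.random.Generator,
    jitter: dict[str, float],
    ko_control: bool,
) -> pd.DataFrame:
    n = len(pop_idx)
    cond = config.conditional
    weights = np.array([p.weight[group] for p in config.populations])
    enrich = np.array([p.senescence_enrichment.get(group, 1.0) for p in config.populations])
    norm = float((weights * enrich).sum() / weights.sum())

    p16_marginal = 0.0 if ko_control else config.prevalence["p16"][group] * jitter.get("p16", 1.0)
    p16_prob = np.clip(p16_marginal * enrich[pop_idx] / norm, 0.0, 1.0)
    p16 = rng.random(n) < p16_prob

    bcl2_prob = np.where(
        p16,
        float(cond["bcl2_given_p16"][group]),
        float(cond["bcl2_given_not_p16"]),
    )
    bcl2 = rng.random(n) < bcl2_prob

    ki67_prob = np.where(
        p16,
        np.where(bcl2, float(cond["ki67_given_p16_bcl2"]), float(cond["ki67_given_p16_not_bcl2"])),
        float(cond["ki67_background"]),
    )
    ki67 = rng.random(n) < ki67_prob

    # p21+ cells mark a distinct (non-p16) senescence route; the flags are
    # disjoint, with the conditional rate renormalized to keep the marginal
    p21_marginal = np.clip(config.prevalence["p21"][group] * jitter.get("p21", 1.0), 0.0, 1.0)
    p16_marginal_eff = min(float(np.mean(p16_prob)), 0.99)
    p21 = (~p16) & (rng.random(n) < min(p21_marginal / (1.0 - p16_marginal_eff), 1.0))

    return pd.DataFrame(
        {
            "p16_true": p16,
            "p21_true": p21,
            "ki67_true": ki67,
            "bcl2_true": bcl2,
            "p16kb_true": p16 & ~ki67 & bcl2,
            "p21kb_true": p21 & ~ki67 & bcl2,
        }
    )


def _apply_flag_intensities(
    config: SimulationConfig,
    panel: PanelDefinition,
    values: np.ndarray,
    flags: pd.DataFrame,
    rng: np.random.Generator,
) -> None:
    """Regenerate flag-driven channels (p16/p21/Ki67/BCL-2) for positive events."""
    markers = panel.markers
    for flag, marker in (
        ("p16_true", "p16"),
        ("p21_true", "p21"),
        ("ki67_true", "Ki67"),
        ("bcl2_true", "BCL-2"),
    ):
        if marker not in markers:
            continue
        mask = flags[flag].to_numpy()
        if not mask.any():
            continue
        mean = config.marker_positive_means[marker]
        col = markers.index(marker)
        values[mask, col] = rng.normal(mean, max(config.positive_cv * mean, config.baseline_sd), mask.sum())


def _assign_archetypes(
    config: SimulationConfig,
    panel: PanelDefinition,
    values: np.ndarray,
    flags: pd.DataFrame,
    rng: np.random.Generator,
) -> np.ndarray:
    """Pick a flag-compatible archetype per p16+ event and apply its shifts."""
    markers = panel.markers
    n = len(flags)
    archetype = np.array([""] * n, dtype=object)
    p16 = flags["p16_true"].to_numpy()
    bcl2 = flags["bcl2_true"].to_numpy()
    ki67 = flags["ki67_true"].to_numpy()
    family = np.where(ki67, "ki67", np.where(bcl2, "bcl2", "other"))

    for fam in ("bcl2", "ki67", "other"):
        members = p16 & (family == fam)
        if not members.any():
            continue
        options = [a for a in config.archetypes if a.family == fam]
        if not options:
            continue
        w = np.array([a.weight for a in options], dtype=float)
        pick = rng.choice(len(options), size=int(members.sum()), p=w / w.sum())
        archetype[members] = [options[i].name for i in pick]
        member_rows = np.flatnonzero(members)
        for i, arch in enumerate(options):
            rows = member_rows[pick == i]
            for marker, shift in arch.shifts.items():
                if marker in markers:
                    values[rows, markers.index(marker)] += shift
    return archetype


def sample_seed_for(config_seed: int, sample_id: str) -> list[int]:
    """Deterministic per-sample seed material from (master seed, sample_id)."""
    return [int(config_seed), zlib.crc32(sample_id.encode("utf-8")) & 0x7FFFFFFF]


def simulate_sample(
    config: SimulationConfig,
    group: str,
    sample_seed: int | list[int],
    panel: PanelDefinition | None = None,
    sample_id: str = "sample",
    ko_control: bool = False,
) -> EventMatrix:
    """Simulate one sample's raw-scale event matrix with truth labels.

    ``ko_control`` emulates a p16-null animal: no event expresses p16, so the
    p16 channel carries pure background noise (the negative-control input to
    knock-out-anchored thresholding).
    """
    if group not in GROUPS:
        raise PanelError(f"unknown group {group!r}; valid: {GROUPS}")
    for pop in config.populations:
        if group not in pop.weight:
            raise PanelError(f"population {pop.name!r} has no weight for group {group!r}")
    panel = panel or default_panel()
    markers = panel.markers
    rng = np.random.default_rng(
        np.random.SeedSequence(sample_seed if isinstance(sample_seed, list) else [int(sample_seed)])
    )

    n = config.events_per_sample
    classes = list(config.contamination.keys())
    fracs = np.array([config.contamination[c] for c in classes], dtype=float)
    probs = np.concatenate([[1.0 - fracs.sum()], fracs])
    class_names = ["cell"] + [
        {"beads": "bead", "doublets": "doublet"}.get(c, c) for c in classes
    ]
    contamination = np.array(class_names, dtype=object)[
        rng.choice(len(class_names), size=n, p=probs)
    ]

    # between-animal prevalence jitter (lognormal, mean-preserving)
    cv = config.between_animal_cv
    jitter = {}
    for marker in ("p16", "p21"):
        z = rng.standard_normal()
        jitter[marker] = float(np.exp(cv * z - 0.5 * cv**2)) if cv > 0 else 1.0

    values = np.zeros((n, len(markers)))
    pop_names = np.array([""] * n, dtype=object)
    archetype = np.array([""] * n, dtype=object)
    flags = pd.DataFrame(
        {c: np.zeros(n, dtype=bool) for c in
         ["p16_true", "p21_true", "ki67_true", "bcl2_true", "p16kb_true", "p21kb_true"]}
    )

    inst = config.instrument
    idx = {m: i for i, m in enumerate(markers)}
    dna_col = idx[panel.instrument_channel("instrument_dna")]
    via_col = idx[panel.instrument_channel("instrument_viability")]
    len_col = idx[panel.instrument_channel("instrument_event_length")]
    bead_cols = [idx[m] for m in panel.markers_of("instrument_bead")]
    cd45_col = idx["CD45"] if "CD45" in idx else None

    # --- single cells (clean, dead, CD45+ carryover) ----------------------
    cellish = np.isin(contamination, ["cell", "dead", "cd45pos"])
    n_cellish = int(cellish.sum())
    if n_cellish:
        cell_vals, pop_idx = _draw_cells(config, panel, group, n_cellish, rng)
        cell_flags = _assign_flags(config, group, pop_idx, rng, jitter, ko_control)
        # contamination events never count as senescent in the truth
        clean_sub = (contamination[cellish] == "cell")
        for col in cell_flags.columns:
            cell_flags.loc[~clean_sub, col] = False
        _apply_flag_intensities(config, panel, cell_vals, cell_flags, rng)
        cell_arch = _assign_archetypes(config, panel, cell_vals, cell_flags, rng)
        values[cellish] = cell_vals
        pop_names[cellish] = [config.populations[i].name for i in pop_idx]
        archetype[cellish] = cell_arch
        for col in cell_flags.columns:
            flags.loc[cellish, col] = cell_flags[col].to_numpy()

        # CD45 carryover: hematopoietic events are CD45-bright
        carry = cellish & (contamination == "cd45pos")
        if cd45_col is not None and carry.any():
            mean = config.marker_positive_means.get("CD45", 4.0)
            values[carry, cd45_col] = rng.normal(
                mean, max(config.positive_cv * mean, config.baseline_sd), int(carry.sum())
            )

    # instrument channels for single cells
    values[cellish, dna_col] = rng.normal(inst["dna_mean"], inst["dna_sd"], n_cellish)
    dead = contamination == "dead"
    live_cellish = cellish & ~dead
    values[live_cellish, via_col] = rng.normal(
        inst["viability_live_mean"], inst["viability_live_sd"], int(live_cellish.sum())
    )
    values[dead, via_col] = rng.normal(
        inst["viability_dead_mean"], inst["viability_dead_sd"], int(dead.sum())
    )
    for col in bead_cols:
        values[cellish, col] = rng.normal(inst["bead_noise_mean"], inst["bead_noise_sd"], n_cellish)

    # --- debris: low-DNA fragments with background antibody signal --------
    debris = contamination == "debris"
    n_debris = int(debris.sum())
    if n_debris:
        values[debris] = rng.normal(config.baseline_mean, config.baseline_sd, (n_debris, len(markers)))
        values[debris, dna_col] = rng.normal(inst["debris_dna_mean"], inst["debris_dna_sd"], n_debris)
        values[debris, via_col] = rng.normal(inst["viability_live_mean"], inst["viability_live_sd"], n_debris)
        pop_names[debris] = "debris"

    # --- beads: bead-channel bright, DNA-free -----------------------------
    beads = contamination == "bead"
    n_beads = int(beads.sum())
    if n_beads:
        values[beads] = rng.normal(0.05, 0.1, (n_beads, len(markers)))
        for col in bead_cols:
            values[beads, col] = rng.normal(inst["bead_signal_mean"], inst["bead_signal_sd"], n_beads)
        values[beads, dna_col] = rng.normal(0.05, 0.1, n_beads)
        values[beads, via_col] = rng.normal(0.05, 0.1, n_beads)

    # inverse arcsinh to the ion-count scale, truncated at zero
    raw = np.clip(config.cofactor * np.sinh(values), 0.0, None)

    # event length is acquired on its own raw scale
    raw[:, len_col] = np.clip(
        rng.normal(inst["event_length_mean"], inst["event_length_sd"], n), 1.0, None
    )

    # --- doublets: sum of two independent clean cells ---------------------
    doublets = contamination == "doublet"
    n_doub = int(doublets.sum())
    if n_doub:
        a_vals, _ = _draw_cells(config, panel, group, n_doub, rng)
        b_vals, _ = _draw_cells(config, panel, group, n_doub, rng)
        raw_pair = np.clip(config.cofactor * np.sinh(a_vals), 0, None) + np.clip(
            config.cofactor * np.sinh(b_vals), 0, None
        )
        dna_pair = 0.5 * (
            config.cofactor * np.sinh(rng.normal(inst["dna_mean"], inst["dna_sd"], n_doub))
            + config.cofactor * np.sinh(rng.normal(inst["dna_mean"], inst["dna_sd"], n_doub))
        )
        mlo, mhi = inst.get("doublet_dna_multiplier", [1.8, 2.0])
        raw_pair[:, dna_col] = rng.uniform(mlo, mhi, n_doub) * dna_pair
        ulo, uhi = inst.get("doublet_length_multiplier", [1.4, 1.7])
        raw_pair[:, len_col] = rng.uniform(ulo, uhi, n_doub) * np.clip(
            rng.normal(inst["event_length_mean"], inst["event_length_sd"] / np.sqrt(2), n_doub), 1, None
        )
        raw_pair[:, via_col] = np.clip(
            config.cofactor
            * np.sinh(rng.normal(inst["viability_live_mean"], inst["viability_live_sd"], n_doub)),
            0,
            None,
        )
        for col in bead_cols:
            raw_pair[:, col] = np.clip(
                config.cofactor * np.sinh(rng.normal(inst["bead_noise_mean"], inst["bead_noise_sd"], n_doub)),
                0,
                None,
            )
        raw[doublets] = raw_pair

    # --- acquisition-order signal drift (all channels except event length)
    if config.drift_slope:
        factor = 1.0 + config.drift_slope * ((np.arange(n) + 0.5) / n - 0.5)
        keep = raw[:, len_col].copy()
        raw = raw * factor[:, None]
        raw[:, len_col] = keep

    truth = pd.DataFrame(
        {
            "population": pop_names,
            "contamination_class": contamination,
            "archetype": archetype,
            **{c: flags[c] for c in flags.columns},
        }
    )
    return EventMatrix(
        values=pd.DataFrame(raw, columns=pd.Index(markers)),
        panel=panel,
        sample_id=sample_id,
        transformed=False,
        truth=truth,
    )


def simulate_cohort(
    config: SimulationConfig,
    design: CohortDesign,
    panel: PanelDefinition | None = None,
) -> dict[str, EventMatrix]:
    """Simulate one sample per design row; seeds derive from (config.seed, sample_id)."""
    panel = panel or default_panel()
    out: dict[str, EventMatrix] = {}
    for _, row in design.samples.iterrows():
        sid = row["sample_id"]
        group = (
            "young"
            if row["age_group"] == "young"
            else ("old_senolytic" if row["treatment"] == "senolytic" else "old")
        )
        out[sid] = simulate_sample(
            config,
            group=group,
            sample_seed=sample_seed_for(config.seed, sid),
            panel=panel,
            sample_id=sid,
            ko_control=(row["genotype"] == "ko_control"),
        )
    return out


def truth_summary(matrices: Mapping[str, EventMatrix] | list[EventMatrix]) -> pd.DataFrame:
    """Per-sample truth prevalences (% of clean cells carrying each flag)."""
    if isinstance(matrices, Mapping):
        items = list(matrices.values())
    else:
        items = list(matrices)
    rows = []
    for m in items:
        if m.truth is None:
            raise ValueError(f"sample {m.sample_id}: no truth labels")
        clean = m.truth[m.truth["contamination_class"] == "cell"]
        denom = len(clean)
        row: dict[str, Any] = {"sample_id": m.sample_id, "n_clean": denom}
        for flag in ("p16_true", "p21_true", "ki67_true", "bcl2_true", "p16kb_true", "p21kb_true"):
            row[f"pct_{flag[:-5]}"] = 100.0 * clean[flag].mean() if denom else np.nan
        rows.append(row)
    if not rows:
        return pd.DataFrame(
            columns=["sample_id", "n_clean"]
            + [f"pct_{f}" for f in ("p16", "p21", "ki67", "bcl2", "p16kb", "p21kb")]
        )
    return pd.DataFrame(rows)
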