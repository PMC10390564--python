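"""Preprocessing: bead-anchored drift normalization, arcsinh, cleanup gating.

The cleanup gate reduces raw acquisitions to the clean Lin-CD45- mesenchymal
analysis set through a fixed sequence: calibration-bead removal, DNA/event-
length singlet selection (doublets and debris), viability (cisplatin-high =
dead) exclusion, and CD45/lineage negative selection. Every stage is recorded
in a :class:`QCReport` with per-event attribution so simulated truth labels
can score the gate.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd

from .events import EventMatrix
from .panel import PanelDefinition, PanelError

__all__ = [
    "CleanupParams",
    "QCReport",
    "detect_beads",
    "bead_normalize",
    "arcsinh_transform",
    "cleanup_gate",
    "subsample_events",
]

logger = logging.getLogger(__name__)

DEFAULT_COFACTOR = 5.0  # cytometry community standard for CyTOF ion counts


@dataclasses.dataclass(frozen=True)
class CleanupParams:
    """Cleanup gate cutoffs, all on the arcsinh scale.

    ``dna_bounds`` is the singlet DNA-intercalator window; events above
    ``event_length_max`` or outside the DNA window are doublets/debris;
    ``viability_max`` excludes cisplatin-high dead cells; ``cd45_max`` and
    ``lineage_max`` implement Lin-CD45- negative selection.
    """

    dna_bounds: tuple[float, float]
    event_length_max: float
    viability_max: float
    bead_min: float
    cd45_max: float
    lineage_max: float

    def __post_init__(self) -> None:
        lo, hi = self.dna_bounds
        if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
            raise ValueError(f"dna_bounds {self.dna_bounds} not a well-ordered finite interval")
        for name in ("event_length_max", "viability_max", "bead_min", "cd45_max", "lineage_max"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")

    @classmethod
    def from_dict(cls, raw: dict) -> "CleanupParams":
        return cls(
            dna_bounds=(float(raw["dna_bounds"][0]), float(raw["dna_bounds"][1])),
            event_length_max=float(raw["event_length_max"]),
            viability_max=float(raw["viability_max"]),
            bead_min=float(raw["bead_min"]),
            cd45_max=float(raw["cd45_max"]),
            lineage_max=float(raw["lineage_max"]),
        )


@dataclasses.dataclass
class QCReport:
    """Per-stage accounting of the cleanup gate."""

    sample_id: str
    stage_counts: dict[str, int]  # events remaining after each stage (incl. 'input')
    removed_class: pd.Series  # per input event: 'kept' or predicted contamination class

    def __post_init__(self) -> None:
        counts = list(self.stage_counts.values())
        if any(b > a for a, b in zip(counts, counts[1:])):
            raise ValueError("stage counts must be nonincreasing")

    @property
    def fractions_removed(self) -> dict[str, float]:
        out = {}
        stages = list(self.stage_counts)
        for prev, cur in zip(stages, stages[1:]):
            n_prev = self.stage_counts[prev]
            out[cur] = (n_prev - self.stage_counts[cur]) / n_prev if n_prev else 0.0
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"stage": list(self.stage_counts), "events": list(self.stage_counts.values())}
        )


def detect_beads(matrix: EventMatrix, panel: PanelDefinition | None = None) -> np.ndarray:
    """Boolean mask of calibration-bead events on the raw scale.

    An event is a bead when any bead channel exceeds 10x the file's background
    bead-channel median (floored at 1 ion count); the detected set must show a
    >= 50x median contrast against background, otherwise no beads are called.
    """
    panel = panel or matrix.panel
    bead_markers = panel.markers_of("instrument_bead")
    if not bead_markers:
        raise PanelError("panel has no instrument_bead channel")
    signal = matrix.values[bead_markers].to_numpy().max(axis=1) if matrix.n_events else np.zeros(0)
    if matrix.n_events == 0:
        return np.zeros(0, dtype=bool)
    background = float(np.median(signal))
    threshold = max(10.0 * background, 1.0)
    is_bead = signal > threshold
    if not is_bead.any():
        return is_bead
    bead_level = float(np.median(signal[is_bead]))
    if bead_level / (background + 1e-9) < 50.0:
        return np.zeros(matrix.n_events, dtype=bool)
    # second pass anchored on the detected bead level, so rare background
    # outliers just above the first threshold drop out
    return signal > 0.1 * bead_level


def bead_normalize(
    matrix: EventMatrix, panel: PanelDefinition | None = None, n_bins: int = 20
) -> EventMatrix:
    """Correct slow intra-file signal drift against calibration-bead signal.

    Events are split into ``n_bins`` contiguous acquisition-order bins; each
    bin's multiplicative correction is (global median bead signal)/(bin median
    bead signal), averaged over bead channels and computed from bead-positive
    events only, then applied to every intensity channel except event length.
    Corrections are clamped to [0.2, 5].
    """
    panel = panel or matrix.panel
    if matrix.transformed:
        raise ValueError("bead_normalize expects raw-scale data")
    bead_markers = panel.markers_of("instrument_bead")
    if not bead_markers:
        raise PanelError("panel has no instrument_bead channel")
    n = matrix.n_events
    if n == 0:
        return matrix

    bead_signal = matrix.values[bead_markers].to_numpy()
    is_bead = detect_beads(matrix, panel)
    if is_bead.sum() < n_bins:
        logger.warning(
            "%s: only %d bead events (< %d bins); drift left uncorrected",
            matrix.sample_id, int(is_bead.sum()), n_bins,
        )
        return matrix

    edges = np.linspace(0, n, n_bins + 1).astype(int)
    length_marker = panel.instrument_channel("instrument_event_length")
    corrected = matrix.values.to_numpy().copy()
    target_cols = [i for i, m in enumerate(panel.markers) if m != length_marker]

    # global reference = median bead signal per bead channel over the file
    global_med = np.median(bead_signal[is_bead], axis=0)
    for b in range(n_bins):
        lo, hi = edges[b], edges[b + 1]
        in_bin = np.zeros(n, dtype=bool)
        in_bin[lo:hi] = True
        bin_beads = in_bin & is_bead
        if not bin_beads.any():
            logger.warning("%s: bin %d has no bead events; correction 1.0", matrix.sample_id, b)
            continue
        bin_med = np.median(bead_signal[bin_beads], axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            ratios = np.where(bin_med > 0, global_med / bin_med, np.nan)
        factor = float(np.nanmean(ratios))
        if not np.isfinite(factor):
            logger.warning("%s: bin %d bead median is zero; correction clamped", matrix.sample_id, b)
            factor = 1.0
        if not 0.2 <= factor <= 5.0:
            logger.warning(
                "%s: bin %d correction %.3f clamped to [0.2, 5]", matrix.sample_id, b, factor
            )
            factor = float(np.clip(factor, 0.2, 5.0))
        corrected[np.ix_(in_bin, target_cols)] *= factor

    return matrix.replace_values(
        pd.DataFrame(corrected, columns=matrix.values.columns)
    )


def arcsinh_transform(matrix: EventMatrix, cofactor: float = DEFAULT_COFACTOR) -> EventMatrix:
    """x -> asinh(x / cofactor) on every channel; refuses to run twice."""
    if matrix.transformed:
        raise ValueError(f"sample {matrix.sample_id} is already arcsinh-transformed")
    if cofactor <= 0:
        raise ValueError("cofactor must be positive")
    values = np.arcsinh(matrix.values.to_numpy() / cofactor)
    return matrix.replace_values(
        pd.DataFrame(values, columns=matrix.values.columns), transformed=True
    )


def cleanup_gate(
    matrix: EventMatrix,
    params: CleanupParams,
    panel: PanelDefinition | None = None,
) -> tuple[EventMatrix, QCReport]:
    """Sequential cleanup to the Lin-CD45- analysis set.

    Stage order: (1) remove bead-channel-positive events; (2) keep DNA within
    the singlet window and event length below the cutoff; (3) remove
    viability-high (dead) events; (4) keep CD45 and all lineage channels below
    their negative-selection cutoffs.
    """
    panel = panel or matrix.panel
    if not matrix.transformed:
        raise ValueError("cleanup_gate expects arcsinh-transformed data")
    dna = matrix.channel(panel.instrument_channel("instrument_dna"))
    length = matrix.channel(panel.instrument_channel("instrument_event_length"))
    viability = matrix.channel(panel.instrument_channel("instrument_viability"))
    bead_markers = panel.markers_of("instrument_bead")
    if not bead_markers:
        raise PanelError("panel has no instrument_bead channel")

    n = matrix.n_events
    alive = np.ones(n, dtype=bool)
    removed = np.array(["kept"] * n, dtype=object)
    counts = {"input": n}

    # (1) beads
    bead_pos = np.zeros(n, dtype=bool)
    for m in bead_markers:
        bead_pos |= matrix.channel(m) > params.bead_min
    removed[alive & bead_pos] = "bead"
    alive &= ~bead_pos
    counts["bead_removal"] = int(alive.sum())

    # (2) singlets: DNA window + event length
    lo, hi = params.dna_bounds
    debris = dna < lo
    doublet = (dna > hi) | (length > params.event_length_max)
    removed[alive & debris] = "debris"
    removed[alive & ~debris & doublet] = "doublet"
    alive &= ~(debris | doublet)
    counts["singlet_selection"] = int(alive.sum())

    # (3) viability
    dead = viability > params.viability_max
    removed[alive & dead] = "dead"
    alive &= ~dead
    counts["viability"] = int(alive.sum())

    # (4) Lin-CD45- negative selection
    lineage_markers = [m for m in panel.markers_of("lineage") if m != "CD45"]
    cd45_hi = np.zeros(n, dtype=bool)
    if "CD45" in panel.markers:
        cd45_hi = matrix.channel("CD45") > params.cd45_max
    lin_hi = np.zeros(n, dtype=bool)
    for m in lineage_markers:
        lin_hi |= matrix.channel(m) > params.lineage_max
    removed[alive & (cd45_hi | lin_hi)] = "cd45pos"
    alive &= ~(cd45_hi | lin_hi)
    counts["lin_cd45_negative"] = int(alive.sum())

    report = QCReport(
        sample_id=matrix.sample_id,
        stage_counts=counts,
        removed_class=pd.Series(removed, name="removed_class"),
    )
    return matrix.take(np.flatnonzero(alive)), report


def subsample_events(matrix: EventMatrix, n: int, seed: int) -> EventMatrix:
    """Uniform subsample without replacement (all events when n >= count)."""
    if n < 0:
        raise ValueError("n must be >= 0")
    rng = np.random.default_rng(seed)
    total = matrix.n_events
    k = min(n, total)
    index = np.sort(rng.choice(total, size=k, replace=False))
    return matrix.take(index)
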