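"""Marker-positivity thresholds and combinatorial senescence calls.

The p16 gate is anchored on a knock-out negative control: the cutoff is a
high empirical quantile (default 0.999) of the p16 channel in cells from a
p16-null animal processed identically, so the false-positive rate on true
negatives is ~0.1%. Markers without a knock-out line (p21, Ki67, BCL-2, SASP)
are thresholded at a configured quantile of the pooled reference cohort.
Positivity is strict (> cutoff), so control events at the cutoff are negative.

Combinatorial senescent-cell classes:
    p16KB = p16+ AND Ki67- AND BCL-2+
    p21KB = p21+ AND Ki67- AND BCL-2+
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

from .events import EventMatrix
from .panel import CohortDesign

__all__ = [
    "ThresholdEntry",
    "ThresholdSet",
    "derive_threshold",
    "pooled_quantile_threshold",
    "call_markers",
    "summarize_calls",
    "group_summary",
    "group_fold_change",
]

logger = logging.getLogger(__name__)

THRESHOLD_SOURCES = ("ko_control", "quantile_of_pooled", "manual")


@dataclasses.dataclass(frozen=True)
class ThresholdEntry:
    marker: str
    cutoff: float  # arcsinh scale
    source: str
    control_sample_id: str | None = None
    quantile: float | None = None

    def __post_init__(self) -> None:
        if self.source not in THRESHOLD_SOURCES:
            raise ValueError(f"unknown threshold source {self.source!r}")
        if not np.isfinite(self.cutoff):
            raise ValueError(f"{self.marker}: cutoff must be finite")
        if self.source == "ko_control" and not self.control_sample_id:
            raise ValueError(f"{self.marker}: ko_control threshold needs control_sample_id")


@dataclasses.dataclass
class ThresholdSet:
    entries: dict[str, ThresholdEntry] = dataclasses.field(default_factory=dict)

    def add(self, entry: ThresholdEntry) -> "ThresholdSet":
        self.entries[entry.marker] = entry
        return self

    def cutoff(self, marker: str) -> float:
        if marker not in self.entries:
            raise KeyError(f"no threshold for marker {marker!r}")
        return self.entries[marker].cutoff

    def __contains__(self, marker: str) -> bool:
        return marker in self.entries

    def to_yaml(self, path: str | Path) -> Path:
        doc = {
            m: {
                "cutoff": float(e.cutoff),
                "source": e.source,
                "control_sample_id": e.control_sample_id,
                "quantile": e.quantile,
            }
            for m, e in self.entries.items()
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=True)
        return Path(path)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ThresholdSet":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        ts = cls()
        for marker, e in doc.items():
            ts.add(
                ThresholdEntry(
                    marker=marker,
                    cutoff=float(e["cutoff"]),
                    source=e["source"],
                    control_sample_id=e.get("control_sample_id"),
                    quantile=e.get("quantile"),
                )
            )
        return ts


def derive_threshold(control: EventMatrix, marker: str, quantile: float = 0.999) -> ThresholdEntry:
    """Knock-out-anchored cutoff: an empirical quantile of the control channel.

    Uses the linear-interpolation quantile definition (numpy default).
    """
    if not 0.0 < quantile < 1.0:
        raise ValueError("quantile must lie strictly between 0 and 1")
    if control.n_events == 0:
        raise ValueError("control sample is empty")
    if marker not in control.values.columns:
        raise KeyError(f"marker {marker!r} absent from control sample")
    cutoff = float(np.quantile(control.channel(marker), quantile, method="linear"))
    return ThresholdEntry(
        marker=marker,
        cutoff=cutoff,
        source="ko_control",
        control_sample_id=control.sample_id,
        quantile=quantile,
    )


def pooled_quantile_threshold(
    matrices: Iterable[EventMatrix], marker: str, quantile: float
) -> ThresholdEntry:
    """Cohort-wide cutoff at a quantile of the pooled reference cohort."""
    if not 0.0 < quantile < 1.0:
        raise ValueError("quantile must lie strictly between 0 and 1")
    pools = [m.channel(marker) for m in matrices]
    if not pools or sum(len(p) for p in pools) == 0:
        raise ValueError("pooled reference is empty")
    cutoff = float(np.quantile(np.concatenate(pools), quantile, method="linear"))
    return ThresholdEntry(
        marker=marker, cutoff=cutoff, source="quantile_of_pooled", quantile=quantile
    )


def call_markers(matrix: EventMatrix, thresholds: ThresholdSet) -> pd.DataFrame:
    """Per-event positivity flags plus derived p16KB/p21KB classes.

    A flag is True iff the (transformed) intensity strictly exceeds the
    marker's cutoff. p16KB/p21KB columns are added whenever the constituent
    markers are thresholded.
    """
    if not matrix.transformed:
        raise ValueError("call_markers expects arcsinh-transformed data")
    calls = pd.DataFrame(index=matrix.values.index)
    for marker, entry in thresholds.entries.items():
        if marker not in matrix.values.columns:
            raise KeyError(f"thresholded marker {marker!r} absent from sample")
        calls[marker] = matrix.channel(marker) > entry.cutoff
    if {"p16", "Ki67", "BCL-2"} <= set(calls.columns):
        calls["p16KB"] = calls["p16"] & ~calls["Ki67"] & calls["BCL-2"]
    if {"p21", "Ki67", "BCL-2"} <= set(calls.columns):
        calls["p21KB"] = calls["p21"] & ~calls["Ki67"] & calls["BCL-2"]
    return calls


def _pct(numer: int, denom: int) -> float:
    return 100.0 * numer / denom if denom else np.nan


def summarize_calls(
    calls_by_sample: Mapping[str, pd.DataFrame],
    design: CohortDesign | None = None,
    matrices: Mapping[str, EventMatrix] | None = None,
) -> pd.DataFrame:
    """Per-sample senescence percentages and subset shares.

    Reports, per sample: % positive of clean cells for each gated marker and
    class, the p16KB share of p16+ cells, the Ki67- share of p16+BCL-2+
    cells, and (when ``matrices`` is given) mean arcsinh marker expression
    within gated subsets. Undefined shares (empty parent gate) are NaN and
    excluded from group statistics.
    """
    if not calls_by_sample:
        raise ValueError("no samples to summarize")
    rows = []
    for sid, calls in calls_by_sample.items():
        n = len(calls)
        row: dict[str, object] = {"sample_id": sid, "n_cells": n}
        for col in calls.columns:
            row[f"pct_{col}"] = _pct(int(calls[col].sum()), n)
        if {"p16", "p16KB"} <= set(calls.columns):
            n_p16 = int(calls["p16"].sum())
            row["pct_p16KB_of_p16"] = _pct(int(calls["p16KB"].sum()), n_p16)
            if n_p16 == 0:
                logger.warning("%s: no p16+ cells; p16KB share undefined", sid)
        if {"p16", "BCL-2", "Ki67"} <= set(calls.columns):
            parent = calls["p16"] & calls["BCL-2"]
            n_parent = int(parent.sum())
            row["pct_Ki67neg_of_p16_bcl2"] = _pct(int((parent & ~calls["Ki67"]).sum()), n_parent)
        if matrices is not None and sid in matrices:
            values = matrices[sid].values
            for marker in ("p16", "p21", "BCL-2", "Ki67"):
                if marker in calls.columns and marker in values.columns:
                    subset = calls[marker].to_numpy()
                    row[f"mean_{marker}_in_{marker}pos"] = (
                        float(values.loc[subset, marker].mean()) if subset.any() else np.nan
                    )
            if "p16" in calls.columns and "BCL-2" in values.columns:
                subset = calls["p16"].to_numpy()
                row["mean_BCL-2_in_p16pos"] = (
                    float(values.loc[subset, "BCL-2"].mean()) if subset.any() else np.nan
                )
        rows.append(row)
    out = pd.DataFrame(rows)
    if design is not None:
        analysis = design.analysis_samples
        groups = {
            r["sample_id"]: (
                "young"
                if r["age_group"] == "young"
                else ("old_senolytic" if r["treatment"] == "senolytic" else "old")
            )
            for _, r in analysis.iterrows()
        }
        out["group"] = out["sample_id"].map(groups)
    return out


def group_summary(summary: pd.DataFrame, metric: str) -> pd.DataFrame:
    """Group mean ± SD for one summary metric (NaN samples excluded)."""
    if "group" not in summary.columns:
        raise ValueError("summary has no group column (pass a design to summarize_calls)")
    sub = summary.dropna(subset=[metric, "group"])
    return sub.groupby("group")[metric].agg(["mean", "std", "count"])


def group_fold_change(
    summary: pd.DataFrame,
    metric: str,
    groups: tuple[str, str],
) -> dict[str, float]:
    """Fold change mean(comparison)/mean(reference) for a summary metric.

    Returns ``{"fold": ..., "log2_fold": ...}``; a zero reference mean yields
    NaN fold with +inf log2 sentinel and a warning.
    """
    reference, comparison = groups
    if "group" not in summary.columns:
        raise ValueError("summary has no group column")
    vals = {
        g: summary.loc[summary["group"] == g, metric].dropna().to_numpy() for g in groups
    }
    for g, v in vals.items():
        if len(v) == 0:
            raise ValueError(f"group {g!r} has no defined values for {metric!r}")
    mean_ref = float(np.mean(vals[reference]))
    mean_cmp = float(np.mean(vals[comparison]))
    if mean_ref == 0.0:
        logger.warning("reference group %r mean is zero; fold undefined", reference)
        return {"fold": np.nan, "log2_fold": np.inf if mean_cmp > 0 else np.nan}
    fold = mean_cmp / mean_ref
    return {"fold": fold, "log2_fold": float(np.log2(fold)) if fold > 0 else -np.inf}
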