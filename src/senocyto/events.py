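"""Event matrices: per-cell ion-count intensities plus optional truth labels.

An :class:`EventMatrix` holds one sample's events x channels table in the
canonical panel order. Intensities are on the raw ion-count scale until
:func:`senocyto.preprocess.arcsinh_transform` marks them transformed.
Simulated data carry a parallel ``truth`` table (population, contamination
class, senescence flags) used only for validation — truth never enters an
intensity channel, and on disk it lives in a ``<file>.truth.tsv`` sidecar.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import _fcs
from .panel import PanelDefinition, PanelError

__all__ = ["EventMatrix", "read_events", "write_events"]

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class EventMatrix:
    values: pd.DataFrame  # events x channels, columns = panel marker names
    panel: PanelDefinition
    sample_id: str = "sample"
    transformed: bool = False
    truth: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        expected = self.panel.markers
        if list(self.values.columns) != expected:
            if set(self.values.columns) == set(expected):
                self.values = self.values[expected]
            else:
                raise PanelError(
                    f"event matrix columns do not match panel "
                    f"({len(self.values.columns)} vs {len(expected)} channels)"
                )
        if self.values.isna().any().any():
            raise ValueError(f"sample {self.sample_id}: missing intensity values")
        if self.truth is not None and len(self.truth) != len(self.values):
            raise ValueError("truth table row count does not match event count")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def n_events(self) -> int:
        return len(self.values)

    def channel(self, marker: str) -> np.ndarray:
        return self.values[marker].to_numpy()

    def take(self, index: np.ndarray, sample_id: str | None = None) -> "EventMatrix":
        """New matrix restricted to ``index`` (positional), truth carried along."""
        return EventMatrix(
            values=self.values.iloc[index].reset_index(drop=True),
            panel=self.panel,
            sample_id=sample_id or self.sample_id,
            transformed=self.transformed,
            truth=None if self.truth is None else self.truth.iloc[index].reset_index(drop=True),
        )

    def replace_values(self, values: pd.DataFrame, transformed: bool | None = None) -> "EventMatrix":
        return EventMatrix(
            values=values,
            panel=self.panel,
            sample_id=self.sample_id,
            transformed=self.transformed if transformed is None else transformed,
            truth=self.truth,
        )


def _truth_path(path: Path) -> Path:
    return path.with_name(path.name + ".truth.tsv")


def write_events(matrix: EventMatrix, path: str | Path, format: str = "tsv") -> Path:
    """Write an event matrix as TSV or FCS; truth labels go to a sidecar TSV."""
    path = Path(path)
    if format == "tsv":
        matrix.values.to_csv(path, sep="\t", index=False, float_format="%.8g")
    elif format == "fcs":
        metals = [c.metal_tag for c in matrix.panel.channels]
        _fcs.write_fcs(path, matrix.values.to_numpy(), metals, matrix.panel.markers)
    else:
        raise ValueError(f"unknown format {format!r} (use 'tsv' or 'fcs')")
    if matrix.truth is not None:
        matrix.truth.to_csv(_truth_path(path), sep="\t", index=False)
    return path


def read_events(path: str | Path, panel: PanelDefinition, sample_id: str | None = None) -> EventMatrix:
    """Read events from FCS or TSV, resolving file channels to panel markers.

    Unresolvable file columns are dropped with a warning; panel channels absent
    from the file are an error. Negative intensities are clamped to zero (the
    zero-noise convention differs between acquisition tools) with a logged
    count. The output is on the raw scale with ``transformed=False``.
    """
    path = Path(path)
    if path.suffix.lower() == ".fcs" or _looks_like_fcs(path):
        arr, names, stains = _fcs.read_fcs(path)
        df = pd.DataFrame(arr, columns=pd.Index(_unique(stains if stains else names)))
        # prefer the stain ($PnS) name, fall back to channel ($PnN)
        raw_names = [s or n for s, n in zip(stains, names)]
        df.columns = pd.Index(_unique(raw_names))
    else:
        df = pd.read_csv(path, sep="\t")

    resolved: dict[str, str] = {}
    dropped: list[str] = []
    for col in df.columns:
        marker = panel.resolve(str(col))
        if marker is None:
            dropped.append(str(col))
        elif marker not in resolved.values():
            resolved[str(col)] = marker
    if not resolved:
        raise _fcs.FCSFormatError(f"{path}: no file channels resolve to the panel")
    if dropped:
        logger.warning("%s: dropped %d unmapped column(s): %s", path, len(dropped), dropped)
    missing = [m for m in panel.markers if m not in resolved.values()]
    if missing:
        raise PanelError(f"{path}: file lacks panel channels {missing}")

    out = df[list(resolved)].rename(columns=resolved)[panel.markers].astype(float)
    negatives = int((out.to_numpy() < 0).sum())
    if negatives:
        logger.warning("%s: clamped %d negative intensities to 0", path, negatives)
        out = out.clip(lower=0.0)

    truth = None
    tp = _truth_path(path)
    if tp.exists():
        truth = pd.read_csv(tp, sep="\t")

    return EventMatrix(
        values=out.reset_index(drop=True),
        panel=panel,
        sample_id=sample_id or path.stem,
        transformed=False,
        truth=truth,
    )


def _looks_like_fcs(path: Path) -> bool:
    try:
        with open(path, "rb") as fh:
            return fh.read(3) == b"FCS"
    except OSError:
        return False


def _unique(names: list[str]) -> list[str]:
    seen: dict[str, int] = {}
    out = []
    for n in names:
        if n in seen:
            seen[n] += 1
            out.append(f"{n}.{seen[n]}")
        else:
            seen[n] = 0
            out.append(n)
    return out
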