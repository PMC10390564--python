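"""Batch self-organizing map for cytometry events.

A rectangular SOM grid is trained with the batch rule and a linearly
shrinking Gaussian neighborhood (FlowSOM-style): each epoch assigns every
event to its best-matching unit, then every code vector is replaced by the
neighborhood-weighted mean of the data. The quantization-error trace is
recorded per epoch.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .events import EventMatrix

__all__ = ["SOMModel", "train_som"]


@dataclasses.dataclass
class SOMModel:
    grid_shape: tuple[int, int]
    code_vectors: np.ndarray  # (rows*cols) x channels
    clustering_channels: list[str]
    quantization_errors: list[float]
    seed: int

    @property
    def n_nodes(self) -> int:
        return self.grid_shape[0] * self.grid_shape[1]

    def assign(self, data: np.ndarray) -> np.ndarray:
        """Best-matching node per row of ``data`` (Euclidean)."""
        return _bmu(data, self.code_vectors)

    def assign_events(self, matrix: EventMatrix) -> np.ndarray:
        return self.assign(matrix.values[self.clustering_channels].to_numpy())


def _bmu(data: np.ndarray, codes: np.ndarray, chunk: int = 65536) -> np.ndarray:
    out = np.empty(len(data), dtype=np.int64)
    code_sq = (codes**2).sum(axis=1)
    for start in range(0, len(data), chunk):
        block = data[start : start + chunk]
        d2 = code_sq[None, :] - 2.0 * block @ codes.T
        out[start : start + chunk] = np.argmin(d2, axis=1)
    return out


def train_som(
    matrix: EventMatrix,
    channels: list[str] | None = None,
    grid: tuple[int, int] = (10, 10),
    epochs: int = 10,
    seed: int = 0,
) -> SOMModel:
    """Train a batch SOM on the requested (transformed) channels."""
    if not matrix.transformed:
        raise ValueError("train_som expects arcsinh-transformed data")
    channels = channels or matrix.panel.identity_markers
    data = matrix.values[channels].to_numpy(dtype=float)
    rows, cols = grid
    n_nodes = rows * cols
    if len(data) < n_nodes:
        raise ValueError(
            f"{len(data)} events < {n_nodes} SOM nodes; use a smaller grid"
        )

    rng = np.random.default_rng(seed)
    init_idx = rng.choice(len(data), size=n_nodes, replace=False)
    codes = data[init_idx].copy()

    # node coordinates on the grid for the neighborhood kernel
    gy, gx = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    coords = np.column_stack([gy.ravel(), gx.ravel()]).astype(float)
    grid_d2 = ((coords[:, None, :] - coords[None, :, :]) ** 2).sum(axis=2)

    sigma_start = max(rows, cols) / 2.0
    sigma_end = 0.5
    errors: list[float] = []
    for epoch in range(epochs):
        frac = epoch / max(epochs - 1, 1)
        sigma = sigma_start + (sigma_end - sigma_start) * frac
        bmu = _bmu(data, codes)
        # quantization error before the update, for the trace
        qe = float(np.sqrt(((data - codes[bmu]) ** 2).sum(axis=1)).mean())
        errors.append(qe)

        counts = np.bincount(bmu, minlength=n_nodes).astype(float)
        sums = np.zeros_like(codes)
        np.add.at(sums, bmu, data)
        h = np.exp(-grid_d2 / (2.0 * sigma**2))  # node x node neighborhood
        weighted = h @ sums
        weight_totals = h @ counts
        nonzero = weight_totals > 0
        codes[nonzero] = weighted[nonzero] / weight_totals[nonzero, None]

    bmu = _bmu(data, codes)
    errors.append(float(np.sqrt(((data - codes[bmu]) ** 2).sum(axis=1)).mean()))
    return SOMModel(
        grid_shape=grid,
        code_vectors=codes,
        clustering_channels=list(channels),
        quantization_errors=errors,
        seed=seed,
    )
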