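"""Consensus metaclustering of SOM nodes and marker-rule annotation.

SOM code vectors are metaclustered by hierarchical consensus: over a number
of iterations, nodes are bootstrap-resampled (weighted by how many events
they hold), average-linkage clustered and cut at k; the accumulated
co-assignment frequencies form a consensus matrix whose complement is itself
hierarchically clustered and cut at k. Metaclusters are then annotated with
population names by marker rules (required-high / required-low markers versus
cohort-level reference quantiles).
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.metrics import silhouette_score

from .events import EventMatrix
from .panel import PanelError
from .som import SOMModel

__all__ = [
    "MetaclusterResult",
    "AnnotationRule",
    "AnnotationRuleSet",
    "load_rules",
    "consensus_metacluster",
    "annotate_clusters",
    "select_k",
]

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class MetaclusterResult:
    node_of_event: np.ndarray
    metacluster_of_node: np.ndarray
    metacluster_of_event: np.ndarray
    k: int
    consensus: np.ndarray  # node x node co-assignment frequency
    profiles: pd.DataFrame  # metacluster x marker medians (all panel markers)
    annotation: dict[int, str] = dataclasses.field(default_factory=dict)
    seed: int = 0

    @property
    def labels_of_event(self) -> np.ndarray:
        if not self.annotation:
            raise ValueError("metaclusters not annotated yet")
        mapping = np.array(
            [self.annotation.get(m, "unlabeled") for m in range(self.k)], dtype=object
        )
        return mapping[self.metacluster_of_event]

    def abundance(self, sample_ids: np.ndarray) -> pd.DataFrame:
        """Per-sample metacluster event fractions (rows sum to 1)."""
        df = pd.DataFrame({"sample": sample_ids, "meta": self.metacluster_of_event})
        counts = df.groupby(["sample", "meta"]).size().unstack(fill_value=0)
        counts = counts.reindex(columns=range(self.k), fill_value=0)
        return counts.div(counts.sum(axis=1), axis=0)


def consensus_metacluster(
    model: SOMModel,
    matrix: EventMatrix,
    k: int,
    iterations: int = 10,
    seed: int = 0,
    min_node_frac: float = 0.002,
) -> MetaclusterResult:
    """Hierarchical-consensus metaclustering of SOM nodes, cut at k.

    Nodes holding fewer than ``min_node_frac`` of the events (residual
    contamination, population-boundary splinters — far below any real
    population's share) do not seed the cut; they inherit the metacluster of
    the nearest seeded code vector.
    """
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    if k > model.n_nodes:
        raise ValueError(f"k={k} exceeds node count {model.n_nodes}")
    node_of_event = model.assign_events(matrix)
    occupancy = np.bincount(node_of_event, minlength=model.n_nodes).astype(float)
    min_events = max(1.0, min_node_frac * len(node_of_event))
    occupied = np.flatnonzero(occupancy >= min_events)
    if len(occupied) < k:  # relax the guard rather than fail on small data
        occupied = np.flatnonzero(occupancy > 0)
    codes = model.code_vectors

    n = model.n_nodes
    co_assigned = np.zeros((n, n))
    co_sampled = np.zeros((n, n))
    rng = np.random.default_rng(seed)

    if k == 1:
        meta_of_node = np.zeros(n, dtype=int)
        consensus = np.ones((n, n))
    else:
        for _ in range(iterations):
            # occupancy-weighted node bootstrap
            draw = rng.choice(occupied, size=len(occupied), replace=True, p=occupancy[occupied] / occupancy[occupied].sum())
            nodes = np.unique(draw)
            if len(nodes) < k:
                continue
            Z = linkage(codes[nodes], method="average", metric="euclidean")
            labels = fcluster(Z, t=k, criterion="maxclust")
            same = labels[:, None] == labels[None, :]
            co_sampled[np.ix_(nodes, nodes)] += 1.0
            co_assigned[np.ix_(nodes, nodes)] += same
        with np.errstate(invalid="ignore", divide="ignore"):
            consensus = np.where(co_sampled > 0, co_assigned / co_sampled, 0.0)
        np.fill_diagonal(consensus, 1.0)
        consensus = 0.5 * (consensus + consensus.T)

        # final clustering of occupied nodes on consensus dissimilarity; a
        # small Euclidean term breaks the exact ties that arise when the
        # consensus is binary (perfectly stable clusters), keeping the cut
        # deterministic and geometry-consistent
        sub = consensus[np.ix_(occupied, occupied)]
        dist = 1.0 - sub
        euclid = np.sqrt(
            ((codes[occupied][:, None, :] - codes[occupied][None, :, :]) ** 2).sum(axis=2)
        )
        if euclid.max() > 0:
            dist = dist + 1e-3 * euclid / euclid.max()
        np.fill_diagonal(dist, 0.0)
        Z = linkage(squareform(dist, checks=False), method="average")
        labels = fcluster(Z, t=k, criterion="maxclust") - 1
        meta_of_node = np.zeros(n, dtype=int)
        meta_of_node[occupied] = labels
        # unseeded nodes inherit the metacluster of the nearest seeded code
        empty = np.setdiff1d(np.arange(n), occupied)
        if len(empty):
            d2 = ((codes[empty][:, None, :] - codes[occupied][None, :, :]) ** 2).sum(axis=2)
            meta_of_node[empty] = labels[np.argmin(d2, axis=1)]

    meta_of_event = meta_of_node[node_of_event]
    profiles = (
        matrix.values.assign(_meta=meta_of_event)
        .groupby("_meta")
        .median()
        .reindex(range(k))
    )
    profiles.index.name = "metacluster"
    return MetaclusterResult(
        node_of_event=node_of_event,
        metacluster_of_node=meta_of_node,
        metacluster_of_event=meta_of_event,
        k=k,
        consensus=consensus,
        profiles=profiles,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# rule-based annotation
# ---------------------------------------------------------------------------


@dataclasses.dataclass(frozen=True)
class AnnotationRule:
    population: str
    priority: int
    high: tuple[str, ...]
    low: tuple[str, ...]
    split_high: str | None = None  # marker whose high/low split must be exceeded
    split_low: str | None = None


@dataclasses.dataclass
class AnnotationRuleSet:
    rules: list[AnnotationRule]
    high_quantile: float = 0.60
    low_quantile: float = 0.40

    def __post_init__(self) -> None:
        priorities = [r.priority for r in self.rules]
        if len(set(priorities)) != len(priorities):
            raise PanelError("annotation rule priorities must be unique")

    def markers_used(self) -> set[str]:
        out: set[str] = set()
        for r in self.rules:
            out |= set(r.high) | set(r.low)
            out |= {m for m in (r.split_high, r.split_low) if m}
        return out


def load_rules(path: str | Path) -> AnnotationRuleSet:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    rules = [
        AnnotationRule(
            population=r["population"],
            priority=int(r["priority"]),
            high=tuple(r.get("high", [])),
            low=tuple(r.get("low", [])),
            split_high=r.get("split_high"),
            split_low=r.get("split_low"),
        )
        for r in raw["rules"]
    ]
    return AnnotationRuleSet(
        rules=rules,
        high_quantile=float(raw.get("high_quantile", 0.60)),
        low_quantile=float(raw.get("low_quantile", 0.40)),
    )


def _otsu_split(values: np.ndarray) -> float:
    """Exact 1-D Otsu threshold: the cut maximizing between-class variance.

    Used to separate the "high" from the "low" mode of a marker-positive
    subset; deterministic and robust to unequal mode sizes.
    """
    x = np.sort(np.asarray(values, dtype=float))
    n = len(x)
    csum = np.cumsum(x)
    total = csum[-1]
    k = np.arange(1, n)  # class sizes of the lower class
    mean_lo = csum[:-1] / k
    mean_hi = (total - csum[:-1]) / (n - k)
    between = k * (n - k) * (mean_hi - mean_lo) ** 2
    cut = int(np.argmax(between))
    return float(0.5 * (x[cut] + x[cut + 1]))


def annotate_clusters(
    result: MetaclusterResult,
    rules: AnnotationRuleSet,
    matrix: EventMatrix,
) -> MetaclusterResult:
    """Label each metacluster with the highest-priority matching rule.

    Reference levels are cohort-level quantiles of the annotated events; the
    CD24-style high/low split is the Otsu threshold of the marker-positive
    subset (events above the high reference).
    """
    unknown = rules.markers_used() - set(matrix.values.columns)
    if unknown:
        raise PanelError(f"annotation rules reference unknown markers {sorted(unknown)}")

    refs_high = {
        m: float(np.quantile(matrix.channel(m), rules.high_quantile)) for m in rules.markers_used()
    }
    refs_low = {
        m: float(np.quantile(matrix.channel(m), rules.low_quantile)) for m in rules.markers_used()
    }
    splits: dict[str, float] = {}
    for rule in rules.rules:
        for m in (rule.split_high, rule.split_low):
            if m and m not in splits:
                channel = matrix.channel(m)
                positive = channel[channel > refs_high[m]]
                splits[m] = _otsu_split(positive) if len(positive) > 1 else np.inf

    annotation: dict[int, str] = {}
    for meta in range(result.k):
        profile = result.profiles.loc[meta]
        if profile.isna().all():
            annotation[meta] = "unlabeled"
            continue
        label = "unlabeled"
        for rule in sorted(rules.rules, key=lambda r: r.priority):
            ok = all(profile[m] > refs_high[m] for m in rule.high)
            ok = ok and all(profile[m] <= refs_low[m] for m in rule.low)
            if rule.split_high:
                ok = ok and profile[rule.split_high] > splits[rule.split_high]
            if rule.split_low:
                ok = ok and profile[rule.split_low] <= splits[rule.split_low]
            if ok:
                label = rule.population
                break
        annotation[meta] = label
    result.annotation = annotation
    return result


def select_k(
    model: SOMModel,
    matrix: EventMatrix,
    k_range: range | tuple[int, int] = (2, 10),
    iterations: int = 10,
    seed: int = 0,
    score_subsample: int = 10000,
) -> tuple[int, pd.DataFrame]:
    """Choose k by mean silhouette of metaclustered events.

    Returns (best k, diagnostics table with a silhouette score per k). Events
    are subsampled (seeded) to at most ``score_subsample`` for scoring. A
    uniformly low silhouette (< 0.4 everywhere — the level a forced split of
    one Gaussian blob reaches) flags "no structure".
    """
    if isinstance(k_range, tuple):
        ks = range(k_range[0], k_range[1] + 1)
    else:
        ks = k_range
    data = matrix.values[model.clustering_channels].to_numpy()
    if len(np.unique(data, axis=0)) < 2:
        raise ValueError("degenerate data: all events identical")
    rng = np.random.default_rng(seed)
    idx = (
        np.sort(rng.choice(len(data), size=score_subsample, replace=False))
        if len(data) > score_subsample
        else np.arange(len(data))
    )

    records = []
    for k in ks:
        if k < 2 or k > model.n_nodes:
            continue
        result = consensus_metacluster(model, matrix, k=k, iterations=iterations, seed=seed)
        labels = result.metacluster_of_event[idx]
        if len(np.unique(labels)) < 2:
            score = -1.0
        else:
            score = float(silhouette_score(data[idx], labels))
        records.append({"k": k, "silhouette": score})
    table = pd.DataFrame(records)
    if table.empty:
        raise ValueError("no valid k in range")
    best = int(table.loc[table["silhouette"].idxmax(), "k"])
    table["no_structure"] = bool((table["silhouette"] < 0.4).all())
    if table["no_structure"].iloc[0]:
        logger.warning("silhouette low for all k; data may lack cluster structure")
    return best, table
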