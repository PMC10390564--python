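"""CITRUS-style stratified association analysis.

Events are subsampled per sample (stratified), pooled and hierarchically
clustered (average linkage) on the clustering channels; every dendrogram node
holding at least a minimum fraction of the pooled events is retained as an
(overlapping, nested) cluster. Per-cluster features — abundance or median
functional-marker expression per sample — are tested for association with the
sample grouping using a SAM-style moderated difference statistic
d = (mean_B - mean_A)/(s + s0), with permutation-estimated q-values and a
target false-discovery rate.
"""

from __future__ import annotations

import dataclasses
import logging
import zlib
from math import comb
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage

from .events import EventMatrix

__all__ = [
    "StratifiedHierarchy",
    "ClusterFeatureMatrix",
    "AssociationResult",
    "build_hierarchy",
    "extract_features",
    "sam_association",
    "summarize_cleared_clusters",
]

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class StratifiedHierarchy:
    pooled: pd.DataFrame  # subsampled events (clustering channels only)
    sample_of_event: np.ndarray
    linkage_matrix: np.ndarray
    retained_nodes: list[int]  # dendrogram node ids (internal node index + n_leaves)
    members: dict[int, np.ndarray]  # node id -> pooled event indices
    min_fraction: float
    channels: list[str]
    seed: int

    @property
    def n_pooled(self) -> int:
        return len(self.pooled)


@dataclasses.dataclass
class ClusterFeatureMatrix:
    feature_type: str  # abundance | median_marker
    matrix: pd.DataFrame  # features x samples
    groups: pd.Series  # sample -> group label
    cluster_of_feature: dict[str, int]  # feature name -> dendrogram node id


@dataclasses.dataclass
class AssociationResult:
    features: pd.DataFrame  # feature, d, q, significant
    target_fdr: float
    n_permutations: int
    null_abs_d: np.ndarray
    seed: int

    @property
    def significant(self) -> pd.DataFrame:
        return self.features[self.features["significant"]]


def build_hierarchy(
    matrices: Mapping[str, EventMatrix],
    n_per_sample: int = 2000,
    min_fraction: float = 0.02,
    channels: list[str] | None = None,
    seed: int = 0,
) -> StratifiedHierarchy:
    """Subsample per sample, pool, cluster, retain nodes >= min_fraction.

    Samples with fewer than ``n_per_sample`` events contribute all their
    events with a warning. Average-linkage agglomeration runs on the
    clustering channels; retained clusters are all dendrogram merge nodes
    whose leaf count is at least ``min_fraction`` of the pooled events
    (nested and overlapping by construction), plus the root.
    """
    if not 0.0 < min_fraction < 1.0:
        raise ValueError("min_fraction must lie in (0, 1)")
    sample_ids = sorted(matrices)
    blocks, owners = [], []
    for sid in sample_ids:
        m = matrices[sid]
        chans = channels or m.panel.identity_markers
        if m.n_events < n_per_sample:
            logger.warning("%s: only %d events (< %d); using all", sid, m.n_events, n_per_sample)
            take = np.arange(m.n_events)
        else:
            rng = np.random.default_rng([seed, zlib.crc32(sid.encode()) & 0x7FFFFFFF])
            take = np.sort(rng.choice(m.n_events, size=n_per_sample, replace=False))
        blocks.append(m.values.iloc[take][chans])
        owners.append(np.repeat(sid, len(take)))
    pooled = pd.concat(blocks, ignore_index=True)
    sample_of_event = np.concatenate(owners)
    n = len(pooled)
    if n < 1.0 / min_fraction:
        raise ValueError(f"pooled count {n} < 1/min_fraction; nothing retainable")

    Z = linkage(pooled.to_numpy(), method="average", metric="euclidean")

    # leaf membership per internal node, bottom-up
    min_size = min_fraction * n
    sizes = Z[:, 3]
    member_cache: dict[int, np.ndarray] = {}

    def node_members(node_id: int) -> np.ndarray:
        if node_id < n:
            return np.array([node_id])
        if node_id in member_cache:
            return member_cache[node_id]
        left, right = int(Z[node_id - n, 0]), int(Z[node_id - n, 1])
        out = np.concatenate([node_members(left), node_members(right)])
        member_cache[node_id] = out
        return out

    retained = [i + n for i in range(len(Z)) if sizes[i] >= min_size]
    members = {node: np.sort(node_members(node)) for node in retained}
    # drop the cache of unretained nodes to keep memory flat
    chans = channels or matrices[sample_ids[0]].panel.identity_markers
    return StratifiedHierarchy(
        pooled=pooled,
        sample_of_event=sample_of_event,
        linkage_matrix=Z,
        retained_nodes=retained,
        members=members,
        min_fraction=min_fraction,
        channels=list(chans),
        seed=seed,
    )


def extract_features(
    hierarchy: StratifiedHierarchy,
    feature_type: str,
    groups: Mapping[str, str],
    functional_channels: list[str] | None = None,
    functional_values: pd.DataFrame | None = None,
) -> ClusterFeatureMatrix:
    """Per-cluster per-sample features.

    ``abundance``: the fraction of each sample's subsampled events falling in
    the cluster. ``median_marker``: per-sample median of each functional
    channel within the cluster (``functional_values`` supplies channels not
    used for clustering; it must align row-wise with the pooled events).
    Samples with no events in a cluster yield NaN medians with a warning.
    """
    samples = sorted(set(hierarchy.sample_of_event))
    sample_of_event = hierarchy.sample_of_event
    sample_sizes = pd.Series(sample_of_event).value_counts()

    rows: dict[str, dict[str, float]] = {}
    cluster_of_feature: dict[str, int] = {}
    if feature_type == "abundance":
        for node in hierarchy.retained_nodes:
            idx = hierarchy.members[node]
            counts = pd.Series(sample_of_event[idx]).value_counts()
            name = f"cluster{node}_abundance"
            rows[name] = {
                s: float(counts.get(s, 0)) / float(sample_sizes[s]) for s in samples
            }
            cluster_of_feature[name] = node
    elif feature_type == "median_marker":
        source = functional_values if functional_values is not None else hierarchy.pooled
        channels = functional_channels or list(source.columns)
        if not channels:
            raise ValueError("median_marker features need a non-empty functional channel list")
        missing = [c for c in channels if c not in source.columns]
        if missing:
            raise KeyError(f"functional channels {missing} unavailable")
        n_undefined = 0
        for node in hierarchy.retained_nodes:
            idx = hierarchy.members[node]
            sub = source.iloc[idx]
            owner = sample_of_event[idx]
            med = sub.groupby(owner)[channels].median()
            for ch in channels:
                name = f"cluster{node}_{ch}"
                rows[name] = {}
                cluster_of_feature[name] = node
                for s in samples:
                    if s in med.index:
                        rows[name][s] = float(med.loc[s, ch])
                    else:
                        rows[name][s] = np.nan
                        n_undefined += 1
        if n_undefined:
            logger.warning("%d cluster-sample median(s) undefined (no events)", n_undefined)
    else:
        raise ValueError(f"unknown feature type {feature_type!r}")

    matrix = pd.DataFrame(rows).T[samples]
    return ClusterFeatureMatrix(
        feature_type=feature_type,
        matrix=matrix,
        groups=pd.Series({s: groups[s] for s in samples}),
        cluster_of_feature=cluster_of_feature,
    )


def _sam_d(values: np.ndarray, is_b: np.ndarray, s0: float | None = None) -> tuple[np.ndarray, float]:
    """SAM moderated d per feature row. values: features x samples."""
    a = values[:, ~is_b]
    b = values[:, is_b]
    na, nb = a.shape[1], b.shape[1]
    mean_a = np.nanmean(a, axis=1)
    mean_b = np.nanmean(b, axis=1)
    ss = np.nansum((a - mean_a[:, None]) ** 2, axis=1) + np.nansum(
        (b - mean_b[:, None]) ** 2, axis=1
    )
    scale = (1.0 / na + 1.0 / nb) / (na + nb - 2)
    s = np.sqrt(scale * ss)
    if s0 is None:
        s0 = float(np.median(s))
    d = (mean_b - mean_a) / (s + s0)
    return d, s0


def sam_association(
    features: ClusterFeatureMatrix,
    target_fdr: float = 0.05,
    n_permutations: int = 1000,
    seed: int = 0,
    contrast: tuple[str, str] | None = None,
) -> AssociationResult:
    """Permutation SAM: q-value per feature, significant set at target FDR.

    q for a feature with score |d| is the mean count of null |d*| >= |d|
    across balanced label permutations (the expected number of falsely called
    features at that threshold), divided by the observed count of features
    with |d'| >= |d|, monotonized so q is nonincreasing in |d|. The mean is
    used rather than a median because the median collapses to zero at extreme
    thresholds, losing false-discovery control for top-ranked features.
    """
    group_names = list(contrast) if contrast else sorted(features.groups.unique())
    if set(group_names) != set(features.groups.unique()) or len(group_names) != 2:
        raise ValueError(
            f"need exactly 2 groups matching the data, got {group_names} "
            f"vs {sorted(features.groups.unique())}"
        )
    is_b = (features.groups == group_names[1]).to_numpy()
    na, nb = int((~is_b).sum()), int(is_b.sum())
    if min(na, nb) < 3:
        raise ValueError("each group needs >= 3 samples")

    values = features.matrix.to_numpy(dtype=float)
    d_obs, s0 = _sam_d(values, is_b)

    n_samples = len(is_b)
    n_distinct = comb(n_samples, nb)
    if n_distinct < n_permutations:
        logger.warning(
            "only %d distinct permutations (< %d requested); using %d random draws over them",
            n_distinct, n_permutations, n_distinct,
        )
        n_perm = n_distinct
    else:
        n_perm = n_permutations

    rng = np.random.default_rng(seed)
    abs_obs = np.abs(d_obs)
    null_abs = np.empty((n_perm, len(d_obs)))
    for p in range(n_perm):
        perm = np.zeros(n_samples, dtype=bool)
        perm[rng.choice(n_samples, size=nb, replace=False)] = True
        d_null, _ = _sam_d(values, perm, s0=s0)
        null_abs[p] = np.abs(d_null)

    # q-values: expected null exceedance count / observed exceedance count
    order = np.argsort(-abs_obs)
    q = np.ones(len(d_obs))
    sorted_abs = abs_obs[order]
    obs_sorted = np.sort(abs_obs)
    exceed_obs = len(abs_obs) - np.searchsorted(obs_sorted, sorted_abs, side="left")
    null_flat = np.sort(null_abs.ravel())
    exceed_null = (len(null_flat) - np.searchsorted(null_flat, sorted_abs, side="left")) / n_perm
    fdp = np.minimum(exceed_null / np.maximum(exceed_obs, 1), 1.0)
    # monotonize (BH-style): q at a threshold = min FDP over weaker thresholds
    fdp_monotone = np.minimum.accumulate(fdp[::-1])[::-1]
    q[order] = fdp_monotone

    table = pd.DataFrame(
        {
            "feature": features.matrix.index,
            "d": d_obs,
            "q": q,
            "significant": q <= target_fdr,
        }
    ).set_index("feature")
    return AssociationResult(
        features=table,
        target_fdr=target_fdr,
        n_permutations=n_perm,
        null_abs_d=null_abs,
        seed=seed,
    )


def summarize_cleared_clusters(
    assoc: AssociationResult,
    hierarchy: StratifiedHierarchy,
    features: ClusterFeatureMatrix,
    rules=None,
) -> pd.DataFrame:
    """Profile the FDR-significant clusters.

    Per significant feature: direction of change (d > 0 means higher in the
    second group), the cluster's median identity-marker profile, and — when an
    annotation rule set is given — the matching population name.
    """
    rows = []
    for feature in assoc.significant.index:
        node = features.cluster_of_feature[feature]
        idx = hierarchy.members[node]
        profile = hierarchy.pooled.iloc[idx].median()
        d = float(assoc.features.loc[feature, "d"])
        row = {
            "feature": feature,
            "cluster_node": node,
            "n_events": len(idx),
            "d": d,
            "q": float(assoc.features.loc[feature, "q"]),
            "direction": "increased" if d > 0 else "decreased",
        }
        row.update({f"median_{m}": float(profile[m]) for m in hierarchy.channels})
        if rules is not None:
            row["annotation"] = _match_profile(profile, rules, hierarchy.pooled)
        rows.append(row)
    return pd.DataFrame(rows)


def _match_profile(profile: pd.Series, rules, pooled: pd.DataFrame) -> str:
    refs_high = {
        m: float(np.quantile(pooled[m], rules.high_quantile))
        for m in rules.markers_used()
        if m in pooled.columns
    }
    refs_low = {
        m: float(np.quantile(pooled[m], rules.low_quantile))
        for m in rules.markers_used()
        if m in pooled.columns
    }
    for rule in sorted(rules.rules, key=lambda r: r.priority):
        needed = set(rule.high) | set(rule.low)
        if not needed <= set(refs_high):
            continue
        ok = all(profile[m] > refs_high[m] for m in rule.high)
        ok = ok and all(profile[m] <= refs_low[m] for m in rule.low)
        if ok:
            return rule.population
    return "unlabeled"
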