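"""Group-comparison statistics with normality-routed tests.

Routing follows standard practice for small-cohort cytometry comparisons:
Shapiro-Wilk normality in each group; if either group is non-Gaussian
(p < 0.05) the comparison uses a two-sided Mann-Whitney U test, otherwise a
two-sided Welch t test. Families of comparisons are corrected with the
Holm-Sidak step-down procedure. Heatmap profiles are row-standardized
(subtract row mean, divide by row SD, population convention: divide by n).
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GroupComparison",
    "route_test",
    "compare_groups",
    "holm_sidak",
    "scale_heatmap",
    "compare_table",
]

logger = logging.getLogger(__name__)

SHAPIRO_ALPHA = 0.05


@dataclasses.dataclass
class GroupComparison:
    unit: str
    test_used: str  # t_test | mann_whitney
    statistic: float
    p_raw: float
    log2_fold_change: float
    n_a: int
    n_b: int
    p_adjusted: float | None = None


def route_test(values_a: np.ndarray, values_b: np.ndarray) -> str:
    """Choose t_test or mann_whitney from Shapiro-Wilk normality per group.

    Groups below 3 values (or degenerate constant groups, where normality is
    undefined) force the nonparametric branch with a warning.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 3 or len(b) < 3:
        logger.warning("group with < 3 values; Mann-Whitney forced")
        return "mann_whitney"
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        logger.warning("constant group; normality undefined, Mann-Whitney forced")
        return "mann_whitney"
    for grp in (a, b):
        if sps.shapiro(grp).pvalue < SHAPIRO_ALPHA:
            return "mann_whitney"
    return "t_test"


def _log2_fold(mean_a: float, mean_b: float) -> float:
    if mean_a == 0.0:
        return np.inf if mean_b > 0 else 0.0
    ratio = mean_b / mean_a
    return float(np.log2(ratio)) if ratio > 0 else -np.inf


def compare_groups(
    values_a: np.ndarray,
    values_b: np.ndarray,
    unit: str = "cluster_abundance",
    test: str | None = None,
) -> GroupComparison:
    """Two-sided comparison of group B against group A (reference).

    The test is routed unless forced via ``test``. Mann-Whitney uses exact
    enumeration for small tie-free groups (both n <= 8) and the tie-corrected
    normal approximation otherwise. Identical groups report p = 1, log2FC 0.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    chosen = test or route_test(a, b)
    mean_a, mean_b = float(np.mean(a)), float(np.mean(b))
    log2fc = _log2_fold(mean_a, mean_b)

    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0:
        # fully tied data: no evidence of a difference under either test
        return GroupComparison(unit, chosen, 0.0, 1.0, 0.0, len(a), len(b))

    if chosen == "t_test":
        res = sps.ttest_ind(b, a, equal_var=False)
        stat, p = float(res.statistic), float(res.pvalue)
    else:
        has_ties = len(np.unique(pooled)) < len(pooled)
        method = "exact" if (len(a) <= 8 and len(b) <= 8 and not has_ties) else "asymptotic"
        res = sps.mannwhitneyu(b, a, alternative="two-sided", method=method)
        stat, p = float(res.statistic), float(res.pvalue)
    return GroupComparison(unit, chosen, stat, min(p, 1.0), log2fc, len(a), len(b))


def holm_sidak(p_values: np.ndarray | list[float]) -> pd.DataFrame:
    """Holm-Sidak step-down adjustment of one family of p values.

    adjusted_(i) = max_{j <= i} [1 - (1 - p_(j))^(m - j + 1)] over the
    ascending ordering, capped at 1 and returned in the original order.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size and (np.min(p) < 0 or np.max(p) > 1):
        raise ValueError("p values must lie in [0, 1]")
    if p.size == 0:
        return pd.DataFrame({"p_raw": [], "p_adjusted": []})
    _, adjusted, _, _ = multipletests(p, method="holm-sidak")
    return pd.DataFrame({"p_raw": p, "p_adjusted": np.minimum(adjusted, 1.0)})


def scale_heatmap(profiles: pd.DataFrame) -> pd.DataFrame:
    """Row-standardize a clusters x markers profile matrix.

    Each row is transformed by subtracting the row mean and dividing by the
    row standard deviation (population convention, ddof=0). Zero-variance
    rows are returned as all zeros with a warning.
    """
    if profiles.shape[1] < 2:
        raise ValueError("need at least 2 columns per row to scale")
    values = profiles.to_numpy(dtype=float)
    means = values.mean(axis=1, keepdims=True)
    sds = values.std(axis=1, ddof=0, keepdims=True)
    flat = (sds == 0).ravel()
    if flat.any():
        logger.warning("%d constant row(s) scaled to zeros", int(flat.sum()))
    sds = np.where(sds == 0, 1.0, sds)
    scaled = (values - means) / sds
    scaled[flat, :] = 0.0
    return pd.DataFrame(scaled, index=profiles.index, columns=profiles.columns)


def compare_table(
    values: pd.DataFrame,
    groups: pd.Series,
    contrast: tuple[str, str],
    unit: str = "marker_mean_in_subset",
) -> pd.DataFrame:
    """Routed comparisons for every column of ``values`` between two groups,
    Holm-Sidak-corrected as one family."""
    ref, cmp_ = contrast
    mask_a = (groups == ref).to_numpy()
    mask_b = (groups == cmp_).to_numpy()
    rows = []
    for col in values.columns:
        a = values.loc[mask_a, col].dropna().to_numpy()
        b = values.loc[mask_b, col].dropna().to_numpy()
        res = compare_groups(a, b, unit=unit)
        rows.append(
            {
                "feature": col,
                "test_used": res.test_used,
                "statistic": res.statistic,
                "p_raw": res.p_raw,
                "log2_fold_change": res.log2_fold_change,
            }
        )
    out = pd.DataFrame(rows)
    out["p_adjusted"] = holm_sidak(out["p_raw"].to_numpy())["p_adjusted"].to_numpy()
    return out
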