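"""Subpopulation profiling: gated-subset expression, per-cluster senescent
burden, and senolytic clearance reports.

Subsets are defined by a small boolean gate grammar over named per-event
flags (marker calls, derived classes) and metacluster labels, e.g.::

    p16KB
    p16 AND NOT Ki67
    cluster:CD24high Osteolineage AND p16

so the manual gates of an interactive analysis have a reproducible textual
form.
"""

from __future__ import annotations

import dataclasses
import logging
import re
from typing import Mapping

import numpy as np
import pandas as pd

from .events import EventMatrix
from .gating import group_fold_change
from .stats import compare_groups, holm_sidak

__all__ = [
    "GateExpressionError",
    "parse_gate",
    "evaluate_gate",
    "profile_subset",
    "cluster_burden",
    "burden_contrast",
    "clearance_report",
]

logger = logging.getLogger(__name__)


class GateExpressionError(ValueError):
    def __init__(self, message: str, position: int) -> None:
        super().__init__(f"{message} (at position {position})")
        self.position = position


_TOKEN = re.compile(r"\s*(\(|\)|AND\b|OR\b|NOT\b|cluster:[^()]+?(?=\s+AND|\s+OR|\s*\)|\s*$)|[A-Za-z0-9_+\-./]+)")


def _tokenize(text: str) -> list[tuple[str, int]]:
    tokens, pos = [], 0
    while pos < len(text):
        m = _TOKEN.match(text, pos)
        if not m:
            raise GateExpressionError(f"unexpected character {text[pos]!r}", pos)
        tokens.append((m.group(1), m.start(1)))
        pos = m.end()
    return tokens


@dataclasses.dataclass
class _Parser:
    """Recursive-descent parser for OR > AND > NOT > atom."""

    tokens: list[tuple[str, int]]
    i: int = 0
    length: int = 0

    def peek(self) -> tuple[str, int] | None:
        return self.tokens[self.i] if self.i < len(self.tokens) else None

    def next(self) -> tuple[str, int]:
        tok = self.peek()
        if tok is None:
            raise GateExpressionError("unexpected end of expression", self.length)
        self.i += 1
        return tok

    def parse(self):
        node = self.parse_or()
        if self.peek() is not None:
            tok, pos = self.peek()
            raise GateExpressionError(f"unexpected token {tok!r}", pos)
        return node

    def parse_or(self):
        node = self.parse_and()
        while self.peek() and self.peek()[0] == "OR":
            self.next()
            node = ("or", node, self.parse_and())
        return node

    def parse_and(self):
        node = self.parse_not()
        while self.peek() and self.peek()[0] == "AND":
            self.next()
            node = ("and", node, self.parse_not())
        return node

    def parse_not(self):
        if self.peek() and self.peek()[0] == "NOT":
            self.next()
            return ("not", self.parse_not())
        return self.parse_atom()

    def parse_atom(self):
        tok, pos = self.next()
        if tok == "(":
            node = self.parse_or()
            closing = self.peek()
            if closing is None or closing[0] != ")":
                raise GateExpressionError("missing closing parenthesis", pos)
            self.next()
            return node
        if tok in (")", "AND", "OR"):
            raise GateExpressionError(f"unexpected token {tok!r}", pos)
        if tok.startswith("cluster:"):
            return ("cluster", tok[len("cluster:") :].strip(), pos)
        return ("flag", tok, pos)


def parse_gate(expression: str):
    """Parse a gate expression into an AST; errors carry the position."""
    tokens = _tokenize(expression)
    if not tokens:
        raise GateExpressionError("empty gate expression", 0)
    parser = _Parser(tokens=tokens, length=len(expression))
    return parser.parse()


def evaluate_gate(
    node,
    calls: pd.DataFrame,
    cluster_labels: np.ndarray | None = None,
) -> np.ndarray:
    """Evaluate a parsed gate over per-event flags / cluster labels."""
    kind = node[0]
    if kind == "or":
        return evaluate_gate(node[1], calls, cluster_labels) | evaluate_gate(node[2], calls, cluster_labels)
    if kind == "and":
        return evaluate_gate(node[1], calls, cluster_labels) & evaluate_gate(node[2], calls, cluster_labels)
    if kind == "not":
        return ~evaluate_gate(node[1], calls, cluster_labels)
    if kind == "cluster":
        if cluster_labels is None:
            raise GateExpressionError("gate references clusters but no labels given", node[2])
        return np.asarray(cluster_labels) == node[1]
    name = node[1]
    if name not in calls.columns:
        raise GateExpressionError(f"unknown flag {name!r}", node[2])
    return calls[name].to_numpy()


def profile_subset(
    matrices: Mapping[str, EventMatrix],
    calls_by_sample: Mapping[str, pd.DataFrame],
    subset: str,
    markers: list[str],
    cluster_labels: Mapping[str, np.ndarray] | None = None,
    thresholds=None,
) -> pd.DataFrame:
    """Per-sample mean expression and %positive for ``markers`` in a subset.

    ``subset`` is a gate expression; samples whose subset is empty are
    excluded with a warning. ``%positive`` columns require ``thresholds``.
    """
    ast = parse_gate(subset)
    rows = []
    for sid, matrix in matrices.items():
        calls = calls_by_sample[sid]
        labels = None if cluster_labels is None else cluster_labels.get(sid)
        mask = evaluate_gate(ast, calls, labels)
        if not mask.any():
            logger.warning("%s: subset %r is empty; sample excluded", sid, subset)
            continue
        sub = matrix.values.loc[mask, markers]
        row: dict[str, object] = {"sample_id": sid, "n_events": int(mask.sum())}
        for m in markers:
            row[f"mean_{m}"] = float(sub[m].mean())
            if thresholds is not None and m in thresholds:
                row[f"pct_{m}_pos"] = 100.0 * float((sub[m] > thresholds.cutoff(m)).mean())
        rows.append(row)
    return pd.DataFrame(rows)


def cluster_burden(
    matrices: Mapping[str, EventMatrix],
    calls_by_sample: Mapping[str, pd.DataFrame],
    cluster_labels: Mapping[str, np.ndarray],
    groups: Mapping[str, str],
) -> pd.DataFrame:
    """Per-cluster per-sample senescence metrics (long table).

    For each (cluster label, sample): %p16KB of the cluster's cells, mean p16
    and mean BCL-2. Clusters absent from a sample get NaN metrics.
    """
    all_labels = sorted({str(l) for labels in cluster_labels.values() for l in labels})
    rows = []
    for sid, matrix in matrices.items():
        labels = np.asarray(cluster_labels[sid], dtype=object)
        calls = calls_by_sample[sid]
        for lab in all_labels:
            mask = labels == lab
            row = {
                "sample_id": sid,
                "group": groups.get(sid),
                "cluster": lab,
                "n_events": int(mask.sum()),
            }
            if mask.any():
                row["pct_p16KB"] = 100.0 * float(calls.loc[mask, "p16KB"].mean()) if "p16KB" in calls else np.nan
                row["mean_p16"] = float(matrix.values.loc[mask, "p16"].mean())
                row["mean_BCL-2"] = float(matrix.values.loc[mask, "BCL-2"].mean())
            else:
                row["pct_p16KB"] = np.nan
                row["mean_p16"] = np.nan
                row["mean_BCL-2"] = np.nan
            rows.append(row)
    return pd.DataFrame(rows)


def burden_contrast(
    burden: pd.DataFrame,
    metric: str,
    contrast: tuple[str, str],
) -> pd.DataFrame:
    """Per-cluster group contrast of one burden metric with routed tests and
    Holm-Sidak correction across clusters."""
    ref, cmp_ = contrast
    rows = []
    for lab, sub in burden.groupby("cluster"):
        a = sub.loc[sub["group"] == ref, metric].dropna().to_numpy()
        b = sub.loc[sub["group"] == cmp_, metric].dropna().to_numpy()
        if len(a) == 0 or len(b) == 0:
            continue
        res = compare_groups(a, b, unit="marker_mean_in_subset")
        rows.append(
            {
                "cluster": lab,
                "test_used": res.test_used,
                "p_raw": res.p_raw,
                "log2_fold_change": res.log2_fold_change,
                "mean_ref": float(np.mean(a)),
                "mean_cmp": float(np.mean(b)),
            }
        )
    out = pd.DataFrame(rows)
    if len(out):
        out["p_adjusted"] = holm_sidak(out["p_raw"].to_numpy())["p_adjusted"].to_numpy()
    return out


def clearance_report(
    abundances: pd.DataFrame,
    contrast: tuple[str, str] = ("old", "old_senolytic"),
    alpha: float = 0.05,
    log2fc_cleared: float = -0.5,
) -> pd.DataFrame:
    """Per-cluster abundance change between treatment arms.

    ``abundances`` is long-form with columns sample_id, group, cluster,
    fraction. A cluster is labeled "cleared" when adjusted p < alpha and
    log2FC <= log2fc_cleared; "increased" when adjusted p < alpha and
    log2FC >= +0.5; otherwise "unchanged". Arms below 3 samples force
    nonparametric tests with a warning.
    """
    ref, cmp_ = contrast
    for arm in contrast:
        n_arm = abundances.loc[abundances["group"] == arm, "sample_id"].nunique()
        if n_arm == 0:
            raise ValueError(f"arm {arm!r} absent from abundance table")
        if n_arm < 3:
            logger.warning("arm %r has %d samples; tests forced nonparametric", arm, n_arm)
    rows = []
    for lab, sub in abundances.groupby("cluster"):
        a = sub.loc[sub["group"] == ref, "fraction"].dropna().to_numpy()
        b = sub.loc[sub["group"] == cmp_, "fraction"].dropna().to_numpy()
        if len(a) == 0 or len(b) == 0:
            continue
        force = "mann_whitney" if (len(a) < 3 or len(b) < 3) else None
        res = compare_groups(a, b, unit="cluster_abundance", test=force)
        summary = pd.DataFrame(
            {
                "sample_id": range(len(a) + len(b)),
                "group": [ref] * len(a) + [cmp_] * len(b),
                "fraction": np.concatenate([a, b]),
            }
        )
        fold = group_fold_change(summary, "fraction", (ref, cmp_))
        rows.append(
            {
                "cluster": lab,
                "log2_fold_change": fold["log2_fold"],
                "fold": fold["fold"],
                "p_raw": res.p_raw,
                "test_used": res.test_used,
            }
        )
    out = pd.DataFrame(rows)
    if out.empty:
        return out
    out["p_adjusted"] = holm_sidak(out["p_raw"].to_numpy())["p_adjusted"].to_numpy()
    direction = []
    for _, r in out.iterrows():
        if r["p_adjusted"] < alpha and r["log2_fold_change"] <= log2fc_cleared:
            direction.append("cleared")
        elif r["p_adjusted"] < alpha and r["log2_fold_change"] >= 0.5:
            direction.append("increased")
        else:
            direction.append("unchanged")
    out["direction"] = direction
    return out
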