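"""Proteome COMPARE: response-correlated protein selection and clustering.

Given a compound's log10(IC50) fingerprint and a proteins x cell-lines
abundance matrix, this stage (i) correlates every protein's abundance
with the fingerprint, (ii) keeps the top k directly and top k inversely
correlated proteins, (iii) Ward-clusters the reduced matrix in both
dimensions and codes each value by quartile for heat-map display,
(iv) calls each cell line sensitive/resistant by a median split of the
fingerprint, and (v) tests cluster membership against the
sensitive/resistant call with a Pearson chi-square test.

Omics matrices are plain pandas DataFrames with protein ids as the index
and cell-line ids as columns; missing values are NaN.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy

from .docking import CorrelationResult, pearson
from .errors import InsufficientDataError, PanelomicsError, UndefinedCorrelationError
from .oncobiogram import ActivityProfile

__all__ = [
    "CompareSelection",
    "SensitivityCall",
    "ChiSquareResult",
    "compare_proteins",
    "select_top",
    "quartile_code",
    "ward_cluster",
    "cut_tree",
    "dendrogram_to_newick",
    "classify_sensitivity",
    "cluster_response_chi2",
]

QUARTILE_CODES = ("Q1", "Q2", "MEDIAN", "Q3", "Q4")


@dataclass(frozen=True)
class CompareSelection:
    """Top directly and inversely response-correlated features.

    `direct` is sorted by r descending (all r > 0), `inverse` by r
    ascending (all r < 0); the two lists are disjoint.
    """

    direct: tuple[tuple[str, float], ...]
    inverse: tuple[tuple[str, float], ...]

    @property
    def feature_ids(self) -> list[str]:
        return [f for f, _ in self.direct] + [f for f, _ in self.inverse]


@dataclass(frozen=True)
class SensitivityCall:
    """Median-split response call per cell line.

    A line is sensitive iff its log10(IC50) is strictly below the panel
    median, resistant iff strictly above, tie at exact equality.
    """

    calls: Mapping[str, str]
    threshold: float


@dataclass(frozen=True)
class ChiSquareResult:
    """Pearson chi-square on a K x 2 cluster-by-response table."""

    statistic: float
    df: int
    p: float
    table: pd.DataFrame


def compare_proteins(
    profile: ActivityProfile,
    matrix: pd.DataFrame,
    min_overlap: int = 3,
) -> tuple[list[tuple[str, CorrelationResult]], dict[str, str]]:
    """Correlate each feature's abundance with the activity fingerprint.

    Returns ``(results, skipped)`` where `results` holds one
    ``(feature_id, CorrelationResult)`` per eligible feature (in input
    order) and `skipped` maps ineligible features to a reason.
    """
    shared = [c for c in matrix.columns if c in profile.values]
    x_full = profile.vector(shared)
    if not shared or not np.isfinite(x_full).any():
        raise PanelomicsError("no overlapping cell lines between profile and matrix")
    sub = matrix[shared]
    results: list[tuple[str, CorrelationResult]] = []
    skipped: dict[str, str] = {}
    for feature, row in zip(sub.index, sub.to_numpy(dtype=float)):
        keep = np.isfinite(row) & np.isfinite(x_full)
        if keep.sum() < min_overlap:
            skipped[feature] = (
                f"only {int(keep.sum())} overlapping cell lines (< {min_overlap})"
            )
            continue
        try:
            results.append((feature, pearson(x_full[keep], row[keep])))
        except UndefinedCorrelationError as exc:
            skipped[feature] = str(exc)
    return results, skipped


def select_top(
    correlations: Sequence[tuple[str, CorrelationResult]],
    k_direct: int = 20,
    k_inverse: int = 20,
) -> CompareSelection:
    """Keep the k most positively and k most negatively correlated features.

    Selection is by r with ties broken by feature id, so the result is
    invariant to the input ordering. Raises if fewer than the requested
    number of features of either sign are available.
    """
    pos = sorted(
        ((f, res.r) for f, res in correlations if res.r > 0),
        key=lambda t: (-t[1], t[0]),
    )
    neg = sorted(
        ((f, res.r) for f, res in correlations if res.r < 0),
        key=lambda t: (t[1], t[0]),
    )
    if len(pos) < k_direct:
        raise InsufficientDataError(
            f"need {k_direct} positively correlated features, have {len(pos)}"
        )
    if len(neg) < k_inverse:
        raise InsufficientDataError(
            f"need {k_inverse} negatively correlated features, have {len(neg)}"
        )
    return CompareSelection(
        direct=tuple(pos[:k_direct]), inverse=tuple(neg[:k_inverse])
    )


def _code_vector(values: np.ndarray) -> np.ndarray:
    """Five-category quartile coding of one vector (NaN passes through).

    Values exactly equal to the median are coded MEDIAN; the remaining
    values are binned by the quartiles of the non-median values into
    half-open, lower-inclusive bins Q1..Q4. Computing the boundaries on
    the non-median values keeps the four bins balanced (counts differ by
    at most 1 for distinct-valued vectors of length 4k+1).
    """
    out = np.full(values.shape, None, dtype=object)
    finite = np.isfinite(values)
    obs = values[finite]
    if obs.size < 4:
        raise InsufficientDataError(
            f"need >= 4 non-missing values to quartile-code, got {obs.size}"
        )
    med = float(np.median(obs))
    rest = obs[obs != med]
    if rest.size == 0:  # constant vector
        out[finite] = "MEDIAN"
        return out
    q1, q2, q3 = np.percentile(rest, [25, 50, 75])
    for i in np.nonzero(finite)[0]:
        v = values[i]
        if v == med:
            out[i] = "MEDIAN"
        elif v < q1:
            out[i] = "Q1"
        elif v < q2:
            out[i] = "Q2"
        elif v < q3:
            out[i] = "Q3"
        else:
            out[i] = "Q4"
    return out


def quartile_code(matrix: pd.DataFrame, axis: str = "per_feature") -> pd.DataFrame:
    """Quartile-code an abundance matrix for heat-map display.

    axis="per_feature" codes each row against its own distribution;
    axis="global" codes every value against the pooled distribution.
    """
    values = matrix.to_numpy(dtype=float)
    if axis == "per_feature":
        coded = np.vstack([_code_vector(row) for row in values])
    elif axis == "global":
        coded = _code_vector(values.ravel()).reshape(values.shape)
    else:
        raise PanelomicsError(f"unknown axis {axis!r}")
    return pd.DataFrame(coded, index=matrix.index, columns=matrix.columns)


def ward_cluster(
    matrix: pd.DataFrame, axis: str = "rows", zscore: bool = True
) -> np.ndarray:
    """Agglomerative Ward minimum-variance clustering of rows or columns.

    Distances are Euclidean on per-feature z-scores (``zscore=False``
    preserves raw values). Missing entries are mean-imputed per feature
    before computing distances; an all-missing item raises. Returns a
    scipy linkage matrix whose merge heights are monotone non-decreasing
    (Ward produces no inversions); ties merge the lowest pair index
    first (scipy's deterministic order).
    """
    data = matrix.to_numpy(dtype=float)
    if zscore:
        mu = np.nanmean(data, axis=1, keepdims=True)
        sd = np.nanstd(data, axis=1, keepdims=True)
        sd[sd == 0] = 1.0
        data = (data - mu) / sd
    # mean-impute per feature so occasional gaps do not veto clustering
    if np.isnan(data).any():
        if np.all(np.isnan(data), axis=1).any():
            raise PanelomicsError("all-missing feature(s) in matrix")
        means = np.nanmean(data, axis=1, keepdims=True)
        data = np.where(np.isnan(data), means, data)
    if axis == "cols":
        data = data.T
    elif axis != "rows":
        raise PanelomicsError(f"unknown axis {axis!r}")
    if data.shape[0] < 2:
        raise PanelomicsError("need at least 2 items to cluster")
    return hierarchy.linkage(data, method="ward")


def cut_tree(tree: np.ndarray, k: int, labels: Sequence[str]) -> dict[str, int]:
    """Cut a linkage tree into K clusters (undoing the last K-1 merges).

    Cluster indices run 1..K and are assigned in order of first item
    appearance in `labels`.
    """
    n = tree.shape[0] + 1
    if len(labels) != n:
        raise PanelomicsError(f"expected {n} labels, got {len(labels)}")
    if not (1 <= k <= n):
        raise PanelomicsError(f"K must be in [1, {n}], got {k}")
    flat = hierarchy.fcluster(tree, t=k, criterion="maxclust")
    relabel: dict[int, int] = {}
    out: dict[str, int] = {}
    for label, raw in zip(labels, flat):
        if raw not in relabel:
            relabel[raw] = len(relabel) + 1
        out[label] = relabel[raw]
    return out


def dendrogram_to_newick(tree: np.ndarray, labels: Sequence[str]) -> str:
    """Serialize a linkage tree as a newick string with branch lengths."""
    n = tree.shape[0] + 1
    if len(labels) != n:
        raise PanelomicsError(f"expected {n} labels, got {len(labels)}")

    def build(node, parent_height):
        if node.is_leaf():
            name = str(labels[node.id]).replace(",", "_").replace(":", "_")
            return f"{name}:{parent_height - 0.0:.6g}"
        left = build(node.get_left(), node.dist)
        right = build(node.get_right(), node.dist)
        return f"({left},{right}):{parent_height - node.dist:.6g}"

    root = hierarchy.to_tree(tree)
    left = build(root.get_left(), root.dist)
    right = build(root.get_right(), root.dist)
    return f"({left},{right});"


def classify_sensitivity(profile: ActivityProfile) -> SensitivityCall:
    """Median-split sensitive/resistant call over a panel fingerprint."""
    items = [
        (c, v) for c, v in profile.values.items()
        if v is not None and not (isinstance(v, float) and math.isnan(v))
    ]
    if len(items) < 2:
        raise InsufficientDataError("need >= 2 non-missing values")
    med = float(np.median([v for _, v in items]))
    calls = {
        c: ("sensitive" if v < med else "resistant" if v > med else "tie")
        for c, v in items
    }
    return SensitivityCall(calls=calls, threshold=med)


def cluster_response_chi2(
    col_clusters: Mapping[str, int], calls: SensitivityCall
) -> ChiSquareResult:
    """Pearson chi-square of cluster membership vs. response call.

    Cell lines called tie (log10 IC50 exactly at the median) are
    dropped; the K x 2 contingency of the remaining lines is tested
    without continuity correction, df = K - 1. An empty margin (a
    retained cluster with no lines, or no sensitive/resistant lines at
    all) raises with a suggestion to merge clusters.
    """
    rows: dict[int, dict[str, int]] = {}
    for line, cluster in col_clusters.items():
        call = calls.calls.get(line)
        if call is None or call == "tie":
            continue
        rows.setdefault(cluster, {"sensitive": 0, "resistant": 0})
        rows[cluster][call] += 1
    if len(rows) < 2:
        raise PanelomicsError("need >= 2 clusters with non-tie cell lines")
    table = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    table = table[["sensitive", "resistant"]].fillna(0).astype(int)
    if (table.sum(axis=1) == 0).any() or (table.sum(axis=0) == 0).any():
        raise PanelomicsError(
            "empty margin in contingency table; merge clusters and retry"
        )
    stat, p, df, _ = stats.chi2_contingency(table.values, correction=False)
    return ChiSquareResult(statistic=float(stat), df=int(df), p=float(p), table=table)
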