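"""Kaplan-Meier screening of expression-stratified cohorts.

Each cohort is a table of (subject_id, time in months, event indicator,
continuous expression of the gene of interest). Subjects are split into
high/low expressors (median split by default, or a quantile, or a
KM-Plotter-style scan over the 25th-75th percentile cutoffs), the two
arms are compared with the Mantel-Haenszel log-rank test, and p-values
across cohorts are screened with Benjamini-Hochberg FDR control at 5%.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.utils import restricted_mean_survival_time
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import InsufficientDataError, PanelomicsError

__all__ = [
    "KMCurve",
    "km_estimate",
    "dichotomize",
    "logrank",
    "fdr_screen",
    "survival_screen",
]

SURVIVAL_COLUMNS = ("time", "event")


@dataclass(frozen=True)
class KMCurve:
    """Product-limit estimate: distinct event times (ascending), the
    survival probability immediately after each, and at-risk counts."""

    event_times: tuple[float, ...]
    survival: tuple[float, ...]
    at_risk: tuple[int, ...]

    def probability_at(self, t: float) -> float:
        """S(t): right-continuous step function starting at 1."""
        s = 1.0
        for et, sv in zip(self.event_times, self.survival):
            if et <= t:
                s = sv
            else:
                break
        return s


def _check_table(table: pd.DataFrame) -> pd.DataFrame:
    missing = set(SURVIVAL_COLUMNS) - set(table.columns)
    if missing:
        raise PanelomicsError(f"survival table needs columns {sorted(missing)}")
    if (table["time"] < 0).any() or not np.isfinite(table["time"]).all():
        raise PanelomicsError("times must be finite and non-negative")
    if not table["event"].isin([0, 1]).all():
        raise PanelomicsError("event indicator must be 0 (censored) or 1 (death)")
    return table


def km_estimate(table: pd.DataFrame) -> KMCurve:
    """Kaplan-Meier product-limit estimator for one group.

    Subjects censored exactly at an event time are counted at risk at
    that time (the standard convention).
    """
    table = _check_table(table)
    if table.empty:
        raise InsufficientDataError("empty survival table")
    kmf = KaplanMeierFitter()
    kmf.fit(table["time"], table["event"])
    event_times = sorted(table.loc[table["event"] == 1, "time"].unique())
    sf = kmf.survival_function_["KM_estimate"]
    at_risk = [
        int((table["time"] >= t).sum()) for t in event_times
    ]
    surv = [float(sf.loc[t]) for t in event_times]
    return KMCurve(
        event_times=tuple(float(t) for t in event_times),
        survival=tuple(surv),
        at_risk=tuple(at_risk),
    )


def dichotomize(
    expression: Sequence[float], method: str = "median", q: float | None = None
) -> tuple[np.ndarray, float, np.ndarray]:
    """Split a continuous covariate into {high, low} labels.

    Returns ``(labels, cutoff, at_cutoff)``: low iff value < cutoff,
    high otherwise; values exactly at the cutoff are assigned high and
    flagged in the boolean `at_cutoff` mask. method="median" uses the
    sample median; method="quantile" uses the q-quantile.
    """
    x = np.asarray(expression, dtype=float)
    if np.unique(x[np.isfinite(x)]).size < 2:
        raise PanelomicsError("constant expression cannot be dichotomized")
    if method == "median":
        cutoff = float(np.median(x))
    elif method == "quantile":
        if q is None or not (0 < q < 1):
            raise PanelomicsError("quantile method needs q in (0, 1)")
        cutoff = float(np.quantile(x, q))
    else:
        raise PanelomicsError(f"unknown method {method!r}")
    labels = np.where(x < cutoff, "low", "high")
    return labels, cutoff, x == cutoff


def _logrank_arrays(ta, ea, tb, eb) -> tuple[float, float]:
    """Mantel-Haenszel log-rank from raw arrays (vectorized over the
    distinct pooled event times; ties pooled with the hypergeometric
    variance)."""
    times = np.concatenate([ta, tb])
    events = np.concatenate([ea, eb]).astype(bool)
    in_a = np.zeros(times.size, dtype=bool)
    in_a[: ta.size] = True
    ets = np.unique(times[events])
    # at-risk and event counts per distinct event time
    n_at = (times[None, :] >= ets[:, None]).sum(axis=1).astype(float)
    n1_at = ((times[None, :] >= ets[:, None]) & in_a[None, :]).sum(axis=1)
    d = ((times[None, :] == ets[:, None]) & events[None, :]).sum(axis=1)
    d1 = (
        (times[None, :] == ets[:, None]) & events[None, :] & in_a[None, :]
    ).sum(axis=1)
    frac = n1_at / n_at
    observed = d1.sum()
    expected = (d * frac).sum()
    with np.errstate(invalid="ignore", divide="ignore"):
        var_terms = d * frac * (1 - frac) * (n_at - d) / (n_at - 1)
    variance = np.nansum(np.where(n_at > 1, var_terms, 0.0))
    if variance == 0:
        return 0.0, 1.0
    stat = (observed - expected) ** 2 / variance
    return float(stat), float(stats.chi2.sf(stat, df=1))


def logrank(group_a: pd.DataFrame, group_b: pd.DataFrame) -> tuple[float, float]:
    """Two-group Mantel-Haenszel log-rank test (chi-square_1, two-sided).

    Ties at identical event times are pooled with the standard
    hypergeometric variance.
    """
    a, b = _check_table(group_a), _check_table(group_b)
    if a["event"].sum() + b["event"].sum() == 0:
        raise InsufficientDataError("no events in either group")
    return _logrank_arrays(
        a["time"].to_numpy(float), a["event"].to_numpy(int),
        b["time"].to_numpy(float), b["event"].to_numpy(int),
    )


def fdr_screen(pvalues: Sequence[float], fdr: float = 0.05) -> pd.DataFrame:
    """Benjamini-Hochberg step-up q-values; pass iff q <= fdr.

    Returns a DataFrame with columns (p, q, passed) in input order.
    q >= p always, and q is monotone in p.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise PanelomicsError("empty p-value list")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise PanelomicsError("p-values must lie in [0, 1]")
    passed, q, _, _ = multipletests(p, alpha=fdr, method="fdr_bh")
    return pd.DataFrame({"p": p, "q": q, "passed": q <= fdr})


def _arm_location(table: pd.DataFrame) -> float:
    """Median survival of one arm; restricted mean over follow-up when
    the median is never reached."""
    kmf = KaplanMeierFitter().fit(table["time"], table["event"])
    med = kmf.median_survival_time_
    if math.isfinite(med):
        return float(med)
    return float(restricted_mean_survival_time(kmf, t=float(table["time"].max())))


@dataclass(frozen=True)
class CohortScreenResult:
    """Log-rank screen across cohorts with BH-FDR control."""

    table: pd.DataFrame
    curves: Mapping[str, Mapping[str, KMCurve]] = field(default_factory=dict)


def survival_screen(
    cohorts: Sequence[tuple[str, pd.DataFrame]],
    method: str = "median",
    q: float | None = None,
    fdr: float = 0.05,
) -> CohortScreenResult:
    """Dichotomize -> log-rank per cohort -> BH-FDR across cohorts.

    Each cohort table needs columns (time, event, expression). The
    result table has one row per cohort: log-rank statistic, p, BH q,
    pass flag, and the direction (which expression arm survives longer,
    by median survival with a restricted-mean fallback).

    method="scan" emulates the KM-Plotter auto-cutoff: the quantile in
    [0.25, 0.75] (step 0.05) minimizing the log-rank p is used and the
    chosen quantile recorded; note the scanned p is optimistically
    biased and the scan column should be reported alongside.
    """
    if not cohorts:
        raise PanelomicsError("empty cohort list")
    rows = []
    curves: dict[str, dict[str, KMCurve]] = {}
    for label, table in cohorts:
        if "expression" not in table.columns:
            raise PanelomicsError(f"cohort {label!r}: missing expression column")
        try:
            if method == "scan":
                best = None
                for qq in np.arange(0.25, 0.751, 0.05):
                    labels, _, _ = dichotomize(
                        table["expression"], method="quantile", q=float(qq)
                    )
                    high, low = table[labels == "high"], table[labels == "low"]
                    if high.empty or low.empty:
                        continue
                    stat, p = logrank(high, low)
                    if best is None or p < best[1]:
                        best = (stat, p, float(qq), labels)
                if best is None:
                    raise InsufficientDataError("no usable cutoff in scan")
                stat, p, chosen_q, labels = best
            else:
                labels, _, _ = dichotomize(table["expression"], method=method, q=q)
                chosen_q = q
                high, low = table[labels == "high"], table[labels == "low"]
                stat, p = logrank(high, low)
            high, low = table[labels == "high"], table[labels == "low"]
            direction = (
                "low expression survives longer"
                if _arm_location(low) > _arm_location(high)
                else "high expression survives longer"
            )
            curves[label] = {
                "high": km_estimate(high),
                "low": km_estimate(low),
            }
            rows.append(
                {"cohort": label, "statistic": stat, "p": p,
                 "cutoff_quantile": chosen_q, "direction": direction}
            )
        except PanelomicsError as exc:
            raise type(exc)(f"cohort {label!r}: {exc}") from exc
    table_out = pd.DataFrame(rows)
    bh = fdr_screen(table_out["p"], fdr=fdr)
    table_out["q"] = bh["q"].values
    table_out["passed"] = bh["passed"].values
    return CohortScreenResult(table=table_out, curves=curves)
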