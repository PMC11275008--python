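"""Relative expression (ddCt) and dose-response summarization.

The Livak method quantifies relative gene expression from qPCR cycle
thresholds: dCt = mean Ct(target) - mean Ct(reference) per sample group,
ddCt = dCt(treated) - dCt(control), fold change = 2^(-ddCt). The sign
convention matters — downregulation must come out as a negative log2
fold — and is switchable for tables produced under the opposite
convention.

Dose-response curves (percent viability vs. concentration) are
summarized by a four-parameter logistic (4PL) fit with the top
constrained near 100% and the bottom near 0%; an IC50 that is not
reached within the tested range is reported as a censored value
("> c_max") that propagates through resistance ratios.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

from .errors import FitError, PanelomicsError

__all__ = [
    "Censored",
    "ddct_fold",
    "ic50_from_curve",
    "degree_of_resistance",
]


@dataclass(frozen=True)
class Censored:
    """A right-censored positive quantity: the true value exceeds `bound`."""

    bound: float

    def __post_init__(self):
        if not self.bound > 0:
            raise PanelomicsError("censoring bound must be > 0")

    def __str__(self):
        return f"> {self.bound:g}"


def _group_mean_ct(table: pd.DataFrame, group: str, role: str) -> float:
    sel = table[(table["group"] == group) & (table["role"] == role)]["ct"]
    if sel.empty:
        raise PanelomicsError(f"no Ct rows for group={group!r}, role={role!r}")
    if (sel <= 0).any():
        raise PanelomicsError("Ct values must be > 0")
    return float(sel.mean())


def ddct_fold(
    table: pd.DataFrame, convention: str = "livak"
) -> tuple[float, float]:
    """Fold change and log2 fold from a Ct table.

    `table` needs columns (group, role, ct) with group in
    {treated, control} and role in {target, reference}; replicates are
    averaged on the Ct scale. convention="livak" returns 2^(-ddCt)
    (downregulation => fold < 1, log2 < 0); convention="plus" returns
    2^(+ddCt) for tables recorded under the opposite sign.
    """
    required = {"group", "role", "ct"}
    if not required <= set(table.columns):
        raise PanelomicsError(f"Ct table needs columns {sorted(required)}")
    dct_treated = _group_mean_ct(table, "treated", "target") - _group_mean_ct(
        table, "treated", "reference"
    )
    dct_control = _group_mean_ct(table, "control", "target") - _group_mean_ct(
        table, "control", "reference"
    )
    ddct = dct_treated - dct_control
    if convention == "livak":
        log2_fold = -ddct
    elif convention == "plus":
        log2_fold = ddct
    else:
        raise PanelomicsError(f"unknown convention {convention!r}")
    return 2.0 ** log2_fold, log2_fold


def _four_pl(c, top, bottom, ic50, hill):
    return bottom + (top - bottom) / (1.0 + (c / ic50) ** hill)


def ic50_from_curve(
    concentrations,
    viability,
    extrapolate: bool = False,
) -> float | Censored:
    """IC50 from a percent-viability dose-response series.

    Fits a monotone-decreasing 4PL (top <= 110, bottom >= -10, on the
    percent-of-control scale) and returns the concentration at 50% of
    the fitted top-bottom span (the 4PL midpoint parameter). If the
    observed viability never reaches the 50% level within the tested
    range the result is censored at the highest tested concentration
    (mirroring "> c_max" reporting) unless ``extrapolate=True``.
    """
    c = np.asarray(concentrations, dtype=float)
    v = np.asarray(viability, dtype=float)
    if c.size < 4:
        raise PanelomicsError("need >= 4 concentrations")
    if np.any(c <= 0) or np.any(np.diff(c) <= 0):
        raise PanelomicsError("concentrations must be positive and increasing")
    if not np.all(np.isfinite(v)):
        raise PanelomicsError("viability values must be finite")

    if v.min() > 50.0 and not extrapolate:
        return Censored(float(c.max()))

    try:
        popt, _ = optimize.curve_fit(
            _four_pl,
            c,
            v,
            p0=[100.0, 0.0, float(np.sqrt(c.min() * c.max())), 1.0],
            bounds=([50.0, -10.0, c.min() / 1e4, 0.05], [110.0, 49.0, c.max() * 1e4, 10.0]),
            maxfev=20000,
        )
    except RuntimeError as exc:
        raise FitError(f"4PL fit did not converge: {exc}") from exc
    top, bottom, ic50, _hill = popt
    midpoint = 0.5 * (top + bottom)
    if ic50 > c.max() and not extrapolate:
        return Censored(float(c.max()))
    if not extrapolate and _four_pl(c.max(), *popt) > midpoint:
        return Censored(float(c.max()))
    return float(ic50)


def degree_of_resistance(
    ic50_resistant: float | Censored, ic50_parental: float
) -> float | Censored:
    """Fold resistance: IC50(resistant line) / IC50(parental line).

    A censored numerator propagates: "> 100 µM" over 13.7 µM gives
    "> 7.3"-style censored folds.
    """
    if isinstance(ic50_parental, Censored):
        raise PanelomicsError("parental IC50 must be a definite value")
    if not ic50_parental > 0:
        raise PanelomicsError("parental IC50 must be > 0")
    if isinstance(ic50_resistant, Censored):
        return Censored(ic50_resistant.bound / ic50_parental)
    if not ic50_resistant > 0:
        raise PanelomicsError("resistant IC50 must be > 0")
    return ic50_resistant / ic50_parental
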