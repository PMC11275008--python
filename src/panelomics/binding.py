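"""Mass-action binding isotherms and K_D estimation from titrations.

Microscale-thermophoresis-type experiments titrate a ligand (serial
dilution, concentrations L descending) against a fixed amount T of
fluorescently labeled target and record a normalized signal per point.
For 1:1 binding the exact (ligand-depletion) law-of-mass-action solution
for the bound fraction of target is the quadratic isotherm

    FB(L) = ((L + T + Kd) - sqrt((L + T + Kd)^2 - 4*L*T)) / (2*T)

and the measured signal is a linear mix of the bound and unbound
fluorescence states. The quadratic form matters whenever T is not
negligible against Kd (here: T = 200 nM labeled target vs. a Kd near
1 µM); the hyperbolic approximation FB = L/(L + Kd) is available as an
option for the deep ligand-excess regime.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .errors import FitError, PanelomicsError

__all__ = [
    "TitrationSeries",
    "KdFit",
    "fraction_bound",
    "fraction_bound_hyperbolic",
    "predict_signal",
    "fit_kd",
]


@dataclass(frozen=True)
class TitrationSeries:
    """One titration: ligand totals (molar, strictly decreasing),
    normalized signals, and the fixed labeled-target concentration."""

    ligand_totals: tuple[float, ...]
    signals: tuple[float, ...]
    target_total: float

    def __post_init__(self):
        lig = np.asarray(self.ligand_totals, dtype=float)
        if lig.size < 6:
            raise PanelomicsError("need >= 6 titration points")
        if len(self.signals) != lig.size:
            raise PanelomicsError("ligand_totals and signals length mismatch")
        if not np.all(lig > 0):
            raise PanelomicsError("ligand totals must be strictly positive")
        if not np.all(np.diff(lig) < 0):
            raise PanelomicsError("ligand totals must be strictly decreasing")
        if not self.target_total > 0:
            raise PanelomicsError("target_total must be > 0")


@dataclass(frozen=True)
class KdFit:
    """Result of a K_D fit: the dissociation constant (molar), the two
    fluorescence plateaus, a curvature-based standard error, and the
    residual norm. `poorly_constrained` is set when the data do not span
    the binding transition at the fitted K_D."""

    kd: float
    signal_unbound: float
    signal_bound: float
    kd_se: float
    residual_norm: float
    poorly_constrained: bool = False


def fraction_bound(ligand_total, target_total: float, kd: float):
    """Exact 1:1 bound fraction of target with ligand depletion.

    Continuous, increasing in L, decreasing in Kd, and always in [0, 1].
    Accepts a scalar or array ligand concentration.
    """
    L = np.asarray(ligand_total, dtype=float)
    if np.any(L < 0):
        raise PanelomicsError("ligand_total must be >= 0")
    if not target_total > 0 or not kd > 0:
        raise PanelomicsError("target_total and kd must be > 0")
    T = target_total
    s = L + T + kd
    disc = np.maximum(s * s - 4.0 * L * T, 0.0)
    fb = (s - np.sqrt(disc)) / (2.0 * T)
    fb = np.clip(fb, 0.0, 1.0)
    return float(fb) if np.isscalar(ligand_total) else fb


def fraction_bound_hyperbolic(ligand_total, target_total: float, kd: float):
    """Hyperbolic (no ligand depletion) approximation FB = L/(L+Kd)."""
    L = np.asarray(ligand_total, dtype=float)
    if np.any(L < 0):
        raise PanelomicsError("ligand_total must be >= 0")
    if not kd > 0:
        raise PanelomicsError("kd must be > 0")
    fb = L / (L + kd)
    return float(fb) if np.isscalar(ligand_total) else fb


def predict_signal(
    ligand_totals,
    target_total: float,
    kd: float,
    signal_unbound: float,
    signal_bound: float,
    model: str = "quadratic",
):
    """Signal as a linear mix of the unbound and bound states:
    s(L) = signal_unbound + (signal_bound - signal_unbound) * FB(L)."""
    fb_fn = {"quadratic": fraction_bound, "hyperbolic": fraction_bound_hyperbolic}
    if model not in fb_fn:
        raise PanelomicsError(f"unknown model {model!r}")
    fb = fb_fn[model](ligand_totals, target_total, kd)
    return signal_unbound + (signal_bound - signal_unbound) * fb


def fit_kd(
    series: TitrationSeries,
    model: str = "quadratic",
    weights=None,
) -> KdFit:
    """Least-squares K_D estimate from a titration series.

    Fits (Kd, signal_unbound, signal_bound) with Kd optimized on the log
    scale; optional per-point `weights` multiply the residuals. The
    plateaus are initialized from the first/last-tertile signal medians
    (the series is concentration-descending, so the first tertile is the
    bound side) and Kd from the mid-signal crossing. `kd_se` comes from
    the local curvature of the fit (delta method on log Kd). The series
    must span at least 2 decades of ligand concentration.
    """
    L = np.asarray(series.ligand_totals, dtype=float)
    s = np.asarray(series.signals, dtype=float)
    if L.max() / L.min() < 100.0:
        raise PanelomicsError("series must span at least 2 decades of concentration")
    w = np.ones_like(s) if weights is None else np.asarray(weights, dtype=float)

    third = max(1, L.size // 3)
    sb0 = float(np.median(s[:third]))
    su0 = float(np.median(s[-third:]))
    mid = 0.5 * (sb0 + su0)
    kd0 = float(L[np.argmin(np.abs(s - mid))])
    kd0 = min(max(kd0, L.min()), L.max())

    def residuals(theta):
        log_kd, su, sb = theta
        pred = predict_signal(L, series.target_total, math.exp(log_kd), su, sb, model)
        return w * (pred - s)

    span = abs(sb0 - su0) or 1.0
    res = optimize.least_squares(
        residuals,
        x0=[math.log(kd0), su0, sb0],
        bounds=(
            [math.log(L.min()) - math.log(1e4), su0 - 10 * span, sb0 - 10 * span],
            [math.log(L.max()) + math.log(1e4), su0 + 10 * span, sb0 + 10 * span],
        ),
        method="trf",
    )
    if not res.success:
        raise FitError("K_D fit did not converge", best=res.x)
    log_kd, su, sb = res.x
    kd = math.exp(log_kd)

    # covariance from local curvature: cov = (J'J)^-1 * s^2
    dof = max(1, L.size - 3)
    sigma2 = 2.0 * res.cost / dof
    try:
        cov = np.linalg.inv(res.jac.T @ res.jac) * sigma2
        kd_se = kd * math.sqrt(max(cov[0, 0], 0.0))
    except np.linalg.LinAlgError:
        kd_se = math.nan

    fb = fraction_bound(L, series.target_total, kd) if model == "quadratic" \
        else fraction_bound_hyperbolic(L, series.target_total, kd)
    poorly = bool(np.all(fb < 0.1) or np.all(fb > 0.9))
    return KdFit(
        kd=kd,
        signal_unbound=float(su),
        signal_bound=float(sb),
        kd_se=float(kd_se),
        residual_norm=float(np.linalg.norm(res.fun)),
        poorly_constrained=poorly,
    )
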