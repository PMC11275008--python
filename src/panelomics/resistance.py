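"""Drug-resistance marker profiling.

Correlates a compound's log10(IC50) panel fingerprint against
measurements of classical resistance markers (ABC transporter
expression, TP53 status, EGFR expression, ...) and flags associations
passing the screening rule p < alpha and |r| > r_min. Both signs flag:
a positive r means the marker tracks resistance, a negative r collateral
sensitivity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .docking import pearson
from .errors import InsufficientDataError, PanelomicsError, UndefinedCorrelationError
from .oncobiogram import ActivityProfile

__all__ = ["MarkerAssay", "resistance_table"]


@dataclass(frozen=True)
class MarkerAssay:
    """One resistance-marker measurement across cell lines.

    `assay_label` records the platform (microarray, RT-PCR, protein
    array, ...); `control_drug` is carried as annotation only — the
    corresponding control correlations are external data and are never
    recomputed here.
    """

    marker_id: str
    assay_label: str
    values: Mapping[str, float]
    control_drug: str | None = field(default=None)

    def __post_init__(self):
        n = sum(
            1 for v in self.values.values()
            if v is not None and not (isinstance(v, float) and math.isnan(v))
        )
        if n < 3:
            raise InsufficientDataError(
                f"{self.marker_id} ({self.assay_label}): fewer than 3 values"
            )


def resistance_table(
    profile: ActivityProfile,
    markers: Sequence[MarkerAssay],
    r_min: float = 0.30,
    alpha: float = 0.05,
    min_overlap: int = 3,
) -> pd.DataFrame:
    """Marker-by-marker correlation report with significance flags.

    Returns a DataFrame with columns (marker, assay, control_drug, n, r,
    p, flagged). ``flagged`` is True iff p < alpha and |r| > r_min, both
    strict, so a boundary value r = r_min exactly is not flagged.
    Markers with insufficient overlap get NaN r/p and flagged=False.
    """
    if not markers:
        raise PanelomicsError("empty marker list")
    rows = []
    for marker in markers:
        lines = [
            c for c, v in marker.values.items()
            if c in profile.values
            and v is not None and not (isinstance(v, float) and math.isnan(v))
        ]
        x = profile.vector(lines)
        y = np.array([marker.values[c] for c in lines], dtype=float)
        keep = np.isfinite(x)
        r = p = math.nan
        n = int(keep.sum())
        if n >= min_overlap:
            try:
                res = pearson(x[keep], y[keep])
                r, p, n = res.r, res.p, res.n
            except UndefinedCorrelationError:
                pass
        flagged = bool(p < alpha and abs(r) > r_min) if math.isfinite(p) else False
        rows.append(
            {
                "marker": marker.marker_id,
                "assay": marker.assay_label,
                "control_drug": marker.control_drug,
                "n": n,
                "r": r,
                "p": p,
                "flagged": flagged,
            }
        )
    return pd.DataFrame(rows)
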