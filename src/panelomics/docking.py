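"""Post-processing of docking score tables.

AutoDock-style runs report, per ligand, a lowest binding energy (LBE,
kcal/mol; more negative = stronger predicted binding) and a predicted
inhibition constant Ki. The two are linked by the thermodynamic relation

    Ki = exp(dG / (R * T))

with Ki in molar, dG in kcal/mol, and R the gas constant in
kcal/(mol*K). This module interconverts the two quantities and runs the
standard quality-control check on a score table: the Pearson correlation
of LBE against predicted Ki across ligands, which should be strongly
positive because Ki is a monotone transform of dG.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import UndefinedCorrelationError, UnitError

__all__ = [
    "GAS_CONSTANT_KCAL",
    "STANDARD_TEMPERATURE",
    "DockedCompound",
    "CorrelationResult",
    "ki_from_energy",
    "energy_from_ki",
    "pearson",
    "correlate_lbe_pki",
    "load_nfkb_docking_table",
    "load_tubulin_docking_table",
]

#: Gas constant in kcal mol^-1 K^-1 (AutoDock convention).
GAS_CONSTANT_KCAL = 1.98719e-3

#: Default absolute temperature for Ki <-> dG conversion (25 C).
STANDARD_TEMPERATURE = 298.15

#: Molar scale factor per accepted concentration unit tag.
UNIT_SCALE = {"M": 1.0, "mM": 1e-3, "uM": 1e-6, "µM": 1e-6, "nM": 1e-9}

# Residue labels are letters+digits, optionally "chain:" prefixed
# (e.g. "GLU222", "α:LEU248"); chains may be Greek letters.
_RESIDUE_RE = re.compile(r"^(?:[^\W\d_]+\s*:\s*)?[^\W\d_]+\d+$", re.UNICODE)


@dataclass(frozen=True)
class CorrelationResult:
    """Pearson product-moment correlation with its two-sided p-value.

    p is computed from t = r*sqrt(n-2)/sqrt(1-r^2) on n-2 degrees of
    freedom; |r| = 1 yields p = 0 within floating tolerance.
    """

    r: float
    p: float
    n: int


@dataclass(frozen=True)
class DockedCompound:
    """One row of a docking score table.

    Parameters
    ----------
    name : ligand identifier.
    lbe_mean, lbe_sd : lowest binding energy in kcal/mol (mean over
        independent dockings, SD >= 0); negative for favorable binding.
    pki_mean, pki_sd : predicted inhibition constant in `pki_unit`.
    pki_unit : one of {"M", "mM", "uM"/"µM", "nM"}.
    site_label : binding pocket / grid-box annotation (opaque).
    pharmacophore : residue identifiers involved in binding, e.g.
        "GLU222" or "α:LEU248"; treated as opaque labels.
    """

    name: str
    lbe_mean: float
    lbe_sd: float
    pki_mean: float
    pki_sd: float
    pki_unit: str = "uM"
    site_label: str = ""
    pharmacophore: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self):
        if self.pki_unit not in UNIT_SCALE:
            raise UnitError(
                f"{self.name}: unknown concentration unit {self.pki_unit!r}"
            )
        if not (self.pki_mean > 0):
            raise ValueError(f"{self.name}: pki_mean must be > 0")
        if self.lbe_sd < 0 or self.pki_sd < 0:
            raise ValueError(f"{self.name}: SD must be >= 0")
        for res in self.pharmacophore:
            if not _RESIDUE_RE.match(res):
                raise ValueError(
                    f"{self.name}: malformed residue identifier {res!r}"
                )

    @property
    def pki_molar(self) -> float:
        """Predicted inhibition constant converted to molar."""
        return self.pki_mean * UNIT_SCALE[self.pki_unit]


def ki_from_energy(delta_g: float, temperature: float = STANDARD_TEMPERATURE) -> float:
    """Predicted inhibition constant (molar) from binding free energy.

    Ki = exp(dG / (R*T)); strictly increasing in dG, so more negative
    energies give smaller (tighter) constants.
    """
    if not math.isfinite(delta_g):
        raise ValueError("delta_g must be finite")
    if not temperature > 0:
        raise ValueError("temperature must be > 0")
    return math.exp(delta_g / (GAS_CONSTANT_KCAL * temperature))


def energy_from_ki(ki: float, temperature: float = STANDARD_TEMPERATURE) -> float:
    """Binding free energy (kcal/mol) from an inhibition constant (molar)."""
    if not ki > 0:
        raise ValueError("ki must be > 0")
    if not temperature > 0:
        raise ValueError("temperature must be > 0")
    return GAS_CONSTANT_KCAL * temperature * math.log(ki)


def pearson(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Pearson correlation with pairwise-complete deletion.

    Pairs where either value is missing (NaN/None) are dropped. Requires
    at least 3 complete pairs and nonzero variance on both sides;
    otherwise raises :class:`UndefinedCorrelationError`.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have the same length")
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    n = x.size
    if n < 3:
        raise UndefinedCorrelationError(f"need >= 3 complete pairs, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError("zero variance in one of the vectors")
    r, p = stats.pearsonr(x, y)
    return CorrelationResult(r=float(r), p=float(p), n=int(n))


def correlate_lbe_pki(
    compounds: Sequence[DockedCompound], convert: bool = True
) -> CorrelationResult:
    """QC correlation of LBE means against predicted-Ki means.

    With ``convert=True`` (default) all Ki values are converted to molar
    before correlating, so tables with mixed unit tags are handled.
    With ``convert=False`` the printed values are used as-is, which is
    only allowed when every row carries the same unit tag (Pearson r is
    scale-invariant, so for single-unit tables both paths agree).
    """
    compounds = list(compounds)
    if convert:
        ki = [c.pki_molar for c in compounds]
    else:
        units = {c.pki_unit for c in compounds}
        if len(units) > 1:
            raise UnitError(f"mixed pKi units without conversion: {sorted(units)}")
        ki = [c.pki_mean for c in compounds]
    return pearson([c.lbe_mean for c in compounds], ki)


def _load_packaged_table(filename: str) -> list[DockedCompound]:
    from .io import read_docking_table  # local import to avoid a cycle

    with resources.as_file(
        resources.files("panelomics.data").joinpath(filename)
    ) as path:
        return read_docking_table(path)


def load_nfkb_docking_table() -> list[DockedCompound]:
    """The packaged 28-compound NF-κB p65-RelA docking table (pKi in µM)."""
    return _load_packaged_table("nfkb_docking.tsv")


def load_tubulin_docking_table() -> list[DockedCompound]:
    """The packaged 9-row tubulin docking table (pKi in mM)."""
    return _load_packaged_table("tubulin_docking.tsv")
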