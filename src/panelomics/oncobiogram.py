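"""COMPARE-style mode-of-action inference on a tumor cell-line panel.

A compound's cytotoxicity fingerprint — its vector of log10(IC50) values
over a panel of cell lines (the NCI-60 layout: nine tissue types, 60
lines) — is correlated against a library of reference agents with known
mechanisms. Agents acting through the compound's mechanism tend to show
similar fingerprints, so high positive Pearson r against a mechanism
class is evidence for a shared mode of action. The per-class summary
("which class correlates most often?") and the per-reference-agent
r-vector (the oncobiogram) are the two outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .docking import CorrelationResult, pearson
from .errors import InsufficientDataError, PanelomicsError, UndefinedCorrelationError

__all__ = [
    "NCI_TISSUES",
    "PanelDefinition",
    "ActivityProfile",
    "AgentLibrary",
    "MoaSummary",
    "compare_rank",
    "moa_enrichment",
    "oncobiogram_vector",
    "tissue_mean_ic50",
]

#: The nine tissue-of-origin classes of the NCI tumor cell-line panel.
NCI_TISSUES = (
    "leukemia", "melanoma", "brain", "colon", "ovary",
    "breast", "kidney", "lung", "prostate",
)


@dataclass(frozen=True)
class PanelDefinition:
    """Ordered cell-line identifiers with their tissue-of-origin labels."""

    cell_line_ids: tuple[str, ...]
    tissue_labels: Mapping[str, str]

    def __post_init__(self):
        if len(set(self.cell_line_ids)) != len(self.cell_line_ids):
            raise PanelomicsError("duplicate cell line ids in panel")
        missing = [c for c in self.cell_line_ids if c not in self.tissue_labels]
        if missing:
            raise PanelomicsError(f"cell line(s) without tissue label: {missing}")


@dataclass(frozen=True)
class ActivityProfile:
    """Per-compound log10(IC50) (molar) over named cell lines.

    Missing entries are allowed (absent keys or NaN values); at least 3
    non-missing values are required.
    """

    compound_id: str
    values: Mapping[str, float]

    def __post_init__(self):
        if sum(1 for v in self.values.values() if _present(v)) < 3:
            raise InsufficientDataError(
                f"{self.compound_id}: fewer than 3 non-missing values"
            )

    def vector(self, cell_lines: Sequence[str]) -> np.ndarray:
        """Values aligned to `cell_lines`, NaN where missing."""
        return np.array(
            [self.values.get(c, math.nan) for c in cell_lines], dtype=float
        )

    def overlap(self, other: "ActivityProfile") -> list[str]:
        return [
            c for c, v in self.values.items()
            if _present(v) and _present(other.values.get(c, math.nan))
        ]


def _present(v) -> bool:
    return v is not None and not (isinstance(v, float) and math.isnan(v))


@dataclass(frozen=True)
class AgentLibrary:
    """Reference agents with annotated mode-of-action classes."""

    agents: tuple[tuple[ActivityProfile, str], ...]

    def __post_init__(self):
        if any(not cls for _, cls in self.agents):
            raise PanelomicsError("empty moa_class label in library")

    @property
    def classes(self) -> list[str]:
        return sorted({cls for _, cls in self.agents})

    def class_of(self) -> dict[str, str]:
        return {prof.compound_id: cls for prof, cls in self.agents}


@dataclass(frozen=True)
class MoaSummary:
    """Per-mechanism-class summary of a COMPARE ranking.

    per_class maps class -> (n_significant, n_agents, mean_r);
    ranked_classes is ordered by n_significant descending, ties broken
    alphabetically.
    """

    per_class: Mapping[str, tuple[int, int, float]]
    ranked_classes: tuple[str, ...] = field(default=())


def compare_rank(
    profile: ActivityProfile,
    library: AgentLibrary,
    min_overlap: int = 3,
) -> tuple[list[tuple[str, CorrelationResult]], dict[str, str]]:
    """Correlate a profile against every library agent and rank by r.

    Returns ``(ranked, skipped)``: `ranked` has one
    ``(agent_id, CorrelationResult)`` entry per agent with at least
    `min_overlap` jointly observed cell lines, sorted by r descending
    (ties by agent id); `skipped` maps excluded agent ids to a reason.
    """
    if not library.agents:
        raise PanelomicsError("empty agent library")
    ranked: list[tuple[str, CorrelationResult]] = []
    skipped: dict[str, str] = {}
    for agent, _cls in library.agents:
        lines = profile.overlap(agent)
        if len(lines) < min_overlap:
            skipped[agent.compound_id] = (
                f"only {len(lines)} overlapping cell lines (< {min_overlap})"
            )
            continue
        try:
            res = pearson(profile.vector(lines), agent.vector(lines))
        except UndefinedCorrelationError as exc:
            skipped[agent.compound_id] = str(exc)
            continue
        ranked.append((agent.compound_id, res))
    ranked.sort(key=lambda item: (-item[1].r, item[0]))
    return ranked, skipped


def moa_enrichment(
    ranked: Sequence[tuple[str, CorrelationResult]],
    library: AgentLibrary,
    r_min: float = 0.30,
    alpha: float = 0.05,
) -> MoaSummary:
    """Summarize a COMPARE ranking by mechanism class.

    An agent counts as a significant class hit iff r >= r_min and
    p <= alpha; only positive correlations count (mechanism similarity
    is inferred from positive profile similarity — negative r is
    reported in the ranking but never counted). Classes are ranked by
    the number of significant agents, ties broken alphabetically.
    """
    if not (0 <= alpha <= 1):
        raise PanelomicsError("alpha must be in [0, 1]")
    if not (-1 <= r_min <= 1):
        raise PanelomicsError("r_min must be in [-1, 1]")
    class_of = library.class_of()
    per_class: dict[str, list] = {cls: [0, 0, []] for cls in library.classes}
    for agent_id, res in ranked:
        cls = class_of[agent_id]
        per_class[cls][1] += 1
        per_class[cls][2].append(res.r)
        if res.r >= r_min and res.p <= alpha:
            per_class[cls][0] += 1
    summary = {
        cls: (nsig, nag, float(np.mean(rs)) if rs else math.nan)
        for cls, (nsig, nag, rs) in per_class.items()
    }
    order = tuple(sorted(summary, key=lambda c: (-summary[c][0], c)))
    return MoaSummary(per_class=summary, ranked_classes=order)


def oncobiogram_vector(
    profile: ActivityProfile,
    reference_agents: Sequence[ActivityProfile],
    min_overlap: int = 3,
) -> dict[str, float | None]:
    """Correlation coefficients of a profile to each reference agent.

    Agents with insufficient overlap or an undefined correlation
    (constant profile) map to ``None``.
    """
    if not reference_agents:
        raise PanelomicsError("empty reference agent list")
    out: dict[str, float | None] = {}
    for agent in reference_agents:
        lines = profile.overlap(agent)
        if len(lines) < min_overlap:
            out[agent.compound_id] = None
            continue
        try:
            out[agent.compound_id] = pearson(
                profile.vector(lines), agent.vector(lines)
            ).r
        except UndefinedCorrelationError:
            out[agent.compound_id] = None
    return out


def tissue_mean_ic50(
    profile: ActivityProfile, panel: PanelDefinition
) -> dict[str, float]:
    """Arithmetic mean log10(IC50) per tissue of origin.

    Tissues with no observed value are omitted. A profile entry for a
    cell line absent from the panel raises, naming the id.
    """
    sums: dict[str, list[float]] = {}
    for line, value in profile.values.items():
        if not _present(value):
            continue
        if line not in panel.tissue_labels:
            raise PanelomicsError(f"unknown cell line id {line!r}")
        sums.setdefault(panel.tissue_labels[line], []).append(value)
    return {tissue: float(np.mean(v)) for tissue, v in sorted(sums.items())}
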