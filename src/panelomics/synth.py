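"""Synthetic inputs with the statistical structure the pipeline assumes.

The study's raw screens (panel IC50 profiles, the proteome matrix,
titration traces, patient cohorts, Ct tables) are external databases and
instruments, so every stage is exercised on generated data that plants
the structure the analysis is supposed to find: mechanism classes as
single latent factors with a stated within-class correlation, proteome
features tilted toward the activity fingerprint at a stated population
r, quadratic-binding titrations with multiplicative signal noise,
exponential survival with an arm-specific hazard ratio, and Ct tables
with a known log2 fold. All generators are deterministic given a seed.

Single-factor construction: with z-scored latent factor f and noise e,
a profile sqrt(rho)*f + sqrt(1-rho)*e has population correlation rho
with any other profile built on the same factor, and a planted feature
alpha*z(x) + sqrt(1-alpha^2)*e has population correlation alpha with
the fingerprint x.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .binding import TitrationSeries, predict_signal
from .errors import PanelomicsError
from .oncobiogram import ActivityProfile, AgentLibrary, PanelDefinition

__all__ = [
    "DEFAULT_TISSUE_SPEC",
    "DEFAULT_MOA_CLASSES",
    "GeneratorConfig",
    "gen_panel",
    "gen_activity",
    "gen_proteome",
    "gen_titration",
    "gen_survival",
    "gen_survival_cohorts",
    "gen_ct",
]

#: Cell lines per tissue in the NCI-60 layout (sums to 60).
DEFAULT_TISSUE_SPEC: dict[str, int] = {
    "leukemia": 6, "melanoma": 9, "brain": 6, "colon": 7, "ovary": 7,
    "breast": 6, "kidney": 8, "lung": 9, "prostate": 2,
}

_TISSUE_PREFIX = {
    "leukemia": "LE", "melanoma": "ME", "brain": "CNS", "colon": "CO",
    "ovary": "OV", "breast": "BRE", "kidney": "RE", "lung": "LC",
    "prostate": "PR",
}

#: Ten mechanism classes; "microtubule" carries 10 agents and the other
#: nine carry 9 each, totalling the 91-agent reference library layout.
DEFAULT_MOA_CLASSES: dict[str, int] = {
    "alkylating": 9, "antimetabolite": 9, "topoisomerase1": 9,
    "topoisomerase2": 9, "microtubule": 10, "mtor": 9, "kinase": 9,
    "platinum": 9, "antibiotic": 9, "hormonal": 9,
}


@dataclass(frozen=True)
class GeneratorConfig:
    """All generator knobs in one place; identical config + seed gives
    bit-identical output.

    Defaults state the emulated world: a 60-line panel over the nine
    NCI tissues, a 91-agent library in 10 mechanism classes with
    within-class correlation 0.8, a reduced 500-protein matrix with
    20+20 planted correlates at |r| = 0.6, 14-point 1:1 titrations from
    300 µM against 200 nM labeled target at 2% multiplicative noise,
    exponential survival with hazard ratio 2 and 20% censoring, and Ct
    tables with sigma = 0.1 cycle replicate noise.
    """

    seed: int = 0
    n_cell_lines: int = 60
    tissue_spec: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_TISSUE_SPEC)
    )
    # activity / agent library
    moa_classes: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_MOA_CLASSES)
    )
    compound_class: str = "microtubule"
    rho: float = 0.8
    ic50_mean: float = -5.0
    ic50_sd: float = 0.5
    tissue_shifts: Mapping[str, float] = field(default_factory=dict)
    # proteome
    n_proteins: int = 500
    n_planted_direct: int = 20
    n_planted_inverse: int = 20
    planted_r: float = 0.6
    # titration
    kd: float = 943e-9
    target_total: float = 200e-9
    titration_top: float = 300e-6
    titration_points: int = 14
    titration_noise: float = 0.02
    signal_unbound: float = 0.0
    signal_bound: float = 1.0
    # survival
    n_per_arm: int = 200
    hazard_ratio: float = 2.0
    censoring_fraction: float = 0.2
    baseline_median_months: float = 24.0
    n_cohorts: int = 21
    # qPCR
    true_log2_fold: float = -1.11
    ct_sigma: float = 0.1
    ct_replicates: int = 3

    def rng(self, stream: int = 0) -> np.random.Generator:
        """Independent generator per (seed, stream). Each gen_* function
        uses its own stream constant so that, e.g., the noise draws of
        the proteome generator never collide with the latent factors of
        the activity generator under the same seed."""
        return np.random.default_rng([stream, self.seed])


def gen_panel(config: GeneratorConfig) -> PanelDefinition:
    """Deterministic panel ids with tissue labels (no randomness)."""
    if sum(config.tissue_spec.values()) != config.n_cell_lines:
        raise PanelomicsError(
            f"tissue counts sum to {sum(config.tissue_spec.values())}, "
            f"expected n_cell_lines={config.n_cell_lines}"
        )
    ids, labels = [], {}
    for tissue, count in config.tissue_spec.items():
        prefix = _TISSUE_PREFIX.get(tissue, tissue[:3].upper())
        for i in range(1, count + 1):
            cid = f"{prefix}_{i:02d}"
            ids.append(cid)
            labels[cid] = tissue
    return PanelDefinition(cell_line_ids=tuple(ids), tissue_labels=labels)


def _factor_profile(rng, factor, rho, mean, sd):
    noise = rng.standard_normal(factor.size)
    z = np.sqrt(rho) * factor + np.sqrt(1.0 - rho) * noise
    return mean + sd * z


def gen_activity(
    config: GeneratorConfig, panel: PanelDefinition
) -> tuple[ActivityProfile, AgentLibrary, str]:
    """Compound profile + annotated agent library with planted structure.

    Each mechanism class gets one latent factor over the panel; agents
    of the class load on it with within-class correlation rho. The test
    compound loads on `compound_class`'s factor at the same rho, which
    is returned as the ground-truth class. `tissue_shifts` (tissue ->
    additive log10 IC50 offset) apply to the compound profile only, so
    library agents stay exchangeable under the null.
    """
    if not (0 < config.rho < 1):
        raise PanelomicsError("rho must be in (0, 1)")
    if config.compound_class not in config.moa_classes:
        raise PanelomicsError(f"unknown compound_class {config.compound_class!r}")
    rng = config.rng(stream=1)
    lines = list(panel.cell_line_ids)
    n = len(lines)
    factors = {
        cls: rng.standard_normal(n) for cls in config.moa_classes
    }
    agents = []
    for cls, count in config.moa_classes.items():
        for i in range(1, count + 1):
            vals = _factor_profile(
                rng, factors[cls], config.rho, config.ic50_mean, config.ic50_sd
            )
            prof = ActivityProfile(
                compound_id=f"{cls}_{i:02d}", values=dict(zip(lines, vals))
            )
            agents.append((prof, cls))
    vals = _factor_profile(
        rng, factors[config.compound_class], config.rho,
        config.ic50_mean, config.ic50_sd,
    )
    shift = np.array(
        [config.tissue_shifts.get(panel.tissue_labels[c], 0.0) for c in lines]
    )
    compound = ActivityProfile(
        compound_id="compound", values=dict(zip(lines, vals + shift))
    )
    return compound, AgentLibrary(agents=tuple(agents)), config.compound_class


def gen_proteome(
    config: GeneratorConfig, profile: ActivityProfile
) -> tuple[pd.DataFrame, list[str], list[str]]:
    """Protein x cell-line matrix with planted direct/inverse correlates.

    Planted features are alpha*z(x) +/- sqrt(1-alpha^2)*noise with
    alpha = `planted_r`, so their population correlation with the
    fingerprint x equals +/-planted_r; the remaining features are
    independent standard normals. Returns (matrix, direct_ids,
    inverse_ids) exactly as generated.
    """
    k = config.n_planted_direct + config.n_planted_inverse
    if k > config.n_proteins:
        raise PanelomicsError("more planted features than proteins")
    if not (0 < config.planted_r < 1):
        raise PanelomicsError("planted_r must be in (0, 1)")
    rng = config.rng(stream=2)
    lines = [c for c in profile.values]
    x = profile.vector(lines)
    z = (x - x.mean()) / x.std()
    alpha = config.planted_r
    rows, direct, inverse = [], [], []
    for j in range(config.n_proteins):
        name = f"P{j:04d}"
        if j < config.n_planted_direct:
            row = alpha * z + np.sqrt(1 - alpha**2) * rng.standard_normal(z.size)
            direct.append(name)
        elif j < k:
            row = -alpha * z + np.sqrt(1 - alpha**2) * rng.standard_normal(z.size)
            inverse.append(name)
        else:
            row = rng.standard_normal(z.size)
        rows.append(row)
    matrix = pd.DataFrame(
        np.vstack(rows),
        index=[f"P{j:04d}" for j in range(config.n_proteins)],
        columns=lines,
    )
    return matrix, direct, inverse


def gen_titration(config: GeneratorConfig) -> tuple[TitrationSeries, float]:
    """Quadratic-binding titration with multiplicative Gaussian noise.

    1:1 serial dilution (`titration_points` points from `titration_top`,
    300 µM -> ~36.6 nM at 14 points) against the fixed labeled-target
    concentration. Returns (series, true_kd).
    """
    rng = config.rng(stream=3)
    lig = config.titration_top / (2.0 ** np.arange(config.titration_points))
    clean = predict_signal(
        lig, config.target_total, config.kd,
        config.signal_unbound, config.signal_bound,
    )
    noisy = clean * (1.0 + config.titration_noise * rng.standard_normal(lig.size))
    series = TitrationSeries(
        ligand_totals=tuple(lig),
        signals=tuple(noisy),
        target_total=config.target_total,
    )
    return series, config.kd


def gen_survival(
    config: GeneratorConfig, rng: np.random.Generator | None = None,
    hazard_ratio: float | None = None,
) -> pd.DataFrame:
    """One cohort: exponential survival with expression-linked hazard.

    The low-expression arm has the baseline hazard (median survival
    `baseline_median_months`); the high-expression arm's hazard is
    multiplied by `hazard_ratio` (HR > 1 => high expressors die
    earlier). Censoring is independent uniform on (0, b) with b solved
    so the expected censored fraction matches `censoring_fraction`.
    Expression is drawn well-separated between arms so that a median
    split recovers them.
    """
    hr = config.hazard_ratio if hazard_ratio is None else hazard_ratio
    if not hr > 0:
        raise PanelomicsError("hazard ratio must be > 0")
    if not (0 <= config.censoring_fraction < 1):
        raise PanelomicsError("censoring fraction must be in [0, 1)")
    rng = config.rng(stream=4) if rng is None else rng
    n = config.n_per_arm
    base_rate = np.log(2.0) / config.baseline_median_months
    rates = np.concatenate([np.full(n, base_rate), np.full(n, base_rate * hr)])
    expression = np.concatenate(
        [rng.normal(0.0, 0.25, n), rng.normal(2.0, 0.25, n)]
    )
    times = rng.exponential(1.0 / rates)
    events = np.ones(2 * n, dtype=int)
    if config.censoring_fraction > 0:
        b = _uniform_censoring_bound(rates.mean(), config.censoring_fraction)
        ctimes = rng.uniform(0.0, b, 2 * n)
        censored = ctimes < times
        times = np.where(censored, ctimes, times)
        events = (~censored).astype(int)
    return pd.DataFrame(
        {
            "subject_id": [f"S{i:04d}" for i in range(2 * n)],
            "time": times,
            "event": events,
            "expression": expression,
        }
    )


def _uniform_censoring_bound(rate: float, fraction: float) -> float:
    """Solve (1 - exp(-r b)) / (r b) = fraction for b (C ~ U(0, b))."""
    from scipy.optimize import brentq

    f = lambda b: (1.0 - np.exp(-rate * b)) / (rate * b) - fraction
    return brentq(f, 1e-9 / rate, 1e6 / rate)


def gen_survival_cohorts(
    config: GeneratorConfig, hazard_ratios: Sequence[float] | None = None
) -> list[tuple[str, pd.DataFrame]]:
    """`n_cohorts` cohorts (default 21, the tumor-type layout).

    `hazard_ratios` gives one HR per cohort; None applies the config HR
    to the first cohort and HR = 1 (null) to the rest.
    """
    rng = config.rng(stream=4)
    if hazard_ratios is None:
        hazard_ratios = [config.hazard_ratio] + [1.0] * (config.n_cohorts - 1)
    if len(hazard_ratios) != config.n_cohorts:
        raise PanelomicsError("need one hazard ratio per cohort")
    return [
        (f"cohort_{i:02d}", gen_survival(config, rng=rng, hazard_ratio=hr))
        for i, hr in enumerate(hazard_ratios, start=1)
    ]


def gen_ct(config: GeneratorConfig) -> tuple[pd.DataFrame, float]:
    """Ct table with a known treated-vs-control log2 fold for the target.

    Reference gene Ct sits at a fixed baseline; the target gene sits at
    baseline + offset in controls and shifts by -true_log2_fold cycles
    under treatment (one extra cycle = half the expression). Gaussian
    replicate noise with `ct_sigma` cycles. Returns (table, true fold).
    """
    if config.ct_sigma < 0:
        raise PanelomicsError("ct_sigma must be >= 0")
    rng = config.rng(stream=5)
    base_ref, offset = 18.0, 5.0
    rows = []
    for group in ("control", "treated"):
        target_mu = base_ref + offset
        if group == "treated":
            # downregulation (negative log2 fold) raises the treated Ct
            target_mu -= config.true_log2_fold
        for rep in range(1, config.ct_replicates + 1):
            rows.append(
                {"group": group, "role": "reference", "replicate": rep,
                 "ct": base_ref + config.ct_sigma * rng.standard_normal()}
            )
            rows.append(
                {"group": group, "role": "target", "replicate": rep,
                 "ct": target_mu + config.ct_sigma * rng.standard_normal()}
            )
    return pd.DataFrame(rows), config.true_log2_fold
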