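# Methods

This note records the models behind each `panelomics` stage, the
defaults and why, what the synthetic generators do and do not emulate,
and the numerical choices that are not obvious from the API.

## Docking-score thermodynamics

Score tables report a lowest binding energy ΔG (kcal/mol, mean ± SD
over independent docking runs) and a predicted inhibition constant.
The two are linked by `Ki = exp(ΔG/(R·T))` with
R = 1.98719×10⁻³ kcal·mol⁻¹·K⁻¹ (the docking-engine convention) and
T defaulting to 298.15 K; temperature is a parameter, never hard-coded.
The QC correlation (`correlate_lbe_pki`) uses per-ligand **means** —
replicate-level values are not available in score tables — and converts
all constants to molar first (Pearson r is scale-invariant, so this
only matters for mixed-unit tables, which otherwise raise).

A caveat that matters for validation: printed tables quantize ΔG to
0.01 kcal/mol, which propagates to ≈0.85% in Ki at 298 K. Constants
printed with more resolution than that (e.g. 2.72 µM) therefore cannot
be reproduced to their last digit from the printed energy; the packaged
tables reproduce 27/28 NF-κB-table constants within 2% relative, and
exactly at printed rounding only where the print is coarse enough.

## Pearson correlation

All correlation screens share one routine: pairwise-complete deletion,
n ≥ 3 and nonzero variance required (violations raise a dedicated
error rather than returning NaN), two-sided p from the t-transform on
n − 2 df. Two-sided is the conservative default since screening
contexts rarely justify a one-sided alternative.

## COMPARE / oncobiogram

`compare_rank` correlates the compound fingerprint against every
library agent over their jointly observed cell lines (minimum overlap
3, configurable); agents below the overlap floor are reported with a
reason, not dropped silently. Ranking is by r descending with
lexicographic agent-id tie-breaks for determinism.
`moa_enrichment` counts an agent as a class hit iff **r ≥ 0.30 and
p ≤ 0.05** — the only stated threshold convention in this literature —
and only positive correlations count, because mechanism similarity is
inferred from positive profile similarity; negative r is reported in
the ranking but never counted. Under the null this one-sided rule
fires for ≈2.5% of agents at n = 60 (half the two-sided rate), which
the test suite checks by simulation.

## Proteome response correlates

`select_top` keeps the k_direct most positive and k_inverse most
negative protein–response correlations (defaults 20 + 20), ties broken
by feature id so the selection is order-invariant. Clustering is
agglomerative Ward (Lance–Williams, via scipy) on **per-feature
z-scores** — features with different dynamic ranges become
commensurate, the standard choice for expression heat maps; a
`zscore=False` switch preserves raw-value clustering. Occasional
missing entries are mean-imputed per feature before distances;
all-missing items raise. Merge heights are the usual agglomerative
scale √(2·ΔESS), which the tests pin against an exhaustive
variance-recomputation oracle. Default cut depths are 3 protein
clusters and 2 cell-line clusters, both configurable; which axis gets
letters vs. numbers in a display is the caller's choice — nothing is
hard-coded, because conventions differ between publications.

**Quartile coding.** The heat-map legend has five categories: four
quartile colors plus "median value". On continuous data the only
consistent reading is: values exactly equal to the median code as
MEDIAN; the remaining values are binned by the quartiles **of the
non-median values**, half-open and lower-inclusive. Computing the
boundaries after removing the median keeps the four bins balanced
(counts differ by ≤ 1 on distinct-valued vectors of length 4k+1),
which boundaries computed on the full vector do not.

**Response calls and χ².** A line is sensitive iff its log₁₀IC₅₀ is
strictly below the panel median, resistant iff strictly above; exact
equality is a tie, which the χ² stage excludes (the rule is built from
strict inequalities, so equality is genuinely undefined). The K×2
contingency is tested with plain Pearson χ², no Yates correction,
df = K−1; empty margins raise with a suggestion to merge clusters
rather than producing a 0/0.

## Resistance-marker report

Same correlation machinery; the flagging rule here is **strict**
(p < 0.05 and |r| > 0.30, so r = 0.30 exactly is not flagged) and
symmetric in sign: positive r flags a resistance marker, negative r
collateral sensitivity. At n = 60 under independence the |r| > 0.30
condition dominates and ≈2% of null markers flag. The `control_drug`
field is annotation only — control-agent correlations come from
external screens and are never recomputed.

## Binding isotherm and K_D fit

The quadratic (ligand-depletion) 1:1 solution is the default because
the labeled-target concentration in the motivating assay (200 nM) is
not negligible against a K_D near 1 µM; the hyperbolic `L/(L+K_D)`
form is available for the deep-excess regime. `fit_kd` optimizes
(log K_D, unbound plateau, bound plateau) by least squares
(trust-region reflective, box bounds four decades beyond the titration
range). Initialization: plateaus from the first/last-tertile signal
medians (the series is concentration-descending), K_D from the
mid-signal crossing — robust and assay-agnostic. `kd_se` is the
delta-method standard error from the fit's local curvature; it
reflects the curvature of *this* series, not a replicate spread.
Residuals are unweighted by default (`weights` accepts per-point
multipliers); with ≈2% multiplicative noise and a normalized signal
the heteroscedasticity across one titration is mild. A fit whose
bound-fraction never leaves [0.1, 0.9] is flagged `poorly_constrained`
instead of failing. A series must span ≥ 2 decades.

## ΔΔCt and dose–response

`ddct_fold` implements the Livak convention:
ΔCt = Ct(target) − Ct(reference) per group,
ΔΔCt = ΔCt(treated) − ΔCt(control), fold = 2^(−ΔΔCt). The −ΔΔCt sign
is the one under which downregulation yields negative log₂ folds; a
`convention="plus"` switch handles tables recorded the other way. No
amplification-efficiency correction is applied. IC₅₀ comes from a
monotone-decreasing 4PL with top ∈ [50, 110] and bottom ∈ [−10, 49]
(percent-of-control scale); a curve whose observed viability never
reaches the 50% level inside the tested range returns a **censored**
value tagged with the top dose, and censoring propagates through
`degree_of_resistance` so a "> 100 µM" numerator yields a "> 7.3"
fold, never a bare number.

## Survival screening

Product-limit estimation and per-arm median survival use lifelines;
the log-rank statistic is computed directly (vectorized over distinct
event times, ties pooled with the hypergeometric variance) and is
cross-checked against lifelines in the tests — the direct form keeps
2000-replicate calibration suites fast. Dichotomization defaults to
the median split; `method="scan"` emulates auto-cutoff selection by
minimizing the log-rank p over the 25th–75th expression percentiles,
recording the chosen quantile (the scanned p is optimistically biased
and should be reported together with the scan). Direction is decided
by per-arm median survival, falling back to the restricted mean over
observed follow-up when a median is never reached. Across cohorts,
Benjamini–Hochberg q-values gate at 5% FDR.

## Synthetic generators

Defaults state the emulated world: a 60-line panel over the nine
standard tissues (6 leukemia, 9 melanoma, 6 brain, 7 colon, 7 ovary,
6 breast, 8 kidney, 9 lung, 2 prostate); a 91-agent library in ten
mechanism classes (microtubule carries 10 agents, the rest 9) with
within-class correlation ρ = 0.8 realized by single latent factors —
`√ρ·factor + √(1−ρ)·noise` gives exactly the stated population
correlation and is analytically checkable; a 500-protein matrix
(reduced from the thousands of a real proteome screen to keep the
suite fast; size configurable) with 20 + 20 planted correlates at
population |r| = 0.6; 14-point 1:1 titrations from 300 µM (ending at
≈36.6 nM) against 200 nM target, K_D 943 nM, 2% multiplicative
Gaussian noise; exponential survival with baseline median 24 months,
hazard ratio 2 on the high-expression arm, and uniform censoring whose
upper bound is solved so the expected censored fraction is 20%; Ct
tables with replicate σ = 0.1 cycles around a planted log₂ fold of
−1.11. log₁₀IC₅₀ values are N(−5, 0.5²) — centered on 10 µM,
realistic for moderately cytotoxic natural products. Optional
`tissue_shifts` offsets apply to the compound profile only, so library
agents remain exchangeable under the null.

Each generator draws from its own seed-sequence stream
(`default_rng([stream, seed])`); a shared stream would let, e.g., the
proteome generator's noise reuse the exact draws that formed the
activity generator's latent factors, silently planting spurious
correlation (this failure mode was observed and is guarded against).

What the generators do **not** emulate: real marginal IC₅₀
distributions, genuine proteome covariance structure, non-exponential
follow-up, batch effects, or assay-specific artifacts. A green
recovery test therefore establishes that each stage finds the
structure it is designed to find at the stated effect sizes and noise
levels — not that it is robust to everything real screens contain.

## Calibration facts the suite enforces

Type-I error of the log-rank test and of the cluster–response χ² sits
at 0.05 ± 0.015 over 2000 null replicates; the 21-cohort BH screen
passes anything in ≤ 7% of all-null screens; the planted proteome
structure (|r| = 0.6, 60 lines, 500 features) is recovered at ≥ 36/40
features on average with the χ² rejecting in ≥ 90% of runs; the
K_D estimator's median over 200 noisy replicates is within 5% of
truth. These are computed, not asserted from memory — see
`tests/test_acceptance.py`.

## Known limitations

- No plotting: heat-map content is exported as coded matrices and
  newick dendrograms for external renderers.
- Censored IC₅₀ bounds assume the viability curve is monotone
  decreasing; non-monotone (hormetic) curves will fit poorly.
- The χ² stage relies on asymptotic calibration; with very unbalanced
  clusters on a 60-line panel expected counts can drop below 5.
- `method="scan"` reports the minimized p without a multiplicity
  adjustment for the scan itself, by design mirroring common database
  practice; interpret it descriptively.
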