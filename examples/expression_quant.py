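"""Relative expression by ddCt and resistance folds from IC50s.

Generates a qPCR Ct table with a planted log2 fold of -1.11 (a strongly
downregulated cytokine), quantifies it with the Livak 2^-ddCt method,
then demonstrates dose-response summarization with a censored IC50
propagating into a censored resistance fold.
"""

import numpy as np

from panelomics.quant import Censored, ddct_fold, degree_of_resistance, ic50_from_curve
from panelomics.synth import GeneratorConfig, gen_ct

table, true_fold = gen_ct(GeneratorConfig(seed=1))
fold, log2_fold = ddct_fold(table)
print(f"ddCt: fold = {fold:.3f}, log2 fold = {log2_fold:.2f} "
      f"(planted {true_fold:.2f}); negative log2 = downregulation")

# a well-behaved dose-response: IC50 = 13.7 uM
conc = np.logspace(-6.5, -3.5, 8)
viability = 100.0 / (1.0 + conc / 13.7e-6)
parental = ic50_from_curve(conc, viability)
print(f"\nparental IC50: {parental * 1e6:.1f} uM")

# a resistant line that never reaches 50% inhibition in the tested range
conc_r = np.array([10e-6, 25e-6, 50e-6, 100e-6])
viability_r = np.array([99.0, 95.0, 88.0, 74.0])
resistant = ic50_from_curve(conc_r, viability_r)
print(f"resistant IC50: {resistant} M (censored at the top dose)")

fold_res = degree_of_resistance(resistant, parental)
assert isinstance(fold_res, Censored)
print(f"degree of resistance: {fold_res} -- the censoring propagates, "
      "so the ratio is reported as a bound, never as a fake number.")
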