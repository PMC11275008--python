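"""Docking-score QC: are the predicted inhibition constants consistent
with the binding energies?

Loads the packaged 28-ligand NF-kB score table, reconstructs each Ki
from its energy via Ki = exp(dG/RT), and runs the Pearson QC between
the two tabulated columns.
"""

from panelomics.docking import (
    correlate_lbe_pki,
    ki_from_energy,
    load_nfkb_docking_table,
)

table = load_nfkb_docking_table()

print(f"{'ligand':28s} {'dG kcal/mol':>12s} {'Ki printed':>12s} {'Ki from dG':>12s}")
for row in table[:6]:
    reconstructed = ki_from_energy(row.lbe_mean) * 1e6
    print(f"{row.name:28s} {row.lbe_mean:12.2f} {row.pki_mean:10.2f} uM "
          f"{reconstructed:10.2f} uM")
print("...")

qc = correlate_lbe_pki(table)
print(f"\nPearson QC over all {qc.n} ligands: r = {qc.r:.3f}, p = {qc.p:.3g}")
print("A strongly positive r confirms the tabulated constants are the "
      "thermodynamic transform of the energies; deviations flag "
      "transcription errors in a score table.")
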