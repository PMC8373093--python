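"""Exact-mass bookkeeping: [M+H]+ ions of the synthesized designs.

Computes molecular formulas (with implicit hydrogens) and monoisotopic
masses, minus one electron mass per positive charge — the convention that
matches high-resolution ESI-MS "calculated for" values at 4 decimals.
"""

from npdesign import compounds, molecular_formula, monoisotopic_mass

for name in ["2", "2a", "2b", "3", "4"]:
    mol = compounds.mol(name)
    ion = molecular_formula(mol, extra_protons=1)
    print(f"compound {name:>2}: [M+H]+ = {ion}  m/z {monoisotopic_mass(ion):.4f}")

# Each line prints the protonated-ion formula and the exact m/z a
# high-resolution mass spectrometer should report for that design.
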