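"""Virtual synthesis: reproduce both worked routes with the scheme registry.

Route A: Debus-Radziszewski imidazole condensation of the
bis(2-chlorophenyl) diketone with a hydroxy-benzaldehyde (ammonia source
implicit).  Route B: esterification of the resulting phenol with a small
carboxylic acid.
"""

from npdesign import apply_scheme, builtin_registry, compounds
from npdesign.chem import canonical_key

registry = {s.id: s for s in builtin_registry()}

step1 = apply_scheme(
    registry["debus_radziszewski"],
    [compounds.mol("diketone-5"), compounds.mol("aldehyde-6")],
)
print("condensation product:", canonical_key(step1[0]))
print("  equals the named imidazole phenol (4):",
      canonical_key(step1[0]) == canonical_key(compounds.mol("4")))

for acid, expected in [("glycolic-acid", "2"), ("methoxyacetic-acid", "2a"), ("acetic-acid", "2b")]:
    ester = apply_scheme(registry["o_acylation"], [compounds.mol(acid), step1[0]])[0]
    ok = canonical_key(ester) == canonical_key(compounds.mol(expected))
    print(f"+ {acid:>18} -> design {expected} reproduced: {ok}")

# Every route step is canonical-key identical to the synthesized compound.
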