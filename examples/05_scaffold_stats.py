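"""Murcko scaffold statistics of a design run.

Scaffolds are ring systems + linkers with side chains pruned; the generic
framework further abstracts atom and bond types.  The frequency table
shows which core dominates a design population.
"""

from npdesign import (
    DesignConfig, FixtureSpec, builtin_registry, compounds,
    generate_blocks, murcko_scaffold, run_design, scaffold_stats, substructure_count,
)

blocks = generate_blocks(FixtureSpec(seed=1, n_building_blocks=24))
candidates = run_design(DesignConfig(
    template=compounds.mol("marinopyrrole_a"),
    library=tuple(blocks), schemes=tuple(builtin_registry()),
    n_start_fragments=24, max_steps=2, beam_width=30, seed=1,
))
mols = [c.mol for c in candidates[:100]]

table, n_unique = scaffold_stats(mols)
print(f"unique scaffolds in top designs: {n_unique}")
print(table.head(3).to_string(index=False))

count, _ids = substructure_count(compounds.mol("lophine"), mols)
print(f"\ndesigns containing the triphenyl-imidazole (lophine) core: {count}/{len(mols)}")
print("lophine generic framework:", murcko_scaffold(compounds.mol("lophine")).generic_key)

# The most frequent scaffold is the lophine-type triaryl imidazole,
# mirroring the scaffold convergence of the full-scale design run.
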