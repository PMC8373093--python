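"""De novo design: breadth-first forward synthesis from a fixture library.

A seeded 24-block library (containing the worked-route reagents plus
decoys) is searched up to two linear steps; candidates are ranked by CATS
distance to Marinopyrrole A and each carries its own synthesis route.
"""

from npdesign import DesignConfig, FixtureSpec, builtin_registry, compounds, generate_blocks, run_design

blocks = generate_blocks(FixtureSpec(seed=1, n_building_blocks=24))
cfg = DesignConfig(
    template=compounds.mol("marinopyrrole_a"),
    library=tuple(blocks),
    schemes=tuple(builtin_registry()),
    n_start_fragments=24,
    max_steps=2,
    beam_width=30,
    seed=1,
)
candidates = run_design(cfg)
print(f"{len(candidates)} candidates from {len(blocks)} blocks\n")
print("rank  CATS-dist  steps  product")
for c in candidates[:5]:
    print(f"{c.rank:>4}  {c.cats_distance:9.3f}  {len(c.route):>5}  {c.key}")

# The top-ranked products are triaryl imidazoles and their phenol esters —
# the same scaffold family the full-scale search converged on.
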