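# npdesign

Natural-product-inspired de novo molecular design, offline and fully
seeded: forward-synthetic construction of candidate molecules from
building blocks and virtual reaction schemes, topological-pharmacophore
(CATS) ranking against a template, Murcko scaffold statistics, and
cascaded self-organizing-map (SOM) target prediction with empirical
p-values.

The package is aimed at computational medicinal chemists who want to turn
a structurally intricate bioactive natural product — the bundled worked
example is the marine bis-pyrrole Marinopyrrole A — into synthetically
accessible mimetics: molecules with different scaffolds but a similar
arrangement of pharmacophoric features, each accompanied by a concrete
synthesis route of at most three linear steps.

## The method

**Construction.** A deterministic breadth-first search grows molecules
from a seeded random sample of building blocks. At each depth every
surviving intermediate is combined with every applicable block under
every applicable reaction scheme (mapped SMARTS transforms with per-slot
substructure queries, e.g. the Debus–Radziszewski imidazole condensation
and phenol O-acylation). Survivors per depth are the top *w* products by
template fitness with a total-order tie-break, so a fixed configuration
and seed reproduce the run byte for byte. Every emitted candidate carries
its route; routes never exceed three steps.

**Ranking.** Each molecule is abstracted into potential pharmacophore
points — H-bond donor (D), acceptor (A), positively/negatively ionizable
(P/N), lipophilic (L) — via an explicit SMARTS rule table. The CATS
correlation vector counts atom pairs of each of the 15 unordered type
combinations at shortest-path distances 0–9:

    c(t1 t2, d) = #{(i, j) : t1 ∈ T(i), t2 ∈ T(j), d_topo(i, j) = d}

giving 150 entries, occurrence-scaled (each pair block divided by the
summed incidence of its two types) and compared by Euclidean distance.
Lower distance = more similar pharmacophore pattern, which is what lets a
template hop to an entirely different scaffold.

**Scaffolds.** Bemis–Murcko scaffolds (rings + linkers, side chains
pruned) and generic frameworks (atoms→C, bonds→single) summarize what
core chemistry a design population converged on.

**Target prediction.** Two SOMs — one over an 8-property physicochemical
block, one over CATS space — are trained on an annotated reference
library. A query's per-target score is the mean frequency of that target
among reference compounds co-located in the query's best-matching-unit
neighbourhood in each grid; significance is the add-one empirical
p-value against a seeded background resampled from the reference
library, filtered at p ≤ 0.05.

## Worked example

```bash
python examples/03_reaction_routes.py
```

```
condensation product: C=CCc1cccc(-c2nc(-c3ccccc3Cl)c(-c3ccccc3Cl)[nH]2)c1O
  equals the named imidazole phenol (4): True
+      glycolic-acid -> design 2 reproduced: True
+ methoxyacetic-acid -> design 2a reproduced: True
+        acetic-acid -> design 2b reproduced: True
```

The Debus–Radziszewski scheme condenses the bis(2-chlorophenyl) diketone
with 3-allyl-2-hydroxybenzaldehyde into the triaryl-imidazole phenol, and
O-acylation with three small acids yields the ester designs — each
product canonical-key identical to the synthesized compound. Exact-mass
bookkeeping agrees with high-resolution MS at four decimals:

```bash
python examples/01_exact_mass.py
```

```
compound  2: [M+H]+ = C26H21Cl2N2O3+  m/z 479.0924
compound 2a: [M+H]+ = C27H23Cl2N2O3+  m/z 493.1080
compound 2b: [M+H]+ = C26H21Cl2N2O2+  m/z 463.0975
compound  3: [M+H]+ = C23H19Cl2N2O2+  m/z 425.0818
compound  4: [M+H]+ = C24H19Cl2N2O+  m/z 421.0869
```

The other examples cover pharmacophore ranking (`02`), the de novo
search (`04`), scaffold statistics (`05`), target prediction (`06`) and
the end-to-end pipeline with its reproducibility manifest (`07`). A thin
CLI wraps the same API (`npdesign --help`).

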