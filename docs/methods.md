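# Methods

This note documents the models and procedures implemented in `npdesign`,
the parameters that matter, the numerical conventions, and what the
synthetic fixtures do and do not show about real data.

## Molecular data model

Molecules are RDKit graphs under a single aromaticity model (RDKit
default perception), applied identically in parsing, pharmacophore
typing, reaction products and scaffold extraction — descriptor and
scaffold identity both depend on the aromaticity assignment, so mixing
models would silently change results. Identity is canonical SMILES
("canonical key"); inputs are taken as drawn (no salt stripping, no
tautomer canonicalization). Stereochemistry is intentionally ignored:
the design process uses chemical constitution only.

Monoisotopic masses use the most-abundant-isotope masses of RDKit's
periodic table (IUPAC values, ≥6 decimals) and subtract one electron
mass (0.000549 Da) per unit positive charge. The electron correction is
what makes computed [M+H]+ values match ESI-HRMS "calculated for" values
at 4 decimals; without it the last digit is off by ~5.

## CATS pharmacophore vectors

Typing uses an explicit, versioned SMARTS rule table (`cats.PPP_RULES`),
since the descriptor's literature names the five feature classes but not
the fine print. Notable conventions:

- donor: O–H, N–H; acceptor: any oxygen, plus two-connected N without H
  (pyridine/imine type); pyrrole-type aromatic N (three-connected, no
  lone pair in the σ plane) is neither;
- lipophilic: Cl/Br/I, thioether S, and carbons whose neighbours are
  only C, H or halogen;
- an atom may carry several types (a phenol O is both donor and
  acceptor).

The vector has 15 unordered type pairs × 10 shortest-path distance bins
(0–9); longer pairs are discarded. Same-atom pairs (distance 0) count
once per unordered type pair the atom carries. Scaling variants: `raw`
integer counts; `occurrence` (default) divides each pair block by the
summed incidence of its two types (0/0 → 0), removing most size
dependence; `size` divides by heavy-atom count. Distances: Euclidean
(default) or Manhattan.

**Calibration caveat.** The published calibration distances for the
Marinopyrrole A template against the two synthesized designs (1.45 and
1.70) were produced by proprietary software whose exact typing and
scaling are not restated in the open literature. Under this package's
defaults the distances are 1.04 and 1.15 — same ordering, same
magnitude, both inside the < 1.8 selection band — and no documented
variant (raw/occurrence/size × Euclidean/Manhattan, plus several
defensible typing-rule readings that were examined) reproduces the
printed values. The default was therefore chosen on principle
(occurrence scaling is the published size-correction; Euclidean is the
conventional metric) rather than fitted to the printed numbers, and the
acceptance script prints the full sweep so the discrepancy is auditable.

## Reaction schemes

Schemes are mapped reaction-SMARTS transforms in a plain-text registry
(`data/schemes.tsv`), one record per scheme with a worked literature
example that is re-executed at load time — a registry that loads is a
registry whose chemistry is verified. Fixed reagents are not slots: the
Debus–Radziszewski condensation is modeled as diketone + aldehyde with
the ammonia source implicit (declared as two implicit N atoms for
mass-balance checks), because ammonium acetate is a constant of the
reaction, not a combinatorial choice. Esterification is modeled from
the carboxylic acid (the realized carbodiimide chemistry); the
acyl-halide variant forms the same strategic bond. Protecting-group
logistics (silylation/desilylation) are not modeled — virtual chemistry
tracks strategic bonds only. The bundled registry holds four schemes;
the full industrial transform sets are much larger, and the registry
format is deliberately user-extensible (each added record must carry its
own example).

## De novo search

Breadth-first over depths 1..3 (three linear steps is the hard
synthesizability bound; routes are linear chains, never convergent).
Start fragments are sampled uniformly without replacement with the
config seed — the only stochastic element. At each depth, every
frontier molecule is paired with every library block under every
applicable 2-slot scheme (and applied directly under 1-slot schemes);
3-slot schemes are loaded but not enumerated combinatorially (cubic
blowup; none are bundled). Default beam width is 50 products per depth,
kept by fitness with the tie-break (fitness, route length, canonical
key) so the order is total; `beam_width=None` disables pruning, which is
how the exhaustive-oracle tests run. Intermediates that no scheme can
extend still count as final candidates (a one-step product can be a
design). Candidates are deduplicated by canonical key, keeping the
best route (highest fitness, then shortest, then lexicographic).

Fitness defaults to `1/(1 + CATS distance)` to the template, so
construction and final ranking optimize the same similarity; the kernel
is pluggable (`run_design(fitness_fn=...)`) for alternative graph
similarities.

## Scaffold statistics

Bemis–Murcko scaffolds via RDKit (exocyclic double-bonded atoms
retained, the standard convention); acyclic molecules map to the empty
scaffold. Both the scaffold key and the generic framework key
(atoms→carbon, bonds→single) are emitted, because published scaffold
counts rarely state which convention they used — either grouping is
reproducible here. Frequency tables sort by descending count with a
stable key tie-break; fractions sum to 1 within 1e-9.

## Cascaded-SOM target prediction

Physicochemical space: molecular weight, Crippen logP, H-bond
donor/acceptor counts, ring count, rotatable bonds, TPSA, heavy-atom
count, z-scaled against the reference library (constant columns pass
through). Pharmacophore space: the package's CATS vectors. One SOM per
space, default 6×6 lattice, 50 epochs, initial learning rate 0.5 and
initial neighbourhood radius max(w,h)/2, both decaying exponentially;
training is the classical online algorithm and is exactly reproducible
from the seed.

Scoring: the query's best-matching unit plus its 8-connected lattice
neighbours (Chebyshev radius 1, configurable) defines the local
ensemble in each grid; the per-target score is the mean (or max,
selectable) of the target's frequency among ensemble members across the
two grids — symmetric in the grids by construction. Significance: the
add-one empirical estimator p = (1 + #{background ≥ observed}) / (1 + B)
with B = 1000 background queries resampled with replacement from the
reference library (seeded); p is never 0 and at most 1. Default filter
p ≤ 0.05.

Caveat at fixture scale: with only five planted target classes, a fifth
of the background shares any query's class and scores equally well, so
p bottoms out near class prevalence (~0.2) and the 0.05 filter passes
nothing. This is the estimator working as defined, not a defect; with a
realistically broad target panel, high scorers for a given target are
rare and confident predictions clear the threshold.

## Synthetic fixtures

`generate_blocks` emulates a vendor catalog at desk scale: the six
worked-route reagents always included, decoys drawn per category
(diketones 15%, aldehydes 25%, acids 25%, phenols 15%, inert 20% by
default, largest-remainder apportionment). Category pools are small, so
very large requested libraries may saturate a category before its
quota; at the bundled sizes (≤ 60 blocks) quotas are met within the
2/n composition contract.

`generate_reference_library` plants target classes as chemotypes
(carboxylic acids, aliphatic amines, phenols, halogenated aromatics,
polyols — five classes with distinct physicochemical and pharmacophore
profiles). Class separation is realized as mixing: each member is drawn
from its own class pool with probability `separation/2`, else from the
shared pool. Separation 2.0 (the default study condition) gives fully
chemotype-separated classes; separation 0 makes labels independent of
structure, the negative control. Because molecules are discrete,
"shifting class means" by a continuous effect size is not literally
possible; mixing is the closest faithful realization and reproduces the
intended endpoints (between/within descriptor variance ratio > 1 at
2.0, chance-level recovery at 0).

What passing the fixture tests shows: the machinery — search,
descriptors, statistics — behaves to contract under controlled
conditions. What it does not show: performance on a real 25k-block
vendor catalog, a 58-scheme transform set, or a curated chemogenomic
reference panel; the published full-scale endpoint counts (hundreds of
designs and scaffolds, specific prediction counts) require exactly
those proprietary inputs and are out of desk-scale reach by design.

## Problem sizes and determinism

Default test and demo sizes: 24–60-block libraries, ≤ 3 search depths,
beam 30–50, 6×6 SOMs with 30–50 epochs, 200-compound reference
libraries, 100–1000-draw backgrounds. These sizes exercise every code
path while keeping the full suite in tens of seconds. Every stochastic
element — start-fragment sampling, SOM initialization and shuffling,
background resampling, fixture generation — draws from
`numpy.random.default_rng` with an explicit seed, and the pipeline
manifest (config hash, per-output SHA-256, manifest hash) makes
run-level reproducibility checkable with a string comparison.
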