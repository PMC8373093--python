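"""CATS topological pharmacophore correlation vectors.

CATS (chemically advanced template search) abstracts a molecule into
potential pharmacophore points (PPPs) — hydrogen-bond donor (D), acceptor
(A), positively ionizable (P), negatively ionizable (N), lipophilic (L) —
and counts atom pairs of each unordered type combination, binned by
shortest-path topological distance.  With 15 unordered type pairs and
distance bins 0..9 the vector has 150 entries; pairs farther than 9 bonds
apart are discarded.  Lower vector distance means higher pharmacophore
similarity, which is what makes the descriptor suitable for scaffold
hopping: two molecules with different ring systems but the same spatial
arrangement of interaction features score as neighbours.

The typing rules are an explicit, versioned substructure table
(:data:`PPP_RULES`): the descriptor's literature sources state the five
feature classes but implementations differ in the fine print, so the table
is user-visible and swappable.  Three scaling schemes are provided:

``raw``
    integer pair counts;
``occurrence`` (default)
    each pair-type block divided by the summed incidence of its two member
    types in the molecule (0/0 -> 0), which removes most of the molecular
    size dependence;
``size``
    counts divided by the number of heavy atoms.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
from rdkit import Chem

from .chem import canonical_key

__all__ = [
    "PPP_TYPES",
    "PPP_RULES",
    "PAIR_TYPES",
    "CATSVector",
    "assign_ppp_types",
    "cats_vector",
    "cats_distance",
    "rank_by_cats",
    "vector_labels",
]

PPP_TYPES: tuple[str, ...] = ("D", "A", "P", "N", "L")

ScalingScheme = Literal["raw", "occurrence", "size"]
Metric = Literal["euclidean", "manhattan"]

N_BINS = 10  # topological distances 0..9

#: Versioned potential-pharmacophore-point rule table, applied in order.
#: Each entry: (type, SMARTS, human description).  An atom may carry any
#: subset of the five types.  Lipophilic carbons are handled by an explicit
#: environment rule below (SMARTS recursion for "neighbours only C/H or
#: halogen" is clearer in code).
PPP_RULES_VERSION = "2024.1"
PPP_RULES: tuple[tuple[str, str, str], ...] = (
    ("D", "[O;H1]", "hydroxyl oxygen"),
    ("D", "[#7;!H0]", "N-H nitrogen (amine, amide, pyrrole/imidazole NH)"),
    ("A", "[#8]", "any oxygen (lone-pair acceptor)"),
    ("A", "[#7;H0;X2]", "two-connected N without H (pyridine/imine-type)"),
    ("P", "[NX3;H2,H1,H0;!$(NC=O);!$(N[a]);!$(Na)]", "basic aliphatic amine"),
    ("P", "[NX2]=[CX3][NX3]", "amidine/guanidine nitrogen"),
    ("P", "[*+;!$([*+]~[*-])]", "formal positive charge (not ylide)"),
    ("N", "[CX3](=O)[OX2H1]", "carboxylic acid carbon"),
    ("N", "[SX4](=O)(=O)[OX2H1]", "sulfonic acid sulfur"),
    ("N", "[PX4](=O)([OX2H1])", "phosphonic acid phosphorus"),
    ("N", "[*-;!$([*-]~[*+])]", "formal negative charge (not ylide)"),
    ("L", "[Cl,Br,I]", "heavy halogen"),
    ("L", "[S;D2;$(S(C)C)]", "thioether sulfur"),
)

#: atomic numbers a carbon may neighbour and still count as lipophilic
_LIPO_NEIGHBOURS = frozenset({1, 6, 17, 35, 53})

#: the 15 unordered type pairs, in canonical (sorted, lexicographic) order
PAIR_TYPES: tuple[tuple[str, str], ...] = tuple(
    sorted(
        {tuple(sorted(p)) for p in itertools.combinations_with_replacement(PPP_TYPES, 2)}
    )
)

_PAIR_INDEX = {pair: k for k, pair in enumerate(PAIR_TYPES)}
_COMPILED_RULES = tuple(
    (ppp_type, Chem.MolFromSmarts(smarts)) for ppp_type, smarts, _ in PPP_RULES
)


def rule_table() -> list[dict[str, str]]:
    """Dump the active PPP rule table (for audit / CLI output)."""
    return [
        {"type": t, "smarts": s, "description": d, "version": PPP_RULES_VERSION}
        for t, s, d in PPP_RULES
    ] + [
        {
            "type": "L",
            "smarts": "<carbon with only C/H/halogen neighbours>",
            "description": "lipophilic carbon (environment rule)",
            "version": PPP_RULES_VERSION,
        }
    ]


def assign_ppp_types(mol: Chem.Mol) -> dict[int, frozenset[str]]:
    """Deterministic PPP typing: atom index -> subset of {D,A,P,N,L}."""
    types: dict[int, set[str]] = {i: set() for i in range(mol.GetNumAtoms())}
    for ppp_type, query in _COMPILED_RULES:
        for match in mol.GetSubstructMatches(query):
            types[match[0]].add(ppp_type)
    for atom in mol.GetAtoms():
        if atom.GetAtomicNum() == 6 and all(
            nb.GetAtomicNum() in _LIPO_NEIGHBOURS for nb in atom.GetNeighbors()
        ):
            types[atom.GetIdx()].add("L")
    return {i: frozenset(s) for i, s in types.items()}


@dataclass(frozen=True)
class CATSVector:
    """150-dimensional correlation vector plus its scaling-scheme tag."""

    values: np.ndarray
    scaling: str

    def __post_init__(self):
        arr = np.asarray(self.values, dtype=float)
        if arr.shape != (len(PAIR_TYPES) * N_BINS,):
            raise ValueError(f"CATS vector must have {len(PAIR_TYPES) * N_BINS} entries")
        if (arr < 0).any():
            raise ValueError("CATS entries must be non-negative")
        arr.setflags(write=False)
        object.__setattr__(self, "values", arr)

    def as_matrix(self) -> np.ndarray:
        """(15 pair types x 10 distance bins) view of the vector."""
        return self.values.reshape(len(PAIR_TYPES), N_BINS)


def vector_labels() -> list[str]:
    """Column labels ``<pair>_d<bin>`` matching the vector layout."""
    return [f"{a}{b}_d{d}" for a, b in PAIR_TYPES for d in range(N_BINS)]


def cats_vector(mol: Chem.Mol, scaling: ScalingScheme = "occurrence") -> CATSVector:
    """Compute the CATS correlation vector of ``mol``.

    Entry (pair, d) counts atom pairs at shortest-path distance ``d`` whose
    PPP types match the pair.  Same-atom pairs (d = 0) are counted once per
    unordered type pair the atom carries, e.g. a phenol oxygen (D and A)
    contributes to DD, AA and AD at distance 0.  Distances > 9 are
    discarded.
    """
    if mol.GetNumHeavyAtoms() < 1:
        raise ValueError("molecule must have at least one heavy atom")
    typing = assign_ppp_types(mol)
    dist = Chem.GetDistanceMatrix(mol)
    counts = np.zeros((len(PAIR_TYPES), N_BINS))
    n = mol.GetNumAtoms()
    for i in range(n):
        t_i = sorted(typing[i])
        for a, b in itertools.combinations_with_replacement(t_i, 2):
            counts[_PAIR_INDEX[(a, b)], 0] += 1
        for j in range(i + 1, n):
            d = int(dist[i, j])
            if d >= N_BINS:
                continue
            for a in t_i:
                for b in typing[j]:
                    counts[_PAIR_INDEX[tuple(sorted((a, b)))], d] += 1
    if scaling == "raw":
        values = counts
    elif scaling == "size":
        values = counts / mol.GetNumHeavyAtoms()
    elif scaling == "occurrence":
        incidence = {
            t: sum(1 for s in typing.values() if t in s) for t in PPP_TYPES
        }
        values = counts.astype(float)
        for k, (a, b) in enumerate(PAIR_TYPES):
            denom = incidence[a] + incidence[b]
            values[k] = counts[k] / denom if denom > 0 else 0.0
    else:
        raise ValueError(f"unknown scaling scheme: {scaling!r}")
    return CATSVector(values.ravel(), scaling)


def cats_distance(a: CATSVector, b: CATSVector, metric: Metric = "euclidean") -> float:
    """Distance between two CATS vectors (lower = more similar).

    Euclidean by default, Manhattan selectable.  Vectors must share a
    scaling scheme; comparing across schemes is meaningless.
    """
    if a.scaling != b.scaling:
        raise ValueError(f"scaling mismatch: {a.scaling!r} vs {b.scaling!r}")
    diff = a.values - b.values
    if metric == "euclidean":
        return float(np.sqrt(np.dot(diff, diff)))
    if metric == "manhattan":
        return float(np.abs(diff).sum())
    raise ValueError(f"unknown metric: {metric!r}")


def rank_by_cats(
    template: Chem.Mol,
    candidates: Iterable[Chem.Mol] | Sequence[Chem.Mol],
    scaling: ScalingScheme = "occurrence",
    metric: Metric = "euclidean",
) -> list[tuple[Chem.Mol, float]]:
    """Rank ``candidates`` by ascending CATS distance to ``template``.

    Ties are broken by canonical SMILES so the ordering is total and
    independent of input order.
    """
    candidates = list(candidates)
    if not candidates:
        raise ValueError("need at least one candidate")
    ref = cats_vector(template, scaling)
    scored = [
        (mol, cats_distance(ref, cats_vector(mol, scaling), metric))
        for mol in candidates
    ]
    scored.sort(key=lambda item: (item[1], canonical_key(item[0])))
    return scored
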