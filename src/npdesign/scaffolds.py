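"""Murcko scaffold extraction and scaffold statistics.

The Bemis-Murcko scaffold of a molecule is its ring systems plus the
linkers connecting them, with side chains pruned (exocyclic double-bonded
atoms retained, the standard convention).  The *generic framework* further
abstracts every atom to carbon and every bond to a single bond, so that
molecules differing only in heteroatom placement or bond order share a
framework.  Both keys are emitted because published scaffold counts rarely
say which convention they used; either grouping is reproducible here.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd
from rdkit import Chem
from rdkit.Chem.Scaffolds import MurckoScaffold

from .chem import canonical_key

__all__ = ["Scaffold", "murcko_scaffold", "scaffold_stats", "substructure_count"]

EMPTY_SCAFFOLD_KEY = ""  # acyclic molecules have no ring system


@dataclass(frozen=True)
class Scaffold:
    """Canonical scaffold key + generic (atom/bond-abstracted) framework key."""

    key: str
    generic_key: str

    @property
    def is_empty(self) -> bool:
        return self.key == EMPTY_SCAFFOLD_KEY


def murcko_scaffold(mol: Chem.Mol) -> Scaffold:
    """Bemis-Murcko scaffold of ``mol``; acyclic input -> empty scaffold."""
    core = MurckoScaffold.GetScaffoldForMol(mol)
    if core.GetNumAtoms() == 0:
        return Scaffold(EMPTY_SCAFFOLD_KEY, EMPTY_SCAFFOLD_KEY)
    generic = MurckoScaffold.MakeScaffoldGeneric(core)
    return Scaffold(canonical_key(core), canonical_key(generic))


def scaffold_stats(
    designs: Sequence[Chem.Mol] | Iterable[Chem.Mol], generic: bool = False
) -> tuple[pd.DataFrame, int]:
    """Scaffold frequency table over a design set.

    Returns ``(table, n_unique)`` where the table has columns
    ``scaffold``, ``count``, ``fraction``, sorted by descending count with
    a stable tie-break on the scaffold key.  ``generic=True`` groups by the
    generic framework instead of the Murcko scaffold.
    """
    designs = list(designs)
    if not designs:
        raise ValueError("need at least one design")
    keys = [
        (s.generic_key if generic else s.key)
        for s in (murcko_scaffold(m) for m in designs)
    ]
    counts = pd.Series(keys).value_counts().rename_axis("scaffold").reset_index(name="count")
    counts["fraction"] = counts["count"] / len(designs)
    counts = counts.sort_values(
        ["count", "scaffold"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    return counts, int(counts.shape[0])


def substructure_count(
    query: Chem.Mol, library: Sequence[tuple[Chem.Mol, str]] | Sequence[Chem.Mol]
) -> tuple[int, list[str]]:
    """Count library members containing ``query`` as a subgraph.

    Matching is aromatic-perceived, consistent with the package-wide
    aromaticity model.  Library entries may be molecules or (molecule, id)
    pairs; returns ``(count, matching_ids)`` with ids in input order
    (canonical key stands in for a missing id).
    """
    count = 0
    ids: list[str] = []
    for entry in library:
        if isinstance(entry, tuple):
            mol, ident = entry
        else:
            mol, ident = entry, canonical_key(entry)
        if mol.HasSubstructMatch(query):
            count += 1
            ids.append(ident)
    return count, ids
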