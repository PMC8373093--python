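"""Molecular data model shared by every other module.

Molecules are RDKit ``Mol`` objects carrying a canonical SMILES key; this
module provides the parsing, formula and monoisotopic-mass arithmetic, and
plain-text library I/O that the design, ranking and prediction stages build
on.  One aromaticity model (RDKit's default perception) is applied
everywhere, because pharmacophore typing and scaffold identity both depend
on it.  Inputs are taken as drawn: no salt stripping, no tautomer
canonicalization.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from rdkit import Chem, RDLogger
from rdkit.Chem import AllChem  # noqa: F401  (registers reaction support)

__all__ = [
    "StructureParseError",
    "UnknownElementError",
    "MolecularFormula",
    "parse_structure",
    "canonical_key",
    "molecular_formula",
    "monoisotopic_mass",
    "protonated_mass",
    "read_library",
    "write_results",
]

logger = logging.getLogger(__name__)

# RDKit is chatty on invalid input; we raise structured errors instead.
RDLogger.DisableLog("rdApp.error")

ELECTRON_MASS = 0.000548579909  # Da

_PERIODIC_TABLE = Chem.GetPeriodicTable()


class StructureParseError(ValueError):
    """Raised when a structure string cannot be parsed or sanitized."""

    def __init__(self, text: str, reason: str = "invalid structure"):
        self.text = text
        self.reason = reason
        super().__init__(f"{reason}: {text!r}")


class UnknownElementError(KeyError):
    """Raised when a formula contains an element with no tabulated mass."""


def parse_structure(text: str) -> Chem.Mol:
    """Parse a SMILES string into a sanitized, aromaticity-perceived Mol.

    The returned molecule carries its canonical key as the ``canonical_key``
    property (also available through :func:`canonical_key`).

    Raises
    ------
    StructureParseError
        If ``text`` is empty or not valid SMILES.
    """
    if not isinstance(text, str) or not text.strip():
        raise StructureParseError(str(text), "empty structure string")
    mol = Chem.MolFromSmiles(text)
    if mol is None:
        raise StructureParseError(text)
    mol.SetProp("canonical_key", Chem.MolToSmiles(mol))
    return mol


def canonical_key(mol: Chem.Mol) -> str:
    """Canonical SMILES of ``mol`` — the identity used for deduplication."""
    return Chem.MolToSmiles(mol)


@dataclass(frozen=True)
class MolecularFormula:
    """Element -> count map plus the net formal charge."""

    counts: dict[str, int] = field(default_factory=dict)
    charge: int = 0

    def __post_init__(self):
        if any(c < 0 for c in self.counts.values()):
            raise ValueError("element counts must be non-negative")
        # normalize away zero entries so equality is well-defined
        object.__setattr__(
            self, "counts", {el: n for el, n in self.counts.items() if n > 0}
        )

    def __str__(self) -> str:  # Hill order: C, H, then alphabetical
        items = []
        rest = dict(self.counts)
        for el in ("C", "H"):
            if el in rest:
                items.append((el, rest.pop(el)))
        items.extend(sorted(rest.items()))
        body = "".join(f"{el}{n if n > 1 else ''}" for el, n in items)
        if self.charge:
            sign = "+" if self.charge > 0 else "-"
            body += sign if abs(self.charge) == 1 else f"{abs(self.charge)}{sign}"
        return body

    def merge(self, other: "MolecularFormula") -> "MolecularFormula":
        """Disjoint union of two formulas (counts add, charges add)."""
        counts = Counter(self.counts)
        counts.update(other.counts)
        return MolecularFormula(dict(counts), self.charge + other.charge)


def molecular_formula(mol: Chem.Mol, extra_protons: int = 0) -> MolecularFormula:
    """Molecular formula of ``mol`` including implicit hydrogens.

    ``extra_protons`` adds that many H and +1 charges — the [M+H]+ adduct of
    electrospray mass spectrometry is ``extra_protons=1``.
    """
    counts: Counter[str] = Counter()
    charge = 0
    for atom in mol.GetAtoms():
        counts[atom.GetSymbol()] += 1
        h = atom.GetTotalNumHs()
        if h:
            counts["H"] += h
        charge += atom.GetFormalCharge()
    if extra_protons:
        counts["H"] += extra_protons
        charge += extra_protons
    return MolecularFormula(dict(counts), charge)


def monoisotopic_mass(formula: MolecularFormula) -> float:
    """Monoisotopic mass in Da: sum of most-abundant-isotope masses minus
    one electron mass per unit of positive charge.

    The electron correction is what makes computed [M+H]+ values agree with
    high-resolution ESI-MS "calculated for" values at 4 decimals.
    """
    mass = 0.0
    for el, n in formula.counts.items():
        try:
            if _PERIODIC_TABLE.GetAtomicNumber(el) == 0:
                raise UnknownElementError(el)
        except RuntimeError as exc:
            raise UnknownElementError(el) from exc
        mass += n * _PERIODIC_TABLE.GetMostCommonIsotopeMass(el)
    mass -= formula.charge * ELECTRON_MASS
    return mass


def protonated_mass(mol: Chem.Mol) -> float:
    """Convenience: monoisotopic m/z of the [M+H]+ ion of ``mol``."""
    return monoisotopic_mass(molecular_formula(mol, extra_protons=1))


def read_library(path: str | Path) -> list[tuple[Chem.Mol, str]]:
    """Read a molecule library from a tab-separated file or an SD file.

    TSV layout is one record per line: ``SMILES<TAB>identifier`` (the id is
    optional; missing ids become ``line<N>``).  Records that fail to parse
    are skipped with a logged warning; input order is preserved.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in {".sdf", ".sd", ".mol"}:
        return _read_sdf(path)
    records: list[tuple[Chem.Mol, str]] = []
    n_bad = 0
    with path.open("r", encoding="utf-8") as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            smiles = parts[0].strip()
            ident = parts[1].strip() if len(parts) > 1 and parts[1].strip() else f"line{lineno}"
            try:
                records.append((parse_structure(smiles), ident))
            except StructureParseError:
                n_bad += 1
                logger.warning("skipping invalid structure at %s:%d: %r", path, lineno, smiles)
    if n_bad:
        logger.warning("%d invalid record(s) skipped in %s", n_bad, path)
    return records


def _read_sdf(path: Path) -> list[tuple[Chem.Mol, str]]:
    records = []
    supplier = Chem.SDMolSupplier(str(path))
    for i, mol in enumerate(supplier):
        if mol is None:
            logger.warning("skipping unreadable SD record %d in %s", i, path)
            continue
        ident = mol.GetProp("_Name") if mol.HasProp("_Name") and mol.GetProp("_Name") else f"sd{i}"
        mol.SetProp("canonical_key", Chem.MolToSmiles(mol))
        records.append((mol, ident))
    return records


def write_results(path: str | Path, records: Iterable[tuple[Chem.Mol, str] | Sequence]) -> int:
    """Write ``(mol, id, *extra_columns)`` records as a UTF-8 TSV.

    Returns the number of records written.  Round-trips with
    :func:`read_library` (extra columns are ignored on read).
    """
    path = Path(path)
    n = 0
    with path.open("w", encoding="utf-8") as handle:
        for record in records:
            mol, ident, *extra = record
            cols = [canonical_key(mol), str(ident), *map(str, extra)]
            handle.write("\t".join(cols) + "\n")
            n += 1
    return n
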