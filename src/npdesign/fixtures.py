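"""Synthetic data generators: building-block libraries and annotated
reference libraries, so that every stage of the pipeline runs offline.

The building-block generator emulates a vendor catalog at desk scale: it
always includes the worked-route reagents (the bis(2-chlorophenyl)
diketone, the two hydroxy-benzaldehydes, and the three small carboxylic
acids) and pads the library with seeded decoys drawn from per-category
structure pools (1,2-diketones, aldehydes, carboxylic acids, phenols, and
inert molecules that no bundled scheme can touch).

The reference-library generator plants target classes as chemotypes.
Because molecules are discrete, class separation is realized as mixing:
each member is drawn from its own class's structure pool with probability
``separation / 2`` and from the shared pool of all classes otherwise.  At
``separation=2`` classes are fully chemotype-separated (descriptor
recovery should approach 100%); at ``separation=0`` labels are independent
of structure and recovery falls to chance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from rdkit import Chem

from . import compounds
from .chem import parse_structure, write_results

__all__ = ["FixtureSpec", "generate_blocks", "generate_reference_library"]


@dataclass(frozen=True)
class FixtureSpec:
    """Declarative description of a synthetic fixture set."""

    seed: int = 0
    n_building_blocks: int = 40
    fractions: dict[str, float] = field(
        default_factory=lambda: {
            "diketones": 0.15,
            "aldehydes": 0.25,
            "acids": 0.25,
            "phenols": 0.15,
            "inert": 0.20,
        }
    )
    n_reference_targets: int = 5
    compounds_per_target: int = 40
    separation: float = 2.0

    def __post_init__(self):
        total = sum(self.fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"category fractions must sum to 1 (got {total})")
        if self.n_building_blocks < 0 or self.compounds_per_target < 0:
            raise ValueError("counts must be non-negative")
        if not 0.0 <= self.separation <= 2.0:
            raise ValueError("separation must be in [0, 2]")


# -- building blocks ---------------------------------------------------------

_ARYL = [
    "c1ccccc1", "c1ccc(C)cc1", "c1ccc(Cl)cc1", "c1ccc(OC)cc1", "c1ccc(F)cc1",
    "c1cccc(C)c1", "c1cccc(Cl)c1", "c1ccc(CC)cc1", "c1ccc(Br)cc1",
]

_NAMED_BLOCKS = {
    "diketones": [("diketone-5", compounds.DIKETONE_5)],
    "aldehydes": [("aldehyde-6", compounds.ALDEHYDE_6), ("aldehyde-7", compounds.ALDEHYDE_7)],
    "acids": [
        ("methoxyacetic-acid", compounds.METHOXYACETIC_ACID),
        ("acetic-acid", compounds.ACETIC_ACID),
        ("glycolic-acid", compounds.GLYCOLIC_ACID),
    ],
    "phenols": [],
    "inert": [],
}


def _decoy(category: str, rng: np.random.Generator) -> str:
    if category == "diketones":
        a, b = rng.choice(_ARYL, size=2)
        return f"O=C({a})C(=O){b}"
    if category == "aldehydes":
        if rng.random() < 0.7:
            return f"O=C{rng.choice(_ARYL)}"
        return "C" * int(rng.integers(1, 9)) + "C=O"
    if category == "acids":
        if rng.random() < 0.6:
            return "C" * int(rng.integers(1, 8)) + "C(=O)O"
        return f"OC(=O){rng.choice(_ARYL)}"
    if category == "phenols":
        sub = rng.choice(["C", "CC", "Cl", "OC", "CCC", "F"])
        pattern = rng.choice([f"Oc1ccc({sub})cc1", f"Oc1cccc({sub})c1", "Oc1ccc2ccccc2c1"])
        return str(pattern)
    if category == "inert":
        choice = rng.choice(
            ["C" * int(rng.integers(4, 10)), "CCOCC", "C1CCCCC1", "c1ccccc1" + "C" * int(rng.integers(1, 4)), "CC(C)CC(C)C"]
        )
        return str(choice)
    raise ValueError(f"unknown category {category!r}")


def _apportion(n: int, fractions: dict[str, float]) -> dict[str, int]:
    """Largest-remainder apportionment of ``n`` across categories."""
    raw = {k: n * f for k, f in fractions.items()}
    counts = {k: int(v) for k, v in raw.items()}
    remainder = n - sum(counts.values())
    order = sorted(raw, key=lambda k: (-(raw[k] - counts[k]), k))
    for k in order[:remainder]:
        counts[k] += 1
    return counts


def generate_blocks(
    spec: FixtureSpec, path: str | Path | None = None
) -> list[tuple[Chem.Mol, str]]:
    """Seeded building-block library; optionally written as a TSV file.

    The named worked-route reagents are always included (they count toward
    their categories); seeded decoys fill the remaining quota.  Every
    emitted structure parses.
    """
    rng = np.random.default_rng(spec.seed)
    counts = _apportion(spec.n_building_blocks, spec.fractions)
    records: list[tuple[Chem.Mol, str]] = []
    for category in sorted(counts):
        quota = counts[category]
        emitted: list[tuple[str, str]] = []
        seen: set[str] = set()
        for ident, smiles in _NAMED_BLOCKS[category][:quota]:
            emitted.append((ident, smiles))
            seen.add(Chem.CanonSmiles(smiles))
        attempts = 0
        while len(emitted) < quota and attempts < 200 * quota:
            attempts += 1
            smiles = _decoy(category, rng)
            key = Chem.CanonSmiles(smiles)
            if key in seen:
                continue
            seen.add(key)
            singular = category[:-1] if category.endswith("s") else category
            emitted.append((f"{singular}-gen{len(emitted)}", smiles))
        for ident, smiles in emitted:
            records.append((parse_structure(smiles), ident))
    if path is not None:
        write_results(path, records)
    return records


# -- annotated reference library --------------------------------------------

#: chemotype pools per planted target class; pool entries are callables
#: drawing one SMILES from a seeded rng
def _acidic(rng):  # carboxylic acids: negatively ionizable
    k = int(rng.integers(1, 9))
    return "C" * k + "C(=O)O"


def _basic(rng):  # aliphatic amines: positively ionizable
    k = int(rng.integers(2, 9))
    head = rng.choice(["N", "NC", "N(C)C"])
    return "C" * k + str(head)


def _phenolic(rng):  # (poly)phenols: aromatic donors/acceptors
    core = str(rng.choice(["Oc1ccccc1", "Oc1ccc(O)cc1", "Oc1cccc(O)c1"]))
    tail = "C" * int(rng.integers(0, 3))
    return core + tail


def _lipophilic(rng):  # halogenated aromatics / hydrocarbons
    base = rng.choice(["c1ccccc1", "c1ccc2ccccc2c1"])
    n_cl = int(rng.integers(1, 4))
    mol = str(base)
    for _ in range(n_cl):
        mol = mol.replace("cc", "c(Cl)c", 1)
    return mol + "C" * int(rng.integers(0, 3))


def _polyol(rng):  # sugar-like polyols: many donors, high TPSA
    k = int(rng.integers(2, 6))
    return "OC" + "C(O)" * k + "CO"


_CLASS_POOLS: dict[str, object] = {
    "protease": _acidic,
    "gpcr": _basic,
    "oxidoreductase": _phenolic,
    "nuclear-receptor": _lipophilic,
    "glycosidase": _polyol,
}


def generate_reference_library(
    spec: FixtureSpec, path: str | Path | None = None
) -> list[tuple[Chem.Mol, tuple[str, ...]]]:
    """Annotated reference library with planted, chemotype-separated target
    classes; optionally written as ``SMILES<TAB>id<TAB>targets`` TSV."""
    class_names = sorted(_CLASS_POOLS)[: spec.n_reference_targets]
    if spec.n_reference_targets > len(_CLASS_POOLS):
        raise ValueError(f"at most {len(_CLASS_POOLS)} planted target classes available")
    rng = np.random.default_rng(spec.seed)
    p_own = spec.separation / 2.0
    records: list[tuple[Chem.Mol, tuple[str, ...]]] = []
    rows = []
    for cls in class_names:
        for j in range(spec.compounds_per_target):
            pool = cls if rng.random() < p_own else str(rng.choice(class_names))
            smiles = _CLASS_POOLS[pool](rng)  # type: ignore[operator]
            mol = parse_structure(smiles)
            records.append((mol, (cls,)))
            rows.append((mol, f"{cls}-{j}", cls))
    if path is not None:
        path = Path(path)
        with path.open("w", encoding="utf-8") as handle:
            for mol, ident, cls in rows:
                handle.write(f"{Chem.MolToSmiles(mol)}\t{ident}\t{cls}\n")
    return records


def read_reference_library(path: str | Path) -> list[tuple[Chem.Mol, tuple[str, ...]]]:
    """Read ``SMILES<TAB>id<TAB>target;target`` records."""
    records = []
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        smiles, _ident, targets = line.split("\t")
        records.append((parse_structure(smiles), tuple(targets.split(";"))))
    return records
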