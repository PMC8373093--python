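"""Bundled reference structures.

SMILES for the marine natural product Marinopyrrole A (the design
template), the 2,4,5-triaryl-imidazole de novo designs built around it, the
building blocks of their synthesis routes, and lophine — the parent
2,4,5-triphenyl-imidazole scaffold.  All strings are constitution only (no
stereochemistry): the design pipeline uses the template's chemical
constitution and nothing else.
"""

from __future__ import annotations

from rdkit import Chem

from .chem import parse_structure

# Template: axially chiral tetrachloro-1,3'-bipyrrole bearing two
# salicyloyl groups; drawn without axial chirality (constitution only).
MARINOPYRROLE_A = "Oc1ccccc1C(=O)c1cc(Cl)c(Cl)n1-c1c(Cl)c(Cl)[nH]c1C(=O)c1ccccc1O"

# 2,4,5-triphenyl-1H-imidazole, the parent scaffold of the design series.
LOPHINE = "c1ccc(-c2nc(-c3ccccc3)c(-c3ccccc3)[nH]2)cc1"

# De novo designs and their synthesis intermediates (Experimental names).
IMIDAZOLE_PHENOL_4 = "C(=C)Cc1cccc(-c2nc(-c3ccccc3Cl)c(-c3ccccc3Cl)[nH]2)c1O"
GLYCOLATE_ESTER_2 = "C(=C)Cc1cccc(-c2nc(-c3ccccc3Cl)c(-c3ccccc3Cl)[nH]2)c1OC(=O)CO"
METHOXYACETATE_ESTER_2A = "C(=C)Cc1cccc(-c2nc(-c3ccccc3Cl)c(-c3ccccc3Cl)[nH]2)c1OC(=O)COC"
ACETATE_ESTER_2B = "C(=C)Cc1cccc(-c2nc(-c3ccccc3Cl)c(-c3ccccc3Cl)[nH]2)c1OC(=O)C"
ETHOXYPHENOL_IMIDAZOLE_3 = "CCOc1cc(-c2nc(-c3ccccc3Cl)c(-c3ccccc3Cl)[nH]2)ccc1O"

# Building blocks of the realized routes.
DIKETONE_5 = "O=C(c1ccccc1Cl)C(=O)c1ccccc1Cl"  # 1,2-bis(2-chlorophenyl)ethane-1,2-dione
ALDEHYDE_6 = "C(=C)Cc1cccc(C=O)c1O"  # 3-allyl-2-hydroxybenzaldehyde
ALDEHYDE_7 = "CCOc1cc(C=O)ccc1O"  # 3-ethoxy-4-hydroxybenzaldehyde
METHOXYACETIC_ACID = "COCC(=O)O"
ACETIC_ACID = "CC(=O)O"
GLYCOLIC_ACID = "OCC(=O)O"

DESIGNS: dict[str, str] = {
    "2": GLYCOLATE_ESTER_2,
    "2a": METHOXYACETATE_ESTER_2A,
    "2b": ACETATE_ESTER_2B,
    "3": ETHOXYPHENOL_IMIDAZOLE_3,
    "4": IMIDAZOLE_PHENOL_4,
}

BUILDING_BLOCKS: dict[str, str] = {
    "diketone-5": DIKETONE_5,
    "aldehyde-6": ALDEHYDE_6,
    "aldehyde-7": ALDEHYDE_7,
    "methoxyacetic-acid": METHOXYACETIC_ACID,
    "acetic-acid": ACETIC_ACID,
    "glycolic-acid": GLYCOLIC_ACID,
}


def mol(name_or_smiles: str) -> Chem.Mol:
    """Resolve a bundled compound name (``"2a"``, ``"diketone-5"``,
    ``"marinopyrrole_a"``, ``"lophine"``) or raw SMILES to a molecule."""
    table = {
        "marinopyrrole_a": MARINOPYRROLE_A,
        "lophine": LOPHINE,
        **DESIGNS,
        **BUILDING_BLOCKS,
    }
    return parse_structure(table.get(name_or_smiles, name_or_smiles))
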