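"""Virtual reaction schemes: substructure-query transforms with bookkeeping.

A :class:`ReactionScheme` is a mapped reaction-SMARTS transform with one
substructure query per reactant slot.  Schemes live in a plain-text,
user-extensible registry; each record carries a worked literature example
that is re-run at load time, so a registry that loads is a registry whose
chemistry is demonstrably right.  Products are sanitized molecules,
deduplicated by canonical key.  Virtual chemistry tracks strategic bond
formation only: fixed reagents (e.g. the ammonia source of an imidazole
condensation) and protecting-group logistics are deliberately outside the
model.

A :class:`SynthesisRoute` is the linear recipe recorded for each design:
at most three steps, the product of step *k* feeding step *k+1*.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

from rdkit import Chem
from rdkit.Chem import AllChem

from .chem import canonical_key, parse_structure

__all__ = [
    "ReactionScheme",
    "RouteStep",
    "SynthesisRoute",
    "SchemeError",
    "SlotMismatchError",
    "match_slots",
    "apply_scheme",
    "load_scheme_registry",
    "builtin_registry",
]

logger = logging.getLogger(__name__)

MAX_ROUTE_STEPS = 3


class SchemeError(ValueError):
    """Raised for malformed scheme definitions or failed load-time self-tests."""


class SlotMismatchError(ValueError):
    """Raised when a reactant does not match its slot query."""

    def __init__(self, scheme_id: str, slots: Sequence[int]):
        self.scheme_id = scheme_id
        self.slots = tuple(slots)
        super().__init__(
            f"scheme {scheme_id!r}: reactant(s) at slot(s) {list(slots)} do not match"
        )


@dataclass(frozen=True)
class ReactionScheme:
    """A virtual transform: id, name, mapped SMARTS, worked example."""

    id: str
    name: str
    smarts: str
    example_reactants: tuple[str, ...]
    example_product: str
    literature: str = ""
    #: heavy atoms contributed by fixed (non-slot) reagents, e.g. the two
    #: ring nitrogens an implicit ammonia source donates to an imidazole
    implicit_atoms: tuple[tuple[str, int], ...] = ()

    def __post_init__(self):
        try:
            rxn = AllChem.ReactionFromSmarts(self.smarts)
        except Exception as exc:  # pragma: no cover - rdkit raises various types
            raise SchemeError(f"scheme {self.id!r}: bad transform: {exc}") from exc
        if rxn is None or rxn.GetNumReactantTemplates() == 0:
            raise SchemeError(f"scheme {self.id!r}: bad transform SMARTS")
        object.__setattr__(self, "_rxn", rxn)
        object.__setattr__(
            self,
            "_slot_queries",
            tuple(rxn.GetReactantTemplate(i) for i in range(rxn.GetNumReactantTemplates())),
        )

    @property
    def arity(self) -> int:
        """Number of reactant slots (1-3)."""
        return len(self._slot_queries)

    def slot_query(self, slot: int) -> Chem.Mol:
        return self._slot_queries[slot]

    def self_test(self) -> None:
        """Re-run the worked example; raise SchemeError if it fails."""
        if len(self.example_reactants) != self.arity:
            raise SchemeError(
                f"scheme {self.id!r}: example has {len(self.example_reactants)} "
                f"reactants for {self.arity} slots"
            )
        reactants = [parse_structure(s) for s in self.example_reactants]
        products = apply_scheme(self, reactants)
        expected = canonical_key(parse_structure(self.example_product))
        if expected not in {canonical_key(p) for p in products}:
            raise SchemeError(
                f"scheme {self.id!r}: self-test failed — example product not reproduced"
            )


@dataclass(frozen=True)
class RouteStep:
    scheme_id: str
    reactants: tuple[str, ...]  # canonical SMILES, slot order
    product: str  # canonical SMILES

    def to_dict(self) -> dict:
        return {
            "scheme": self.scheme_id,
            "reactants": list(self.reactants),
            "product": self.product,
        }


@dataclass(frozen=True)
class SynthesisRoute:
    """Linear recipe of at most three steps."""

    steps: tuple[RouteStep, ...]

    def __post_init__(self):
        if not 1 <= len(self.steps) <= MAX_ROUTE_STEPS:
            raise ValueError(f"route length must be 1..{MAX_ROUTE_STEPS}")
        for prev, nxt in zip(self.steps, self.steps[1:]):
            if prev.product not in nxt.reactants:
                raise ValueError("route is not a linear chain")

    def __len__(self) -> int:
        return len(self.steps)

    @property
    def product(self) -> str:
        return self.steps[-1].product

    def extended(self, step: RouteStep) -> "SynthesisRoute":
        return SynthesisRoute(self.steps + (step,))

    def to_dict(self) -> dict:
        return {"n_steps": len(self.steps), "steps": [s.to_dict() for s in self.steps]}


def match_slots(scheme: ReactionScheme, mol: Chem.Mol) -> set[int]:
    """Indices of the scheme's reactant slots that ``mol`` can fill."""
    return {
        i
        for i in range(scheme.arity)
        if mol.HasSubstructMatch(scheme.slot_query(i))
    }


def apply_scheme(
    scheme: ReactionScheme, reactants: Sequence[Chem.Mol]
) -> list[Chem.Mol]:
    """Apply ``scheme`` to ordered ``reactants``; all distinct valid products.

    Products are sanitized and deduplicated by canonical key, returned in
    canonical-key order (deterministic regardless of reactant atom
    numbering).  A transform that fires but yields no chemically valid
    product returns an empty list with a logged reason.
    """
    if len(reactants) != scheme.arity:
        raise SlotMismatchError(scheme.id, list(range(scheme.arity)))
    bad = [i for i, m in enumerate(reactants) if not m.HasSubstructMatch(scheme.slot_query(i))]
    if bad:
        raise SlotMismatchError(scheme.id, bad)
    out: dict[str, Chem.Mol] = {}
    n_invalid = 0
    for product_set in scheme._rxn.RunReactants(tuple(reactants)):
        for product in product_set:
            try:
                Chem.SanitizeMol(product)
            except Exception:
                n_invalid += 1
                continue
            key = canonical_key(product)
            product.SetProp("canonical_key", key)
            out.setdefault(key, product)
    if not out and n_invalid:
        logger.warning(
            "scheme %s produced %d chemically invalid product(s) and nothing valid",
            scheme.id,
            n_invalid,
        )
    return [out[k] for k in sorted(out)]


def _parse_registry_line(line: str, lineno: int, source: str) -> ReactionScheme:
    parts = line.rstrip("\n").split("\t")
    if len(parts) < 5:
        raise SchemeError(f"{source}:{lineno}: expected >=5 tab-separated fields")
    scheme_id, name, smarts, example_reactants, example_product = parts[:5]
    literature = parts[5] if len(parts) > 5 else ""
    implicit = parts[6] if len(parts) > 6 else ""
    implicit_atoms = tuple(
        (el.strip(), int(n))
        for el, n in (item.split(":") for item in implicit.split(",") if item.strip())
    )
    return ReactionScheme(
        id=scheme_id.strip(),
        name=name.strip(),
        smarts=smarts.strip(),
        example_reactants=tuple(s.strip() for s in example_reactants.split(";") if s.strip()),
        example_product=example_product.strip(),
        literature=literature.strip(),
        implicit_atoms=implicit_atoms,
    )


def load_scheme_registry(path: str | Path) -> list[ReactionScheme]:
    """Load and validate a scheme registry file.

    Every scheme's worked example is re-run; any failure aborts the load
    with an error naming the offending scheme.
    """
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    return _load_registry_text(text, str(path))


def _load_registry_text(text: str, source: str) -> list[ReactionScheme]:
    schemes: list[ReactionScheme] = []
    seen: set[str] = set()
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        scheme = _parse_registry_line(line, lineno, source)
        if scheme.id in seen:
            raise SchemeError(f"{source}:{lineno}: duplicate scheme id {scheme.id!r}")
        scheme.self_test()
        seen.add(scheme.id)
        schemes.append(scheme)
    return schemes


def builtin_registry() -> list[ReactionScheme]:
    """The bundled scheme registry (imidazole condensation, O-acylation,
    amide coupling, Williamson ether)."""
    text = resources.files("npdesign.data").joinpath("schemes.tsv").read_text("utf-8")
    return _load_registry_text(text, "npdesign.data/schemes.tsv")
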