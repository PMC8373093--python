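"""Forward-synthetic de novo design by deterministic breadth-first search.

Starting from a seeded random sample of building blocks, the designer
grows molecules depth by depth: at each depth every surviving intermediate
is combined with every applicable building block under every applicable
reaction scheme, so each emitted candidate carries its own linear
synthesis route of at most three steps.  Construction is guided solely by
similarity to a template molecule — no target information enters the
search — which is what enables scaffold hopping: the search keeps whatever
chemistry brings the pharmacophore pattern closer to the template,
regardless of the ring systems involved.

Survivors per depth are the top ``beam_width`` products by fitness with a
total-order tie-break (score, route length, canonical key), so identical
configuration and seed reproduce identical output, byte for byte.  Setting
``beam_width=None`` disables pruning (exhaustive mode, used by the oracle
tests).  A depth-1 product is itself a valid final design; intermediates
that no scheme can extend still survive to ranking.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
from rdkit import Chem

from .cats import CATSVector, cats_distance, cats_vector
from .chem import canonical_key
from .reactions import (
    MAX_ROUTE_STEPS,
    ReactionScheme,
    RouteStep,
    SynthesisRoute,
    apply_scheme,
    match_slots,
)

__all__ = ["DesignConfig", "DesignCandidate", "fitness", "run_design", "select_top"]

logger = logging.getLogger(__name__)


def fitness(mol: Chem.Mol, template: Chem.Mol, scaling: str = "occurrence") -> float:
    """Template similarity in [0, 1]; 1 iff the CATS vectors coincide.

    The default kernel is ``1 / (1 + d)`` with ``d`` the CATS distance, so
    construction and final ranking optimize the same pharmacophore
    geometry.  Alternative graph-similarity kernels can be passed to
    :func:`run_design` via ``fitness_fn``.
    """
    d = cats_distance(cats_vector(mol, scaling), cats_vector(template, scaling))
    return 1.0 / (1.0 + d)


@dataclass(frozen=True)
class DesignConfig:
    """Configuration of a design run.

    ``n_start_fragments`` building blocks are sampled uniformly without
    replacement using ``seed`` — the only stochastic element of the whole
    run.  ``beam_width=None`` disables pruning.
    """

    template: Chem.Mol
    library: tuple[tuple[Chem.Mol, str], ...]
    schemes: tuple[ReactionScheme, ...]
    n_start_fragments: int = 200
    max_steps: int = MAX_ROUTE_STEPS
    beam_width: int | None = 50
    seed: int = 0
    scaling: str = "occurrence"

    def __post_init__(self):
        if not 1 <= self.max_steps <= MAX_ROUTE_STEPS:
            raise ValueError(f"max_steps must be 1..{MAX_ROUTE_STEPS}")
        object.__setattr__(self, "library", tuple(self.library))
        object.__setattr__(self, "schemes", tuple(self.schemes))


@dataclass(frozen=True)
class DesignCandidate:
    """A designed product with its route, scores and rank."""

    mol: Chem.Mol
    route: SynthesisRoute
    fitness: float
    cats_distance: float
    rank: int

    @property
    def key(self) -> str:
        return self.route.product


def _partner_products(
    scheme: ReactionScheme,
    mol: Chem.Mol,
    mol_slots: set[int],
    library: Sequence[tuple[Chem.Mol, str]],
    library_slots: dict[int, set[int]],
) -> list[tuple[Chem.Mol, tuple[str, ...]]]:
    """All products of placing ``mol`` in one slot and a library block in the
    other.  Only arity-1 and arity-2 schemes are enumerated combinatorially;
    for arity-3 schemes the two partner slots are both filled from the
    library (cubic blowup is deliberately not attempted)."""
    out: list[tuple[Chem.Mol, tuple[str, ...]]] = []
    if scheme.arity == 1:
        if 0 in mol_slots:
            for product in apply_scheme(scheme, [mol]):
                out.append((product, (canonical_key(mol),)))
        return out
    if scheme.arity != 2:
        return out
    for slot in mol_slots:
        other = 1 - slot
        for block_idx, (block, _ident) in enumerate(library):
            if other not in library_slots.get(block_idx, set()):
                continue
            ordered = [None, None]
            ordered[slot] = mol
            ordered[other] = block
            for product in apply_scheme(scheme, ordered):  # type: ignore[arg-type]
                out.append(
                    (product, tuple(canonical_key(m) for m in ordered))  # type: ignore[arg-type]
                )
    return out


def run_design(
    cfg: DesignConfig,
    fitness_fn: Callable[[Chem.Mol, Chem.Mol], float] | None = None,
) -> list[DesignCandidate]:
    """Breadth-first forward synthesis over depths 1..``max_steps``.

    Returns candidates deduplicated by canonical key, each with its best
    route (highest fitness, then shortest, then lexicographic), ranked by
    ascending CATS distance to the template.
    """
    if not cfg.library:
        raise ValueError("building-block library is empty")
    if not cfg.schemes:
        raise ValueError("scheme registry is empty")
    score = fitness_fn or (lambda m, t: fitness(m, t, cfg.scaling))

    rng = np.random.default_rng(cfg.seed)
    n_start = min(cfg.n_start_fragments, len(cfg.library))
    start_idx = sorted(rng.choice(len(cfg.library), size=n_start, replace=False).tolist())
    logger.info("design: %d start fragments of %d blocks", n_start, len(cfg.library))

    # slot-match table for the full library, computed once per scheme
    scheme_library_slots: dict[str, dict[int, set[int]]] = {}
    for scheme in cfg.schemes:
        table: dict[int, set[int]] = {}
        for i, (block, _ident) in enumerate(cfg.library):
            slots = match_slots(scheme, block)
            if slots:
                table[i] = slots
        scheme_library_slots[scheme.id] = table

    # frontier: canonical key -> (mol, route); depth 0 holds bare blocks
    frontier: dict[str, tuple[Chem.Mol, SynthesisRoute | None]] = {}
    for i in start_idx:
        mol, _ident = cfg.library[i]
        frontier.setdefault(canonical_key(mol), (mol, None))

    # candidate pool: key -> (mol, best route, fitness)
    pool: dict[str, tuple[Chem.Mol, SynthesisRoute, float]] = {}

    def route_sort_key(route: SynthesisRoute) -> tuple:
        return (len(route), tuple(s.to_dict().items() for s in route.steps).__repr__())

    for depth in range(1, cfg.max_steps + 1):
        produced: dict[str, tuple[Chem.Mol, SynthesisRoute, float]] = {}
        n_fired = 0
        for key in sorted(frontier):
            mol, route = frontier[key]
            for scheme in cfg.schemes:
                mol_slots = match_slots(scheme, mol)
                if not mol_slots:
                    continue
                for product, reactant_keys in _partner_products(
                    scheme, mol, mol_slots, cfg.library, scheme_library_slots[scheme.id]
                ):
                    n_fired += 1
                    pkey = canonical_key(product)
                    step = RouteStep(scheme.id, reactant_keys, pkey)
                    new_route = route.extended(step) if route else SynthesisRoute((step,))
                    fit = score(product, cfg.template)
                    prev = produced.get(pkey)
                    if prev is None or (
                        (-fit, *route_sort_key(new_route))
                        < (-prev[2], *route_sort_key(prev[1]))
                    ):
                        produced[pkey] = (product, new_route, fit)
        logger.info(
            "depth %d: %d reaction applications, %d distinct products", depth, n_fired, len(produced)
        )
        for pkey, entry in produced.items():
            prev = pool.get(pkey)
            if prev is None or (
                (-entry[2], *route_sort_key(entry[1]))
                < (-prev[2], *route_sort_key(prev[1]))
            ):
                pool[pkey] = entry
        survivors = sorted(
            produced.items(),
            key=lambda kv: (-kv[1][2], len(kv[1][1]), kv[0]),
        )
        if cfg.beam_width is not None:
            survivors = survivors[: cfg.beam_width]
        frontier = {k: (m, r) for k, (m, r, _f) in survivors}
        if not frontier:
            break

    if not pool:
        logger.warning(
            "design produced zero products (library %d blocks, %d schemes)",
            len(cfg.library),
            len(cfg.schemes),
        )
        return []

    template_vec = cats_vector(cfg.template, cfg.scaling)
    ranked: list[DesignCandidate] = []
    for key in sorted(pool):
        mol, route, fit = pool[key]
        d = cats_distance(template_vec, cats_vector(mol, cfg.scaling))
        ranked.append(DesignCandidate(mol, route, fit, d, rank=-1))
    ranked.sort(key=lambda c: (c.cats_distance, c.key))
    return [replace(c, rank=i + 1) for i, c in enumerate(ranked)]


def select_top(
    candidates: Sequence[DesignCandidate],
    k: int,
    distance_cutoff: float | None = None,
) -> list[DesignCandidate]:
    """First ``k`` candidates by ascending CATS distance, optionally keeping
    only those below ``distance_cutoff``.  ``k`` larger than the pool simply
    returns everything."""
    ordered = sorted(candidates, key=lambda c: (c.cats_distance, c.key))
    if distance_cutoff is not None:
        ordered = [c for c in ordered if c.cats_distance < distance_cutoff]
    return ordered[:k]
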