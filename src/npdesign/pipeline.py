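"""End-to-end pipeline: design -> CATS ranking -> scaffold statistics ->
target prediction, with a reproducibility manifest.

The pipeline is the computational half of a design-make-test-analyze
cycle: it constructs candidates forward-synthetically, ranks them against
the template, summarizes their scaffold population, and predicts targets
for the top-ranked designs.  Every artifact it writes is deterministic
under a fixed configuration, and the manifest records the config hash, all
seeds, and a content hash per output file, so two runs of the same config
are verifiably identical (equal manifest hashes).
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Any

import pandas as pd

from . import compounds
from .chem import parse_structure, read_library
from .designer import DesignConfig, run_design, select_top
from .fixtures import FixtureSpec, generate_blocks, generate_reference_library, read_reference_library
from .reactions import builtin_registry, load_scheme_registry
from .scaffolds import murcko_scaffold, scaffold_stats
from .som import CascadeTargetPredictor

__all__ = ["DEFAULT_CONFIG", "run_pipeline", "demo_config"]

logger = logging.getLogger(__name__)

DEFAULT_CONFIG: dict[str, Any] = {
    "template": "marinopyrrole_a",
    "blocks": None,  # path to a TSV library, or None to generate fixtures
    "schemes": None,  # path to a scheme registry, or None for the bundled one
    "refs": None,  # path to an annotated reference library, or None to generate
    "seed": 7,
    "n_blocks": 40,
    "n_start": 200,
    "max_steps": 3,
    "beam": 50,
    "top_k": 100,
    "distance_cutoff": None,
    "n_predict": 3,  # predict targets for this many top-ranked designs
    "som_grid": [6, 6],
    "som_epochs": 30,
    "n_background": 300,
    "p_max": 0.05,
    "ref_targets": 5,
    "ref_per_target": 20,
    "ref_separation": 2.0,
}


def demo_config() -> dict[str, Any]:
    """A small, fully self-contained configuration (bundled fixtures)."""
    cfg = dict(DEFAULT_CONFIG)
    cfg.update(n_blocks=24, n_start=24, beam=30, max_steps=2, som_epochs=20, n_background=200)
    return cfg


def _sha256(data: bytes) -> str:
    return hashlib.sha256(data).hexdigest()


def _config_hash(config: dict[str, Any]) -> str:
    return _sha256(json.dumps(config, sort_keys=True, default=str).encode())


def run_pipeline(config: dict[str, Any], out_dir: str | Path) -> dict[str, Any]:
    """Run the full pipeline; returns the manifest (also written to disk).

    Outputs in ``out_dir``: ``candidates.csv`` (key, fitness, CATS
    distance, rank, route length), ``routes.json`` (one record per
    candidate), ``scaffolds.csv`` (scaffold frequency table),
    ``predictions.csv`` (per-design target predictions), and
    ``manifest.json``.
    """
    cfg = {**DEFAULT_CONFIG, **config}
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])

    template = compounds.mol(cfg["template"])
    if cfg["blocks"]:
        library = read_library(cfg["blocks"])
    else:
        library = generate_blocks(FixtureSpec(seed=seed, n_building_blocks=int(cfg["n_blocks"])))
    schemes = load_scheme_registry(cfg["schemes"]) if cfg["schemes"] else builtin_registry()

    candidates = run_design(
        DesignConfig(
            template=template,
            library=tuple(library),
            schemes=tuple(schemes),
            n_start_fragments=int(cfg["n_start"]),
            max_steps=int(cfg["max_steps"]),
            beam_width=None if cfg["beam"] in (None, "none") else int(cfg["beam"]),
            seed=seed,
        )
    )
    logger.info("pipeline: %d candidates", len(candidates))
    top = select_top(candidates, int(cfg["top_k"]), cfg["distance_cutoff"])

    cand_table = pd.DataFrame(
        {
            "canonical_key": [c.key for c in candidates],
            "fitness": [round(c.fitness, 6) for c in candidates],
            "cats_distance": [round(c.cats_distance, 6) for c in candidates],
            "rank": [c.rank for c in candidates],
            "route_steps": [len(c.route) for c in candidates],
        }
    )
    cand_table.to_csv(out / "candidates.csv", index=False)

    routes = [
        {"canonical_key": c.key, "rank": c.rank, "route": c.route.to_dict()}
        for c in candidates
    ]
    (out / "routes.json").write_text(json.dumps(routes, indent=1, sort_keys=True) + "\n")

    if top:
        table, n_unique = scaffold_stats([c.mol for c in top])
        table.to_csv(out / "scaffolds.csv", index=False)
    else:
        n_unique = 0
        pd.DataFrame(columns=["scaffold", "count", "fraction"]).to_csv(
            out / "scaffolds.csv", index=False
        )

    refs = (
        read_reference_library(cfg["refs"])
        if cfg["refs"]
        else generate_reference_library(
            FixtureSpec(
                seed=seed,
                n_reference_targets=int(cfg["ref_targets"]),
                compounds_per_target=int(cfg["ref_per_target"]),
                separation=float(cfg["ref_separation"]),
            )
        )
    )
    predictor = CascadeTargetPredictor(
        grid_shape=tuple(cfg["som_grid"]), epochs=int(cfg["som_epochs"]), seed=seed
    ).fit(refs)
    rows = []
    for c in top[: int(cfg["n_predict"])]:
        for p in predictor.predict(
            c.mol, n_background=int(cfg["n_background"]), seed=seed, p_max=cfg["p_max"]
        ):
            rows.append(
                {
                    "canonical_key": c.key,
                    "rank": c.rank,
                    "target": p.target,
                    "score": round(p.score, 6),
                    "p_value": round(p.p_value, 6),
                }
            )
    pd.DataFrame(rows, columns=["canonical_key", "rank", "target", "score", "p_value"]).to_csv(
        out / "predictions.csv", index=False
    )

    manifest: dict[str, Any] = {
        "config": cfg,
        "config_hash": _config_hash(cfg),
        "seed": seed,
        "counts": {
            "blocks": len(library),
            "schemes": len(schemes),
            "candidates": len(candidates),
            "top": len(top),
            "unique_scaffolds_top": n_unique,
            "reference_compounds": len(refs),
        },
        "outputs": {
            name: _sha256((out / name).read_bytes())
            for name in ("candidates.csv", "routes.json", "scaffolds.csv", "predictions.csv")
        },
    }
    manifest["manifest_hash"] = _sha256(
        json.dumps(manifest, sort_keys=True, default=str).encode()
    )
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True) + "\n")
    return manifest
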