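"""Pipeline orchestration, config validation, and run manifests.

Three recipes tie the library together: ``cluster_analysis`` (synthesize or
load a fluorescence table, symmetrize, run the cluster permutation test),
``overlap_analysis`` (synthetic chain with planted surfaces, interface
overlap Z/p), and ``flux_analysis`` (paired PPI-on/PPI-off desk-scale
simulations, flux ratios).  Every run emits a manifest carrying the tool
version, the config, all seeds, input digests and output paths, so results
reproduce from config + seed alone.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import numpy as np

from . import __version__
from .matrix import PPIMatrix, symmetrize
from .permutation import PermutationSpec, cluster_permutation_test
from .surfaces import RandomSurfaceSpec, overlap_significance
from .synth import (PlantedSurface, StructureGeneratorSpec,
                    default_cluster_spec, synth_mfi, synth_structure)

RECIPES = ("cluster_analysis", "overlap_analysis", "flux_analysis")

_SCHEMA = {
    "cluster_analysis": {"seed", "n_perm", "cluster_size", "matrix_path"},
    "overlap_analysis": {"seed", "n_sets", "chain_length", "shared_fraction",
                         "n_surfaces"},
    "flux_analysis": {"seed", "n_steps", "copies_per_type", "mfi"},
}


def _digest(obj) -> str:
    return hashlib.sha256(json.dumps(obj, sort_keys=True, default=str)
                          .encode()).hexdigest()[:16]


def validate_config(recipe: str, config: dict) -> None:
    if recipe not in RECIPES:
        raise ValueError(f"unknown recipe {recipe!r}; choose from {RECIPES}")
    unknown = set(config) - _SCHEMA[recipe]
    if unknown:
        raise ValueError(f"unknown config keys for {recipe}: {sorted(unknown)}")
    if "seed" in config and not isinstance(config["seed"], int):
        raise ValueError("seed must be an integer")


def _manifest(recipe, config, seeds, outputs, inputs=None) -> dict:
    return {
        "tool_version": __version__,
        "recipe": recipe,
        "config": config,
        "config_hash": _digest(config),
        "seeds": seeds,
        "input_digests": inputs or {},
        "timestamp_unix": int(time.time()),
        "output_paths": outputs,
    }


def run_pipeline(recipe: str, config: dict | None = None,
                 out_dir=None) -> dict:
    """Run a named recipe end to end; returns {result, manifest}."""
    config = dict(config or {})
    validate_config(recipe, config)
    seed = int(config.get("seed", 0))
    inputs = {}

    if recipe == "cluster_analysis":
        n_perm = int(config.get("n_perm", 10_000))
        if config.get("matrix_path"):
            matrix = PPIMatrix.read_tsv(config["matrix_path"])
            inputs["matrix"] = _digest(matrix.to_frame().to_csv())
            cluster = matrix.proteins[:int(config.get("cluster_size", 5))]
        else:
            spec = default_cluster_spec(seed=seed)
            matrix = symmetrize(synth_mfi(spec), min_cells=spec.min_cells)
            cluster = list(spec.clusters[0])
        pairs = [(a, b) for i, a in enumerate(cluster)
                 for b in cluster[i + 1:] if not matrix.is_missing(a, b)]
        res = cluster_permutation_test(
            matrix, pairs, PermutationSpec(n_perm=n_perm, seed=seed))
        result = res.to_dict()

    elif recipe == "overlap_analysis":
        n_sets = int(config.get("n_sets", 10_000))
        length = int(config.get("chain_length", 60))
        f = float(config.get("shared_fraction", 1.0))
        n_surf = int(config.get("n_surfaces", 4))
        sspec = StructureGeneratorSpec(
            chain_length=length, seed=seed,
            surfaces=tuple(PlantedSurface(center=length // 2, radius=10.0,
                                          shared_fraction=f if k else 0.0)
                           for k in range(n_surf)))
        structure, surfaces = synth_structure(sspec)
        res = overlap_significance(
            surfaces, structure, RandomSurfaceSpec(n_sets=n_sets, seed=seed))
        result = res.to_dict()

    elif recipe == "flux_analysis":
        from .sim import PPIEnergyMap, ReactionScheme, desk_config, flux_ratio, run as sim_run

        cfg = desk_config(n_steps=int(config.get("n_steps", 80_000)),
                          copies_per_type=int(config.get("copies_per_type", 6)))
        mfi = np.asarray(config.get("mfi", np.full((10, 10), 1200.0)), dtype=float)
        energy = PPIEnergyMap.from_mfi(mfi)
        scheme = ReactionScheme.sample(seed=seed)
        on = sim_run(cfg, scheme, energy, mode="ppi_on", seed=seed)
        off = sim_run(cfg, scheme, energy, mode="ppi_off", seed=seed)
        ratios = flux_ratio(on, off)
        result = {
            "flux_ratios": [None if np.isnan(r) else (r if np.isfinite(r) else "inf")
                            for r in ratios],
            "reaction_counts_on": on.reaction_counts.tolist(),
            "reaction_counts_off": off.reaction_counts.tolist(),
        }

    outputs = {}
    manifest = _manifest(recipe, config, {"root_seed": seed}, outputs, inputs)
    bundle = {"result": result, "manifest": manifest}
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        path = out_dir / f"{recipe}.json"
        manifest["output_paths"] = {"result": str(path)}
        path.write_text(json.dumps(bundle, indent=2, sort_keys=True))
    return bundle
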