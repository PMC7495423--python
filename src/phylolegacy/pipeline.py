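"""File-based orchestration of the analysis stages.

Each stage reads its inputs from, and writes its outputs to, a run
directory.  ``run_all`` chains every stage and writes a manifest (config
hash, seed, package version, artifact list) sufficient to reproduce the
run bit-exactly in deterministic mode.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .climate import climate_stability, vocc
from .drivers import (build_driver_stack, lmg_importance,
                      predictor_correlations)
from .io import (read_climate_stack, read_community, read_config, read_tree,
                 read_ascii_grid, write_ascii_grid, write_climate_stack,
                 write_community, write_config, write_tree)
from .refugia import detect_refugia, distance_to_refugia, mean_range_size
from .synthetic import Scenario, ScenarioConfig, generate_scenario, standard_scenario
from .turnover import compute_turnover_table

logger = logging.getLogger(__name__)

__all__ = ["default_config", "run_simulate", "run_turnover", "run_climate",
           "run_refugia", "run_drivers", "run_all", "load_scenario_inputs"]


def default_config(outdir: str | Path, seed: int = 0, **scenario_kwargs) -> dict:
    """Pipeline config for the bundled demo scenario."""
    sc = standard_scenario(seed=seed, **scenario_kwargs)
    return {
        "outdir": str(outdir),
        "scenario": sc.to_dict(),
        "k_neighbors": 24,
        "n_axes": 6,
        "pair_level": False,
        "mode": "deterministic",
        "m_min": 1,
        "m_max": 10,
        "stability_mode": "sd",
        "rate_selection": "mean",
        "lmg_level": "group",
    }


def _scenario_config(cfg: dict, seed: int | None) -> ScenarioConfig:
    sc = ScenarioConfig.from_dict(cfg["scenario"])
    if seed is not None:
        sc.seed = seed
    return sc


# ----------------------------------------------------------------------
def run_simulate(cfg: dict, seed: int | None = None) -> list[Path]:
    """Generate the synthetic study and write its artifacts."""
    out = Path(cfg["outdir"])
    out.mkdir(parents=True, exist_ok=True)
    sc = _scenario_config(cfg, seed)
    scen = generate_scenario(sc)
    paths = []

    write_community(out / "community.csv", scen.community)
    write_tree(out / "tree.nwk", scen.tree)
    rows = [(sp, int(c)) for sp, cells in sorted(scen.true_refugia.items())
            for c in cells]
    pd.DataFrame(rows, columns=["species", "cell_id"]).to_csv(
        out / "true_refugia.csv", index=False)
    write_config(out / "scenario.yaml", sc.to_dict())
    paths += [out / "community.csv", out / "tree.nwk",
              out / "true_refugia.csv", out / "scenario.yaml"]
    paths += write_climate_stack(out / "climate", scen.climate)
    return paths


def load_scenario_inputs(cfg: dict) -> tuple:
    """(community, tree, climate stack) from a run directory."""
    out = Path(cfg["outdir"])
    community = read_community(out / "community.csv")
    sc = ScenarioConfig.from_dict(read_config(out / "scenario.yaml"))
    ages = (np.arange(sc.n_slices)[::-1]) * sc.step_years
    paths = {
        var: [out / "climate" / f"{var}_{int(a):06d}.asc" for a in ages]
        for var in sc.variables
    }
    stack = read_climate_stack(paths, ages)
    tree = read_tree(out / "tree.nwk", community_species=community.species_ids)
    return community, tree, stack


def run_turnover(cfg: dict) -> Path:
    community, tree, stack = load_scenario_inputs(cfg)
    env = stack.present_site_values(community.site_ids)
    table = compute_turnover_table(
        tree, community, env, k=int(cfg.get("k_neighbors", 24)),
        n_axes=cfg.get("n_axes", 6),
        pair_level=bool(cfg.get("pair_level", False)),
    )
    path = Path(cfg["outdir"]) / "turnover.csv"
    table.to_csv(path, index=False)
    return path


def run_climate(cfg: dict) -> list[Path]:
    _, _, stack = load_scenario_inputs(cfg)
    out = Path(cfg["outdir"])
    vel = vocc(stack)
    stab = climate_stability(stack, mode=cfg.get("stability_mode", "sd"))
    write_ascii_grid(out / "vocc.asc", vel.v_final, stack.grid)
    write_ascii_grid(out / "climstab.asc", stab.combined, stack.grid)
    return [out / "vocc.asc", out / "climstab.asc"]


def run_refugia(cfg: dict, seed: int | None = None) -> Path:
    community, _, stack = load_scenario_inputs(cfg)
    out = Path(cfg["outdir"])
    mode = cfg.get("mode", "deterministic")
    m_range = range(int(cfg.get("m_min", 1)), int(cfg.get("m_max", 10)) + 1)
    base_seed = seed if seed is not None else int(cfg["scenario"].get("seed", 0))
    rows = []
    for j, sp in enumerate(community.species_ids):
        res = detect_refugia(
            sp, community.presence[:, j].astype(float), stack,
            m_range=m_range, mode=mode, seed=base_seed,
            rate_selection=cfg.get("rate_selection", "mean"),
        )
        for cell, d2a in zip(res.retained, res.d2_access):
            rows.append((sp, int(cell), res.m_star, res.d2_initial, d2a))
    df = pd.DataFrame(rows, columns=["species", "cell_id", "m_star",
                                     "D2_initial", "D2_access"])
    path = out / "refugia.csv"
    df.to_csv(path, index=False)
    return path


def run_drivers(cfg: dict) -> list[Path]:
    community, _, stack = load_scenario_inputs(cfg)
    out = Path(cfg["outdir"])
    turnover = pd.read_csv(out / "turnover.csv")
    ref = pd.read_csv(out / "refugia.csv")
    refugia = {sp: g["cell_id"].to_numpy()
               for sp, g in ref.groupby("species")}
    dist_ref = distance_to_refugia(refugia, community, stack.grid)
    range_s = mean_range_size(community)
    v_final, _ = read_ascii_grid(out / "vocc.asc")
    stab, _ = read_ascii_grid(out / "climstab.asc")
    stack_df = build_driver_stack(turnover, dist_ref, v_final, stab, range_s,
                                  community.site_ids)
    stack_df.to_csv(out / "drivers.csv", index=False)
    level = cfg.get("lmg_level", "group")
    frames = [lmg_importance(stack_df, use_climstab=u, level=level).as_frame()
              for u in (False, True)]
    pd.concat(frames, ignore_index=True).to_csv(out / "importance.csv",
                                                index=False)
    predictor_correlations(stack_df).to_csv(out / "correlations.csv")
    return [out / "drivers.csv", out / "importance.csv", out / "correlations.csv"]


def run_all(cfg: dict, seed: int | None = None) -> dict:
    """Run every stage; returns the manifest (also written to disk)."""
    out = Path(cfg["outdir"])
    artifacts = [str(p) for p in run_simulate(cfg, seed=seed)]
    artifacts.append(str(run_turnover(cfg)))
    artifacts += [str(p) for p in run_climate(cfg)]
    artifacts.append(str(run_refugia(cfg, seed=seed)))
    artifacts += [str(p) for p in run_drivers(cfg)]
    cfg_bytes = json.dumps(cfg, sort_keys=True, default=str).encode()
    manifest = {
        "version": __version__,
        "config_sha256": hashlib.sha256(cfg_bytes).hexdigest(),
        "seed": seed if seed is not None else cfg["scenario"].get("seed"),
        "mode": cfg.get("mode", "deterministic"),
        "artifacts": sorted(artifacts),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
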