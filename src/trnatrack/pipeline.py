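"""End-to-end pipeline orchestration with manifests and deterministic seeds.

Each stage reads/writes the formats defined in :mod:`trnatrack.io`; every
output file is listed in a manifest with its checksum and the configuration
hash, so a run is fully reproducible from its config + seed.
"""

from __future__ import annotations

import logging
import time
from pathlib import Path

import pandas as pd

from . import io
from .config import AnalysisConfig, ImagingConfig, TrackingConfig
from .diffusion import apparent_D_table, fit_gamma_mixture
from .geometry import CellGeometry
from .linking import link, trajectories_to_table
from .simulate import simulate_localized_tracks
from .spatial import enrichment, normalize_positions, slow_fast_split

log = logging.getLogger("trnatrack")

STAGES = ("simulate", "track", "diffuse", "spatial")


class PipelineError(RuntimeError):
    pass


def run_demo(out_dir, seed: int = 0,
             imaging: ImagingConfig | None = None,
             tracking: TrackingConfig | None = None,
             analysis: AnalysisConfig | None = None,
             n_cells: int = 200,
             species_mix=((8.0, 0.88), (0.5, 0.12)),
             geometry: CellGeometry | None = None) -> dict:
    """Simulate a field, track it and analyse diffusion + spatial stats.

    Returns the manifest dict (also written to ``manifest.json``). All
    randomness derives from ``seed``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    imaging = imaging or ImagingConfig()
    tracking = tracking or TrackingConfig()
    analysis = analysis or AnalysisConfig()
    geometry = geometry or CellGeometry()
    chash = io.config_hash(imaging, tracking, analysis, seed)
    manifest = {"config_hash": chash, "seed": seed, "stages": {}, "files": {}}
    io.write_config(out / "config.yaml", imaging, tracking, analysis,
                    extra={"seed": seed, "n_cells": n_cells,
                           "species_mix": [list(p) for p in species_mix]})

    t0 = time.time()
    field = simulate_localized_tracks(
        geometry, [tuple(p) for p in species_mix],
        mean_emitters_per_cell=1.5, n_cells=n_cells, config=imaging,
        seed=seed)
    io.write_table(out / "localizations.csv", field.localizations)
    io.write_table(out / "cells.csv", field.cells)
    manifest["stages"]["simulate"] = {"seconds": time.time() - t0,
                                      "n_localizations": len(field.localizations)}

    t0 = time.time()
    trajs = link(field.localizations, tracking)
    traj_table = trajectories_to_table(trajs)
    io.write_table(out / "trajectories.csv", traj_table)
    manifest["stages"]["track"] = {"seconds": time.time() - t0,
                                   "n_trajectories": len(trajs)}

    t0 = time.time()
    dtab = apparent_D_table(trajs, n_steps=analysis.n_steps_for_D,
                            dt=imaging.frame_interval,
                            mobility_threshold=analysis.mobility_threshold)
    io.write_table(out / "d_app.csv", dtab)
    report = {}
    if len(dtab) >= 50:
        fit = fit_gamma_mixture(dtab["D_app_um2_s"], m=2, seed=seed)
        report["gamma_mixture"] = {
            "means_um2_s": fit.means.tolist(),
            "weights": fit.weights.tolist(),
            "log_likelihood": fit.log_likelihood,
            "converged": bool(fit.converged),
        }
    manifest["stages"]["diffuse"] = {"seconds": time.time() - t0,
                                     "n_estimates": len(dtab)}

    t0 = time.time()
    cells = field.cells.set_index("cell_id")
    rows = []
    for tr in trajs:
        if tr.cell_id is None or tr.cell_id < 0:
            continue
        c = cells.loc[tr.cell_id]
        geom = CellGeometry(length=c["length_um"], radius=c["radius_um"],
                            center=(c["center_x_um"], c["center_y_um"]),
                            orientation=c["orientation_rad"])
        unit, _ = normalize_positions(tr.xy, geom)
        unit["traj_id"] = tr.traj_id
        unit["cell_id"] = tr.cell_id
        rows.append(unit)
    positions = pd.concat(rows, ignore_index=True) if rows else pd.DataFrame(
        columns=["x_norm", "y_norm", "traj_id", "cell_id"])
    io.write_table(out / "unit_cell.csv", positions)
    if len(positions) >= 100 and len(dtab):
        slow, fast, frac = slow_fast_split(positions, dtab,
                                           threshold=analysis.mobility_threshold)
        report["slow_fraction"] = frac
        for name, sub in (("slow", slow), ("fast", fast), ("all", positions)):
            if len(sub) >= 100:
                s = enrichment(sub["y_norm"].to_numpy(),
                               cutoff=analysis.periphery_cutoff, seed=seed)
                report[f"enrichment_{name}"] = {
                    "periphery_pct": s.enrichment_periphery_pct,
                    "midcell_pct": s.enrichment_midcell_pct,
                    "n": s.n_positions,
                }
    io.write_json(out / "report.json", report)
    manifest["stages"]["spatial"] = {"seconds": time.time() - t0,
                                     "n_positions": len(positions)}

    for f in sorted(out.iterdir()):
        if f.name != "manifest.json":
            manifest["files"][f.name] = io.file_checksum(f)
    io.write_json(out / "manifest.json", manifest)
    return manifest
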