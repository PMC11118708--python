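"""End-to-end synthetic pipeline: maps -> grid -> stats -> model -> textures.

Each stage derives its own child seed deterministically from the single
configured seed, so stages can be rerun in isolation and the whole run is
bit-reproducible.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from . import connectivity, ffmodel, retinotopy, synthetic, textures
from .io import RunConfig, RunReport, write_cell_table, write_maps, write_results
from .oimaps import rescale_condition_maps, vector_sum_po

__all__ = ["run_pipeline", "stage_seeds"]


def stage_seeds(seed: int) -> dict[str, int]:
    """Deterministic per-stage child seeds fanned out from one seed."""
    names = ["simulate", "maps", "grid", "stats", "model", "textures"]
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {n: int(c.generate_state(1)[0]) for n, c in zip(names, children)}


def run_pipeline(cfg: RunConfig) -> RunReport:
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = stage_seeds(cfg.seed)
    report = RunReport(seed=cfg.seed)

    # --- simulate ---------------------------------------------------------
    map_cfg = synthetic.MapSimConfig(height=cfg.map_height, width=cfg.map_width,
                                     noise_sd=cfg.map_noise_sd,
                                     seed=seeds["simulate"])
    map_set, map_gt = synthetic.simulate_orientation_map(map_cfg)
    inj_center = (cfg.map_width / 2.0, cfg.map_height / 2.0)
    inj_radius = min(cfg.map_width, cfg.map_height) / 10.0
    conn_cfg = synthetic.ConnectivitySimConfig(
        n_cells=cfg.n_cells, bias_strength=cfg.bias_strength,
        like_to_like_fwhm=cfg.like_to_like_fwhm,
        injection_center=inj_center, injection_radius=inj_radius,
        seed=seeds["simulate"] + 1)
    cells, cell_gt = synthetic.simulate_labeled_cells(conn_cfg, map_gt.true_po_map)
    write_maps(out / "condition_maps.npz", maps=map_set.maps,
               true_po=map_gt.true_po_map)
    write_cell_table(cells.table, out / "cells.csv")
    report.add_output(out / "condition_maps.npz")
    report.add_output(out / "cells.csv")
    report.stages["simulate"] = {"seed": seeds["simulate"],
                                 "n_cells": cells.n_cells,
                                 "injection_po": cells.injection_po}

    # --- maps -------------------------------------------------------------
    vessel = np.zeros(map_set.shape, dtype=bool)
    scaled = rescale_condition_maps(map_set.maps - map_set.maps.min(axis=0), vessel)
    po_map = vector_sum_po(scaled, vessel)
    write_maps(out / "po_map.npz", po=po_map.po, magnitude=po_map.magnitude,
               vessel_mask=po_map.vessel_mask)
    report.add_output(out / "po_map.npz")
    report.stages["maps"] = {"n_undefined": int(po_map.undefined.sum())}

    # --- grid -------------------------------------------------------------
    outline = retinotopy.RetinotopicOutline.rectangle(
        (0.0, 0.0), cfg.map_width - 1.0, cfg.map_height - 1.0,
        parallel_extent_deg=2.5, orth_extent_deg=1.5)
    coarse = retinotopy.generate_elliptic_grid(outline, 51, 31)
    grid = retinotopy.resample_grid(coarse, cfg.grid_resolution_deg)
    cell_xy = cells.table[["x_px", "y_px"]].to_numpy()
    assignment = retinotopy.assign_cells(cell_xy, grid)
    write_maps(out / "grid.npz", xy=grid.xy, vf=grid.vf)
    report.add_output(out / "grid.npz")
    report.stages["grid"] = {"shape": list(grid.shape),
                             "converged": bool(grid.converged),
                             "iterations": grid.iterations_used}
    if not grid.converged:
        report.warnings.append("elliptic grid did not converge")

    # --- stats ------------------------------------------------------------
    cell_po = cells.table["po_deg"].to_numpy()
    obs = connectivity.circ_stats(cell_po)
    frac = connectivity.fraction_within(cell_po, cells.injection_po)
    field_mask = np.ones(map_set.shape, dtype=bool)
    resample = connectivity.pixel_resample_null(po_map, field_mask,
                                                m=min(cells.n_cells, 500),
                                                n_rep=cfg.n_resample,
                                                seed=seeds["stats"])
    shifts = connectivity.pattern_shift_null(po_map, cell_xy,
                                             n_shifts=cfg.n_shifts,
                                             seed=seeds["stats"] + 1)
    obs_hist = connectivity.po_histogram(cell_po)
    inj_hist = connectivity.po_histogram([cells.injection_po] * 100,
                                         source="injection_pixels")
    _, l2l = connectivity.like_to_like_sim(inj_hist, obs_hist,
                                           fwhm=cfg.like_to_like_fwhm)
    stats_out = {
        "fraction_within_22_5": frac,
        "observed": {"mrl": obs.mrl, "csd": obs.csd, "mean_po": obs.mean_po},
        "pixel_resample": resample.exceedance(obs),
        "pattern_shift": shifts.exceedance(obs),
        "like_to_like_chisq": {"statistic": l2l.statistic, "dof": l2l.dof,
                               "p": l2l.p},
    }
    write_results(stats_out, out / "stats.json")
    report.add_output(out / "stats.json")
    report.stages["stats"] = {"seed": seeds["stats"], **stats_out}

    # --- model ------------------------------------------------------------
    rng = np.random.default_rng(seeds["model"])
    n_v1 = min(cfg.n_v1_model_cells, cells.n_cells)
    pick = rng.choice(cells.n_cells, size=n_v1, replace=False)
    v1_cells = []
    for idx in pick:
        row = cells.table.iloc[idx]
        vf = assignment.vf_position[idx]
        gamma, _, flag = ffmodel.estimate_aspect_ratio(
            synthetic.cosine_tuning(row["po_deg"]))
        if flag:
            report.warnings.append(f"flat tuning for cell {idx}; gamma=1")
        v1_cells.append(ffmodel.V1Cell(ffmodel.GaborParams(
            xc=float(vf[1]), yc=float(vf[0]), theta_c=float(row["po_deg"]),
            gamma_c=gamma, sigma_x=cfg.sigma_x, sf=cfg.sf)))
    v1_tunings = np.stack([ffmodel.grating_tuning(c) for c in v1_cells])
    targets = rng.uniform(0.0, 180.0, size=cfg.n_v2_model_pixels)
    v2_tunings = np.stack([synthetic.simulate_v2_pixel(
        v1_tunings, synthetic.like_to_like_weights(
            [c.params.theta_c for c in v1_cells], t))[0] for t in targets])
    cv = ffmodel.loo_cross_validate(v1_tunings, v2_tunings,
                                    v1_grating_responses=v1_tunings)
    wm = ffmodel.compute_weights(v1_tunings, v2_tunings)
    write_maps(out / "weights.npz", w=wm.w, v1_tunings=v1_tunings,
               v2_tunings=v2_tunings)
    report.add_output(out / "weights.npz")
    report.stages["model"] = {
        "seed": seeds["model"],
        "mean_relative_error": cv.mean_relative_error,
        "median_po_error": float(np.median(cv.po_abs_error)),
        "excluded_cells": wm.excluded_cells,
    }

    # --- textures ---------------------------------------------------------
    tex_seed = seeds["textures"]
    kinds = ["oriented-composite", "thresholded-noise", "plaid"]
    raster = textures.image_raster(cfg.texture_size, cfg.px_per_deg)
    tex_cells = v1_cells[:min(6, len(v1_cells))]
    w_v2 = synthetic.like_to_like_weights(
        [c.params.theta_c for c in tex_cells], targets[0])
    v1_mis, v2_mis = [], []
    for f in range(cfg.n_texture_families):
        fam = synthetic.simulate_texture_family(
            cfg.n_texture_pairs, kinds[f % len(kinds)], seed=tex_seed + f,
            size=cfg.texture_size)
        rotated = textures.rotate_family(fam)
        resp = textures.family_responses(tex_cells, w_v2, rotated, raster)
        for ci in range(len(tex_cells)):
            v1_mis.append(textures.modulation_index(resp["v1"][ci, ..., 0],
                                                    resp["v1"][ci, ..., 1]).mi)
        v2_mis.append(textures.modulation_index(resp["v2"][..., 0],
                                                resp["v2"][..., 1]).mi)
    tex_out = {"v1_mis": v1_mis, "v2_mis": v2_mis}
    if len(v1_mis) >= 2 and len(v2_mis) >= 2:
        cmp_ = textures.compare_populations(v1_mis, v2_mis)
        tex_out["t"] = cmp_.t
        tex_out["p"] = cmp_.p
    write_results(tex_out, out / "textures.json")
    report.add_output(out / "textures.json")
    report.stages["textures"] = {"seed": tex_seed,
                                 "mean_v1_mi": float(np.mean(v1_mis)),
                                 "mean_v2_mi": float(np.mean(v2_mis))}

    report.to_json(out / "report.json")
    return report
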