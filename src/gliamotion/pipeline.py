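"""End-to-end orchestration: config schema, logging, and ``run_pipeline``.

A single YAML (or dict) config drives synthesis, preprocessing, and the
metric stages; every run writes tidy CSV tables, a JSON summary, and a log
recording the seed, package version, and parameters, so a rerun with the
same config and seed is byte-identical.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .chemotaxis import ChemotaxisGeometry, chemotaxis_timecourse
from .motility import (cumulative_survey, motion_maps, ramification_trace,
                       surveillance_index)
from .preprocess import preprocess_stack, write_tiff
from .synthetic import SynthConfig, generate_swc_population, save_ground_truth, \
    simulate_chemotaxis, simulate_surveillance

log = logging.getLogger("gliamotion")

__all__ = ["run_pipeline", "demo_config", "load_config"]

DEMO_CONFIG = {
    "mode": "surveillance",          # surveillance | chemotaxis | sholl
    "seed": 0,
    "synth": {
        # scaled-down study geometry so the demo completes in minutes
        "field_width_um": 90.0,
        "frame_px": 192,
        "n_z": 7,
        "z_step_um": 2.0,
        "frame_interval_s": 60.0,
        "n_frames": 10,
        "n_cells": 1,
        "n_primary_processes": 6,
    },
    "preprocess": {
        "median_window": 3,
        "ball_radius_px": 30,
        "binarise_method": "otsu",
    },
    "metrics": {
        "control_window_min": 5.0,
        "slope_window_min": 2.0,
        "perimeter_estimator": "geometric",
    },
    "chemotaxis": {
        "ring_um": 2.0,
        "n_sectors": 32,
        "min_pixels": 10,
        "max_radius_um": 40.0,
    },
    "sholl": {"n_cells": 6, "dr_um": 1.0},
}


def demo_config(mode: str = "surveillance") -> dict:
    import copy

    cfg = copy.deepcopy(DEMO_CONFIG)
    cfg["mode"] = mode
    if mode == "chemotaxis":
        cfg["synth"]["target_point"] = (45.0, 45.0)
        cfg["synth"]["bias_strength"] = 0.9
        cfg["synth"]["frame_interval_s"] = 30.0
    return cfg


def load_config(path) -> dict:
    import yaml

    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict) or "mode" not in cfg:
        raise ValueError(f"config {path} must be a mapping with a 'mode' key")
    return cfg


def _setup_logging(out_dir: Path) -> None:
    handler = logging.FileHandler(out_dir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)


def run_pipeline(config: dict, out_dir, seed: int | None = None) -> dict:
    """Execute the configured stages and write all outputs under ``out_dir``.

    Returns a dict of the key result tables/values.  Any stage failure is
    re-raised with the stage name prepended.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    _setup_logging(out_dir)
    if seed is not None:
        config = {**config, "seed": int(seed)}
    seed = int(config.get("seed", 0))
    mode = config["mode"]
    log.info("gliamotion %s, mode=%s, seed=%d", __version__, mode, seed)
    with open(out_dir / "config.json", "w") as fh:
        json.dump(config, fh, indent=2, default=str)

    results: dict = {"mode": mode, "seed": seed}
    stage = "synth"
    try:
        if mode == "sholl":
            return _run_sholl(config, out_dir, seed, results)
        sc_kwargs = dict(config.get("synth", {}))
        if "target_point" in sc_kwargs and sc_kwargs["target_point"] is not None:
            sc_kwargs["target_point"] = tuple(sc_kwargs["target_point"])
        sc = SynthConfig(seed=seed, **sc_kwargs)
        if mode == "chemotaxis":
            stack, gt = simulate_chemotaxis(sc)
        elif mode == "surveillance":
            stack, gt = simulate_surveillance(sc)
        else:
            raise ValueError(f"unknown mode {mode!r}")
        write_tiff(stack, out_dir / "stack.tif")
        save_ground_truth(gt, out_dir / "ground_truth")

        stage = "preprocess"
        pp = config.get("preprocess", {})
        cells, info = preprocess_stack(
            stack,
            median_window=int(pp.get("median_window", 3)),
            ball_radius_px=int(pp.get("ball_radius_px", 30)),
            binarise_method=pp.get("binarise_method", "otsu"),
            threshold=pp.get("threshold"),
        )
        movie = cells[0]
        results["threshold"] = info["threshold"]

        mc = config.get("metrics", {})
        if mode == "surveillance":
            stage = "metrics"
            maps = motion_maps(movie)
            trace = surveillance_index(
                maps, control_window_min=float(mc.get("control_window_min", 20.0)))
            ram = ramification_trace(
                movie, perimeter_estimator=mc.get("perimeter_estimator",
                                                  "geometric"))
            curve = cumulative_survey(
                movie, slope_window_min=float(mc.get("slope_window_min", 2.0)))
            table = trace.to_dataframe().merge(
                ram.to_dataframe(), on="time_s", how="outer").merge(
                curve.to_dataframe(), on="time_s", how="outer")
            table.insert(0, "cell", 0)
            table.to_csv(out_dir / "surveillance.csv", index=False)
            summary = {
                "mean_R": float(np.nanmean(ram.index)),
                "mean_S_raw": float(trace.s_raw.mean()),
                "initial_slope_px_per_min": curve.initial_slope_px_per_min,
                "threshold": info["threshold"],
            }
            with open(out_dir / "summary.json", "w") as fh:
                json.dump(summary, fh, indent=2)
            results.update(summary)
            results["table"] = table
        else:
            stage = "chemotaxis"
            cc = config.get("chemotaxis", {})
            ps = stack.pixel_size_um
            tx_um, ty_um = sc.target_point
            geom = ChemotaxisGeometry(
                target_px=(tx_um / ps, ty_um / ps),
                pixel_size_um=ps,
                ring_um=float(cc.get("ring_um", 2.0)),
                n_sectors=int(cc.get("n_sectors", 32)),
                min_pixels=int(cc.get("min_pixels", 10)),
                max_radius_um=float(cc.get("max_radius_um",
                                           0.45 * sc.field_width_um)),
            )
            front = chemotaxis_timecourse(movie, geom)
            front.to_sector_dataframe().to_csv(out_dir / "front_sectors.csv",
                                               index=False)
            front.to_area_dataframe().to_csv(out_dir / "clear_area.csv",
                                             index=False)
            results["front"] = front
        log.info("stage %s complete", stage)
        return results
    except Exception as exc:
        log.error("stage %s failed: %s", stage, exc)
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc


def _run_sholl(config: dict, out_dir: Path, seed: int, results: dict) -> dict:
    from .morphometry import compare_groups, read_swc, sholl_intersections

    sh = config.get("sholl", {})
    n_cells = int(sh.get("n_cells", 6))
    dr = float(sh.get("dr_um", 1.0))
    swc_dir = out_dir / "swc"
    trees, gt = generate_swc_population(n_cells, seed=seed, dr_um=dr,
                                        out_dir=swc_dir)
    profiles = []
    rows = []
    for i, path in enumerate(gt.paths):
        tree = read_swc(path)
        prof = sholl_intersections(tree, dr_um=dr)
        prof.label = Path(path).stem
        profiles.append(prof)
        rows.append(prof.to_dataframe())
    pd.concat(rows).to_csv(out_dir / "sholl_profiles.csv", index=False)
    half = max(2, n_cells // 2)
    groups = {"A": profiles[:half], "B": profiles[half:]}
    if all(len(v) >= 2 for v in groups.values()):
        summary, anova = compare_groups(groups)
        summary.to_csv(out_dir / "sholl_group_summary.csv", index=False)
        anova.to_json(out_dir / "sholl_anova.json")
        results["anova"] = anova
    results["profiles"] = profiles
    return results
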