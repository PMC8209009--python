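"""Configuration-driven pipeline: simulate -> analyze -> classify.

A pipeline config is a mapping with a ``stages`` list, a global
``seed``, and one parameter block per selected stage.  Validation is
strict: unknown keys fail before any computation.  Every run writes
its resolved configuration and a deterministic ``summary.json`` beside
its outputs, so a run is reproducible from the resolved config alone.
"""

from __future__ import annotations

import copy
import logging
from pathlib import Path

import numpy as np
import yaml

from . import anisotropy as aniso
from . import simulate as sim
from . import spatial
from .errors import ConfigError
from .io import (
    read_image_pair,
    read_localization_csv,
    write_image_pair,
    write_json,
    write_localization_csv,
)

log = logging.getLogger(__name__)

STAGE_DEFAULTS: dict = {
    "simulate_images": {
        "mode": "clustered",  # monomer | clustered | ctxb | ramp
        "densities_per_um2": [0.5, 2.0, 8.0],
        "emitters_per_cluster": 4,
        "cluster_sigma_nm": 3.0,
        "pentamer_occupancy": 5,
        "photon_mean": 20000.0,
        "fov_um": 12.8,
        "pixel_size_nm": 100.0,
        "psf_sigma_nm": 150.0,
        "detection_ratio": 1.0,
        "offset": 100.0,
        "read_noise": 2.0,
        "noise": True,
    },
    "anisotropy": {
        "parallel": None,  # explicit inputs; None = use simulate_images outputs
        "perpendicular": None,
        "g": 1.0,
        "n_bins": 20,
        "roi_threshold": 0.1,
        "pixel_size_nm": 100.0,
        "background": 0.0,
    },
    "classify": {
        "monomer_reference": 0.35,
        "flat_threshold": 0.01,
        "low_fraction": 0.8,
    },
    "simulate_pattern": {
        "process": "thomas",
        "intensity_per_um2": 100.0,
        "kappa_per_um2": 50.0,
        "mu": 20.0,
        "sigma_nm": 30.0,
        "two_channel": False,
        "linkage": "independent",
        "blinking_mean": 1.0,
        "precision_nm": 10.0,
        "window_um": 3.0,
    },
    "density": {"input": None, "radius_nm": 100.0, "window_um": 3.0},
    "ripley": {
        "input": None,
        "window_um": 3.0,
        "r_max_nm": 500.0,
        "dr_nm": 5.0,
        "edge_correction": "isotropic",
        "tile_um": None,
    },
    "crosscorr": {
        "input": None,
        "channel_a": "A",
        "channel_b": "B",
        "window_um": 3.0,
        "dr_nm": 10.0,
        "r_max_nm": 500.0,
    },
}

GLOBAL_KEYS = {"stages", "seed", "out"}


def validate_config(config: dict) -> dict:
    """Fill defaults and reject unknown keys (fail-fast, before any work)."""
    if not isinstance(config, dict):
        raise ConfigError("config must be a mapping")
    unknown = set(config) - GLOBAL_KEYS - set(STAGE_DEFAULTS)
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    stages = config.get("stages")
    if not stages or not isinstance(stages, list):
        raise ConfigError("config needs a nonempty 'stages' list")
    for st in stages:
        if st not in STAGE_DEFAULTS:
            raise ConfigError(f"unknown stage {st!r}; known: {sorted(STAGE_DEFAULTS)}")
    resolved = {"stages": list(stages), "seed": int(config.get("seed", 0))}
    for st in stages:
        block = config.get(st, {})
        if not isinstance(block, dict):
            raise ConfigError(f"stage block {st!r} must be a mapping")
        bad = set(block) - set(STAGE_DEFAULTS[st])
        if bad:
            raise ConfigError(f"unknown keys in stage {st!r}: {sorted(bad)}")
        resolved[st] = copy.deepcopy(STAGE_DEFAULTS[st]) | dict(block)
    return resolved


def load_config(path) -> dict:
    return yaml.safe_load(Path(path).read_text())


def run_pipeline(config: dict, out_dir) -> dict:
    """Execute the selected stages in order; returns the summary dict.

    Artifacts (TIFF pairs, CSV tables, summary.json, resolved config)
    land in ``out_dir``.  Failures leave a ``_FAILED`` marker naming
    the stage and error.
    """
    resolved = validate_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "resolved_config.yaml").write_text(yaml.safe_dump(resolved, sort_keys=True))
    seed = resolved["seed"]
    rng = np.random.default_rng(seed)
    summary: dict = {"seed": seed, "stages": resolved["stages"]}
    state: dict = {}
    try:
        for st in resolved["stages"]:
            log.info("stage %s starting (seed %d)", st, seed)
            _STAGE_RUNNERS[st](resolved[st], state, rng, out, summary)
    except Exception as exc:
        (out / "_FAILED").write_text(f"stage failure: {exc}\n")
        raise
    summary["resolved_config"] = resolved
    write_json(summary, out / "summary.json")
    return summary


def _stage_simulate_images(cfg, state, rng, out, summary):
    fov = (cfg["fov_um"] * 1000.0, cfg["fov_um"] * 1000.0)
    optics = sim.Optics(cfg["psf_sigma_nm"], cfg["pixel_size_nm"])
    camera = sim.Camera(cfg["detection_ratio"], cfg["offset"], cfg["read_noise"])
    pairs, records = [], []
    for i, dens in enumerate(cfg["densities_per_um2"]):
        if cfg["mode"] == "monomer" or cfg["mode"] == "ramp":
            field = sim.monomer_field(dens, fov, cfg["photon_mean"], rng=rng)
        elif cfg["mode"] == "clustered":
            field = sim.clustered_field(dens, cfg["emitters_per_cluster"],
                                        cfg["cluster_sigma_nm"], fov,
                                        cfg["photon_mean"], rng=rng)
        elif cfg["mode"] == "ctxb":
            field = sim.ctxb_field(dens, fov, cfg["photon_mean"],
                                   occupancy=cfg["pentamer_occupancy"], rng=rng)
        else:
            raise ConfigError(f"unknown simulate_images mode {cfg['mode']!r}")
        pair, rec = sim.simulate_polarized_image_pair(
            field, optics, camera, rng=rng, noise=cfg["noise"])
        write_image_pair(pair, out / f"sim_{i:02d}_par.tif", out / f"sim_{i:02d}_perp.tif")
        pairs.append(pair)
        records.append(rec)
    state["image_pairs"] = pairs
    state["camera"] = camera
    summary["simulate_images"] = {
        "n_images": len(pairs),
        "mode": cfg["mode"],
        "mean_emitter_anisotropy": [r["mean_emitter_anisotropy"] for r in records],
        "n_emitters": [r["n_emitters"] for r in records],
    }


def _stage_anisotropy(cfg, state, rng, out, summary):
    if cfg["parallel"] is not None:
        pair = read_image_pair(cfg["parallel"], cfg["perpendicular"],
                               pixel_size=cfg["pixel_size_nm"],
                               background_parallel=cfg["background"],
                               background_perpendicular=cfg["background"])
        pairs = [pair]
        g = float(cfg["g"])
    else:
        pairs = state.get("image_pairs")
        if not pairs:
            raise ConfigError("anisotropy stage needs inputs or a simulate_images stage")
        g = state["camera"].detection_ratio
    maps_list = [aniso.compute_anisotropy_maps(p, g) for p in pairs]
    rois = [[aniso.roi_from_intensity(m, cfg["roi_threshold"])] for m in maps_list]
    curve = aniso.bin_intensity_anisotropy(maps_list, rois, n_bins=cfg["n_bins"])
    curve.to_frame().to_csv(out / "curve.csv", index=False)
    state["curve"] = curve
    summary["anisotropy"] = {
        "n_bins": int(curve.n_bins),
        "mean_anisotropy": [float(v) for v in curve.bin_mean_anisotropy],
        "mean_intensity": [float(v) for v in curve.bin_mean_intensity],
    }


def _stage_classify(cfg, state, rng, out, summary):
    curve = state.get("curve")
    if curve is None:
        raise ConfigError("classify stage needs an anisotropy stage before it")
    sig = aniso.classify_clustering_signature(
        curve, cfg["monomer_reference"], cfg["flat_threshold"], cfg["low_fraction"])
    write_json(sig, out / "signature.json")
    summary["classify"] = {
        "label": sig.label, "slope": sig.slope,
        "mean_anisotropy": sig.mean_anisotropy,
    }


def _stage_simulate_pattern(cfg, state, rng, out, summary):
    w = cfg["window_um"] * 1000.0
    window = spatial.AnalysisWindow(w, w)
    truth = sim.PatternTruth(
        process=cfg["process"], intensity_per_um2=cfg["intensity_per_um2"],
        kappa_per_um2=cfg["kappa_per_um2"], mu=cfg["mu"], sigma_nm=cfg["sigma_nm"],
        linkage=cfg["linkage"], blinking_mean=cfg["blinking_mean"],
        precision_nm=cfg["precision_nm"],
    )
    if cfg["two_channel"]:
        table, record = sim.simulate_two_channel_pattern(truth, window, rng=rng)
    else:
        table, record = sim.simulate_point_pattern(truth, window, rng=rng)
    write_localization_csv(table, out / "localizations.csv")
    write_json(record, out / "pattern_truth.json")
    state["pattern"] = table
    state["pattern_window"] = window
    summary["simulate_pattern"] = {"n_points": len(table), "process": truth.process}


def _load_pattern(cfg, state):
    if cfg.get("input"):
        table = read_localization_csv(cfg["input"])
        w = cfg["window_um"] * 1000.0
        return table, spatial.AnalysisWindow(w, w)
    if "pattern" not in state:
        raise ConfigError("stage needs an input CSV or a simulate_pattern stage")
    return state["pattern"], state["pattern_window"]


def _stage_density(cfg, state, rng, out, summary):
    table, window = _load_pattern(cfg, state)
    res = spatial.neighbor_density(table, window, cfg["radius_nm"])
    res.histogram.to_csv(out / "density_histogram.csv", index=False)
    summary["density"] = {
        "radius_nm": cfg["radius_nm"],
        "mean_neighbors": float(np.mean(res.per_point_counts)) if len(res.per_point_counts) else 0.0,
    }


def _stage_ripley(cfg, state, rng, out, summary):
    table, window = _load_pattern(cfg, state)
    r_grid = np.arange(cfg["dr_nm"], cfg["r_max_nm"] + cfg["dr_nm"] / 2, cfg["dr_nm"])
    if cfg["tile_um"]:
        tiles = spatial.tile_windows(table, window, cfg["tile_um"] * 1000.0,
                                     min_points=2)
        rmaxes = []
        for i, (win, sub) in enumerate(tiles):
            res = spatial.ripley_k(sub, win, r_grid, cfg["edge_correction"])
            res.to_frame().to_csv(out / f"ripley_tile_{i:02d}.csv", index=False)
            rmaxes.append(res.r_max)
        summary["ripley"] = {
            "n_tiles": len(tiles),
            "r_max_mean": float(np.nanmean(rmaxes)) if rmaxes else None,
            "r_max_sd": float(np.nanstd(rmaxes, ddof=1)) if len(rmaxes) > 1 else None,
        }
    else:
        res = spatial.ripley_k(table, window, r_grid, cfg["edge_correction"])
        res.to_frame().to_csv(out / "ripley.csv", index=False)
        summary["ripley"] = {"r_max": res.r_max, "n_points": res.n_points}


def _stage_crosscorr(cfg, state, rng, out, summary):
    table, window = _load_pattern(cfg, state)
    a = table.channel(cfg["channel_a"])
    b = table.channel(cfg["channel_b"])
    edges = np.arange(0.0, cfg["r_max_nm"] + cfg["dr_nm"] / 2, cfg["dr_nm"])
    res = spatial.cross_correlation(a, b, window, edges)
    res.to_frame().to_csv(out / "crosscorr.csv", index=False)
    c = res.c_values
    summary["crosscorr"] = {
        "c_first_bin": float(c[0]),
        "c_long_range_mean": float(np.nanmean(c[len(c) // 2:])),
    }


_STAGE_RUNNERS = {
    "simulate_images": _stage_simulate_images,
    "anisotropy": _stage_anisotropy,
    "classify": _stage_classify,
    "simulate_pattern": _stage_simulate_pattern,
    "density": _stage_density,
    "ripley": _stage_ripley,
    "crosscorr": _stage_crosscorr,
}
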