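"""End-to-end study drivers: forward and reverse factor-model studies and
the measurement-model comparison, wiring every stage together.

The forward study mirrors the headline analysis: simulate Set 1 (one
pouring scene, 32 viscosities × 6 time periods = 192 stimuli) and Set 2
(8 scenes × 7 viscosities = 56 stimuli), fit the factor chain (Horn →
ML FA → Harman scores → viscosity regression) on Set 1 alone, then apply
the frozen loadings and regression weights to Set 2.  The reverse study
swaps the roles and additionally compares the two models' factor-space
RDMs.  The measurement-model comparison renders scaled-down mesh stimuli
for Set 2 and pits optical flow, 20 silhouette statistics, and the four 3D
mesh metrics against each other under fixed and free per-scene weights.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as vio
from .factors import (build_viscosity_model, factor_scores, fit_factor_model,
                      horn_parallel_analysis, predict_transfer)
from .image_models import (fit_measurement_model, filter_frames,
                           mean_flow_speed, silhouette_statistics,
                           normalize_stats, stats_mean_predictor,
                           SHAPE_STAT_NAMES)
from .mesh_metrics import METRIC_NAMES, extract_metrics
from .representation import compare_rdms, compute_rdm
from .synth import (GroundTruth, RatingsTable, default_scenes,
                    generate_feature_ratings, generate_liquid_sequence,
                    generate_viscosity_ratings, make_ground_truth,
                    make_set1_design, make_set2_design, render_silhouette)

__all__ = ["RunConfig", "run_forward_study", "run_reverse_study",
           "run_measurement_model_comparison"]


@dataclass
class RunConfig:
    """Single source of truth for a reproduction run.

    All randomness flows from ``seed`` via fixed per-component offsets;
    rerunning with an identical config reproduces every output byte for
    byte.
    """

    seed: int = 0
    out_dir: str | None = None
    # design
    n_viscosities_set1: int = 32
    n_viscosities_set2: int = 7
    n_periods: int = 6
    feature_repetitions_set1: int = 1
    feature_repetitions_set2: int = 2
    viscosity_repetitions: int = 4
    # generative model
    noise_sd: float = 0.05
    monotone_share: float = 0.9
    n_factors: int = 4
    # model flags
    rotation: str | None = None
    transfer_standardization: str = "self"
    use_horn: bool = True
    # mesh stimuli (measurement-model comparison); scaled-down defaults
    grid_n: int = 32
    n_frames: int = 120
    frame_step: int = 12
    resolution: tuple[int, int] = (160, 120)
    flow_frame_step: int = 6

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["resolution"] = list(self.resolution)
        return d

    @property
    def hash(self) -> str:
        d = self.to_dict()
        d.pop("out_dir")  # the output location is not part of the science
        return vio.config_hash(d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text()) or {}
        if "resolution" in d:
            d["resolution"] = tuple(d["resolution"])
        return cls(**d)


def _make_datasets(config: RunConfig) -> dict:
    """Both designs plus their simulated rating tables under one truth model."""
    seed = config.seed
    d1 = make_set1_design(config.n_viscosities_set1, n_periods=config.n_periods)
    d2 = make_set2_design(config.n_viscosities_set2)
    t1 = make_ground_truth(d1, seed=seed, scores="monotone",
                           noise_sd=config.noise_sd,
                           monotone_share=config.monotone_share)
    t2 = make_ground_truth(d2, seed=seed + 1000, scores="monotone",
                           noise_sd=config.noise_sd,
                           monotone_share=config.monotone_share)
    return {
        "design1": d1, "design2": d2, "truth1": t1, "truth2": t2,
        "features1": generate_feature_ratings(t1, d1, config.feature_repetitions_set1, seed),
        "viscosity1": generate_viscosity_ratings(t1, d1, config.viscosity_repetitions, seed),
        "features2": generate_feature_ratings(t2, d2, config.feature_repetitions_set2, seed + 1),
        "viscosity2": generate_viscosity_ratings(t2, d2, config.viscosity_repetitions, seed + 1),
    }


def _fit_and_transfer(train_feat, train_visc, test_feat, test_visc,
                      config: RunConfig, log: list) -> dict:
    horn_k = horn_parallel_analysis(train_feat, seed=config.seed) \
        if config.use_horn else None
    n_factors = config.n_factors
    if config.use_horn and horn_k != n_factors:
        log.append(f"parallel analysis retained {horn_k} factors; "
                   f"fitting the configured {n_factors}")
    model = fit_factor_model(train_feat, n_factors, rotation=config.rotation)
    scores = factor_scores(model, train_feat)
    vmodel, train_report = build_viscosity_model(model, scores, train_visc)
    predictions, transfer_report = predict_transfer(
        vmodel, test_feat, test_visc,
        standardize_with=config.transfer_standardization)
    return {"horn_retained": horn_k, "factor_model": model,
            "viscosity_model": vmodel, "train_scores": scores,
            "train_report": train_report, "predictions": predictions,
            "transfer_report": transfer_report}


def _write_study(bundle: dict, data: dict, config: RunConfig, name: str) -> None:
    if config.out_dir is None:
        return
    out = Path(config.out_dir)
    h = config.hash
    for key in ("features1", "viscosity1", "features2", "viscosity2"):
        vio.write_ratings(data[key], out / "ratings" / f"{key}.csv", h)
    vio.write_json(bundle["viscosity_model"].to_json_dict(),
                   out / f"{name}_model.json", h)
    reports = {
        "horn_retained": bundle["horn_retained"],
        "train": bundle["train_report"].to_dict(),
        "transfer": bundle["transfer_report"].to_dict(),
        "log": bundle["log"],
    }
    if "rdm_comparison" in bundle:
        reports["rdm_comparison"] = {k: v.to_dict()
                                     for k, v in bundle["rdm_comparison"].items()}
    vio.write_json(reports, out / "reports" / f"{name}.json", h)


def run_forward_study(config: RunConfig) -> dict:
    """Train on Set 1 (pouring), transfer the frozen model to Set 2."""
    log: list[str] = []
    data = _make_datasets(config)
    log.append(f"set1: {len(data['design1'])} stimulus rows; "
               f"set2: {len(data['design2'])} stimulus rows")
    bundle = _fit_and_transfer(data["features1"], data["viscosity1"],
                               data["features2"], data["viscosity2"], config, log)
    rep = bundle["train_report"]
    log.append(f"train R2={rep.r2:.3f} F({rep.df1},{rep.df2})={rep.fstat:.1f}")
    trep = bundle["transfer_report"]
    log.append(f"transfer R2={trep.r2:.3f} F({trep.df1},{trep.df2})={trep.fstat:.1f}")
    bundle["log"] = log
    bundle["data"] = data
    _write_study(bundle, data, config, "forward")
    return bundle


def run_reverse_study(config: RunConfig, forward: dict | None = None) -> dict:
    """Train on Set 2 (eight scenes), transfer to Set 1; compare RDMs.

    The RDM comparison scores the same stimuli with the forward and reverse
    factor models and regresses one factor-space RDM on the other, for both
    stimulus sets.
    """
    log: list[str] = []
    if forward is None:
        forward = run_forward_study(config)
    data = forward["data"]
    bundle = _fit_and_transfer(data["features2"], data["viscosity2"],
                               data["features1"], data["viscosity1"], config, log)
    rep = bundle["train_report"]
    log.append(f"reverse train R2={rep.r2:.3f} F({rep.df1},{rep.df2})={rep.fstat:.1f}")
    trep = bundle["transfer_report"]
    log.append(f"reverse transfer R2={trep.r2:.3f} F({trep.df1},{trep.df2})={trep.fstat:.1f}")

    fmodel = forward["factor_model"]
    rmodel = bundle["factor_model"]
    rdm_cmp = {}
    for name, feats in (("set1", data["features1"]), ("set2", data["features2"])):
        sf = factor_scores(fmodel, feats, standardize_with="self")
        sr = factor_scores(rmodel, feats, standardize_with="self")
        rdm_cmp[name] = compare_rdms(compute_rdm(sf), compute_rdm(sr))
        log.append(f"RDM comparison {name}: R2={rdm_cmp[name].r2:.3f} "
                   f"df=({rdm_cmp[name].df1},{rdm_cmp[name].df2})")
    bundle["rdm_comparison"] = rdm_cmp
    bundle["log"] = log
    bundle["data"] = data
    _write_study(bundle, data, config, "reverse")
    return bundle


def simulate_set2_stimuli(config: RunConfig) -> list:
    """Scaled-down mesh sequences for every Set 2 stimulus."""
    design = make_set2_design(config.n_viscosities_set2)
    scenes = default_scenes(config.grid_n)
    seqs = []
    for _, row in design.iterrows():
        seqs.append(generate_liquid_sequence(
            scenes[row["scene_id"]], row["viscosity"],
            n_frames=config.n_frames, seed=config.seed, grid_n=config.grid_n))
    return seqs


def run_measurement_model_comparison(config: RunConfig,
                                     datasets: dict | None = None) -> dict:
    """Flow, 2D-statistics and 3D-metric models on synthetic Set 2.

    Renders each Set 2 stimulus, computes the three measurement-based
    predictor sets, and regresses the simulated viscosity ratings on each
    under fixed (pooled) and free (per-scene) weights.
    """
    log: list[str] = []
    if datasets is None:
        datasets = _make_datasets(config)
    design = datasets["design2"]
    y = datasets["viscosity2"].average_repetitions().values.to_numpy().ravel()
    scene_ids = design["scene_id"].to_numpy()
    seqs = simulate_set2_stimuli(config)
    log.append(f"simulated {len(seqs)} Set 2 mesh sequences "
               f"(grid {config.grid_n}, {config.n_frames} frames)")

    # keep the frame filter's liquid-area fraction (300 px of 800x600)
    W, H = config.resolution
    min_px = max(1, round(300 * (W * H) / (800 * 600)))
    flow_vals, stat_rows = [], []
    for seq in seqs:
        video, masks = render_silhouette(seq, config.resolution)
        sub = slice(None, None, config.flow_frame_step)
        flow_vals.append(mean_flow_speed(video[sub], masks=masks[sub]))
        frames = filter_frames(video[::config.frame_step], masks[::config.frame_step],
                               min_pixels=min_px)
        if frames:
            stat_rows.append(silhouette_statistics(frames))
        else:
            stat_rows.append(pd.Series(np.nan, index=SHAPE_STAT_NAMES))
    stats = pd.DataFrame(stat_rows).reset_index(drop=True)
    unmeasurable = stats.isna().any(axis=1)
    if unmeasurable.any():
        log.append(f"{int(unmeasurable.sum())} stimuli unmeasurable for 2D stats; "
                   "filled with column medians")
        stats = stats.fillna(stats.median())
    metrics3d = extract_metrics(seqs, aggregation="full_sequence",
                                frame_step=config.frame_step, dry_height=1e-5,
                                normalize="per_scene")
    m3d = metrics3d[[c + "_z" for c in METRIC_NAMES]].to_numpy()

    mean2d = stats_mean_predictor(stats, design["viscosity"].to_numpy()).to_numpy()
    predictors = {
        "flow": np.asarray(flow_vals)[:, None],
        "stats2d_mean": mean2d[:, None],
        "stats2d_full": normalize_stats(stats).to_numpy(),
        "mesh3d": m3d,
    }
    table = {}
    for name, X in predictors.items():
        fixed = fit_measurement_model(X, y, "fixed_across_contexts")
        free = fit_measurement_model(X, y, "free_per_scene", scene_ids)
        table[name] = {"fixed": fixed, "free": free}
        rep = fixed["report"]
        log.append(f"{name}: fixed R2={rep.r2:.3f} F({rep.df1},{rep.df2})"
                   f"={rep.fstat:.2f}; free mean R2={free['r2']:.3f} "
                   f"[{free['r2_min']:.2f}, {free['r2_max']:.2f}]")
    out = {"models": table, "log": log, "stats": stats, "flow": flow_vals,
           "metrics3d": metrics3d, "design": design}
    if config.out_dir is not None:
        h = config.hash
        outdir = Path(config.out_dir)
        vio.write_table(stats, outdir / "stats2d.csv", h)
        vio.write_table(metrics3d, outdir / "metrics3d.csv", h)
        summary = {name: {"fixed_r2": t["fixed"]["r2"], "free_mean_r2": t["free"]["r2"],
                          "fixed_df": [t["fixed"]["report"].df1, t["fixed"]["report"].df2]}
                   for name, t in table.items()}
        vio.write_json({"summary": summary, "log": log},
                       outdir / "reports" / "measurement_models.json", h)
    return out
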