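"""2D comparison models: silhouette shape statistics and mean optical flow.

Two image-computable baselines against which the factor model is compared:

* twenty simple shape statistics of the liquid's binary silhouette
  (area, perimeter, circularity, solidity, moments, contour curvature, ...),
  combined either as the plain mean of normalized statistics (single
  predictor) or as twenty separate regressors;
* the mean speed of dense optical flow, computed with a coarse-to-fine
  iterated Lucas-Kanade scheme and averaged over liquid pixels.

Frame filtering follows the measurement protocol: frames with fewer than
300 liquid pixels are excluded, and one-pixel-wide regions are removed by
a morphological opening before any contour measurement.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import partial
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import measure, morphology

from .report import FitReport, ols_report

__all__ = [
    "SilhouetteFrame",
    "filter_frames",
    "silhouette_statistics",
    "normalize_stats",
    "stats_mean_predictor",
    "mean_flow_speed",
    "fit_measurement_model",
    "SHAPE_STAT_NAMES",
    "MIN_LIQUID_PIXELS",
]

MIN_LIQUID_PIXELS = 300

SHAPE_STAT_NAMES = [
    "area", "perimeter", "circularity", "solidity", "convexity",
    "eccentricity", "elongation", "orientation", "extent", "component_count",
    "hole_count", "centroid_height", "vertical_extent", "horizontal_extent",
    "radial_spread", "centroid_dispersion", "contour_curvature_mean",
    "contour_curvature_var", "curvature_zero_crossings", "perimeter_area_ratio",
]


@dataclass
class SilhouetteFrame:
    """One retained video frame: intensity image plus its binary liquid mask."""

    intensity: np.ndarray
    mask: np.ndarray

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != np.asarray(self.intensity).shape:
            raise ValueError("mask and intensity shapes differ")


def filter_frames(video: np.ndarray, masks: np.ndarray | None = None,
                  min_pixels: int = MIN_LIQUID_PIXELS) -> list[SilhouetteFrame]:
    """Retain measurable frames and clean their masks.

    A frame is dropped when its raw mask holds fewer than ``min_pixels``
    liquid pixels (strict "fewer than": exactly ``min_pixels`` is
    retained).  The default of 300 px corresponds to 0.06% of a full
    800 × 600 render; callers measuring at reduced resolution should scale
    it by the pixel-count ratio to keep the same area fraction.  One-pixel-
    wide regions are removed by a binary opening with a 2×2 structuring
    element before measurement; a frame whose opened mask is empty is
    dropped too.  An empty return value means the stimulus is unmeasurable.
    """
    video = np.asarray(video, dtype=float)
    if masks is None:
        masks = video > 0
    out: list[SilhouetteFrame] = []
    selem = np.ones((2, 2), dtype=bool)
    for img, m in zip(video, np.asarray(masks, dtype=bool)):
        if m.sum() < min_pixels:
            continue
        opened = morphology.opening(m, selem)
        if not opened.any():
            continue
        out.append(SilhouetteFrame(img, opened))
    return out


# ---------------------------------------------------------------------------
# silhouette shape statistics
# ---------------------------------------------------------------------------


def _contour_curvature(mask: np.ndarray, step_px: float = 2.0):
    """Curvature along the arc-length-resampled outer contour of the
    largest component; returns (mean |κ|, var κ, zero crossings)."""
    lab = measure.label(mask)
    if lab.max() == 0:
        return 0.0, 0.0, 0.0
    sizes = np.bincount(lab.ravel())[1:]
    largest = lab == (1 + int(np.argmax(sizes)))
    contours = measure.find_contours(largest.astype(float), 0.5)
    if not contours:
        return 0.0, 0.0, 0.0
    c = max(contours, key=len)
    d = np.r_[0.0, np.cumsum(np.linalg.norm(np.diff(c, axis=0), axis=1))]
    total = d[-1]
    if total < 4 * step_px:
        return 0.0, 0.0, 0.0
    s = np.arange(0.0, total, step_px)
    x = np.interp(s, d, c[:, 1])
    y = np.interp(s, d, c[:, 0])
    # central differences on the closed resampled curve
    dx = (np.roll(x, -1) - np.roll(x, 1)) / (2 * step_px)
    dy = (np.roll(y, -1) - np.roll(y, 1)) / (2 * step_px)
    ddx = (np.roll(x, -1) - 2 * x + np.roll(x, 1)) / step_px**2
    ddy = (np.roll(y, -1) - 2 * y + np.roll(y, 1)) / step_px**2
    denom = (dx * dx + dy * dy) ** 1.5
    kappa = np.where(denom > 1e-12, (dx * ddy - dy * ddx) / np.maximum(denom, 1e-12), 0.0)
    zc = float(np.sum(np.sign(kappa[:-1]) * np.sign(kappa[1:]) < 0))
    return float(np.mean(np.abs(kappa))), float(np.var(kappa)), zc


def _frame_statistics(mask: np.ndarray) -> dict:
    H, W = mask.shape
    area = float(mask.sum())
    # Crofton perimeter: close to the true contour length for smooth shapes
    perim = float(measure.perimeter_crofton(mask, directions=4))
    lab, n_comp = ndimage.label(mask)
    euler = int(measure.euler_number(mask, connectivity=2))
    holes = max(n_comp - euler, 0)
    hull = morphology.convex_hull_image(mask)
    hull_area = float(hull.sum())
    hull_perim = float(measure.perimeter_crofton(hull, directions=4))
    rows, cols = np.nonzero(mask)
    cy, cx = rows.mean(), cols.mean()
    # central second moments of the full mask
    mu20 = np.mean((cols - cx) ** 2)
    mu02 = np.mean((rows - cy) ** 2)
    mu11 = np.mean((cols - cx) * (rows - cy))
    cov = np.array([[mu20, mu11], [mu11, mu02]])
    evals = np.sort(np.linalg.eigvalsh(cov))[::-1]
    lam1, lam2 = max(evals[0], 1e-12), max(evals[1], 1e-12)
    ecc = float(np.sqrt(max(1.0 - lam2 / lam1, 0.0)))
    elong = float(np.sqrt(lam1 / lam2))
    orient = float(0.5 * np.arctan2(2 * mu11, mu20 - mu02))
    bbox_area = float((rows.max() - rows.min() + 1) * (cols.max() - cols.min() + 1))
    radial = float(np.sqrt(np.mean((rows - cy) ** 2 + (cols - cx) ** 2)))
    if n_comp > 1:
        cents = np.array(ndimage.center_of_mass(mask, lab, np.arange(1, n_comp + 1)))
        disp = float(np.linalg.norm(cents - [cy, cx], axis=1).std())
    else:
        disp = 0.0
    curv_mean, curv_var, curv_zc = _contour_curvature(mask)
    return {
        "area": area,
        "perimeter": perim,
        "circularity": 4 * np.pi * area / perim**2 if perim > 0 else 0.0,
        "solidity": area / hull_area if hull_area > 0 else 0.0,
        "convexity": hull_perim / perim if perim > 0 else 0.0,
        "eccentricity": ecc,
        "elongation": elong,
        "orientation": orient,
        "extent": area / bbox_area,
        "component_count": float(n_comp),
        "hole_count": float(holes),
        "centroid_height": float(H - 1 - cy),
        "vertical_extent": float(rows.max() - rows.min() + 1),
        "horizontal_extent": float(cols.max() - cols.min() + 1),
        "radial_spread": radial,
        "centroid_dispersion": disp,
        "contour_curvature_mean": curv_mean,
        "contour_curvature_var": curv_var,
        "curvature_zero_crossings": curv_zc,
        "perimeter_area_ratio": perim / area if area > 0 else 0.0,
    }


def silhouette_statistics(frames: Sequence[SilhouetteFrame]) -> pd.Series:
    """The 20 shape statistics of one stimulus, averaged over retained frames."""
    if len(frames) == 0:
        raise ValueError("no retained frames: stimulus unmeasurable")
    rows = [_frame_statistics(f.mask) for f in frames]
    return pd.DataFrame(rows)[SHAPE_STAT_NAMES].mean(axis=0)


def normalize_stats(stats: pd.DataFrame) -> pd.DataFrame:
    """Min-max normalization of each statistic across the stimulus set."""
    mn, mx = stats.min(axis=0), stats.max(axis=0)
    span = (mx - mn).replace(0.0, 1.0)
    return (stats - mn) / span


def stats_mean_predictor(stats: pd.DataFrame, train_labels: np.ndarray | None = None
                         ) -> pd.Series:
    """Single predictor: mean of the normalized statistics per stimulus.

    The original statistic set was constructed so every measurement covaries
    positively with viscosity; with a generic statistic list the sign of
    each column must first be calibrated.  When ``train_labels`` (physical
    viscosities of the same stimuli) are given, columns negatively
    correlated with the labels are flipped (x → 1 − x) before averaging.
    """
    norm = normalize_stats(stats)
    if train_labels is not None:
        y = np.asarray(train_labels, dtype=float)
        for c in norm.columns:
            x = norm[c].to_numpy()
            if x.std() > 0 and np.corrcoef(x, y)[0, 1] < 0:
                norm[c] = 1.0 - norm[c]
    return norm.mean(axis=1)


# ---------------------------------------------------------------------------
# optical flow
# ---------------------------------------------------------------------------


def _pyramidal_lk(ref: np.ndarray, mov: np.ndarray, pyramid_levels: int,
                  iterations: int, radius: int) -> np.ndarray:
    """Dense coarse-to-fine iterated Lucas-Kanade flow, (2, H, W)."""
    try:
        from skimage.registration._optical_flow import _ilk
        from skimage.registration._optical_flow_utils import _coarse_to_fine
        solver = partial(_ilk, radius=radius, num_warp=iterations,
                         gaussian=False, prefilter=False)
        return _coarse_to_fine(ref, mov, solver, nlevel=pyramid_levels)
    except ImportError:  # fall back to the public API (auto pyramid depth)
        from skimage.registration import optical_flow_ilk
        return optical_flow_ilk(ref, mov, radius=radius, num_warp=iterations,
                                gaussian=False, prefilter=False)


def mean_flow_speed(video: np.ndarray, pyramid_levels: int = 3,
                    iterations: int = 5, radius: int = 7,
                    masks: np.ndarray | None = None,
                    restrict_to_mask: bool = True) -> float:
    """Mean optical-flow speed of a stimulus, px/frame.

    Dense flow between consecutive frames via coarse-to-fine iterated
    Lucas-Kanade; the magnitude is averaged over liquid pixels (the
    reference frame's mask) by default, or the full frame with
    ``restrict_to_mask=False``.  Frame pairs whose mask is empty contribute
    nothing; a fully static video yields 0.
    """
    video = np.asarray(video, dtype=float)
    if video.shape[0] < 2:
        raise ValueError("need at least 2 frames")
    if masks is None:
        masks = np.ones(video.shape, dtype=bool)
    speeds = []
    for t in range(video.shape[0] - 1):
        ref, mov = video[t], video[t + 1]
        if np.array_equal(ref, mov):
            flow_mag = np.zeros(ref.shape)
        else:
            flow = _pyramidal_lk(ref, mov, pyramid_levels, iterations, radius)
            flow_mag = np.hypot(flow[0], flow[1])
        m = masks[t] if restrict_to_mask else np.ones(ref.shape, dtype=bool)
        if m.any():
            speeds.append(float(flow_mag[m].mean()))
    return float(np.mean(speeds)) if speeds else 0.0


# ---------------------------------------------------------------------------
# regression comparison of measurement models
# ---------------------------------------------------------------------------


def fit_measurement_model(predictors, viscosity_ratings,
                          weights: Literal["fixed_across_contexts", "free_per_scene"]
                          = "fixed_across_contexts",
                          scene_ids: Sequence | None = None) -> dict:
    """Regress viscosity ratings on measurement predictors.

    ``fixed_across_contexts``: one pooled OLS over all scenes.
    ``free_per_scene``: a separate OLS per scene; the report carries each
    scene's R² and their mean.  Since per-scene fits nest the pooled fit,
    the mean free R² can never fall below the fixed R² on the same data.
    """
    X = np.asarray(predictors, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(viscosity_ratings, dtype=float).ravel()
    if len(X) != len(y):
        raise ValueError("predictors and ratings are not aligned by stimulus")
    if weights == "fixed_across_contexts":
        rep, _ = ols_report(X, y)
        return {"mode": weights, "report": rep, "r2": rep.r2}
    if weights == "free_per_scene":
        if scene_ids is None:
            raise ValueError("free_per_scene requires scene_ids")
        scene_ids = np.asarray(scene_ids)
        per_scene: dict = {}
        rss_total = 0.0
        for s in pd.unique(scene_ids):
            idx = scene_ids == s
            rep, _ = ols_report(X[idx], y[idx])
            per_scene[s] = rep
            rss_total += float(rep.residuals @ rep.residuals)
        r2s = {s: r.r2 for s, r in per_scene.items()}
        tss = float(((y - y.mean()) ** 2).sum())
        return {"mode": weights, "per_scene": per_scene, "r2_per_scene": r2s,
                "r2": float(np.mean(list(r2s.values()))),
                "r2_min": float(min(r2s.values())), "r2_max": float(max(r2s.values())),
                # pooled-residual form: provably >= the fixed-weights R^2
                "r2_nested": 1.0 - rss_total / tss}
    raise ValueError(f"unknown weights mode {weights!r}")
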