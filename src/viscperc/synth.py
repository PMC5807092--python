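"""Synthetic liquid stimuli and simulated observer ratings.

This module generates the three kinds of raw material the analysis pipeline
consumes, each with known ground truth:

* liquid-like dynamic triangle meshes, driven by a 2.5-D height-field
  simulator whose spreading rate decreases monotonically with a dynamic
  viscosity parameter (Pa·s);
* orthographic side-view silhouette videos of those meshes, with intensity
  proportional to the liquid's depth extent along the viewing axis;
* observer rating tables (20 midlevel shape/motion features, or a single
  viscosity slider) produced from a known 4-factor loading structure plus
  iid Gaussian slider noise.

The simulator is deliberately not a Navier-Stokes solver: poured volume is
deposited at a source location and relaxes by lateral diffusion with
coefficient D = C_SPREAD / viscosity, which produces controllable,
viscosity-monotone shape variation while conserving volume exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "SceneConfig",
    "MeshFrame",
    "MeshSequence",
    "RatingsTable",
    "GroundTruth",
    "ConfigurationError",
    "viscosity_grid",
    "generate_liquid_sequence",
    "render_silhouette",
    "render_mesh_frame",
    "generate_feature_ratings",
    "generate_viscosity_ratings",
    "make_set1_design",
    "make_set2_design",
    "default_scenes",
    "default_loadings",
    "iid_factor_scores",
    "monotone_factor_scores",
    "make_ground_truth",
    "footprint_area",
    "sequence_volumes",
    "child_seed",
]

#: lateral spreading coefficient numerator, m^2·Pa·s / s.  Chosen so the
#: runniest liquid (0.001 Pa·s) wets most of a 1 m domain well before 10 s
#: while the diffusion length at mid-range viscosities (~1 Pa·s) is ~0.1 m,
#: so the whole 0.001-100 Pa·s scale maps onto visibly different spreads.
C_SPREAD = 5e-4

#: height threshold (m) below which a cell counts as dry.
DRY_EPS = 1e-6


class ConfigurationError(ValueError):
    """Raised for physically inconsistent scene configurations."""


# fixed offsets for deriving per-component child seeds from a master seed
_SEED_OFFSETS = {
    "simulate": 101,
    "features": 211,
    "viscosity": 307,
    "scores": 401,
    "perturb": 503,
    "horn": 601,
    "bootstrap": 701,
}


def child_seed(master: int, component: str) -> int:
    """Derive a per-component seed from a master seed by a fixed offset.

    Keeps every stage independently reproducible while all randomness flows
    from a single master seed.  Result is kept below 2**31.
    """
    return (int(master) * 1009 + _SEED_OFFSETS[component]) % (2**31 - 1)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SceneConfig:
    """One scene context: where liquid is poured and what it interacts with."""

    scene_id: str
    pour_location: tuple[float, float] = (0.5, 0.5)  # metres
    obstacle_map: np.ndarray | None = None  # bool grid, True = blocked
    source_rate: float = 1.0e-3  # m^3 / s
    perturbation: tuple[Literal["none", "stir", "noise"], float] = ("none", 0.0)
    domain_size: float = 1.0  # metres, square domain

    def __post_init__(self) -> None:
        if self.source_rate <= 0:
            raise ConfigurationError("source_rate must be positive")
        if self.domain_size <= 0:
            raise ConfigurationError("domain_size must be positive")
        kind, amp = self.perturbation
        if kind not in ("none", "stir", "noise"):
            raise ConfigurationError(f"unknown perturbation kind {kind!r}")
        if self.obstacle_map is not None:
            obs = np.asarray(self.obstacle_map, dtype=bool)
            if obs.ndim != 2 or obs.shape[0] != obs.shape[1]:
                raise ConfigurationError("obstacle_map must be a square 2D grid")
            object.__setattr__(self, "obstacle_map", obs)


@dataclass
class MeshFrame:
    """A single triangle-mesh frame; +z is up."""

    vertices: np.ndarray  # (V, 3) float, metres
    faces: np.ndarray  # (F, 3) int
    up_axis: str = "+z"

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        if len(self.faces) and self.faces.max() >= len(self.vertices):
            raise ValueError("face index out of range")

    def cleaned(self, area_eps: float = 1e-14) -> "MeshFrame":
        """Drop degenerate (near-zero-area) triangles."""
        if len(self.faces) == 0:
            return self
        v = self.vertices
        tri = v[self.faces]
        n = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
        area2 = np.linalg.norm(n, axis=1)
        return MeshFrame(self.vertices, self.faces[area2 > 2 * area_eps], self.up_axis)

    @property
    def is_empty(self) -> bool:
        return len(self.faces) == 0


@dataclass
class MeshSequence:
    """An ordered sequence of mesh frames for one stimulus."""

    frames: list[MeshFrame]
    fps: float
    viscosity: float
    scene: SceneConfig
    seed: int
    height_grids: np.ndarray | None = None  # (T, n, n), fast silhouette path
    dx: float | None = None  # grid spacing of height_grids, metres

    def __post_init__(self) -> None:
        if not (0.001 <= self.viscosity <= 100.0):
            raise ValueError("viscosity must lie in [0.001, 100] Pa·s")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def duration(self) -> float:
        return self.n_frames / self.fps


@dataclass
class RatingsTable:
    """Stimuli × columns slider ratings with per-row design metadata.

    ``values`` holds ratings in [0, 1]; ``meta`` (same index) carries
    viscosity (Pa·s), scene_id, time_period (1..6 or "full") and the
    repetition index.
    """

    values: pd.DataFrame
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        if len(self.values) != len(self.meta):
            raise ValueError("values and meta must have the same number of rows")
        v = self.values.to_numpy()
        if np.isnan(v).any():
            raise ValueError("ratings contain missing cells")
        if v.size and (v.min() < -1e-12 or v.max() > 1 + 1e-12):
            raise ValueError("ratings must lie in [0, 1]")

    @property
    def feature_names(self) -> list[str]:
        return list(self.values.columns)

    def average_repetitions(self) -> "RatingsTable":
        """Average over repetitions, one row per (viscosity, scene, period)."""
        keys = ["viscosity", "scene_id", "time_period"]
        df = pd.concat([self.meta[keys], self.values], axis=1)
        g = df.groupby(keys, sort=False, as_index=False).mean()
        meta = g[keys].copy()
        meta["repetition"] = 0
        return RatingsTable(g[self.values.columns].reset_index(drop=True),
                            meta.reset_index(drop=True))


@dataclass
class GroundTruth:
    """Generative model behind the simulated observers.

    loadings Λ (features × factors) with unit column sum-of-squares,
    per-stimulus factor scores F, regression weights β (intercept first)
    mapping factors to the viscosity slider, and the slider noise sd.
    """

    loadings: np.ndarray  # (n_features, n_factors)
    factor_scores: pd.DataFrame  # rows align with a design table
    regression_weights: np.ndarray  # (n_factors + 1,)
    noise_sd: float

    def __post_init__(self) -> None:
        self.loadings = np.asarray(self.loadings, dtype=float)
        self.regression_weights = np.asarray(self.regression_weights, dtype=float)
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        ss = (self.loadings**2).sum(axis=0)
        if not np.allclose(ss, 1.0, atol=1e-8):
            raise ValueError("loading columns must have unit sum-of-squares")
        if self.regression_weights.shape != (self.loadings.shape[1] + 1,):
            raise ValueError("regression_weights must have length n_factors + 1")


# ---------------------------------------------------------------------------
# viscosity design
# ---------------------------------------------------------------------------


def viscosity_grid(n_steps: int, lo: float = 0.001, hi: float = 100.0) -> np.ndarray:
    """Logarithmically spaced viscosity scale from ``lo`` to ``hi`` (Pa·s).

    The study scale is 64 geometric steps between 0.001 Pa·s (water) and
    100 Pa·s (molten glass); experiment subsets are drawn as geometric grids
    between their own stated endpoints.
    """
    if lo <= 0 or hi <= 0:
        raise ValueError("viscosity bounds must be positive")
    if not lo < hi:
        raise ValueError("require lo < hi")
    if n_steps < 2:
        raise ValueError("n_steps must be at least 2")
    return np.geomspace(lo, hi, n_steps)


_SET2_SCENE_IDS = [
    "pouring", "oozing_holes", "stirred", "waterwheel",
    "dam_break", "rain", "fountain", "ridge_flow",
]


def make_set1_design(n_viscosities: int = 32, lo: float = 0.001, hi: float = 80.30,
                     n_periods: int = 6, scene_id: str = "pouring") -> pd.DataFrame:
    """Set 1 design: pouring scene, 32 viscosities × 6 time periods = 192 rows."""
    visc = viscosity_grid(n_viscosities, lo, hi)
    rows = [(f"{scene_id}_v{i:02d}_t{t}", v, scene_id, t)
            for i, v in enumerate(visc) for t in range(1, n_periods + 1)]
    return pd.DataFrame(rows, columns=["stimulus_id", "viscosity", "scene_id", "time_period"])


def make_set2_design(n_viscosities: int = 7, lo: float = 0.004, hi: float = 7.74,
                     scene_ids: Sequence[str] | None = None) -> pd.DataFrame:
    """Set 2 design: 7 viscosities × 8 scenes = 56 rows, full 10 s sequences."""
    visc = viscosity_grid(n_viscosities, lo, hi)
    scenes = list(scene_ids) if scene_ids is not None else list(_SET2_SCENE_IDS)
    rows = [(f"{s}_v{i:02d}", v, s, "full")
            for s in scenes for i, v in enumerate(visc)]
    return pd.DataFrame(rows, columns=["stimulus_id", "viscosity", "scene_id", "time_period"])


def default_scenes(grid_n: int = 48) -> dict[str, SceneConfig]:
    """Eight scene configurations with qualitatively different interactions.

    Scene realism is not the goal; the scenes provide between-context
    variation (pour location, obstacles, stirring, source rate) against a
    shared viscosity axis.
    """
    def ring_obstacle(n: int) -> np.ndarray:
        yy, xx = np.mgrid[0:n, 0:n] / (n - 1)
        r = np.hypot(xx - 0.5, yy - 0.5)
        ring = (r > 0.28) & (r < 0.34)
        # punch four holes for liquid to ooze through
        ang = np.arctan2(yy - 0.5, xx - 0.5)
        for a in (0.0, np.pi / 2, np.pi, -np.pi / 2):
            ring &= ~(np.abs(np.angle(np.exp(1j * (ang - a)))) < 0.22)
        return ring

    def bar_obstacle(n: int) -> np.ndarray:
        obs = np.zeros((n, n), dtype=bool)
        obs[:, int(0.55 * n):int(0.60 * n)] = True
        obs[int(0.40 * n):int(0.60 * n), int(0.55 * n):int(0.60 * n)] = False
        return obs

    return {
        "pouring": SceneConfig("pouring"),
        "oozing_holes": SceneConfig("oozing_holes", obstacle_map=ring_obstacle(grid_n)),
        "stirred": SceneConfig("stirred", perturbation=("stir", 0.8)),
        "waterwheel": SceneConfig("waterwheel", pour_location=(0.35, 0.5),
                                  obstacle_map=bar_obstacle(grid_n),
                                  perturbation=("noise", 0.6)),
        "dam_break": SceneConfig("dam_break", pour_location=(0.2, 0.2),
                                 source_rate=2.0e-3),
        "rain": SceneConfig("rain", perturbation=("noise", 1.2), source_rate=6.0e-4),
        "fountain": SceneConfig("fountain", pour_location=(0.5, 0.65),
                                source_rate=1.5e-3, perturbation=("stir", 0.4)),
        "ridge_flow": SceneConfig("ridge_flow", pour_location=(0.3, 0.5),
                                  obstacle_map=bar_obstacle(grid_n), source_rate=1.25e-3),
    }


# ---------------------------------------------------------------------------
# height-field liquid simulator
# ---------------------------------------------------------------------------


def _triangulate_height_field(h: np.ndarray, dx: float) -> MeshFrame:
    """Regular-grid surface mesh of the height field, +z up, CCW from above."""
    n = h.shape[0]
    xs = (np.arange(n) + 0.5) * dx
    xx, yy = np.meshgrid(xs, xs, indexing="ij")
    verts = np.column_stack([xx.ravel(), yy.ravel(), h.ravel()])
    idx = np.arange(n * n).reshape(n, n)
    a = idx[:-1, :-1].ravel()
    b = idx[1:, :-1].ravel()
    c = idx[1:, 1:].ravel()
    d = idx[:-1, 1:].ravel()
    faces = np.concatenate([np.column_stack([a, b, c]), np.column_stack([a, c, d])])
    return MeshFrame(verts, faces)


def _source_blob(n: int, dx: float, loc_m: tuple[float, float], sigma_cells: float = 1.5) -> np.ndarray:
    """Unit-mass deposition kernel centred at a world location."""
    xs = (np.arange(n) + 0.5) * dx
    gx = np.exp(-0.5 * ((xs - loc_m[0]) / (sigma_cells * dx)) ** 2)
    gy = np.exp(-0.5 * ((xs - loc_m[1]) / (sigma_cells * dx)) ** 2)
    blob = np.outer(gx, gy)
    s = blob.sum()
    if s <= 0:
        raise ConfigurationError("pour location outside the domain")
    return blob / s


def generate_liquid_sequence(scene: SceneConfig, viscosity: float, n_frames: int = 300,
                             seed: int = 0, fps: float = 30.0, grid_n: int = 48,
                             keep_height_grids: bool = True) -> MeshSequence:
    """Simulate a pouring liquid as a diffusively relaxing height field.

    Volume ``source_rate * dt`` is deposited at the pour location each frame
    and spreads laterally with diffusion coefficient D = C_SPREAD/viscosity,
    so runnier liquids wet more of the domain.  Obstacle cells act as
    (approximately) no-flux: any mass diffused onto them is pushed back to
    the nearest free cell, which keeps total volume exactly conserved.
    Deterministic given (scene, viscosity, n_frames, seed).
    """
    if not (0.001 <= viscosity <= 100.0):
        raise ValueError("viscosity must lie in [0.001, 100] Pa·s")
    n = grid_n
    L = scene.domain_size
    dx = L / n
    dt = 1.0 / fps
    obs = scene.obstacle_map
    if obs is not None and obs.shape != (n, n):
        raise ConfigurationError(
            f"obstacle_map shape {obs.shape} does not match grid ({n}, {n})")

    pour_ix = (int(scene.pour_location[0] / L * n), int(scene.pour_location[1] / L * n))
    if obs is not None and obs[pour_ix]:
        raise ConfigurationError("obstacle covers the pour location")
    if obs is not None:
        # index map from every cell to its nearest free cell
        _, nearest = ndimage.distance_transform_edt(obs, return_indices=True)

    rng = np.random.default_rng(child_seed(seed, "perturb"))
    D = C_SPREAD / viscosity
    sigma_cells = np.sqrt(2.0 * D * dt) / dx

    kind, amp = scene.perturbation
    h = np.zeros((n, n))
    grids = np.empty((n_frames, n, n))
    cell_area = dx * dx
    for t in range(n_frames):
        loc = scene.pour_location
        if kind == "stir":
            # pour point orbits the domain centre
            ang = amp * t * dt * 2 * np.pi
            r0 = 0.18 * L
            loc = (L / 2 + r0 * np.cos(ang), L / 2 + r0 * np.sin(ang))
        h += (scene.source_rate * dt / cell_area) * _source_blob(n, dx, loc)
        if sigma_cells > 1e-3:
            h = ndimage.gaussian_filter(h, sigma_cells, mode="reflect")
        if obs is not None:
            leaked = h[obs]
            if leaked.size:
                h = h.copy()
                h[obs] = 0.0
                np.add.at(h, (nearest[0][obs], nearest[1][obs]), leaked)
        if kind == "noise" and amp > 0:
            total = h.sum()
            bump = ndimage.gaussian_filter(rng.standard_normal((n, n)), 3.0, mode="reflect")
            h = h * np.exp(amp * dt * bump)
            h *= total / h.sum()  # perturbation is mass-neutral
        grids[t] = h
    frames = [_triangulate_height_field(g, dx) for g in grids]
    return MeshSequence(frames, fps, viscosity, scene, seed,
                        height_grids=grids if keep_height_grids else None, dx=dx)


def footprint_area(seq: MeshSequence, frame: int, eps: float = DRY_EPS) -> float:
    """Wetted area (m²) at a frame: cells with height above ``eps``."""
    if seq.height_grids is None:
        raise ValueError("sequence has no stored height grids")
    return float((seq.height_grids[frame] > eps).sum()) * seq.dx**2


def sequence_volumes(seq: MeshSequence) -> np.ndarray:
    """Integrated height × cell area per frame (m³)."""
    if seq.height_grids is None:
        raise ValueError("sequence has no stored height grids")
    return seq.height_grids.sum(axis=(1, 2)) * seq.dx**2


# ---------------------------------------------------------------------------
# silhouette rendering
# ---------------------------------------------------------------------------


def _check_resolution(resolution: tuple[int, int]) -> tuple[int, int]:
    w, h = resolution
    if w * 3 != h * 4:
        raise ValueError(f"resolution {resolution} is not 4:3")
    return int(w), int(h)


def render_mesh_frame(frame: MeshFrame, resolution: tuple[int, int] = (800, 600),
                      window: tuple[tuple[float, float], tuple[float, float]] | None = None,
                      ) -> np.ndarray:
    """Orthographic side view (along +y) of one closed mesh frame.

    Returns an (H, W) image whose value at each pixel is the liquid's depth
    extent along the view axis (metres): each triangle is rasterised into
    its projected footprint with its interpolated y-coordinate, signed by
    the facing of its normal, and the signed contributions sum to the
    thickness of the enclosed volume.  Row 0 is the top of the image.
    """
    from skimage.draw import polygon as _polygon

    W, H = _check_resolution(resolution)
    img = np.zeros((H, W))
    if frame.is_empty:
        return img
    v, f = frame.vertices, frame.faces
    if window is None:
        x0, x1 = v[:, 0].min(), v[:, 0].max()
        span = max(x1 - x0, 1e-9) * 1.1
        cx = 0.5 * (x0 + x1)
        x0, x1 = cx - span / 2, cx + span / 2
        z0 = v[:, 2].min() - 0.05 * span
        z1 = z0 + span * H / W
    else:
        (x0, x1), (z0, z1) = window
    sx = W / (x1 - x0)
    sz = H / (z1 - z0)

    tri = v[f]  # (F, 3, 3)
    normals = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    signs = np.sign(normals[:, 1])
    cols3 = (tri[:, :, 0] - x0) * sx - 0.5
    rows3 = (H - 1) - ((tri[:, :, 2] - z0) * sz - 0.5)  # z up -> row 0 at top
    ys3 = tri[:, :, 1]
    for k in range(len(f)):
        if signs[k] == 0:
            continue
        r3, c3 = rows3[k], cols3[k]
        rr, cc = _polygon(r3, c3, shape=img.shape)
        if rr.size == 0:
            continue
        # barycentric interpolation of y over the projected triangle
        T = np.array([[c3[0] - c3[2], c3[1] - c3[2]],
                      [r3[0] - r3[2], r3[1] - r3[2]]])
        det = T[0, 0] * T[1, 1] - T[0, 1] * T[1, 0]
        if abs(det) < 1e-12:
            continue
        dx_ = cc - c3[2]
        dy_ = rr - r3[2]
        l0 = (T[1, 1] * dx_ - T[0, 1] * dy_) / det
        l1 = (-T[1, 0] * dx_ + T[0, 0] * dy_) / det
        l2 = 1.0 - l0 - l1
        yvals = l0 * ys3[k, 0] + l1 * ys3[k, 1] + l2 * ys3[k, 2]
        np.add.at(img, (rr, cc), signs[k] * yvals)
    return np.clip(img, 0.0, None)


def render_silhouette(seq: MeshSequence, resolution: tuple[int, int] = (800, 600)
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Render a mesh sequence to grayscale depth-extent frames plus masks.

    Returns ``(video, masks)`` with shapes (T, H, W); mask = intensity > 0.
    For height-field sequences the depth extent is computed directly from
    the stored grids (exact and fast); otherwise each frame goes through the
    triangle rasteriser.  The view window spans the scene domain with height
    3/4 of its width (4:3 frame).
    """
    W, H = _check_resolution(resolution)
    L = seq.scene.domain_size
    if seq.height_grids is not None:
        zmax = L * H / W
        z_centres = (np.arange(H) + 0.5) * zmax / H
        dy = seq.dx
        n = seq.height_grids.shape[1]
        col_to_ix = np.minimum((np.arange(W) * n) // W, n - 1)
        video = np.empty((seq.n_frames, H, W))
        for t, g in enumerate(seq.height_grids):
            hx = g[col_to_ix]  # (W, n) heights along y per column
            # for each column, number of y-cells whose surface lies above z
            counts = (hx[:, :, None] > z_centres[None, None, :]).sum(axis=1)
            video[t] = (counts.T * dy)[::-1]  # z up -> row 0 top
        return video, video > 0
    window = ((0.0, L), (0.0, L * H / W))
    video = np.stack([render_mesh_frame(fr, resolution, window) for fr in seq.frames])
    return video, video > 0


# ---------------------------------------------------------------------------
# ground-truth generative model and simulated observers
# ---------------------------------------------------------------------------


def default_loadings(n_features: int = 20, n_factors: int = 4,
                     primary: float = 0.8, cross: float = 0.05) -> np.ndarray:
    """Block loading structure: 5 features per factor, small cross-loadings.

    Each feature loads ``primary`` on its block factor and ``cross`` on the
    next factor (cyclically); columns are rescaled to unit sum-of-squares.
    The default cross-loading is kept small: larger cross-loadings damp
    exactly the between-factor contrasts that parallel analysis needs to
    resolve all four factors when the factors are mutually correlated
    through a shared viscosity axis.
    """
    if n_features % n_factors:
        raise ValueError("n_features must be divisible by n_factors")
    block = n_features // n_factors
    lam = np.zeros((n_features, n_factors))
    for j in range(n_factors):
        rows = slice(j * block, (j + 1) * block)
        lam[rows, j] = primary
        lam[rows, (j + 1) % n_factors] = cross
    return lam / np.sqrt((lam**2).sum(axis=0, keepdims=True))


_FACTOR_NAMES = ["distribution", "irregularity", "rectilinearity", "dynamics"]


def iid_factor_scores(design: pd.DataFrame, seed: int, n_factors: int = 4) -> pd.DataFrame:
    """Independent standard-normal factor scores, one row per design row."""
    rng = np.random.default_rng(child_seed(seed, "scores"))
    F = rng.standard_normal((len(design), n_factors))
    return pd.DataFrame(F, columns=_FACTOR_NAMES[:n_factors], index=design.index)


def _standardize(x: np.ndarray) -> np.ndarray:
    return (x - x.mean()) / x.std()


def monotone_factor_scores(design: pd.DataFrame, seed: int,
                           monotone_share: float = 0.9,
                           n_factors: int = 4,
                           centers: Sequence[float] = (-1.5, -0.5, 0.5, 1.5),
                           steepness: float = 12.0) -> pd.DataFrame:
    """Factor scores in which every factor is monotone in log viscosity.

    Factor k is a logistic response g_k(v) = σ(steepness·(v − c_k)) of the
    standardized log10 viscosity (variance share ``monotone_share``) plus
    iid unique variation.  With the default steep, staggered response
    centres the four factors form a staircase along the viscosity axis:
    each factor "switches on" over its own part of the range, which keeps
    the factors mutually distinguishable (so parallel analysis can resolve
    all four) while their sum — and hence the first principal component of
    the resulting ratings — remains strongly monotone in log viscosity.
    Smaller ``steepness`` (≈ 2) yields smooth, strongly inter-correlated
    response shapes instead.  The transform family is deterministic, so
    designs generated under different seeds share the same latent mapping —
    the basis of cross-context transfer.
    """
    if not 0.0 <= monotone_share <= 1.0:
        raise ValueError("monotone_share must lie in [0, 1]")
    rng = np.random.default_rng(child_seed(seed, "scores"))
    v = _standardize(np.log10(design["viscosity"].to_numpy(dtype=float)))
    cols = []
    for k in range(n_factors):
        c = centers[k % len(centers)]
        g = _standardize(1.0 / (1.0 + np.exp(-steepness * (v - c))))
        u = rng.standard_normal(len(design))
        cols.append(np.sqrt(monotone_share) * g + np.sqrt(1 - monotone_share) * u)
    F = np.column_stack(cols)
    return pd.DataFrame(F, columns=_FACTOR_NAMES[:n_factors], index=design.index)


def make_ground_truth(design: pd.DataFrame, seed: int,
                      scores: Literal["monotone", "iid"] = "monotone",
                      noise_sd: float = 0.05,
                      loadings: np.ndarray | None = None,
                      regression_weights: np.ndarray | None = None,
                      monotone_share: float = 0.9,
                      steepness: float = 12.0) -> GroundTruth:
    """Assemble the generative ground truth for a stimulus design."""
    lam = default_loadings() if loadings is None else np.asarray(loadings, float)
    if scores == "monotone":
        F = monotone_factor_scores(design, seed, monotone_share, lam.shape[1],
                                   steepness=steepness)
    elif scores == "iid":
        F = iid_factor_scores(design, seed, lam.shape[1])
    else:
        raise ValueError(f"unknown scores kind {scores!r}")
    if regression_weights is None:
        k = lam.shape[1]
        regression_weights = np.r_[0.5, np.full(k, 0.05)]
    return GroundTruth(lam, F, np.asarray(regression_weights, float), noise_sd)


def _rescale_unit(signal: np.ndarray, lo: float = 0.1, hi: float = 0.9) -> np.ndarray:
    """Column-wise affine map of the noiseless signal onto [lo, hi]."""
    mn = signal.min(axis=0, keepdims=True)
    mx = signal.max(axis=0, keepdims=True)
    span = np.where(mx - mn > 1e-12, mx - mn, 1.0)
    out = lo + (hi - lo) * (signal - mn) / span
    return np.where(mx - mn > 1e-12, out, (lo + hi) / 2)


_FEATURE_NAMES = [
    "compactness", "spread", "clumping", "coverage", "pooling",
    "irregularity", "detail", "roughness", "complexity", "wrinkling",
    "straightness", "angularity", "rectilinearity", "edginess", "flatness",
    "speed", "pulsing", "wobbling", "splashing", "runniness",
]


def _stack_repetitions(values_once: np.ndarray, design: pd.DataFrame,
                       repetitions: int, noise_sd: float, rng: np.random.Generator,
                       columns: list[str]) -> RatingsTable:
    vals, metas = [], []
    for rep in range(1, repetitions + 1):
        noisy = values_once + rng.normal(0.0, noise_sd, size=values_once.shape) \
            if noise_sd > 0 else values_once.copy()
        vals.append(np.clip(noisy, 0.0, 1.0))
        m = design[["viscosity", "scene_id", "time_period"]].copy()
        m["repetition"] = rep
        metas.append(m)
    values = pd.DataFrame(np.vstack(vals), columns=columns)
    meta = pd.concat(metas, ignore_index=True)
    return RatingsTable(values, meta)


def generate_feature_ratings(truth: GroundTruth, design: pd.DataFrame,
                             repetitions: int = 1, seed: int = 0) -> RatingsTable:
    """Simulated 20-feature slider ratings: clip([0,1]-rescaled F·Λᵀ + noise).

    Each repetition receives independent iid Gaussian slider noise; clipping
    to [0, 1] mirrors the bounded rating bar.
    """
    if repetitions < 1:
        raise ValueError("repetitions must be at least 1")
    if len(truth.factor_scores) != len(design):
        raise ValueError("factor scores not defined for every design row")
    signal = truth.factor_scores.to_numpy() @ truth.loadings.T
    signal = _rescale_unit(signal)
    rng = np.random.default_rng(child_seed(seed, "features"))
    names = _FEATURE_NAMES[: truth.loadings.shape[0]]
    if len(names) < truth.loadings.shape[0]:
        names = names + [f"feature_{i}" for i in range(len(names), truth.loadings.shape[0])]
    return _stack_repetitions(signal, design, repetitions, truth.noise_sd, rng, names)


def generate_viscosity_ratings(truth: GroundTruth, design: pd.DataFrame,
                               repetitions: int = 4, seed: int = 0) -> RatingsTable:
    """Simulated viscosity slider: clip(β₀ + F·β₁..k + noise) per repetition."""
    if repetitions < 1:
        raise ValueError("repetitions must be at least 1")
    if len(truth.factor_scores) != len(design):
        raise ValueError("factor scores not defined for every design row")
    beta = truth.regression_weights
    raw = beta[0] + truth.factor_scores.to_numpy() @ beta[1:]
    rng = np.random.default_rng(child_seed(seed, "viscosity"))
    return _stack_repetitions(raw[:, None], design, repetitions, truth.noise_sd,
                              rng, ["viscosity_rating"])
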