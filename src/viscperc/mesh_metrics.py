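"""Discrete curvature machinery and the four 3D shape metrics.

Per-vertex principal curvatures (κ1 ≥ κ2) come from a local quadric fit in
the vertex tangent frame over an n-ring neighborhood; the Koenderink shape
index S classifies local surface type on [−1, 1].  From these the module
builds four per-frame mesh measurements:

* M1 angular curvature — area-weighted mean of |H|·w(S), emphasising
  angular features (default weighting w(S) = |S|);
* M2 flatness — area-weighted sum of |n·ẑ|, large when the surface forms
  horizontal planes;
* M3 centre-of-mass height — z of the volume centroid (surface centroid
  fallback for open meshes);
* M4 total absolute curvature — ∫|K| dA, large for convoluted surfaces
  (|H| variant behind a flag).

Sign convention: curvatures are positive where the surface bends away from
the outward normal, so a sphere has κ1 = κ2 = +1/r and S = +1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Literal, Sequence

import numpy as np
import pandas as pd
import trimesh
from scipy import sparse

from .synth import MeshFrame, MeshSequence

__all__ = [
    "CurvatureField",
    "principal_curvatures",
    "shape_index",
    "metric_angular_curvature",
    "metric_flatness",
    "metric_com_height",
    "metric_total_abs_curvature",
    "frame_metrics",
    "extract_metrics",
    "DegenerateDesignError",
]

METRIC_NAMES = ["m1_angular_curvature", "m2_flatness", "m3_com_height",
                "m4_total_abs_curvature"]


class DegenerateDesignError(ValueError):
    """Raised when between-stimulus normalization is undefined."""


@dataclass
class CurvatureField:
    """Per-vertex curvature data; NaN where curvature is undefined."""

    k1: np.ndarray  # principal curvatures, k1 >= k2, 1/m
    k2: np.ndarray
    area_weights: np.ndarray  # barycentric vertex areas, m^2
    boundary: np.ndarray  # bool, True at boundary vertices
    normals: np.ndarray  # (V, 3) outward vertex normals

    @property
    def defined(self) -> np.ndarray:
        return ~np.isnan(self.k1) & ~self.boundary

    @property
    def mean_curvature(self) -> np.ndarray:
        return 0.5 * (self.k1 + self.k2)

    @property
    def gaussian_curvature(self) -> np.ndarray:
        return self.k1 * self.k2

    @property
    def shape_index(self) -> np.ndarray:
        return shape_index(self.k1, self.k2)


def _as_trimesh(frame: MeshFrame) -> trimesh.Trimesh:
    return trimesh.Trimesh(vertices=frame.vertices, faces=frame.faces, process=False)


def _vertex_areas(mesh: trimesh.Trimesh) -> np.ndarray:
    """Barycentric vertex areas: one third of each incident face's area."""
    areas = np.zeros(len(mesh.vertices))
    np.add.at(areas, mesh.faces.ravel(), np.repeat(mesh.area_faces / 3.0, 3))
    return areas


def _boundary_vertices(mesh: trimesh.Trimesh) -> np.ndarray:
    """Vertices on edges that belong to exactly one face."""
    flags = np.zeros(len(mesh.vertices), dtype=bool)
    edges = mesh.edges_sorted
    uniq, counts = np.unique(edges, axis=0, return_counts=True)
    flags[uniq[counts == 1].ravel()] = True
    return flags


def _ring_neighbors(mesh: trimesh.Trimesh, rings: int) -> sparse.csr_matrix:
    """Boolean vertex adjacency within ``rings`` edge hops (self excluded)."""
    V = len(mesh.vertices)
    e = mesh.edges_unique
    A = sparse.csr_matrix(
        (np.ones(2 * len(e), dtype=bool),
         (np.r_[e[:, 0], e[:, 1]], np.r_[e[:, 1], e[:, 0]])), shape=(V, V))
    reach = A.copy()
    power = A
    for _ in range(rings - 1):
        power = (power @ A).astype(bool)
        reach = (reach + power).astype(bool)
    reach = reach.tolil()
    reach.setdiag(False)
    return reach.tocsr()


def principal_curvatures(frame: MeshFrame, neighborhood_rings: int = 2,
                         min_neighbors: int = 5) -> CurvatureField:
    """Per-vertex (κ1, κ2) from a batched local quadric fit.

    For every vertex, neighbor offsets are expressed in an orthonormal
    tangent frame (e1, e2, n) and a full quadric
    w = a u² + b uv + c v² + d u + e v is fit by least squares; the shape
    operator follows from the first and second fundamental forms of the fit.
    Vertices with fewer than ``min_neighbors`` usable neighbors get NaN;
    boundary vertices are flagged and excluded from every aggregate.
    """
    if neighborhood_rings < 1:
        raise ValueError("neighborhood_rings must be >= 1")
    frame = frame.cleaned()
    mesh = _as_trimesh(frame)
    V = len(mesh.vertices)
    if V == 0:
        z = np.zeros(0)
        return CurvatureField(z, z, z, z.astype(bool), np.zeros((0, 3)))
    normals = np.asarray(mesh.vertex_normals, dtype=float)
    areas = _vertex_areas(mesh)
    boundary = _boundary_vertices(mesh)
    reach = _ring_neighbors(mesh, neighborhood_rings)

    counts = np.diff(reach.indptr)
    kmax = int(counts.max()) if V else 0
    # padded neighbor index array; padding points at the vertex itself
    nbr = np.repeat(np.arange(V)[:, None], kmax, axis=1)
    mask = np.zeros((V, kmax), dtype=bool)
    for i in range(V):
        c = counts[i]
        nbr[i, :c] = reach.indices[reach.indptr[i]:reach.indptr[i + 1]]
        mask[i, :c] = True

    verts = np.asarray(mesh.vertices, dtype=float)
    n = normals
    # tangent frames: e1 orthogonal to n, e2 = n × e1
    ref = np.tile(np.array([1.0, 0.0, 0.0]), (V, 1))
    swap = np.abs(n[:, 0]) > 0.9
    ref[swap] = [0.0, 1.0, 0.0]
    e1 = np.cross(n, ref)
    e1 /= np.linalg.norm(e1, axis=1, keepdims=True)
    e2 = np.cross(n, e1)

    off = verts[nbr] - verts[:, None, :]  # (V, K, 3)
    u = np.einsum("vkj,vj->vk", off, e1)
    v = np.einsum("vkj,vj->vk", off, e2)
    w = np.einsum("vkj,vj->vk", off, n)

    X = np.stack([u * u, u * v, v * v, u, v], axis=-1)  # (V, K, 5)
    Wm = mask[:, :, None].astype(float)
    XtX = np.einsum("vki,vkj->vij", X * Wm, X)
    Xtw = np.einsum("vki,vk->vi", X * Wm, w)
    XtX += 1e-12 * np.eye(5)
    with np.errstate(all="ignore"):
        coef = np.linalg.solve(XtX, Xtw[..., None])[..., 0]  # (V, 5)
    a, b, c, d, e = coef.T

    # fundamental forms of w(u, v) with the fitted gradient at the vertex
    s = np.sqrt(1.0 + d * d + e * e)
    E = 1.0 + d * d
    F = d * e
    G = 1.0 + e * e
    L = 2.0 * a / s
    M = b / s
    N = 2.0 * c / s
    det_I = E * G - F * F
    # shape operator I^-1 II; positive where bending away from outward normal
    s11 = (G * L - F * M) / det_I
    s12 = (G * M - F * N) / det_I
    s21 = (E * M - F * L) / det_I
    s22 = (E * N - F * M) / det_I
    tr = s11 + s22
    dt = s11 * s22 - s12 * s21
    disc = np.sqrt(np.maximum(tr * tr / 4.0 - dt, 0.0))
    k_hi = -(tr / 2.0 - disc)  # sign flip: outward-normal convention
    k_lo = -(tr / 2.0 + disc)
    k1 = np.maximum(k_hi, k_lo)
    k2 = np.minimum(k_hi, k_lo)

    bad = counts < min_neighbors
    k1[bad] = np.nan
    k2[bad] = np.nan
    return CurvatureField(k1, k2, areas, boundary, normals)


def shape_index(k1: np.ndarray, k2: np.ndarray, tol: float = 1e-9) -> np.ndarray:
    """Koenderink shape index S = (2/π)·arctan((κ1+κ2)/(κ1−κ2)), κ1 ≥ κ2.

    Umbilic points (|κ1−κ2| < tol) map to sign(H)·1; flat points (both
    curvatures below tol) map to 0, making S a total function on [−1, 1].
    """
    k1 = np.asarray(k1, dtype=float)
    k2 = np.asarray(k2, dtype=float)
    H = 0.5 * (k1 + k2)
    flat = (np.abs(k1) < tol) & (np.abs(k2) < tol)
    umbilic = np.abs(k1 - k2) < tol
    with np.errstate(divide="ignore", invalid="ignore"):
        S = (2.0 / np.pi) * np.arctan((k1 + k2) / (k1 - k2))
    S = np.where(umbilic, np.sign(H), S)
    S = np.where(flat, 0.0, S)
    return S


def _defined_or_nan(field: CurvatureField) -> np.ndarray:
    ok = field.defined
    if not ok.any():
        return ok  # caller turns this into NaN
    return ok


def metric_angular_curvature(field: CurvatureField,
                             weighting: Callable[[np.ndarray], np.ndarray] | None = None
                             ) -> float:
    """M1: area-weighted mean of |H| · w(S) over defined interior vertices.

    The default weighting w(S) = |S| up-weights dome/cup and ridge/rut
    vertices over saddles, emphasising angular features.
    """
    w_fn = (lambda S: np.abs(S)) if weighting is None else weighting
    ok = field.defined
    if not ok.any():
        return float("nan")
    H = field.mean_curvature[ok]
    S = field.shape_index[ok]
    a = field.area_weights[ok]
    return float(np.sum(np.abs(H) * w_fn(S) * a) / np.sum(a))


def metric_flatness(frame: MeshFrame, field: CurvatureField | None = None) -> float:
    """M2: area-weighted sum of |n·ẑ| — total horizontally facing area."""
    if field is None:
        mesh = _as_trimesh(frame.cleaned())
        normals = np.asarray(mesh.vertex_normals, dtype=float)
        areas = _vertex_areas(mesh)
    else:
        normals, areas = field.normals, field.area_weights
    if len(normals) == 0:
        return float("nan")
    return float(np.sum(np.abs(normals[:, 2]) * areas))


def metric_com_height(frame: MeshFrame) -> tuple[float, bool]:
    """M3: z of the volume centroid; (value, used_volume_centroid).

    Watertight meshes use the signed-tetrahedron volume centroid; open or
    zero-volume meshes fall back to the area-weighted surface centroid and
    are flagged by the second return value being False.
    """
    mesh = _as_trimesh(frame.cleaned())
    if len(mesh.faces) == 0:
        return float("nan"), False
    if mesh.is_watertight and abs(mesh.volume) > 1e-12:
        return float(mesh.center_mass[2]), True
    centroid = (mesh.triangles_center * mesh.area_faces[:, None]).sum(axis=0) / mesh.area
    return float(centroid[2]), False


def metric_total_abs_curvature(field: CurvatureField,
                               variant: Literal["gaussian", "mean"] = "gaussian"
                               ) -> float:
    """M4: ∫|K| dA (total absolute curvature); ``mean`` variant uses |H|."""
    ok = field.defined
    if not ok.any():
        return float("nan")
    kappa = field.gaussian_curvature if variant == "gaussian" else field.mean_curvature
    return float(np.sum(np.abs(kappa[ok]) * field.area_weights[ok]))


def frame_metrics(frame: MeshFrame, neighborhood_rings: int = 2,
                  m4_variant: Literal["gaussian", "mean"] = "gaussian",
                  dry_height: float | None = None) -> dict:
    """All four raw metrics for one frame.

    ``dry_height``: for height-field meshes, vertices at or below this z are
    part of the dry floor, not the liquid, and are cropped before
    measurement (their flat geometry would otherwise swamp the metrics).
    """
    if dry_height is not None:
        keep = frame.vertices[:, 2] > dry_height
        fmask = keep[frame.faces].any(axis=1)
        used = np.unique(frame.faces[fmask])
        keep2 = np.zeros(len(frame.vertices), dtype=bool)
        keep2[used] = True
        old2new = np.cumsum(keep2) - 1
        frame = MeshFrame(frame.vertices[keep2], old2new[frame.faces[fmask]])
    if frame.is_empty:
        return {m: float("nan") for m in METRIC_NAMES} | {"volume_centroid": False}
    field = principal_curvatures(frame, neighborhood_rings)
    com, vol_ok = metric_com_height(frame)
    return {
        "m1_angular_curvature": metric_angular_curvature(field),
        "m2_flatness": metric_flatness(frame, field),
        "m3_com_height": com,
        "m4_total_abs_curvature": metric_total_abs_curvature(field, m4_variant),
        "volume_centroid": vol_ok,
    }


def _zscore_columns(df: pd.DataFrame, cols: Sequence[str],
                    by_scene: bool = False) -> pd.DataFrame:
    if len(df) < 2:
        raise DegenerateDesignError("z-normalization needs at least 2 stimuli")
    out = df.copy()
    groups = df.groupby("scene_id").groups.values() if by_scene else [df.index]
    for c in cols:
        z = np.full(len(df), np.nan)
        for idx in groups:
            x = df.loc[idx, c].to_numpy(dtype=float)
            sd = x.std()  # population convention
            if sd < 1e-15 or not np.isfinite(sd):
                raise DegenerateDesignError(f"zero variance across stimuli for {c}")
            z[df.index.get_indexer(idx)] = (x - x.mean()) / sd
        out[c + "_z"] = z
    return out


def extract_metrics(sequences: Sequence[MeshSequence],
                    aggregation: Literal["per_time_period", "full_sequence"] = "full_sequence",
                    n_periods: int = 6, frame_step: int = 1,
                    neighborhood_rings: int = 2,
                    dry_height: float | None = None,
                    normalize: Literal["global", "per_scene"] = "global"
                    ) -> pd.DataFrame:
    """Per-stimulus metric vectors with the stated aggregation and normalization.

    ``full_sequence``: the mean of each metric over frames gives one row per
    sequence.  ``per_time_period``: frames split into ``n_periods`` equal
    slices; the within-slice median gives one row per (sequence, period),
    and each metric is then divided by its across-period median within the
    sequence family to compensate for mesh growth over time.  Both modes end
    with a z-normalization (population sd) of each metric across the
    stimulus set; a degenerate design (fewer than 2 stimuli, or zero
    variance) raises DegenerateDesignError.  With ``normalize="per_scene"``
    each metric is z-scored within its scene instead, which removes
    between-scene offsets so that one set of regression weights can apply
    across contexts.  ``frame_step`` subsamples frames uniformly before
    aggregation.
    """
    rows = []
    for si, seq in enumerate(sequences):
        per_frame = []
        for t in range(0, seq.n_frames, frame_step):
            m = frame_metrics(seq.frames[t], neighborhood_rings, dry_height=dry_height)
            m["frame"] = t
            per_frame.append(m)
        pf = pd.DataFrame(per_frame)
        base = {"sequence": si, "viscosity": seq.viscosity,
                "scene_id": seq.scene.scene_id}
        if aggregation == "full_sequence":
            row = dict(base, time_period="full")
            for c in METRIC_NAMES:
                row[c] = float(np.nanmean(pf[c]))
            rows.append(row)
        elif aggregation == "per_time_period":
            edges = np.linspace(0, seq.n_frames, n_periods + 1)
            period = np.searchsorted(edges, pf["frame"], side="right")
            med = pf[METRIC_NAMES].groupby(period).median()
            fam = med.median(axis=0)  # across-period median per family
            med = med / fam.replace(0.0, np.nan)
            for p, r in med.iterrows():
                rows.append(dict(base, time_period=int(p), **r.to_dict()))
        else:
            raise ValueError(f"unknown aggregation {aggregation!r}")
    df = pd.DataFrame(rows)
    return _zscore_columns(df, METRIC_NAMES, by_scene=(normalize == "per_scene"))
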