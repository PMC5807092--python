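"""File interchange: OBJ/PLY mesh frame directories, CSV ratings/metrics
tables with config-hash headers, JSON model serialization."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import trimesh

from .synth import MeshFrame, MeshSequence, RatingsTable

__all__ = [
    "write_mesh_sequence", "read_mesh_frames",
    "write_table", "read_table",
    "write_ratings", "read_ratings",
    "write_json", "read_json", "config_hash",
]


def config_hash(config: dict) -> str:
    """Stable short hash of a configuration mapping."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def write_mesh_sequence(seq: MeshSequence, out_dir: str | Path,
                        fmt: str = "obj") -> list[Path]:
    """One mesh file per frame, zero-padded frame index in the name."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, fr in enumerate(seq.frames):
        p = out / f"frame_{i:04d}.{fmt}"
        trimesh.Trimesh(vertices=fr.vertices, faces=fr.faces, process=False).export(p)
        paths.append(p)
    return paths


def read_mesh_frames(mesh_dir: str | Path) -> list[MeshFrame]:
    """Load all OBJ/PLY frames from a directory, ordered by filename."""
    paths = sorted(p for p in Path(mesh_dir).iterdir()
                   if p.suffix.lower() in (".obj", ".ply"))
    frames = []
    for p in paths:
        m = trimesh.load_mesh(p, process=False)
        frames.append(MeshFrame(np.asarray(m.vertices), np.asarray(m.faces)))
    return frames


def write_table(df: pd.DataFrame, path: str | Path, cfg_hash: str | None = None) -> Path:
    """CSV with an optional ``# config_hash=...`` comment header line."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        if cfg_hash is not None:
            fh.write(f"# config_hash={cfg_hash}\n")
        df.to_csv(fh, index=False)
    return path


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def write_ratings(table: RatingsTable, path: str | Path,
                  cfg_hash: str | None = None) -> Path:
    df = pd.concat([table.meta.reset_index(drop=True),
                    table.values.reset_index(drop=True)], axis=1)
    return write_table(df, path, cfg_hash)


def read_ratings(path: str | Path) -> RatingsTable:
    df = read_table(path)
    meta_cols = ["viscosity", "scene_id", "time_period", "repetition"]
    return RatingsTable(df.drop(columns=meta_cols), df[meta_cols])


def write_json(obj: dict, path: str | Path, cfg_hash: str | None = None) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if cfg_hash is not None:
        obj = {"config_hash": cfg_hash, **obj}
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=_json_default))
    return path


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


def read_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
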