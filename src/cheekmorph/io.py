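"""Mesh and landmark file I/O.

Meshes are STL (ASCII or binary) or PLY, millimetres assumed.  Landmark
files are either a JSON object ``{name: [x, y, z]}`` or a CSV with columns
``name,x,y,z``; names follow the standard abbreviations (Ex_L, Ex_R, C_L,
C_R, Al_L, Al_R, Sn, Or_L, Or_R, Po_L, Po_R, N, S, Ba, U1, U6_L, U6_R).
"""

from __future__ import annotations

import csv
import json
from pathlib import Path
from typing import Union

import numpy as np
import trimesh

from .anatomy import LandmarkSet
from .errors import FormatError

PathLike = Union[str, Path]


def read_mesh(path: PathLike) -> trimesh.Trimesh:
    """Load a surface mesh, validating that it is a non-empty triangulation."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"mesh file not found: {path}")
    try:
        mesh = trimesh.load(str(path), force="mesh", process=False)
    except Exception as exc:
        raise FormatError(f"unreadable mesh file {path}: {exc}") from exc
    if not isinstance(mesh, trimesh.Trimesh) or len(mesh.faces) == 0:
        raise FormatError(f"degenerate mesh file {path}: no triangles")
    if not np.all(np.isfinite(mesh.vertices)):
        raise FormatError(f"degenerate mesh file {path}: non-finite vertices")
    return mesh


def write_mesh(mesh: trimesh.Trimesh, path: PathLike) -> Path:
    """Write STL (ASCII) or PLY depending on the file suffix."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    suffix = path.suffix.lower()
    if suffix == ".stl":
        path.write_text(mesh.export(file_type="stl_ascii"))
    elif suffix == ".ply":
        data = trimesh.exchange.ply.export_ply(mesh, encoding="ascii")
        path.write_bytes(data if isinstance(data, bytes) else data.encode())
    else:
        raise FormatError(f"unsupported mesh format: {path}")
    return path


def read_landmarks(path: PathLike) -> LandmarkSet:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"landmark file not found: {path}")
    try:
        if path.suffix.lower() == ".json":
            data = json.loads(path.read_text())
            points = {str(k): np.asarray(v, float) for k, v in data.items()}
        else:
            points = {}
            with open(path, newline="") as fh:
                for row in csv.DictReader(fh):
                    points[row["name"]] = np.array(
                        [float(row["x"]), float(row["y"]), float(row["z"])])
    except FormatError:
        raise
    except Exception as exc:
        raise FormatError(f"unreadable landmark file {path}: {exc}") from exc
    return LandmarkSet(points)


def write_landmarks(lm: LandmarkSet, path: PathLike) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(
            {k: [float(x) for x in v] for k, v in lm.points.items()}, indent=1))
    else:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["name", "x", "y", "z"])
            for k, v in lm.points.items():
                w.writerow([k, f"{v[0]:.6f}", f"{v[1]:.6f}", f"{v[2]:.6f}"])
    return path
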