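"""Volume and table I/O.

Volumes are MRC2014 files read and written with :mod:`mrcfile`.  Internally
all grids are indexed ``(x, y, z)`` with 0-based voxel indices; MRC stores the
fastest-varying axis last (section/row/column = z/y/x), so data are transposed
on read and write.  Voxel size is kept in nanometres (MRC headers carry
Angstroms; divided by 10 on read).  All geometry downstream is computed in
voxel units; nm enter only when lengths are reported.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import mrcfile
import numpy as np
import pandas as pd

from .errors import ParameterError, VolumeFormatError

__all__ = [
    "ScalarVolume",
    "BinaryVolume",
    "LabelVolume",
    "read_volume",
    "write_volume",
    "isolate_label",
    "write_points",
    "read_points",
    "write_graph",
]


@dataclass
class ScalarVolume:
    """A 3D real-valued field (e.g. a saliency map) indexed ``(x, y, z)``."""

    data: np.ndarray
    voxel_size: float = 1.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ParameterError(f"volume must be 3D, got shape {self.data.shape}")
        if self.voxel_size <= 0:
            raise ParameterError(f"voxel_size must be > 0, got {self.voxel_size}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


@dataclass
class BinaryVolume:
    """A 3D {0,1} mask indexed ``(x, y, z)``."""

    data: np.ndarray
    voxel_size: float = 1.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ParameterError(f"volume must be 3D, got shape {self.data.shape}")
        if self.voxel_size <= 0:
            raise ParameterError(f"voxel_size must be > 0, got {self.voxel_size}")
        vals = np.unique(self.data)
        if not np.isin(vals, (0, 1)).all():
            raise ParameterError("binary volume may contain only 0 and 1")
        self.data = self.data.astype(np.uint8, copy=False)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


@dataclass
class LabelVolume:
    """A 3D multi-label segmentation; label 0 is reserved for background."""

    data: np.ndarray
    voxel_size: float = 1.0
    label_names: dict[int, str] | None = field(default=None)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ParameterError(f"volume must be 3D, got shape {self.data.shape}")
        if self.voxel_size <= 0:
            raise ParameterError(f"voxel_size must be > 0, got {self.voxel_size}")
        if self.data.min() < 0:
            raise ParameterError("labels must be non-negative integers")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


_INT_MODES = {0, 1, 3, 6}
_FLOAT_MODES = {2, 12}


def read_volume(path):
    """Read an MRC2014 volume.

    Integer modes yield a :class:`BinaryVolume` (if the values are a subset of
    {0, 1}) or a :class:`LabelVolume`; float modes yield a
    :class:`ScalarVolume`.  The voxel size is taken from the header cell
    spacing and converted to nm.
    """
    path = Path(path)
    try:
        with mrcfile.open(path, permissive=False) as mrc:
            mode = int(mrc.header.mode)
            if mode not in _INT_MODES | _FLOAT_MODES:
                raise VolumeFormatError(f"unsupported MRC mode {mode} in {path}")
            data = np.asarray(mrc.data).T.copy()  # (z,y,x) -> (x,y,z)
            vs = float(mrc.voxel_size.x) / 10.0  # Angstrom -> nm
    except VolumeFormatError:
        raise
    except Exception as exc:  # truncated/corrupt files
        raise VolumeFormatError(f"cannot read MRC file {path}: {exc}") from exc
    if vs <= 0:
        vs = 1.0
    if mode in _FLOAT_MODES:
        return ScalarVolume(data.astype(np.float32, copy=False), vs)
    vals = np.unique(data)
    if np.isin(vals, (0, 1)).all():
        return BinaryVolume(data, vs)
    return LabelVolume(data, vs)


def write_volume(vol, path) -> None:
    """Write a volume as MRC2014 (binary: mode 0, labels: 0/1, scalar: mode 2)."""
    if isinstance(vol, BinaryVolume):
        out = vol.data.astype(np.int8)
    elif isinstance(vol, LabelVolume):
        out = vol.data.astype(np.int8 if vol.data.max() < 128 else np.int16)
    elif isinstance(vol, ScalarVolume):
        out = vol.data.astype(np.float32)
    else:
        raise ParameterError(f"unsupported volume type {type(vol).__name__}")
    with mrcfile.new(str(path), overwrite=True) as mrc:
        mrc.set_data(out.T.copy())  # (x,y,z) -> (z,y,x)
        mrc.voxel_size = vol.voxel_size * 10.0  # nm -> Angstrom


def isolate_label(vol: LabelVolume, label: int) -> BinaryVolume:
    """Binary mask of one class of a multi-label segmentation.

    ``label=0`` selects the background.  An absent label yields an all-zero
    mask and a warning.
    """
    mask = (vol.data == label).astype(np.uint8)
    if label != 0 and mask.sum() == 0:
        warnings.warn(f"label {label} not present; returning empty mask", stacklevel=2)
    return BinaryVolume(mask, vol.voxel_size)


def write_points(points, path, columns: dict | None = None) -> None:
    """Write a point set as CSV with header ``x,y,z[,extra...]``.

    Coordinates are voxel units.  ``columns`` maps extra column names to
    per-point arrays of the same length.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if points.size == 0:
        points = points.reshape(0, 3)
    if points.shape[1] != 3:
        raise ParameterError("points must be an (n, 3) array")
    df = pd.DataFrame(points, columns=["x", "y", "z"])
    for name, vals in (columns or {}).items():
        df[name] = np.asarray(vals)
    df.to_csv(path, index=False, float_format="%.8g")


def read_points(path) -> pd.DataFrame:
    """Read a CSV point table written by :func:`write_points`."""
    df = pd.read_csv(path)
    for c in ("x", "y", "z"):
        if c not in df.columns:
            raise VolumeFormatError(f"point table {path} lacks column '{c}'")
    return df


def write_graph(graph, path_prefix, vtk: bool = False) -> None:
    """Write a spatial graph as ``<prefix>_nodes.csv`` / ``<prefix>_edges.csv``.

    Nodes carry ``id,x,y,z,filament_id`` (filament_id empty when unset), edges
    ``source,target,length``.  With ``vtk=True`` an additional legacy ASCII
    polydata file ``<prefix>.vtk`` holds the same polyline set.
    """
    prefix = str(path_prefix)
    g = graph.graph
    ids = sorted(g.nodes)
    rows = []
    for n in ids:
        x, y, z = g.nodes[n]["pos"]
        rows.append((n, x, y, z, g.nodes[n].get("filament_id", "")))
    pd.DataFrame(rows, columns=["id", "x", "y", "z", "filament_id"]).to_csv(
        f"{prefix}_nodes.csv", index=False, float_format="%.8g"
    )
    erows = [
        (min(u, v), max(u, v), g.edges[u, v]["length"]) for u, v in sorted(
            (tuple(sorted(e)) for e in g.edges), key=lambda e: (e[0], e[1])
        )
    ]
    pd.DataFrame(erows, columns=["source", "target", "length"]).to_csv(
        f"{prefix}_edges.csv", index=False, float_format="%.8g"
    )
    if vtk:
        _write_vtk_polydata(g, ids, f"{prefix}.vtk")


def _write_vtk_polydata(g, ids, path) -> None:
    index = {n: i for i, n in enumerate(ids)}
    lines = [
        "# vtk DataFile Version 3.0",
        "skeletrace spatial graph",
        "ASCII",
        "DATASET POLYDATA",
        f"POINTS {len(ids)} float",
    ]
    for n in ids:
        x, y, z = g.nodes[n]["pos"]
        lines.append(f"{x:.6g} {y:.6g} {z:.6g}")
    edges = list(g.edges)
    lines.append(f"LINES {len(edges)} {3 * len(edges)}")
    for u, v in edges:
        lines.append(f"2 {index[u]} {index[v]}")
    Path(path).write_text("\n".join(lines) + "\n")
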