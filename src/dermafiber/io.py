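"""File input/output: fiber polyline tables, image stacks, metrics, VTK.

Image stacks are written as multi-page 16-bit TIFF with one page per slice
along the y axis (the compression / skin-surface normal), so a stack reads
like a top-down confocal series. Meshes and polylines are exported as ASCII
legacy VTK for inspection in ParaView.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .fibers import FiberPolyline
from .imaging import VoxelVolume
from .mechanics.mesh import TetMeshModel

FIBER_CSV_COLUMNS = ["fiber_id", "point_index", "x_um", "y_um", "z_um", "radius_um"]


def write_fiber_csv(path: str | Path, fibers: list[FiberPolyline]) -> None:
    """One row per polyline point."""
    rows = []
    for f in fibers:
        for i, (p, r) in enumerate(zip(f.points, f.radii)):
            rows.append((f.fiber_id, i, p[0], p[1], p[2], r))
    df = pd.DataFrame(rows, columns=FIBER_CSV_COLUMNS)
    df.to_csv(path, index=False)


def read_fiber_csv(path: str | Path) -> list[FiberPolyline]:
    df = pd.read_csv(path)
    missing = [c for c in FIBER_CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"fiber CSV missing columns: {missing}")
    fibers = []
    for fid, grp in df.groupby("fiber_id", sort=True):
        grp = grp.sort_values("point_index")
        pts = grp[["x_um", "y_um", "z_um"]].to_numpy(dtype=float)
        radii = grp["radius_um"].to_numpy(dtype=float)
        fibers.append(FiberPolyline(points=pts, radii=radii, fiber_id=int(fid)))
    return fibers


def write_tiff_stack(path: str | Path, volume: VoxelVolume) -> None:
    """16-bit multi-page TIFF, pages along y; in-page rows are z, columns x."""
    data = np.clip(np.round(volume.data), 0, np.iinfo(np.uint16).max).astype(np.uint16)
    pages = np.transpose(data, (1, 2, 0))  # (y, z, x)
    tifffile.imwrite(
        path,
        pages,
        metadata={
            "spacing_um": list(map(float, volume.spacing)),
            "origin_um": list(map(float, volume.origin)),
            "axes_order": "y-pages, z-rows, x-cols",
        },
    )


def write_mask_tiff(path: str | Path, mask) -> None:
    """8-bit multi-page TIFF (0/255) of a binary mask, pages along y."""
    data = np.where(mask.data, 255, 0).astype(np.uint8)
    pages = np.transpose(data, (1, 2, 0))
    tifffile.imwrite(
        path,
        pages,
        metadata={
            "spacing_um": list(map(float, mask.spacing)),
            "origin_um": list(map(float, mask.origin)),
            "axes_order": "y-pages, z-rows, x-cols",
        },
    )


def read_tiff_stack(
    path: str | Path, spacing: np.ndarray | None = None
) -> VoxelVolume:
    """Read a stack written by :func:`write_tiff_stack`.

    ``spacing`` overrides the embedded metadata (required when the file was
    produced elsewhere and carries none)."""
    with tifffile.TiffFile(path) as tf:
        pages = tf.asarray()
        meta = tf.shaped_metadata or tf.imagej_metadata
    if pages.ndim == 2:
        pages = pages[None]
    data = np.transpose(pages.astype(float), (2, 0, 1))  # back to (x, y, z)
    sp = None
    origin = np.zeros(3)
    if isinstance(meta, (list, tuple)) and meta:
        meta = meta[0]
    if isinstance(meta, dict):
        if "spacing_um" in meta:
            sp = np.asarray(meta["spacing_um"], dtype=float)
        if "origin_um" in meta:
            origin = np.asarray(meta["origin_um"], dtype=float)
    if spacing is not None:
        sp = np.broadcast_to(np.asarray(spacing, dtype=float), (3,)).copy()
    if sp is None:
        raise ValueError("no voxel spacing in file metadata; pass spacing explicitly")
    return VoxelVolume(data=data, spacing=sp, origin=origin)


class _NumpyJSONEncoder(json.JSONEncoder):
    def default(self, o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, (np.bool_,)):
            return bool(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        return super().default(o)


def write_metrics_json(path: str | Path, metrics: dict) -> None:
    Path(path).write_text(json.dumps(metrics, indent=2, cls=_NumpyJSONEncoder) + "\n")


def read_metrics_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


def write_vtk_polylines(path: str | Path, fibers: list[FiberPolyline]) -> None:
    """ASCII legacy VTK polydata with per-point radius and per-line fiber id."""
    pts = np.concatenate([f.points for f in fibers]) if fibers else np.zeros((0, 3))
    lines = []
    radii = []
    ids = []
    off = 0
    for f in fibers:
        n = len(f.points)
        lines.append([n] + list(range(off, off + n)))
        radii.extend(f.radii.tolist())
        ids.append(f.fiber_id)
        off += n
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\nfiber polylines\nASCII\n")
        fh.write("DATASET POLYDATA\n")
        fh.write(f"POINTS {len(pts)} float\n")
        for p in pts:
            fh.write(f"{p[0]:.6g} {p[1]:.6g} {p[2]:.6g}\n")
        total = sum(len(l) for l in lines)
        fh.write(f"LINES {len(lines)} {total}\n")
        for l in lines:
            fh.write(" ".join(str(v) for v in l) + "\n")
        fh.write(f"POINT_DATA {len(pts)}\n")
        fh.write("SCALARS radius_um float 1\nLOOKUP_TABLE default\n")
        for r in radii:
            fh.write(f"{r:.6g}\n")
        fh.write(f"CELL_DATA {len(lines)}\n")
        fh.write("SCALARS fiber_id int 1\nLOOKUP_TABLE default\n")
        for i in ids:
            fh.write(f"{i}\n")


def write_vtk_mesh(
    path: str | Path,
    model: TetMeshModel,
    point_data: dict[str, np.ndarray] | None = None,
    cell_data: dict[str, np.ndarray] | None = None,
) -> None:
    """ASCII legacy VTK unstructured grid of the tets (beams excluded)."""
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\ntet mesh\nASCII\n")
        fh.write("DATASET UNSTRUCTURED_GRID\n")
        fh.write(f"POINTS {model.n_nodes} float\n")
        for p in model.nodes:
            fh.write(f"{p[0]:.6g} {p[1]:.6g} {p[2]:.6g}\n")
        fh.write(f"CELLS {model.n_tets} {model.n_tets * 5}\n")
        for t in model.tets:
            fh.write(f"4 {t[0]} {t[1]} {t[2]} {t[3]}\n")
        fh.write(f"CELL_TYPES {model.n_tets}\n")
        fh.write("\n".join(["10"] * model.n_tets) + "\n")
        if point_data:
            fh.write(f"POINT_DATA {model.n_nodes}\n")
            for name, arr in point_data.items():
                arr = np.asarray(arr)
                comps = 1 if arr.ndim == 1 else arr.shape[1]
                if comps == 3:
                    fh.write(f"VECTORS {name} float\n")
                    for v in arr:
                        fh.write(f"{v[0]:.6g} {v[1]:.6g} {v[2]:.6g}\n")
                else:
                    fh.write(f"SCALARS {name} float 1\nLOOKUP_TABLE default\n")
                    for v in arr:
                        fh.write(f"{float(v):.6g}\n")
        if cell_data:
            fh.write(f"CELL_DATA {model.n_tets}\n")
            for name, arr in cell_data.items():
                fh.write(f"SCALARS {name} float 1\nLOOKUP_TABLE default\n")
                for v in np.asarray(arr):
                    fh.write(f"{float(v):.6g}\n")
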