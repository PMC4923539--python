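"""File formats: raw volumes with JSON sidecars, TIFF stacks, seed files,
and legacy-ASCII VTK unstructured grids.

Volumes are stored as raw little-endian arrays (C order) next to a
``<name>.json`` sidecar holding dims, spacing, origin, dtype and, for label
volumes, the label dictionary.  TIFF stacks (one 2D slice per page, sliced
along the last axis) interoperate with scan-slice workflows.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile

from .grids import LABEL_NAMES, LabelMap, VoxelImage
from .mesh import HexMesh
from .segmentation import SegmentationSeeds

__all__ = [
    "save_volume",
    "load_volume",
    "save_tiff_stack",
    "load_tiff_stack",
    "read_seeds",
    "write_seeds",
    "write_vtk",
    "read_vtk",
    "export_fields",
]


def save_volume(vol: VoxelImage | LabelMap, path) -> Path:
    """Write raw little-endian array + JSON sidecar; returns the raw path."""
    path = Path(path)
    if path.suffix != ".raw":
        path = path.with_suffix(".raw")
    arr = vol.values if isinstance(vol, VoxelImage) else vol.labels
    arr = np.ascontiguousarray(arr)
    le = arr.astype(arr.dtype.newbyteorder("<"))
    path.write_bytes(le.tobytes())
    meta = {
        "dims": list(arr.shape),
        "spacing_mm": list(map(float, vol.spacing_mm)),
        "origin_mm": list(map(float, vol.origin_mm)),
        "dtype": arr.dtype.str.replace(">", "<"),
        "order": "C",
        "kind": "labels" if isinstance(vol, LabelMap) else "intensity",
    }
    if isinstance(vol, LabelMap):
        meta["labels"] = {str(k): v for k, v in LABEL_NAMES.items()}
    path.with_suffix(".json").write_text(json.dumps(meta, indent=1))
    return path


def load_volume(path) -> VoxelImage | LabelMap:
    path = Path(path)
    if path.suffix != ".raw":
        path = path.with_suffix(".raw")
    meta = json.loads(path.with_suffix(".json").read_text())
    arr = np.frombuffer(path.read_bytes(), dtype=np.dtype(meta["dtype"]))
    arr = arr.reshape(meta["dims"]).copy()
    cls = LabelMap if meta.get("kind") == "labels" else VoxelImage
    return cls(arr, np.asarray(meta["spacing_mm"]), np.asarray(meta["origin_mm"]))


def save_tiff_stack(vol: VoxelImage | LabelMap, path) -> Path:
    """One page per slice along the last (z) axis."""
    path = Path(path)
    arr = vol.values if isinstance(vol, VoxelImage) else vol.labels
    pages = np.moveaxis(np.ascontiguousarray(arr), 2, 0)
    tifffile.imwrite(
        path,
        pages,
        metadata={
            "spacing_mm": list(map(float, vol.spacing_mm)),
            "origin_mm": list(map(float, vol.origin_mm)),
        },
    )
    return path


def load_tiff_stack(path, spacing_mm=None, origin_mm=None) -> VoxelImage:
    with tifffile.TiffFile(str(path)) as tf:
        pages = tf.asarray()
        meta = tf.shaped_metadata[0] if tf.shaped_metadata else {}
    arr = np.moveaxis(pages, 0, 2)
    spacing = np.asarray(
        spacing_mm if spacing_mm is not None else meta.get("spacing_mm", (1.0, 1.0, 1.0))
    )
    origin = np.asarray(
        origin_mm if origin_mm is not None else meta.get("origin_mm", (0.0, 0.0, 0.0))
    )
    return VoxelImage(arr, spacing, origin)


def write_seeds(seeds: SegmentationSeeds, path) -> Path:
    """Plain text, one seed per line: ``i j k label``."""
    path = Path(path)
    lines = [
        f"{i} {j} {k} {l}"
        for (i, j, k), l in zip(seeds.indices, seeds.labels)
    ]
    path.write_text("\n".join(lines) + "\n")
    return path


def read_seeds(path) -> SegmentationSeeds:
    rows = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 4:
            raise ValueError(f"malformed seed line: {line!r}")
        rows.append([int(p) for p in parts])
    rows = np.asarray(rows, dtype=np.int64).reshape(-1, 4)
    return SegmentationSeeds(rows[:, :3], rows[:, 3])


def write_vtk(
    path,
    points: np.ndarray,
    cells: np.ndarray,
    cell_data: dict[str, np.ndarray] | None = None,
    point_data: dict[str, np.ndarray] | None = None,
    title: str = "perifem",
) -> Path:
    """Legacy-ASCII VTK unstructured grid with hexahedron cells."""
    path = Path(path)
    points = np.asarray(points, dtype=float)
    cells = np.asarray(cells, dtype=np.int64)
    n, m = points.shape[0], cells.shape[0]
    out = [
        "# vtk DataFile Version 3.0",
        title,
        "ASCII",
        "DATASET UNSTRUCTURED_GRID",
        f"POINTS {n} double",
    ]
    out.extend(" ".join(f"{x:.9g}" for x in p) for p in points)
    out.append(f"CELLS {m} {m * 9}")
    out.extend("8 " + " ".join(map(str, c)) for c in cells)
    out.append(f"CELL_TYPES {m}")
    out.extend(["12"] * m)

    def emit(block: dict[str, np.ndarray], count: int, header: str):
        out.append(f"{header} {count}")
        for name, arr in block.items():
            arr = np.asarray(arr, dtype=float)
            if arr.ndim == 1:
                out.append(f"SCALARS {name} double 1")
                out.append("LOOKUP_TABLE default")
                out.extend(f"{v:.9g}" for v in arr)
            elif arr.ndim == 2 and arr.shape[1] == 3:
                out.append(f"VECTORS {name} double")
                out.extend(" ".join(f"{x:.9g}" for x in row) for row in arr)
            else:
                raise ValueError(f"unsupported data shape {arr.shape} for {name}")

    if cell_data:
        emit(cell_data, m, "CELL_DATA")
    if point_data:
        emit(point_data, n, "POINT_DATA")
    path.write_text("\n".join(out) + "\n")
    return path


def read_vtk(path):
    """Minimal reader for the files written by :func:`write_vtk`.

    Returns ``(points, cells, cell_data, point_data)``.
    """
    tokens = Path(path).read_text().split("\n")
    i = 0

    def next_line():
        nonlocal i
        while i < len(tokens) and not tokens[i].strip():
            i += 1
        line = tokens[i].strip()
        i += 1
        return line

    header = [next_line() for _ in range(4)]
    if "UNSTRUCTURED_GRID" not in header[3]:
        raise ValueError("not an unstructured-grid VTK file")
    npts = int(next_line().split()[1])
    points = np.array([[float(x) for x in next_line().split()] for _ in range(npts)])
    ncells = int(next_line().split()[1])
    cells = np.array(
        [[int(x) for x in next_line().split()][1:] for _ in range(ncells)], dtype=np.int64
    )
    next_line()  # CELL_TYPES
    for _ in range(ncells):
        next_line()

    cell_data: dict[str, np.ndarray] = {}
    point_data: dict[str, np.ndarray] = {}
    target, count = None, 0
    while i < len(tokens):
        if not tokens[i].strip():
            i += 1
            continue
        line = next_line()
        key = line.split()[0]
        if key == "CELL_DATA":
            target, count = cell_data, ncells
        elif key == "POINT_DATA":
            target, count = point_data, npts
        elif key == "SCALARS":
            name = line.split()[1]
            next_line()  # LOOKUP_TABLE
            target[name] = np.array([float(next_line()) for _ in range(count)])
        elif key == "VECTORS":
            name = line.split()[1]
            target[name] = np.array(
                [[float(x) for x in next_line().split()] for _ in range(count)]
            )
        else:
            raise ValueError(f"unexpected VTK section {line!r}")
    return points, cells, cell_data, point_data


def export_fields(
    mesh: HexMesh,
    path,
    cell_data: dict[str, np.ndarray] | None = None,
    point_data: dict[str, np.ndarray] | None = None,
) -> Path:
    """Write the mesh with material label/E plus any given fields to VTK."""
    cd = {"material_label": mesh.labels.astype(float)}
    if mesh.E is not None:
        cd["E_MPa"] = mesh.E
    if cell_data:
        cd.update(cell_data)
    return write_vtk(path, mesh.nodes, mesh.elems, cell_data=cd, point_data=point_data)
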