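"""Label maps to solvable voxel hexahedral FE models.

One 8-node hexahedral element per foreground voxel, nodes deduplicated on
the shared corner lattice; per-element isotropic material (E, nu) per the
model variant; implant-bone interface identification by face adjacency; and
the study's boundary/load case (mesial/distal faces fixed, axial load on the
implant tops).  Units are mm / N / MPa throughout.

The bonded (100% osseointegrated) implant-bone interface is realized by
node sharing on the common lattice — no contact mechanics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import InterfaceError, LoadingError, MaterialError, ModelError
from .grids import (
    BACKGROUND,
    CANCELLOUS_BLOCK,
    CORTICAL,
    IMPLANT,
    TRABECULAR,
    LabelMap,
)

__all__ = [
    "MaterialTable",
    "REFINED_MATERIALS",
    "SIMPLIFIED_MATERIALS",
    "HexMesh",
    "BoundaryConditions",
    "voxels_to_hexmesh",
    "assign_materials",
    "find_interface",
    "build_bcs",
]

_STRUCT6 = ndimage.generate_binary_structure(3, 1)

# VTK_HEXAHEDRON corner ordering (right-handed, positive Jacobian):
# bottom face counterclockwise, then top face.
_CORNER_OFFSETS = np.array(
    [
        [0, 0, 0],
        [1, 0, 0],
        [1, 1, 0],
        [0, 1, 0],
        [0, 0, 1],
        [1, 0, 1],
        [1, 1, 1],
        [0, 1, 1],
    ],
    dtype=np.int64,
)


@dataclass(frozen=True)
class MaterialTable:
    """Map label -> (Young's modulus E in MPa, Poisson's ratio nu)."""

    entries: dict[int, tuple[float, float]]

    def __post_init__(self):
        for lab, (E, nu) in self.entries.items():
            if E <= 0:
                raise MaterialError(f"label {lab}: E must be positive, got {E}")
            if not (0.0 < nu < 0.5):
                raise MaterialError(f"label {lab}: nu must lie in (0, 0.5), got {nu}")

    def __getitem__(self, label: int) -> tuple[float, float]:
        try:
            return self.entries[label]
        except KeyError:
            raise MaterialError(f"material table has no entry for label {label}") from None

    def covers(self, labels) -> bool:
        return set(int(l) for l in labels) <= set(self.entries)


# Refined (microstructural) model: trabecular and cortical bone share one
# material, E = 14.4 GPa, nu = 0.309; titanium implant E = 110 GPa, nu = 0.35.
REFINED_MATERIALS = MaterialTable(
    {
        TRABECULAR: (14400.0, 0.309),
        CORTICAL: (14400.0, 0.309),
        IMPLANT: (110000.0, 0.35),
    }
)

# Simplified (homogenized) model: cortical 14.4 GPa / 0.309, solid cancellous
# block 0.48 GPa / 0.225, implant 110 GPa / 0.35.
SIMPLIFIED_MATERIALS = MaterialTable(
    {
        CORTICAL: (14400.0, 0.309),
        CANCELLOUS_BLOCK: (480.0, 0.225),
        IMPLANT: (110000.0, 0.35),
    }
)


@dataclass
class HexMesh:
    """Voxel hexahedral mesh: one element per foreground voxel."""

    nodes: np.ndarray  # (n, 3) float, mm
    elems: np.ndarray  # (m, 8) int, VTK hexahedron corner ordering
    labels: np.ndarray  # (m,) element tissue label
    voxel_idx: np.ndarray  # (m, 3) source voxel index
    spacing_mm: np.ndarray  # (3,) lattice pitch (equal per axis for FE)
    dims: tuple[int, int, int]  # source lattice dims
    origin_mm: np.ndarray
    E: np.ndarray | None = None  # (m,) MPa, set by assign_materials
    nu: np.ndarray | None = None
    node_grid_idx: np.ndarray = field(default=None, repr=False)  # (n, 3) corner lattice index

    @property
    def n_nodes(self) -> int:
        return self.nodes.shape[0]

    @property
    def n_elems(self) -> int:
        return self.elems.shape[0]

    @property
    def h(self) -> float:
        return float(self.spacing_mm[0])

    def label_grid(self) -> np.ndarray:
        """Dense element-label grid (background where no element)."""
        g = np.zeros(self.dims, dtype=np.int8)
        g[tuple(self.voxel_idx.T)] = self.labels
        return g


@dataclass
class BoundaryConditions:
    """Fixed nodes (all three components zero) and nodal loads.

    ``fixed_dofs``/``fixed_values`` allow prescribing individual displacement
    components (used e.g. for patch tests); when absent, ``fixed_nodes``
    pins all three components to zero.
    """

    fixed_nodes: np.ndarray
    load_nodes: np.ndarray
    load_forces: np.ndarray  # (len(load_nodes), 3) N
    total_force_N: np.ndarray  # (3,)
    fixed_dofs: np.ndarray | None = None
    fixed_values: np.ndarray | None = None

    def __post_init__(self):
        self.fixed_nodes = np.asarray(self.fixed_nodes, dtype=np.int64).ravel()
        self.load_nodes = np.asarray(self.load_nodes, dtype=np.int64).ravel()
        self.load_forces = np.asarray(self.load_forces, dtype=float).reshape(-1, 3)
        self.total_force_N = np.asarray(self.total_force_N, dtype=float).reshape(3)
        if self.fixed_dofs is None:
            if self.fixed_nodes.size == 0:
                raise LoadingError("fixed node set is empty")
            if np.intersect1d(self.fixed_nodes, self.load_nodes).size:
                raise LoadingError("fixed and load node sets must be disjoint")

    def dof_constraints(self) -> tuple[np.ndarray, np.ndarray]:
        if self.fixed_dofs is not None:
            vals = (
                np.zeros_like(self.fixed_dofs, dtype=float)
                if self.fixed_values is None
                else np.asarray(self.fixed_values, dtype=float)
            )
            return np.asarray(self.fixed_dofs, dtype=np.int64), vals
        dofs = (3 * self.fixed_nodes[:, None] + np.arange(3)).ravel()
        return dofs, np.zeros(dofs.size)


def voxels_to_hexmesh(labels: LabelMap) -> HexMesh:
    """One element per voxel with label != 0, corners deduplicated exactly."""
    lab = labels.labels
    fg = np.argwhere(lab != BACKGROUND)
    if fg.shape[0] == 0:
        raise ModelError("label map has no foreground voxels")
    dims = labels.dims
    ncy, ncz = dims[1] + 1, dims[2] + 1

    corners = fg[:, None, :] + _CORNER_OFFSETS[None, :, :]  # (m, 8, 3)
    corner_flat = (
        corners[..., 0] * (ncy * ncz) + corners[..., 1] * ncz + corners[..., 2]
    )
    used, elems = np.unique(corner_flat, return_inverse=True)
    elems = elems.reshape(-1, 8).astype(np.int64)

    gx = used // (ncy * ncz)
    gy = (used // ncz) % ncy
    gz = used % ncz
    grid_idx = np.stack([gx, gy, gz], axis=1)
    nodes = labels.origin_mm + grid_idx * labels.spacing_mm

    return HexMesh(
        nodes=nodes.astype(float),
        elems=elems,
        labels=lab[tuple(fg.T)].astype(np.int16),
        voxel_idx=fg.astype(np.int64),
        spacing_mm=labels.spacing_mm.copy(),
        dims=dims,
        origin_mm=labels.origin_mm.copy(),
        node_grid_idx=grid_idx,
    )


def assign_materials(mesh: HexMesh, table: MaterialTable, variant: str = "refined") -> HexMesh:
    """Attach per-element (E, nu) from the table.

    ``variant`` names the model the table should describe ("refined": all
    bone labels share one material; "simplified": cortical and cancellous
    block differ) — it is a consistency check, not a remapping: the table
    must cover every label present.
    """
    if variant not in ("refined", "simplified"):
        raise ValueError("variant must be 'refined' or 'simplified'")
    present = np.unique(mesh.labels)
    if not table.covers(present):
        missing = sorted(set(int(l) for l in present) - set(table.entries))
        raise MaterialError(f"material table missing labels {missing}")
    E = np.empty(mesh.n_elems)
    nu = np.empty(mesh.n_elems)
    for lab in present:
        e, n = table[int(lab)]
        sel = mesh.labels == lab
        E[sel] = e
        nu[sel] = n
    mesh.E = E
    mesh.nu = nu
    return mesh


def find_interface(mesh: HexMesh) -> np.ndarray:
    """Element ids of bone elements sharing >= 1 face with an implant element."""
    grid = mesh.label_grid()
    implant = grid == IMPLANT
    if not implant.any():
        raise InterfaceError("mesh contains no implant elements")
    near = ndimage.binary_dilation(implant, structure=_STRUCT6)
    bone = np.isin(grid, (TRABECULAR, CORTICAL, CANCELLOUS_BLOCK))
    iface_grid = near & bone
    flags = iface_grid[tuple(mesh.voxel_idx.T)]
    return np.flatnonzero(flags)


def _implant_components(mesh: HexMesh) -> list[np.ndarray]:
    grid = mesh.label_grid()
    comp, n = ndimage.label(grid == IMPLANT, structure=_STRUCT6)
    comp_of_elem = comp[tuple(mesh.voxel_idx.T)]
    return [np.flatnonzero(comp_of_elem == c) for c in range(1, n + 1)]


def build_bcs(
    mesh: HexMesh,
    load_N: float = 50.0,
    axis=(0.0, 0.0, 1.0),
    long_axis: int = 0,
    per_implant: bool = True,
) -> BoundaryConditions:
    """Study load case: mesial/distal boundary planes fixed in all directions;
    ``load_N`` applied along ``-axis`` to the nodes of each implant's most
    superior exposed faces, split equally per implant.

    ``per_implant=True`` gives each implant the full ``load_N``;
    ``False`` divides ``load_N`` across implants.
    """
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    coords = mesh.nodes[:, long_axis]
    lo, hi = coords.min(), coords.max()
    tol = 1e-9 * max(1.0, abs(hi - lo))
    fixed = np.flatnonzero((np.abs(coords - lo) < tol) | (np.abs(coords - hi) < tol))
    if fixed.size == 0:
        raise LoadingError("no nodes on the mesial/distal boundary planes")

    groups = _implant_components(mesh)
    if not groups:
        raise LoadingError("mesh has no implant elements to load")

    # axis index along which "superior" is measured: the dominant component
    up = int(np.argmax(np.abs(axis)))
    n_imp = len(groups)
    node_ids: list[np.ndarray] = []
    forces: list[np.ndarray] = []
    total = np.zeros(3)
    for elem_ids in groups:
        k = mesh.voxel_idx[elem_ids, up]
        top = elem_ids[k == k.max()]
        # the 4 corners of the top face in VTK ordering are 4..7 for +axis
        face = (4, 5, 6, 7) if axis[up] > 0 else (0, 1, 2, 3)
        nodes = np.unique(mesh.elems[np.ix_(top, np.asarray(face))])
        if nodes.size == 0:
            raise LoadingError("implant has no loadable top-face nodes")
        share = load_N if per_implant else load_N / n_imp
        f = -axis * share
        per_node = np.tile(f / nodes.size, (nodes.size, 1))
        node_ids.append(nodes)
        forces.append(per_node)
        total += f

    load_nodes = np.concatenate(node_ids)
    load_forces = np.concatenate(forces)
    # a node shared by two implants' tops would appear twice; merge forces
    if np.unique(load_nodes).size != load_nodes.size:
        uniq, inv = np.unique(load_nodes, return_inverse=True)
        merged = np.zeros((uniq.size, 3))
        np.add.at(merged, inv, load_forces)
        load_nodes, load_forces = uniq, merged

    return BoundaryConditions(
        fixed_nodes=fixed,
        load_nodes=load_nodes,
        load_forces=load_forces,
        total_force_N=total,
    )
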