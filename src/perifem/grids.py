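"""Voxel grid containers.

A :class:`VoxelImage` is a 3D scalar intensity volume with physical spacing —
the in-memory stand-in for a micro-CT or CBCT stack.  A :class:`LabelMap` is an
integer volume on the same lattice whose values name tissue roles.

Coordinate convention: voxel indices are 0-based and the physical position of
a voxel *center* is ``origin + (index + 0.5) * spacing``.  Node (voxel corner)
positions are ``origin + index * spacing``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

# Tissue role labels used throughout the package.
BACKGROUND = 0      # marrow / air
TRABECULAR = 1      # trabecular (cancellous) bone struts
CORTICAL = 2        # cortical shell
IMPLANT = 3         # titanium implant
CANCELLOUS_BLOCK = 4  # homogenized cancellous continuum (simplified model)

VALID_LABELS = frozenset({BACKGROUND, TRABECULAR, CORTICAL, IMPLANT, CANCELLOUS_BLOCK})
BONE_LABELS = frozenset({TRABECULAR, CORTICAL, CANCELLOUS_BLOCK})

LABEL_NAMES = {
    BACKGROUND: "background",
    TRABECULAR: "trabecular",
    CORTICAL: "cortical",
    IMPLANT: "implant",
    CANCELLOUS_BLOCK: "cancellous_block",
}


def _as_vec3(x, name: str) -> np.ndarray:
    v = np.asarray(x, dtype=float).reshape(-1)
    if v.size != 3:
        raise ValueError(f"{name} must be a 3-vector, got shape {v.shape}")
    return v


@dataclass
class VoxelImage:
    """3D scalar intensity grid with physical spacing (mm)."""

    values: np.ndarray
    spacing_mm: np.ndarray
    origin_mm: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError("values must be a 3D array")
        self.spacing_mm = _as_vec3(self.spacing_mm, "spacing_mm")
        self.origin_mm = _as_vec3(self.origin_mm, "origin_mm")
        if np.any(self.spacing_mm <= 0):
            raise ValueError("spacing_mm must be strictly positive")
        if min(self.values.shape) < 1:
            raise ValueError("all dims must be >= 1")

    @property
    def dims(self) -> tuple[int, int, int]:
        return self.values.shape

    def voxel_centers(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-axis physical center coordinates (broadcastable open grids)."""
        axes = [
            self.origin_mm[a] + (np.arange(self.dims[a]) + 0.5) * self.spacing_mm[a]
            for a in range(3)
        ]
        return tuple(np.meshgrid(*axes, indexing="ij", sparse=True))

    def same_lattice(self, other) -> bool:
        return (
            self.dims == other.dims
            and np.allclose(self.spacing_mm, other.spacing_mm)
            and np.allclose(self.origin_mm, other.origin_mm)
        )


@dataclass
class LabelMap:
    """3D integer grid of tissue roles on the same lattice as a VoxelImage."""

    labels: np.ndarray
    spacing_mm: np.ndarray
    origin_mm: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("labels must be a 3D array")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be integer-valued")
        self.spacing_mm = _as_vec3(self.spacing_mm, "spacing_mm")
        self.origin_mm = _as_vec3(self.origin_mm, "origin_mm")
        if np.any(self.spacing_mm <= 0):
            raise ValueError("spacing_mm must be strictly positive")
        present = set(np.unique(self.labels).tolist())
        if not present <= VALID_LABELS:
            raise ValueError(f"labels outside the valid set: {sorted(present - VALID_LABELS)}")

    @property
    def dims(self) -> tuple[int, int, int]:
        return self.labels.shape

    def voxel_centers(self):
        return VoxelImage(
            np.zeros(self.dims, dtype=np.uint8), self.spacing_mm, self.origin_mm
        ).voxel_centers()

    def copy(self) -> "LabelMap":
        return LabelMap(self.labels.copy(), self.spacing_mm.copy(), self.origin_mm.copy())

    def count(self, label: int) -> int:
        return int(np.count_nonzero(self.labels == label))

    def same_lattice(self, other) -> bool:
        return (
            self.dims == other.dims
            and np.allclose(self.spacing_mm, other.spacing_mm)
            and np.allclose(self.origin_mm, other.origin_mm)
        )
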