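"""Synthetic implanted-bone specimens and scanner emulation.

The study design needs paired voxel models of an implanted bone segment:
a *microstructural* ground truth (cortical shell + rod-like trabecular
interior + threaded implants) and a *homogenized* counterpart in which the
trabecular interior is replaced by a solid cancellous block.  From the
microstructural truth the module also emulates a high-resolution, noisy
micro-CT-like image (including metal-artifact intensity shading between
implant pairs) and a blurred, downsampled CBCT-like image.

The trabecular phase is a thresholded, anisotropically smoothed Gaussian
random field: the correlation length sets the strut thickness and the
threshold quantile sets the bone volume fraction (BV/TV).  This is the
standard stochastic stand-in for rod-like trabecular architecture when no
scan is available.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .errors import GenerationError, GeometryError, ResamplingError, SizingError
from .grids import (
    BACKGROUND,
    CANCELLOUS_BLOCK,
    CORTICAL,
    IMPLANT,
    TRABECULAR,
    LabelMap,
    VoxelImage,
)

__all__ = [
    "ImplantSpec",
    "SpecimenSpec",
    "ScannerSpec",
    "default_specimen_spec",
    "generate_trabecular_specimen",
    "embed_implant",
    "make_homogenized_truth",
    "simulate_scan",
    "DEFAULT_BASE_INTENSITIES",
]

# Arbitrary intensity units chosen so that discriminant (Otsu) thresholding
# separates implant from bone from background in the noiseless limit.
DEFAULT_BASE_INTENSITIES = {
    BACKGROUND: 20.0,
    TRABECULAR: 100.0,
    CORTICAL: 100.0,
    CANCELLOUS_BLOCK: 100.0,
    IMPLANT: 230.0,
}

_BONE = (TRABECULAR, CORTICAL, CANCELLOUS_BLOCK)


@dataclass(frozen=True)
class ImplantSpec:
    """Threaded cylindrical implant (Straumann-like regular neck geometry).

    The thread is modeled as rectangular annular rings of the given pitch and
    depth — a voxel-friendly approximation of the helix that preserves the
    mechanical role of threads (local interdigitation with bone).

    ``axis_entry_point_mm`` is the center of the implant's top (coronal) face;
    ``axis_direction`` points from the top face toward the apex.
    """

    diameter_mm: float = 4.1
    length_mm: float = 8.0
    thread_pitch_mm: float = 0.8
    thread_depth_mm: float = 0.3
    axis_entry_point_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    axis_direction: tuple[float, float, float] = (0.0, 0.0, -1.0)

    def __post_init__(self):
        if self.length_mm <= 0:
            raise ValueError("length_mm must be positive")
        if self.thread_depth_mm < 0:
            raise ValueError("thread_depth_mm must be >= 0")
        if self.diameter_mm <= 2 * self.thread_depth_mm:
            raise ValueError("diameter_mm must exceed 2 * thread_depth_mm")
        d = np.asarray(self.axis_direction, dtype=float)
        if not np.isclose(np.linalg.norm(d), 1.0, atol=1e-9):
            raise ValueError("axis_direction must be unit-norm")

    @property
    def core_radius_mm(self) -> float:
        return self.diameter_mm / 2.0 - self.thread_depth_mm

    @property
    def outer_radius_mm(self) -> float:
        return self.diameter_mm / 2.0


@dataclass(frozen=True)
class SpecimenSpec:
    """Geometry, morphometry and randomness of a synthetic bone specimen."""

    domain_size_mm: tuple[float, float, float] = (14.0, 6.0, 10.0)
    voxel_mm: float = 0.25
    cortical_thickness_mm: float = 0.75
    target_bvtv: float = 0.30
    correlation_length_mm: float = 0.75
    anisotropy: tuple[float, float, float] = (1.0, 1.0, 1.5)
    implants: tuple[ImplantSpec, ...] = ()
    rng_seed: int = 0

    def __post_init__(self):
        if not (0.0 < self.target_bvtv < 1.0):
            raise ValueError("target_bvtv must lie strictly in (0, 1)")
        if self.voxel_mm <= 0:
            raise ValueError("voxel_mm must be positive")
        if self.cortical_thickness_mm < 0:
            raise ValueError("cortical_thickness_mm must be >= 0")
        if min(self.domain_size_mm) <= 0:
            raise ValueError("domain_size_mm must be positive")

    @property
    def dims(self) -> tuple[int, int, int]:
        return tuple(
            int(round(s / self.voxel_mm)) for s in self.domain_size_mm
        )

    @property
    def shell_voxels(self) -> int:
        return int(round(self.cortical_thickness_mm / self.voxel_mm))


@dataclass(frozen=True)
class ScannerSpec:
    """Emulated scanner: modality, resolution, blur, noise and metal artifact.

    ``artifact_amplitude`` multiplicatively darkens bone intensity by
    ``1 - amplitude * w(x)`` where the weight ``w`` peaks (value 1) on the
    midline between each implant pair and decays to zero away from the
    implants — emulating the inter-implant shading that defeats plain
    threshold binarization on real metal-bearing scans.
    """

    modality: str = "micro_ct"  # "micro_ct" | "cbct"
    out_voxel_mm: float = 0.25
    blur_sigma_mm: float = 0.0
    noise_sd: float = 0.0
    artifact_amplitude: float = 0.0
    rng_seed: int = 0

    def __post_init__(self):
        if self.modality not in ("micro_ct", "cbct"):
            raise ValueError("modality must be 'micro_ct' or 'cbct'")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not (0.0 <= self.artifact_amplitude <= 1.0):
            raise ValueError("artifact_amplitude must lie in [0, 1]")


def default_specimen_spec(rng_seed: int = 0, n_implants: int = 2,
                          gap_mm: float = 4.0) -> SpecimenSpec:
    """Two Ø4.1 × 8 mm implants, vertical, tops flush with the superior face,
    separated edge-to-edge by ``gap_mm`` along the mesiodistal (x) axis."""
    spec = SpecimenSpec(rng_seed=rng_seed)
    lx, ly, lz = spec.domain_size_mm
    imp = ImplantSpec()
    if n_implants == 1:
        xs = [lx / 2.0]
    else:
        half = (imp.diameter_mm + gap_mm) / 2.0
        xs = [lx / 2.0 - half, lx / 2.0 + half][:n_implants]
    implants = tuple(
        replace(imp, axis_entry_point_mm=(x, ly / 2.0, lz)) for x in xs
    )
    return replace(spec, implants=implants)


def _interior_slices(dims, t):
    if any(d - 2 * t < 1 for d in dims):
        raise SizingError(
            f"domain {dims} cannot hold a {t}-voxel cortical shell plus interior"
        )
    return tuple(slice(t, d - t) for d in dims)


def generate_trabecular_specimen(spec: SpecimenSpec) -> LabelMap:
    """Generate the microstructural ground truth (without implants).

    Cortical shell of the stated thickness on all domain faces (label 2);
    interior voxels labeled trabecular (1) where a seeded, anisotropically
    smoothed Gaussian random field exceeds the quantile that realizes the
    target BV/TV within ±0.01 after connectivity cleanup; remaining interior
    voxels are marrow (0).  Trabecular islands not connected to the cortical
    shell are relabeled marrow; the threshold is then re-adjusted by feedback
    so the realized BV/TV still lands in the tolerance band.  Deterministic
    given ``rng_seed``.
    """
    dims = spec.dims
    t = spec.shell_voxels
    interior = _interior_slices(dims, t)

    rng = np.random.default_rng(spec.rng_seed)
    noise = rng.standard_normal(dims)
    # sigma = half the correlation length, per axis, scaled by the anisotropy
    # ratios: larger sigma along an axis elongates struts along it.
    sigma_vox = np.asarray(spec.anisotropy, dtype=float) * (
        spec.correlation_length_mm / spec.voxel_mm / 2.0
    )
    fld = ndimage.gaussian_filter(noise, sigma=sigma_vox, mode="wrap")
    fld_int = fld[interior]
    n_int = fld_int.size

    spacing = np.full(3, spec.voxel_mm)
    tol = 0.01

    q = 1.0 - spec.target_bvtv
    realized = np.nan
    for _ in range(25):
        thr = np.quantile(fld_int, min(max(q, 0.0), 1.0))
        labels = np.zeros(dims, dtype=np.int8)
        labels[...] = CORTICAL if t > 0 else BACKGROUND
        lab_int = np.where(fld_int > thr, TRABECULAR, BACKGROUND)
        labels[interior] = lab_int.reshape(fld_int.shape)
        if t == 0:
            labels[fld > thr] = TRABECULAR
        _prune_disconnected_trabeculae(labels, t)
        realized = np.count_nonzero(labels[interior] == TRABECULAR) / n_int
        if abs(realized - spec.target_bvtv) <= tol - 1e-6:
            return LabelMap(labels, spacing)
        # feedback on the quantile: removing islands lowers realized BV/TV,
        # so push the quantile down by the shortfall.
        q -= spec.target_bvtv - realized
    raise GenerationError(
        f"could not realize BV/TV {spec.target_bvtv:.3f} within ±{tol}; "
        f"achieved {realized:.4f}",
        achieved=float(realized),
    )


_STRUCT6 = ndimage.generate_binary_structure(3, 1)


def _prune_disconnected_trabeculae(labels: np.ndarray, shell_voxels: int) -> None:
    """Relabel trabecular islands not connected (6-conn) to the shell, or to
    a domain face when there is no shell, as marrow.  In place."""
    bone = (labels == TRABECULAR) | (labels == CORTICAL)
    comp, n = ndimage.label(bone, structure=_STRUCT6)
    if n <= 1:
        return
    if shell_voxels > 0:
        anchor = labels == CORTICAL
    else:
        anchor = np.zeros_like(bone)
        for ax in range(3):
            sl = [slice(None)] * 3
            for end in (0, -1):
                sl[ax] = end
                anchor[tuple(sl)] = True
        anchor &= bone
    keep = np.unique(comp[anchor])
    keep = keep[keep > 0]
    drop = ~np.isin(comp, keep) & (labels == TRABECULAR)
    labels[drop] = BACKGROUND


def embed_implant(truth: LabelMap, imp: ImplantSpec) -> LabelMap:
    """Overwrite with label 3 every voxel whose center lies inside the
    threaded solid of revolution; all other labels are unchanged."""
    d = np.asarray(imp.axis_direction, dtype=float)
    entry = np.asarray(imp.axis_entry_point_mm, dtype=float)
    lo = truth.origin_mm
    hi = truth.origin_mm + np.asarray(truth.dims) * truth.spacing_mm
    # bounding check: both end disks of the outer cylinder inside the domain
    # with at least one voxel of margin on lateral faces.
    margin = truth.spacing_mm
    for s in (0.0, imp.length_mm):
        c = entry + s * d
        r = imp.outer_radius_mm
        radial = np.sqrt(np.maximum(0.0, 1.0 - d * d)) * r
        pmin = c - radial
        pmax = c + radial
        if np.any(pmin < lo - 1e-9) or np.any(pmax > hi + 1e-9):
            raise GeometryError("implant extends outside the voxel domain")
        if np.any(pmin < lo + margin * (np.abs(d) < 0.999) - 1e-9) or np.any(
            pmax > hi - margin * (np.abs(d) < 0.999) + 1e-9
        ):
            raise GeometryError("implant violates the one-voxel lateral margin")

    X, Y, Z = LabelMap.voxel_centers(truth)
    px = X - entry[0]
    py = Y - entry[1]
    pz = Z - entry[2]
    tax = px * d[0] + py * d[1] + pz * d[2]
    r2 = (px - tax * d[0]) ** 2 + (py - tax * d[1]) ** 2 + (pz - tax * d[2]) ** 2

    in_span = (tax >= 0.0) & (tax <= imp.length_mm)
    core = r2 <= imp.core_radius_mm**2
    inside = in_span & core
    if imp.thread_depth_mm > 0:
        # rectangular ring profile occupying half of each pitch period
        phase = np.mod(tax, imp.thread_pitch_mm)
        ring = phase < 0.5 * imp.thread_pitch_mm
        thread = in_span & ring & (r2 <= imp.outer_radius_mm**2)
        inside |= thread

    out = truth.copy()
    out.labels[inside] = IMPLANT
    return out


def make_homogenized_truth(truth: LabelMap) -> LabelMap:
    """Replace the microstructural interior (trabecular + marrow) by a solid
    cancellous block (label 4); cortical and implant voxels are untouched."""
    out = truth.copy()
    interior = (out.labels == TRABECULAR) | (out.labels == BACKGROUND)
    out.labels[interior] = CANCELLOUS_BLOCK
    return out


def _artifact_weight(truth: LabelMap) -> np.ndarray:
    """Smooth weight in [0, 1] peaking on the midline between implant pairs.

    Implants are identified as connected components of label 3.  For each
    unordered pair, the weight is a radial Gaussian in the plane transverse
    to the implant axes, exactly 1 on the pair midline, with sigma set to
    half the center distance; axially it is 1 over the implants' shared span
    and rolls off smoothly below it.  The final weight is the max over pairs.
    """
    mask = truth.labels == IMPLANT
    comp, n = ndimage.label(mask, structure=_STRUCT6)
    if n < 2:
        return np.zeros(truth.dims)
    centers = []
    spans = []
    spacing = truth.spacing_mm
    for c in range(1, n + 1):
        idx = np.argwhere(comp == c)
        ctr = truth.origin_mm + (idx.mean(axis=0) + 0.5) * spacing
        zlo = truth.origin_mm[2] + idx[:, 2].min() * spacing[2]
        zhi = truth.origin_mm[2] + (idx[:, 2].max() + 1) * spacing[2]
        centers.append(ctr)
        spans.append((zlo, zhi))
    X, Y, Z = truth.voxel_centers()
    w = np.zeros(truth.dims)
    for i in range(n):
        for j in range(i + 1, n):
            mid = (centers[i] + centers[j]) / 2.0
            dist = np.linalg.norm((centers[i] - centers[j])[:2])
            if dist <= 0:
                continue
            sigma = dist / 2.0
            radial = np.exp(-((X - mid[0]) ** 2 + (Y - mid[1]) ** 2) / (2 * sigma**2))
            # 1 inside the shared axial span, 1 mm cosine rolloff outside it
            zlo = max(spans[i][0], spans[j][0])
            zhi = min(spans[i][1], spans[j][1])
            width = 1.0
            rolloff = np.ones_like(Z)
            rolloff = np.where(
                Z < zlo, 0.5 * (1 + np.cos(np.clip((zlo - Z) / width, 0, 1) * np.pi)), rolloff
            )
            rolloff = np.where(
                Z > zhi, 0.5 * (1 + np.cos(np.clip((Z - zhi) / width, 0, 1) * np.pi)), rolloff
            )
            w = np.maximum(w, radial * rolloff)
    return w


def simulate_scan(
    truth: LabelMap,
    scanner: ScannerSpec,
    base_intensities: dict[int, float] | None = None,
) -> VoxelImage:
    """Emulate a scan of ``truth``.

    Pipeline: per-label base intensities → multiplicative metal-artifact
    darkening of bone → Gaussian blur of ``blur_sigma_mm`` → additive
    zero-mean Gaussian noise → (cbct only) block-averaging down to
    ``out_voxel_mm``.  Deterministic given ``rng_seed``.
    """
    base = dict(DEFAULT_BASE_INTENSITIES)
    if base_intensities:
        base.update(base_intensities)
    lut = np.zeros(max(base) + 1)
    for lab, v in base.items():
        lut[lab] = v
    img = lut[truth.labels].astype(float)

    if scanner.artifact_amplitude > 0:
        w = _artifact_weight(truth)
        bone = np.isin(truth.labels, _BONE)
        img = np.where(bone, img * (1.0 - scanner.artifact_amplitude * w), img)

    if scanner.blur_sigma_mm > 0:
        img = ndimage.gaussian_filter(
            img, sigma=scanner.blur_sigma_mm / truth.spacing_mm, mode="reflect"
        )

    if scanner.noise_sd > 0:
        rng = np.random.default_rng(scanner.rng_seed)
        img = img + rng.normal(0.0, scanner.noise_sd, size=img.shape)

    spacing = truth.spacing_mm.copy()
    if scanner.modality == "cbct":
        ratio = scanner.out_voxel_mm / truth.spacing_mm
        f = np.rint(ratio).astype(int)
        if np.any(np.abs(ratio - f) > 1e-9) or np.any(f < 1):
            raise ResamplingError(
                f"cbct out_voxel_mm {scanner.out_voxel_mm} is not an integer "
                f"multiple of the source spacing {truth.spacing_mm}"
            )
        if any(truth.dims[a] % f[a] for a in range(3)):
            raise ResamplingError(
                f"dims {truth.dims} not divisible by block factor {tuple(f)}"
            )
        nx, ny, nz = (truth.dims[a] // f[a] for a in range(3))
        img = img.reshape(nx, f[0], ny, f[1], nz, f[2]).mean(axis=(1, 3, 5))
        spacing = truth.spacing_mm * f

    return VoxelImage(img, spacing, truth.origin_mm.copy())
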