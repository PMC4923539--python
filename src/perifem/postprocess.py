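"""Stress/strain recovery and interface summaries.

Per-element tensors are evaluated at the element centroid from trilinear
shape-function gradients.  Six scalar measures summarize the solution the
way implant load-transfer studies report it:

* equivalent (von Mises) stress  sqrt(3/2 s:s), s deviatoric stress
* tensile stress                 max(0, largest principal stress)
* compressive stress             max(0, -smallest principal stress)
* equivalent strain              sqrt(2/3 e:e), e deviatoric strain
* tensile strain                 max(0, largest principal strain)
* compressive strain             max(0, -smallest principal strain)

Compressive measures are reported as positive magnitudes.  Interface
statistics (max and mean) are taken over bone elements face-adjacent to the
implant — implant elements are excluded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InterfaceError
from .mesh import HexMesh
from .elasticity import strain_displacement_matrix

__all__ = [
    "MEASURES",
    "ElementTensorField",
    "InterfaceSummary",
    "ComparisonReport",
    "element_strain",
    "element_stress",
    "von_mises",
    "principal_values",
    "equivalent_strain",
    "summarize_interface",
    "compare_models",
]

MEASURES = (
    "equivalent_stress",
    "tensile_stress",
    "compressive_stress",
    "equivalent_strain",
    "tensile_strain",
    "compressive_strain",
)


@dataclass
class ElementTensorField:
    """Per-element symmetric 3x3 tensors; kind is 'stress' (MPa) or
    'strain' (dimensionless)."""

    tensors: np.ndarray  # (m, 3, 3)
    kind: str

    def __post_init__(self):
        t = np.asarray(self.tensors, dtype=float)
        if t.ndim != 3 or t.shape[1:] != (3, 3):
            raise ValueError("tensors must have shape (m, 3, 3)")
        if self.kind not in ("stress", "strain"):
            raise ValueError("kind must be 'stress' or 'strain'")
        self.tensors = 0.5 * (t + np.swapaxes(t, 1, 2))


def element_strain(mesh: HexMesh, u: np.ndarray) -> ElementTensorField:
    """Small-strain tensor at each element centroid."""
    B0 = strain_displacement_matrix(np.zeros(3), mesh.h)  # (6, 24)
    ue = u.reshape(-1, 3)[mesh.elems].reshape(mesh.n_elems, 24)
    voigt = ue @ B0.T  # engineering shear in rows 3..5
    eps = np.zeros((mesh.n_elems, 3, 3))
    eps[:, 0, 0] = voigt[:, 0]
    eps[:, 1, 1] = voigt[:, 1]
    eps[:, 2, 2] = voigt[:, 2]
    eps[:, 0, 1] = eps[:, 1, 0] = 0.5 * voigt[:, 3]
    eps[:, 1, 2] = eps[:, 2, 1] = 0.5 * voigt[:, 4]
    eps[:, 0, 2] = eps[:, 2, 0] = 0.5 * voigt[:, 5]
    return ElementTensorField(eps, "strain")


def element_stress(strain_field: ElementTensorField, mesh: HexMesh) -> ElementTensorField:
    """Isotropic Hooke's law sigma = lambda tr(eps) I + 2 mu eps, per element."""
    if mesh.E is None or mesh.nu is None:
        raise ValueError("mesh has no materials; call assign_materials first")
    eps = strain_field.tensors
    lam = mesh.E * mesh.nu / ((1 + mesh.nu) * (1 - 2 * mesh.nu))
    mu = mesh.E / (2 * (1 + mesh.nu))
    tr = np.trace(eps, axis1=1, axis2=2)
    sig = 2.0 * mu[:, None, None] * eps
    sig[:, np.arange(3), np.arange(3)] += (lam * tr)[:, None]
    return ElementTensorField(sig, "stress")


def von_mises(sigma: np.ndarray) -> np.ndarray:
    """Equivalent (von Mises) stress sqrt(3/2 s:s); rotation invariant,
    zero iff the tensor is hydrostatic.  Accepts (..., 3, 3)."""
    sigma = np.asarray(sigma, dtype=float)
    tr = np.trace(sigma, axis1=-2, axis2=-1)
    s = sigma - tr[..., None, None] / 3.0 * np.eye(3)
    return np.sqrt(1.5 * np.sum(s * s, axis=(-2, -1)))


def principal_values(tensor: np.ndarray) -> np.ndarray:
    """Eigenvalues of symmetric (..., 3, 3) tensors in descending order."""
    vals = np.linalg.eigvalsh(np.asarray(tensor, dtype=float))
    return vals[..., ::-1]


def equivalent_strain(eps: np.ndarray) -> np.ndarray:
    """Deviatoric (von-Mises-type) equivalent strain sqrt(2/3 e:e)."""
    eps = np.asarray(eps, dtype=float)
    tr = np.trace(eps, axis1=-2, axis2=-1)
    e = eps - tr[..., None, None] / 3.0 * np.eye(3)
    return np.sqrt(2.0 / 3.0 * np.sum(e * e, axis=(-2, -1)))


def scalar_measures(
    stress_field: ElementTensorField, strain_field: ElementTensorField
) -> dict[str, np.ndarray]:
    """The six per-element scalar measures (all non-negative)."""
    sp = principal_values(stress_field.tensors)
    ep = principal_values(strain_field.tensors)
    return {
        "equivalent_stress": von_mises(stress_field.tensors),
        "tensile_stress": np.maximum(sp[:, 0], 0.0),
        "compressive_stress": np.maximum(-sp[:, 2], 0.0),
        "equivalent_strain": equivalent_strain(strain_field.tensors),
        "tensile_strain": np.maximum(ep[:, 0], 0.0),
        "compressive_strain": np.maximum(-ep[:, 2], 0.0),
    }


@dataclass
class InterfaceSummary:
    """Max and mean of the six measures over interface bone elements."""

    variant: str
    n_interface: int
    maxima: dict[str, float]
    means: dict[str, float]
    argmax_elem: dict[str, int] = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "variant": self.variant,
            "n_interface": self.n_interface,
            "maxima": {k: self.maxima[k] for k in MEASURES},
            "means": {k: self.means[k] for k in MEASURES},
        }


def summarize_interface(
    stress_field: ElementTensorField,
    strain_field: ElementTensorField,
    mesh: HexMesh,
    interface_ids: np.ndarray,
    variant: str,
) -> InterfaceSummary:
    interface_ids = np.asarray(interface_ids, dtype=np.int64)
    if interface_ids.size == 0:
        raise InterfaceError("interface element set is empty")
    fields = scalar_measures(stress_field, strain_field)
    maxima, means, argmax = {}, {}, {}
    for name, vals in fields.items():
        v = vals[interface_ids]
        k = int(np.argmax(v))
        maxima[name] = float(v[k])
        means[name] = float(v.mean())
        argmax[name] = int(interface_ids[k])
    return InterfaceSummary(
        variant=variant,
        n_interface=int(interface_ids.size),
        maxima=maxima,
        means=means,
        argmax_elem=argmax,
    )


@dataclass
class ComparisonReport:
    """Paired refined-vs-simplified summaries and percent changes,
    100 * (refined - simplified) / simplified, for max and mean of each
    measure.  Undefined changes (simplified value 0) are flagged None."""

    refined: InterfaceSummary
    simplified: InterfaceSummary
    pct_change_max: dict[str, float | None] = field(init=False)
    pct_change_mean: dict[str, float | None] = field(init=False)

    def __post_init__(self):
        def pct(r, s):
            if s == 0:
                return None
            return 100.0 * (r - s) / s

        self.pct_change_max = {
            m: pct(self.refined.maxima[m], self.simplified.maxima[m]) for m in MEASURES
        }
        self.pct_change_mean = {
            m: pct(self.refined.means[m], self.simplified.means[m]) for m in MEASURES
        }

    def as_dict(self) -> dict:
        return {
            "refined": self.refined.as_dict(),
            "simplified": self.simplified.as_dict(),
            "pct_change_max": self.pct_change_max,
            "pct_change_mean": self.pct_change_mean,
        }

    def to_table(self) -> str:
        """TSV table: one row per measure, max/mean for both models + % change."""
        cols = [
            "measure",
            "refined_max",
            "simplified_max",
            "pct_change_max",
            "refined_mean",
            "simplified_mean",
            "pct_change_mean",
        ]
        lines = ["\t".join(cols)]
        for m in MEASURES:
            def fmt(x):
                return "undefined" if x is None else f"{x:.6g}"

            lines.append(
                "\t".join(
                    [
                        m,
                        fmt(self.refined.maxima[m]),
                        fmt(self.simplified.maxima[m]),
                        fmt(self.pct_change_max[m]),
                        fmt(self.refined.means[m]),
                        fmt(self.simplified.means[m]),
                        fmt(self.pct_change_mean[m]),
                    ]
                )
            )
        return "\n".join(lines) + "\n"


def compare_models(refined: InterfaceSummary, simplified: InterfaceSummary) -> ComparisonReport:
    return ComparisonReport(refined=refined, simplified=simplified)
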