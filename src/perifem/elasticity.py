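"""Small-strain linear elasticity on voxel hexahedral meshes.

All elements are geometrically identical cubes of side ``h``, so one element
stiffness template per distinct material serves the whole mesh — the key
micro-FE economy.  The global symmetric positive-definite system (after
eliminating constrained DOFs by reduction, which keeps conditioning clean
and reactions exactly recoverable) is solved by Jacobi-preconditioned
conjugate gradients; a dense direct path is retained for small systems and
oracle checks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.sparse.csgraph import connected_components
from scipy.sparse.linalg import LinearOperator, cg

from .errors import ConvergenceError, RigidModeError
from .mesh import BoundaryConditions, HexMesh

__all__ = ["hex_stiffness", "assemble_system", "assemble_and_solve", "SolveReport"]

# Natural coordinates of the 8 corners, matching the mesh corner ordering.
_XI = np.array(
    [
        [-1, -1, -1],
        [1, -1, -1],
        [1, 1, -1],
        [-1, 1, -1],
        [-1, -1, 1],
        [1, -1, 1],
        [1, 1, 1],
        [-1, 1, 1],
    ],
    dtype=float,
)


def isotropic_elasticity_matrix(E: float, nu: float) -> np.ndarray:
    """6x6 isotropic elasticity tensor in Voigt order (xx, yy, zz, xy, yz, zx)
    with engineering shear strains."""
    if not (0.0 < nu < 0.5):
        raise ValueError(f"Poisson's ratio must lie in (0, 0.5); got {nu} "
                         "(nu >= 0.5 is incompressible)")
    lam = E * nu / ((1 + nu) * (1 - 2 * nu))
    mu = E / (2 * (1 + nu))
    D = np.zeros((6, 6))
    D[:3, :3] = lam
    D[np.arange(3), np.arange(3)] += 2 * mu
    D[np.arange(3, 6), np.arange(3, 6)] = mu
    return D


def shape_gradients(xi: np.ndarray, h: float) -> np.ndarray:
    """(8, 3) gradients of the trilinear shape functions w.r.t. physical
    coordinates, for a cube of side h, at natural point xi."""
    g = np.empty((8, 3))
    for i in range(8):
        s = _XI[i]
        g[i, 0] = s[0] * (1 + s[1] * xi[1]) * (1 + s[2] * xi[2]) / 8.0
        g[i, 1] = (1 + s[0] * xi[0]) * s[1] * (1 + s[2] * xi[2]) / 8.0
        g[i, 2] = (1 + s[0] * xi[0]) * (1 + s[1] * xi[1]) * s[2] / 8.0
    return g * (2.0 / h)  # dxi/dx = 2/h


def strain_displacement_matrix(xi: np.ndarray, h: float) -> np.ndarray:
    """(6, 24) B-matrix (engineering shear rows) at natural point xi."""
    g = shape_gradients(xi, h)
    B = np.zeros((6, 24))
    for i in range(8):
        c = 3 * i
        B[0, c] = g[i, 0]
        B[1, c + 1] = g[i, 1]
        B[2, c + 2] = g[i, 2]
        B[3, c] = g[i, 1]
        B[3, c + 1] = g[i, 0]
        B[4, c + 1] = g[i, 2]
        B[4, c + 2] = g[i, 1]
        B[5, c] = g[i, 2]
        B[5, c + 2] = g[i, 0]
    return B


def hex_stiffness(E: float, nu: float, h: float) -> np.ndarray:
    """24x24 stiffness of a cubic trilinear hexahedron via 2x2x2 Gauss
    quadrature; symmetric PSD with exactly 6 rigid-body zero modes."""
    if h <= 0:
        raise ValueError("element size h must be positive")
    if E <= 0:
        raise ValueError("Young's modulus must be positive")
    D = isotropic_elasticity_matrix(E, nu)
    gp = 1.0 / np.sqrt(3.0)
    detJ = (h / 2.0) ** 3
    K = np.zeros((24, 24))
    for sx in (-gp, gp):
        for sy in (-gp, gp):
            for sz in (-gp, gp):
                B = strain_displacement_matrix(np.array([sx, sy, sz]), h)
                K += B.T @ D @ B * detJ
    return 0.5 * (K + K.T)


@dataclass
class SolveReport:
    iterations: int
    relative_residual: float
    converged: bool
    dof_count: int
    reaction_total: np.ndarray | None = None  # (3,) sum of fixed-node reactions


def element_dofs(mesh: HexMesh) -> np.ndarray:
    """(m, 24) global DOF indices per element."""
    return (3 * mesh.elems[:, :, None] + np.arange(3)).reshape(mesh.n_elems, 24)


def assemble_system(mesh: HexMesh) -> sparse.csr_matrix:
    """Global stiffness (unconstrained), cached element template per material."""
    if mesh.E is None or mesh.nu is None:
        raise ValueError("mesh has no materials; call assign_materials first")
    ndof = 3 * mesh.n_nodes
    edof = element_dofs(mesh).astype(np.int32)
    mats = np.stack([mesh.E, mesh.nu], axis=1)
    uniq, inv = np.unique(mats, axis=0, return_inverse=True)
    K = sparse.csr_matrix((ndof, ndof))
    for gi, (E, nu) in enumerate(uniq):
        sel = inv == gi
        ed = edof[sel]
        Ke = hex_stiffness(float(E), float(nu), mesh.h)
        rows = np.repeat(ed, 24, axis=1).ravel()
        cols = np.tile(ed, (1, 24)).ravel()
        data = np.tile(Ke.ravel(), int(sel.sum()))
        K = K + sparse.coo_matrix((data, (rows, cols)), shape=(ndof, ndof)).tocsr()
    return K


def _check_constrained_components(mesh: HexMesh, fixed_nodes: np.ndarray) -> None:
    n = mesh.n_nodes
    e = mesh.elems
    rows = np.repeat(e[:, 0], 7)
    cols = e[:, 1:].ravel()
    adj = sparse.coo_matrix(
        (np.ones(rows.size, dtype=np.int8), (rows, cols)), shape=(n, n)
    )
    ncomp, comp = connected_components(adj, directed=False)
    has_fix = np.zeros(ncomp, dtype=bool)
    has_fix[np.unique(comp[fixed_nodes])] = True
    if not has_fix.all():
        bad = int(np.flatnonzero(~has_fix[comp])[0])
        raise RigidModeError(
            f"mesh component containing node {bad} has no constrained node "
            "(floating component / rigid mode)"
        )


def assemble_and_solve(
    mesh: HexMesh,
    bcs: BoundaryConditions,
    tol: float = 1e-8,
    maxiter: int = 30000,
    method: str = "pcg",
):
    """Solve K u = f under the boundary conditions.

    Returns ``(u, report)`` where ``u`` is the (n, 3) displacement field with
    constrained DOFs exactly at their prescribed values, and ``report`` a
    :class:`SolveReport` including the summed reaction force at constrained
    nodes.  ``method`` is "pcg" (Jacobi-preconditioned CG, relative residual
    ``tol``) or "dense" (direct, for oracles and small systems).
    """
    ndof = 3 * mesh.n_nodes
    fixed_dofs, fixed_vals = bcs.dof_constraints()
    fixed_nodes_for_check = np.unique(fixed_dofs // 3)
    _check_constrained_components(mesh, fixed_nodes_for_check)

    K = assemble_system(mesh)
    f = np.zeros(ndof)
    np.add.at(
        f,
        (3 * bcs.load_nodes[:, None] + np.arange(3)).ravel(),
        bcs.load_forces.ravel(),
    )

    free = np.ones(ndof, dtype=bool)
    free[fixed_dofs] = False
    u = np.zeros(ndof)
    u[fixed_dofs] = fixed_vals

    rhs = f[free]
    if np.any(fixed_vals != 0.0):
        rhs = rhs - K[free][:, fixed_dofs] @ fixed_vals

    Kff = K[free][:, free].tocsr()
    nfree = int(free.sum())

    bnorm = float(np.linalg.norm(rhs))
    if bnorm == 0.0:
        uf = np.zeros(nfree)
        iters = 0
        relres = 0.0
        converged = True
    elif method == "dense":
        uf = np.linalg.solve(Kff.toarray(), rhs)
        iters = 1
        relres = float(np.linalg.norm(rhs - Kff @ uf)) / bnorm
        converged = relres <= max(tol, 1e-12) * 10
    elif method == "pcg":
        dinv = 1.0 / Kff.diagonal()
        M = LinearOperator((nfree, nfree), matvec=lambda x: dinv * x)
        count = {"n": 0}

        def cb(_):
            count["n"] += 1

        uf, info = cg(Kff, rhs, rtol=tol, atol=0.0, maxiter=maxiter, M=M, callback=cb)
        iters = count["n"]
        relres = float(np.linalg.norm(rhs - Kff @ uf)) / bnorm
        converged = info == 0 and relres <= tol * 10
        if not converged:
            report = SolveReport(iters, relres, False, nfree)
            raise ConvergenceError(
                f"PCG did not converge: relres={relres:.3e} after {iters} iterations",
                report=report,
            )
    else:
        raise ValueError(f"unknown method {method!r}")

    u[free] = uf
    # reactions at constrained DOFs: R = K u - f
    r = K @ u - f
    reaction = np.zeros(3)
    np.add.at(reaction, fixed_dofs % 3, r[fixed_dofs])

    report = SolveReport(
        iterations=iters,
        relative_residual=relres,
        converged=converged,
        dof_count=nfree,
        reaction_total=reaction,
    )
    return u.reshape(-1, 3), report
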