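"""Linear elastostatic solver for the knee FE model.

Simulates single-leg stance: the femoral top surface is fixed transversely
and pushed down by a prescribed uniform displacement (1 mm by default)
along the femoral longitudinal axis, while the most distal tibial and
fibular sections are fully constrained.  The resulting vertical reaction
force at the femoral top is used to rescale all stress/strain fields to one
body weight (linearity of the model).

Elements are standard isoparametric 8-node hexahedra (2x2x2 Gauss) or
10-node quadratic tetrahedra (4-point Gauss).  Tensors are reported at
element centroids.  Units are the consistent mm-MPa-N system; strains are
reported in microstrain.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy import sparse
from scipy.sparse import linalg as spla

from .meshmat import FEMesh, MaterialField

__all__ = [
    "LoadCase",
    "FieldResult",
    "assemble_stiffness",
    "assemble_and_solve",
    "scale_to_bodyweight",
    "principal_and_vm",
    "GRAVITY",
]

GRAVITY = 9.81  # m/s^2; body weight N = mass kg * g


@dataclass
class LoadCase:
    """Single-leg-stance displacement-controlled load case."""

    prescribed_displacement: float = 1.0  # mm, applied downward at femur_top
    body_weight: float = 700.0  # N
    fixed_sets: tuple = ("tibia_distal", "fibula_distal")

    def __post_init__(self) -> None:
        if self.prescribed_displacement <= 0:
            raise ValueError("prescribed_displacement must be positive")
        if self.body_weight <= 0:
            raise ValueError("body_weight must be positive")

    @classmethod
    def from_body_mass(cls, mass_kg: float, **kw) -> "LoadCase":
        return cls(body_weight=mass_kg * GRAVITY, **kw)


@dataclass
class FieldResult:
    """Per-element stress/strain fields plus the femoral reaction force."""

    stress_tensor: np.ndarray  # (M, 3, 3) MPa
    strain_tensor: np.ndarray  # (M, 3, 3) dimensionless
    min_principal_stress: np.ndarray  # MPa
    von_mises_stress: np.ndarray  # MPa
    min_principal_strain: np.ndarray  # microstrain
    von_mises_strain: np.ndarray  # microstrain
    reaction_force: float  # N, vertical at femur_top (pre-scaling magnitude)
    scale_factor: float  # body_weight / reaction_force once scaled, else 1
    displacement: np.ndarray  # (N, 3) mm

    METRICS = (
        "min_principal_stress",
        "von_mises_stress",
        "min_principal_strain",
        "von_mises_strain",
    )


# ---------------------------------------------------------------------------
# element kernels
# ---------------------------------------------------------------------------

def elasticity_matrix(E: float, nu: float) -> np.ndarray:
    """6x6 isotropic elasticity matrix (engineering shear strains)."""
    lam = E * nu / ((1 + nu) * (1 - 2 * nu))
    mu = E / (2 * (1 + nu))
    D = np.zeros((6, 6))
    D[:3, :3] = lam
    D[np.arange(3), np.arange(3)] += 2 * mu
    D[3:, 3:] = np.eye(3) * mu
    return D

# hex corner signs in VTK order
_HEX_XI = np.array(
    [
        (-1, -1, -1),
        (+1, -1, -1),
        (+1, +1, -1),
        (-1, +1, -1),
        (-1, -1, +1),
        (+1, -1, +1),
        (+1, +1, +1),
        (-1, +1, +1),
    ],
    dtype=float,
)


def _hex_dshape(xi: np.ndarray) -> np.ndarray:
    """(8, 3) derivatives of trilinear shape functions at natural point xi."""
    g = np.zeros((8, 3))
    for i, s in enumerate(_HEX_XI):
        g[i, 0] = s[0] * (1 + s[1] * xi[1]) * (1 + s[2] * xi[2]) / 8.0
        g[i, 1] = s[1] * (1 + s[0] * xi[0]) * (1 + s[2] * xi[2]) / 8.0
        g[i, 2] = s[2] * (1 + s[0] * xi[0]) * (1 + s[1] * xi[1]) / 8.0
    return g


_GP1 = 1.0 / np.sqrt(3.0)
_HEX_GAUSS = np.array(
    [(sx * _GP1, sy * _GP1, sz * _GP1) for sx in (-1, 1) for sy in (-1, 1) for sz in (-1, 1)]
)

# 4-point rule for tets, barycentric
_TET_A, _TET_B = 0.5854101966249685, 0.1381966011250105
_TET_GAUSS = np.full((4, 4), _TET_B)
np.fill_diagonal(_TET_GAUSS, _TET_A)


def _tet10_dshape_natural(L: np.ndarray) -> np.ndarray:
    """(10, 3) dN/d(xi,eta,zeta) for the quadratic tet at barycentric L."""
    # L = (L1, L2, L3, L4) with L1 = 1-xi-eta-zeta, L2=xi, L3=eta, L4=zeta
    dL = np.array(
        [[-1.0, -1.0, -1.0], [1.0, 0.0, 0.0], [0.0, 1.0, 0.0], [0.0, 0.0, 1.0]]
    )  # (4, 3)
    g = np.zeros((10, 3))
    for i in range(4):
        g[i] = (4 * L[i] - 1) * dL[i]
    edges = [(0, 1), (1, 2), (0, 2), (0, 3), (1, 3), (2, 3)]
    for k, (i, j) in enumerate(edges):
        g[4 + k] = 4 * (L[i] * dL[j] + L[j] * dL[i])
    return g


def _strain_B(dNdx: np.ndarray) -> np.ndarray:
    """(..., 6, 3*npe) strain-displacement matrix from (..., npe, 3) dN/dx."""
    *lead, npe, _ = dNdx.shape
    B = np.zeros((*lead, 6, 3 * npe))
    dx, dy, dz = dNdx[..., 0], dNdx[..., 1], dNdx[..., 2]
    B[..., 0, 0::3] = dx
    B[..., 1, 1::3] = dy
    B[..., 2, 2::3] = dz
    B[..., 3, 0::3] = dy
    B[..., 3, 1::3] = dx
    B[..., 4, 1::3] = dz
    B[..., 4, 2::3] = dy
    B[..., 5, 0::3] = dz
    B[..., 5, 2::3] = dx
    return B


_VOL_ROWS = np.array([0, 1, 2])


def _bbar(B: np.ndarray, B0: np.ndarray) -> np.ndarray:
    """Mean-dilatation (B-bar) modification of a strain-displacement matrix.

    The volumetric part of B is replaced by its element-centroid value, the
    standard selective treatment that removes volumetric locking for
    near-incompressible materials while leaving constant-strain states (and
    hence the patch test) exact.
    """
    Bb = B.copy()
    vol = B[..., _VOL_ROWS, :].sum(axis=-2, keepdims=True) / 3.0
    vol0 = B0[..., _VOL_ROWS, :].sum(axis=-2, keepdims=True) / 3.0
    Bb[..., _VOL_ROWS, :] += vol0 - vol
    return Bb


def _unit_cube_kernel(nu: float, h: float):
    """(Ke0, B0) for an axis-aligned cube of side h with E = 1 (B-bar)."""
    D = elasticity_matrix(1.0, nu)
    detJ = (h / 2.0) ** 3
    B0 = _strain_B(_hex_dshape(np.zeros(3)) * (2.0 / h))
    Ke = np.zeros((24, 24))
    for xi in _HEX_GAUSS:
        dN = _hex_dshape(xi) * (2.0 / h)  # J = (h/2) I
        B = _bbar(_strain_B(dN), B0)
        Ke += B.T @ D @ B * detJ
    return Ke, B0


def _element_matrices(mesh: FEMesh, materials: MaterialField, chunk: int = 20_000):
    """Yield (element ids, edof (m, ndof), Ke (m, ndof, ndof))."""
    E, nu = materials.E, materials.nu
    if mesh.etype == "hex8" and mesh.uniform_cube:
        h = mesh.element_size
        for nuv in np.unique(nu):
            Ke0, _ = _unit_cube_kernel(float(nuv), h)
            ids_all = np.nonzero(nu == nuv)[0]
            for s in range(0, len(ids_all), chunk):
                ids = ids_all[s : s + chunk]
                Ke = E[ids, None, None] * Ke0[None]  # Ke0 already carries the h scaling
                yield ids, _edof(mesh.elements[ids]), Ke
        return

    npe = mesh.elements.shape[1]
    if mesh.etype == "hex8":
        gauss = [(xi, None) for xi in _HEX_GAUSS]
    else:
        gauss = [(None, L) for L in _TET_GAUSS]
    for nuv in np.unique(nu):
        D = elasticity_matrix(1.0, float(nuv))
        ids_all = np.nonzero(nu == nuv)[0]
        for s in range(0, len(ids_all), chunk):
            ids = ids_all[s : s + chunk]
            coords = mesh.nodes[mesh.elements[ids]]  # (m, npe, 3)
            m = len(ids)
            Ke = np.zeros((m, 3 * npe, 3 * npe))
            B0 = None
            if mesh.etype == "hex8":  # centroid B for the B-bar treatment
                dN0 = _hex_dshape(np.zeros(3))
                J0 = np.einsum("ka,mkb->mab", dN0, coords)
                dNdx0 = np.einsum("mba,ka->mkb", np.linalg.inv(J0), dN0)
                B0 = _strain_B(dNdx0)
            for xi, L in gauss:
                if mesh.etype == "hex8":
                    dN = _hex_dshape(xi)  # (8, 3)
                    w = 1.0
                else:
                    dN = _tet10_dshape_natural(L)  # (10, 3)
                    w = 0.25
                J = np.einsum("ka,mkb->mab", dN, coords)  # (m, 3, 3)
                detJ = np.linalg.det(J)
                if (detJ <= 0).any():
                    raise ValueError("non-positive Jacobian during assembly")
                Jinv = np.linalg.inv(J)
                # J[a,b] = dx_b/dxi_a, so dN/dx_b = sum_a (J^-1)[b,a] dN/dxi_a
                dNdx = np.einsum("mba,ka->mkb", Jinv, dN)
                B = _strain_B(dNdx)
                if B0 is not None:
                    B = _bbar(B, B0)
                scale = detJ if mesh.etype == "hex8" else detJ / 6.0
                Ke += np.einsum("mik,ij,mjl->mkl", B, D, B) * (w * scale)[:, None, None]
            Ke *= E[ids, None, None]
            yield ids, _edof(mesh.elements[ids]), Ke


def _edof(elems: np.ndarray) -> np.ndarray:
    return (3 * elems[:, :, None] + np.arange(3)[None, None, :]).reshape(len(elems), -1)


def assemble_stiffness(mesh: FEMesh, materials: MaterialField) -> sparse.csr_matrix:
    """Assemble the global stiffness matrix (symmetric, CSR)."""
    ndof = 3 * mesh.n_nodes
    K = sparse.csr_matrix((ndof, ndof))
    for _, edof, Ke in _element_matrices(mesh, materials):
        m, nd = edof.shape
        rows = np.repeat(edof, nd, axis=1).ravel()
        cols = np.tile(edof, (1, nd)).ravel()
        K = K + sparse.coo_matrix(
            (Ke.ravel(), (rows, cols)), shape=(ndof, ndof)
        ).tocsr()
    return K


def _dirichlet(mesh: FEMesh, load: LoadCase) -> tuple[np.ndarray, np.ndarray]:
    """Constrained dof ids and prescribed values."""
    dofs, vals = [], []
    top = mesh.node_sets["femur_top"]
    for axis, val in ((0, 0.0), (1, 0.0), (2, -load.prescribed_displacement)):
        dofs.append(3 * top + axis)
        vals.append(np.full(len(top), val))
    for name in load.fixed_sets:
        if name not in mesh.node_sets:
            continue
        ns = mesh.node_sets[name]
        for axis in range(3):
            dofs.append(3 * ns + axis)
            vals.append(np.zeros(len(ns)))
    dofs = np.concatenate(dofs)
    vals = np.concatenate(vals)
    uniq, first = np.unique(dofs, return_index=True)
    return uniq, vals[first]


# direct factorization is used below this size; larger systems go to
# Jacobi-preconditioned CG (3D factorization fill grows too fast above this)
_DIRECT_DOF_LIMIT = 30_000


def solve_displacement(
    mesh: FEMesh, materials: MaterialField, load: LoadCase, method: str = "auto"
) -> tuple[np.ndarray, sparse.csr_matrix]:
    """Solve K u = 0 with prescribed displacements; returns (u, K)."""
    K = assemble_stiffness(mesh, materials)
    ndof = K.shape[0]
    fixed, fixed_vals = _dirichlet(mesh, load)
    if len(fixed) < 6:
        raise ValueError("at least 6 constrained DOFs are required (rigid-body modes)")
    free = np.setdiff1d(np.arange(ndof), fixed, assume_unique=False)

    u = np.zeros(ndof)
    u[fixed] = fixed_vals
    Kcsr = K.tocsr()
    b = -(Kcsr[:, fixed] @ fixed_vals)[free]
    Kff = Kcsr[free][:, free].tocsc()

    if method == "auto":
        method = "direct" if Kff.shape[0] <= _DIRECT_DOF_LIMIT else "cg"
    if method == "direct":
        try:
            lu = spla.splu(Kff)
            uf = lu.solve(b)
        except RuntimeError as err:
            raise ValueError(f"singular system (floating component?): {err}") from err
    elif method == "cg":
        M = sparse.diags(1.0 / Kff.diagonal())
        uf, info = spla.cg(Kff, b, M=M, rtol=1e-9, maxiter=40_000)
        if info != 0:  # non-convergence: fall back to direct
            lu = spla.splu(Kff)
            uf = lu.solve(b)
    else:
        raise ValueError(f"unknown method {method!r}")

    bnorm = np.linalg.norm(b)
    resid = np.linalg.norm(Kff @ uf - b) / max(bnorm, 1e-30)
    if resid > 1e-8:
        warnings.warn(f"equilibrium residual {resid:.2e} exceeds 1e-8")
    u[free] = uf
    return u, Kcsr


def recover_fields(mesh: FEMesh, materials: MaterialField, u: np.ndarray) -> tuple:
    """Element-centroid strain and stress tensors from the displacement field."""
    M = mesh.n_elements
    strain6 = np.zeros((M, 6))
    stress6 = np.zeros((M, 6))
    if mesh.etype == "hex8" and mesh.uniform_cube:
        _, B0 = _unit_cube_kernel(0.3, mesh.element_size)  # B is nu-independent
        ue = u[_edof(mesh.elements)]
        strain6 = np.einsum("ik,mk->mi", B0, ue)
    else:
        npe = mesh.elements.shape[1]
        if mesh.etype == "hex8":
            dN = _hex_dshape(np.zeros(3))
        else:
            dN = _tet10_dshape_natural(np.full(4, 0.25))
        coords = mesh.nodes[mesh.elements]
        J = np.einsum("ka,mkb->mab", dN, coords)
        Jinv = np.linalg.inv(J)
        dNdx = np.einsum("mba,ka->mkb", Jinv, dN)
        B = _strain_B(dNdx)
        ue = u[_edof(mesh.elements)]
        strain6 = np.einsum("mik,mk->mi", B, ue)
    for nuv in np.unique(materials.nu):
        ids = materials.nu == nuv
        D = elasticity_matrix(1.0, float(nuv))
        stress6[ids] = (strain6[ids] @ D.T) * materials.E[ids, None]
    return _voigt_to_tensor(strain6, shear_is_engineering=True), _voigt_to_tensor(
        stress6, shear_is_engineering=False
    )


def _voigt_to_tensor(v6: np.ndarray, shear_is_engineering: bool) -> np.ndarray:
    m = len(v6)
    T = np.zeros((m, 3, 3))
    f = 0.5 if shear_is_engineering else 1.0
    T[:, 0, 0], T[:, 1, 1], T[:, 2, 2] = v6[:, 0], v6[:, 1], v6[:, 2]
    T[:, 0, 1] = T[:, 1, 0] = f * v6[:, 3]
    T[:, 1, 2] = T[:, 2, 1] = f * v6[:, 4]
    T[:, 0, 2] = T[:, 2, 0] = f * v6[:, 5]
    return T


def principal_and_vm(tensor: np.ndarray, kind: str = "stress") -> tuple[np.ndarray, np.ndarray]:
    """Minimum principal value and the von Mises equivalent per element.

    For strain the equivalent uses the (2/3)-normalized convention, which
    reduces to the axial strain for incompressible uniaxial stretch.
    """
    tensor = np.asarray(tensor, dtype=float)
    single = tensor.ndim == 2
    if single:
        tensor = tensor[None]
    if not np.allclose(tensor, np.swapaxes(tensor, -1, -2), atol=1e-8 * max(1.0, np.abs(tensor).max())):
        raise ValueError("tensor must be symmetric")
    eig = np.linalg.eigvalsh(tensor)  # ascending
    min_principal = eig[:, 0]
    d01 = eig[:, 0] - eig[:, 1]
    d12 = eig[:, 1] - eig[:, 2]
    d02 = eig[:, 0] - eig[:, 2]
    vm = np.sqrt(0.5 * (d01**2 + d12**2 + d02**2))
    if kind == "strain":
        vm *= 2.0 / 3.0
    elif kind != "stress":
        raise ValueError("kind must be 'stress' or 'strain'")
    if single:
        return float(min_principal[0]), float(vm[0])
    return min_principal, vm


def vertical_reaction(K: sparse.csr_matrix, u: np.ndarray, node_set: np.ndarray) -> float:
    """Sum of vertical constraint forces on a node set (signed)."""
    r = K @ u
    return float(r[3 * np.asarray(node_set) + 2].sum())


def assemble_and_solve(
    mesh: FEMesh, materials: MaterialField, load: LoadCase, method: str = "auto"
) -> FieldResult:
    """Assemble, apply single-leg-stance BCs, solve and derive element fields."""
    u, K = solve_displacement(mesh, materials, load, method=method)
    strain_t, stress_t = recover_fields(mesh, materials, u)
    mps, vms = principal_and_vm(stress_t, "stress")
    mpe, vme = principal_and_vm(strain_t, "strain")
    reaction = vertical_reaction(K, u, mesh.node_sets["femur_top"])
    disp = u.reshape(-1, 3)
    return FieldResult(
        stress_tensor=stress_t,
        strain_tensor=strain_t,
        min_principal_stress=mps,
        von_mises_stress=vms,
        min_principal_strain=mpe * 1e6,
        von_mises_strain=vme * 1e6,
        reaction_force=abs(reaction),
        scale_factor=1.0,
        displacement=disp,
    )


def scale_to_bodyweight(result: FieldResult, body_weight: float) -> FieldResult:
    """Rescale all fields so the vertical reaction equals one body weight."""
    if result.reaction_force <= 0:
        raise ValueError("reaction force must be positive to scale")
    s = body_weight / result.reaction_force
    return replace(
        result,
        stress_tensor=result.stress_tensor * s,
        strain_tensor=result.strain_tensor * s,
        min_principal_stress=result.min_principal_stress * s,
        von_mises_stress=result.von_mises_stress * s,
        min_principal_strain=result.min_principal_strain * s,
        von_mises_strain=result.von_mises_strain * s,
        displacement=result.displacement * s,
        scale_factor=s,
    )
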