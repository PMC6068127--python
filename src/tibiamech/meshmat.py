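"""FE mesh construction and density -> modulus material mapping.

The default mesh mode is ``hex_voxel``: a structured grid of 8-node cube
elements obtained by coarsening the segmented voxel grid to the requested
element size — deterministic and robust at desk scale.  ``tet_quadratic``
splits each cube into six 10-node quadratic tetrahedra (Kuhn subdivision,
face-compatible across the grid) and is the interchange path mirroring
clinical FE practice (Abaqus C3D10 export).

A soft-tissue cylinder stands in for cartilage/menisci: it spans the
femorotibial gap, encloses both condyles, and is bonded to bone by sharing
grid nodes.  Bone elastic modulus follows the Goulet power law
``E = a * (rho/1000)^2.1`` (rho in mg/cm3, i.e. rho/1000 in g/cm3) with a
1 MPa floor; the femur is modeled as a rigid body via E = 500 GPa and soft
tissue is nearly incompressible (E = 10 MPa, nu = 0.495).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .imageproc import SegmentationMask
from .volume import MG_CM3, DensityVolume

__all__ = [
    "FEMesh",
    "MaterialField",
    "MaterialLaw",
    "build_mesh",
    "goulet_modulus",
    "map_materials",
    "write_vtk",
    "write_inp",
]

DOMAIN_CODES = {"tibia": 1, "femur": 2, "fibula": 3, "soft_tissue": 4}
DOMAIN_NAMES = {v: k for k, v in DOMAIN_CODES.items()}

# default material constants (mm-MPa-N unit system)
E_FLOOR = 1.0  # MPa
E_SOFT = 10.0  # MPa
NU_SOFT = 0.495
NU_BONE = 0.3
E_RIGID = 500_000.0  # MPa (rigid femur)
GOULET_EXPONENT = 2.1
# power-law coefficient, MPa per (g/cm3)^2.1; default keeps the maximum bone
# modulus near the ~25 GPa envelope for cortical BMD around 0.9 g/cm3
GOULET_COEFF_A = 30_000.0


@dataclass
class MaterialLaw:
    """Configurable density-modulus mapping (see :func:`goulet_modulus`)."""

    coeff_a: float = GOULET_COEFF_A
    exponent: float = GOULET_EXPONENT
    floor: float = E_FLOOR
    # optional linear pre-transform from K2HPO4-equivalent BMD to the density
    # measure the power law expects: rho' = pre_slope * rho + pre_intercept
    pre_slope: float = 1.0
    pre_intercept: float = 0.0

    def __call__(self, rho: np.ndarray) -> np.ndarray:
        rho = self.pre_slope * np.asarray(rho, dtype=float) + self.pre_intercept
        return goulet_modulus(rho, self.coeff_a, self.exponent, self.floor)


@dataclass
class FEMesh:
    """Nodes, connectivity, per-element domain and named node/element sets."""

    nodes: np.ndarray  # (N, 3) mm
    elements: np.ndarray  # (M, 8) hex8 or (M, 10) tet10
    etype: str  # "hex8" | "tet10"
    element_domain: np.ndarray  # (M,) codes per DOMAIN_CODES
    node_sets: dict = field(default_factory=dict)
    element_sets: dict = field(default_factory=dict)
    element_size: float = 0.0
    split_x: float = 0.0  # sagittal medial/lateral split plane
    uniform_cube: bool = False  # all elements congruent axis-aligned cubes
    lattice_origin: np.ndarray | None = None  # cell-lattice corner, world mm
    cell_index: np.ndarray | None = None  # (M, 3) lattice cell per element
    node_index: np.ndarray | None = None  # (N, 3) lattice corner per node

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_elements(self) -> int:
        return len(self.elements)

    def domain_mask(self, name: str) -> np.ndarray:
        return self.element_domain == DOMAIN_CODES[name]

    def centroids(self) -> np.ndarray:
        corners = self.elements[:, :4] if self.etype == "tet10" else self.elements
        return self.nodes[corners].mean(axis=1)

    def element_volumes(self) -> np.ndarray:
        if self.etype == "hex8":
            if self.uniform_cube:
                return np.full(self.n_elements, self.element_size**3)
            # decompose each hex into the same 6 tets used by tet mode
            # (_KUHN_TETS indexes lattice corner ids, not VTK order)
            lattice = self.elements[:, _LATTICE_TO_VTK]
            vols = np.zeros(self.n_elements)
            for tet in _KUHN_TETS:
                p = self.nodes[lattice[:, tet]]
                vols += _tet_volume(p)
            return vols
        p = self.nodes[self.elements[:, :4]]
        return _tet_volume(p)

    def validate(self) -> None:
        if self.elements.min() < 0 or self.elements.max() >= self.n_nodes:
            raise ValueError("element connectivity references invalid node ids")
        used = np.zeros(self.n_nodes, dtype=bool)
        used[self.elements.ravel()] = True
        if not used.all():
            raise ValueError(f"{(~used).sum()} orphan nodes")
        vols = self.element_volumes()
        if (vols <= 0).any():
            bad = np.nonzero(vols <= 0)[0]
            raise ValueError(f"non-positive element Jacobian in elements {bad[:10]}")
        for name, ids in {**self.node_sets}.items():
            if len(ids) and (ids.min() < 0 or ids.max() >= self.n_nodes):
                raise ValueError(f"node set {name} out of range")


@dataclass
class MaterialField:
    """Per-element elastic constants."""

    E: np.ndarray  # MPa
    nu: np.ndarray
    rho: np.ndarray  # mg/cm3 (0 for soft tissue)
    rigid_flags: np.ndarray
    n_clamped_rho: int = 0


def _tet_volume(p: np.ndarray) -> np.ndarray:
    a = p[:, 1] - p[:, 0]
    b = p[:, 2] - p[:, 0]
    c = p[:, 3] - p[:, 0]
    return np.einsum("ij,ij->i", np.cross(a, b), c) / 6.0


# Kuhn subdivision of the unit cube (corner id = dx + 2*dy + 4*dz), all six
# tets share the 0-7 diagonal and are positively oriented, and face
# diagonals match across translated copies of the cell.
_KUHN_TETS = [
    (0, 1, 3, 7),
    (0, 3, 2, 7),
    (0, 2, 6, 7),
    (0, 6, 4, 7),
    (0, 4, 5, 7),
    (0, 5, 1, 7),
]
# VTK/assembly hex corner order -> (dx, dy, dz) lattice offsets
_HEX_OFFSETS = np.array(
    [
        (0, 0, 0),
        (1, 0, 0),
        (1, 1, 0),
        (0, 1, 0),
        (0, 0, 1),
        (1, 0, 1),
        (1, 1, 1),
        (0, 1, 1),
    ]
)
# lattice corner id (dx + 2dy + 4dz) for each VTK corner
_VTK_TO_LATTICE = np.array([o[0] + 2 * o[1] + 4 * o[2] for o in _HEX_OFFSETS])
_LATTICE_TO_VTK = np.argsort(_VTK_TO_LATTICE)


# ---------------------------------------------------------------------------
# density -> modulus
# ---------------------------------------------------------------------------

def goulet_modulus(
    rho: np.ndarray,
    coeff_a: float = GOULET_COEFF_A,
    exponent: float = GOULET_EXPONENT,
    floor: float = E_FLOOR,
) -> np.ndarray:
    """Power-law elastic modulus from BMD: ``E = max(floor, a*(rho/1000)^b)``.

    ``rho`` is in mg/cm3; negative densities (air/partial-volume artifacts)
    are clamped to zero before the power.
    """
    if coeff_a <= 0:
        raise ValueError("coeff_a must be positive")
    rho = np.asarray(rho, dtype=float)
    if not np.isfinite(rho).all():
        raise ValueError("rho must be finite")
    rho_g = np.maximum(rho, 0.0) / 1000.0  # g/cm3
    return np.maximum(floor, coeff_a * rho_g**exponent)


# ---------------------------------------------------------------------------
# mesh construction
# ---------------------------------------------------------------------------

def _sample_labels(labels: np.ndarray, volume: DensityVolume, points_world: np.ndarray) -> np.ndarray:
    idx = volume.world_to_index(points_world)
    return ndimage.map_coordinates(labels, idx.T, order=0, mode="constant", cval=0)


def build_mesh(
    mask: SegmentationMask,
    volume: DensityVolume,
    element_size: float = 2.0,
    mode: str = "hex_voxel",
    soft_radius_factor: float = 1.1,
    soft_z_margin: float = 2.0,
    femur_extent: float | None = 35.0,
    tibia_extent: float | None = 65.0,
    smooth_surface: bool = True,
    subdivide: int = 1,
) -> FEMesh:
    """Coarsen the segmented voxel grid into a conforming FE mesh.

    Every grid cell of side ``element_size`` whose majority subsample lies in
    a bone becomes a bone element; non-bone cells inside the soft-tissue
    cylinder (vertical axis through the joint-gap centroid, radius
    ``soft_radius_factor`` x the maximal condylar half-width, spanning from
    just below the tibial subchondral surface to the femoral condyles)
    become soft-tissue elements.  Bone and soft tissue share nodes (bonded
    contact as merged nodes).

    ``femur_extent`` / ``tibia_extent`` crop the model to the distal
    ``femur_extent`` mm of the (rigid) femur and the proximal
    ``tibia_extent`` mm of the tibia/fibula: the boundary conditions act on
    the cropped sections, which stay far (> 25 mm) from the deepest analyzed
    band, and the femur is rigid, so the crop does not affect proximal-tibia
    fields.  Pass ``None`` to mesh the full imaged extents.

    ``subdivide`` splits every occupied cell into ``subdivide``^3 conforming
    children after the occupancy decisions are made: the mesh boundary is
    bit-identical to the unsubdivided mesh, so solving both isolates pure
    FE discretization error (a nested one-step refinement study at fixed
    geometry).  ``smooth_surface`` optionally projects bone-surface nodes
    onto the smooth segmented surface (< 1 voxel deviation).
    """
    if mode not in ("hex_voxel", "tet_quadratic"):
        raise ValueError(f"unknown mesh mode {mode!r}")
    h = float(element_size)
    if h < min(volume.spacing):
        raise ValueError("element_size must be at least the voxel size")

    labels = mask.labels
    tib = labels == 1
    fem = labels == 2
    if not tib.any() or not fem.any():
        raise ValueError("mesh requires both tibia and femur in the mask")
    # joint gap must be open: tibia dilated by one voxel must not touch femur
    if (ndimage.binary_dilation(tib) & fem).any():
        raise ValueError("joint gap is zero (tibia and femur touch); cannot mesh")

    # world-frame extents of the bones
    idx = np.argwhere(labels > 0)
    w_lo = volume.index_to_world(idx.min(axis=0))[0] - h
    w_hi = volume.index_to_world(idx.max(axis=0))[0] + h

    # condyle band geometry for the soft cylinder
    tib_idx = np.argwhere(tib)
    tib_world_z = volume.origin[2] + tib_idx[:, 2] * volume.spacing[2]
    tib_top = float(tib_world_z.max())
    fem_idx = np.argwhere(fem)
    fem_world_z = volume.origin[2] + fem_idx[:, 2] * volume.spacing[2]
    fem_bot = float(fem_world_z.min())
    band_pts = []
    sel_t = tib_world_z >= tib_top - 10.0
    band_pts.append(volume.index_to_world(tib_idx[sel_t]))
    sel_f = fem_world_z <= fem_bot + 15.0
    band_pts.append(volume.index_to_world(fem_idx[sel_f]))
    band = np.vstack(band_pts)
    center_xy = band[:, :2].mean(axis=0)
    half_width = max(
        np.abs(band[:, 0] - center_xy[0]).max(), np.abs(band[:, 1] - center_xy[1]).max()
    )
    soft_r = soft_radius_factor * half_width
    soft_zlo = tib_top - 6.0 - soft_z_margin
    soft_zhi = fem_bot + 15.0 + soft_z_margin

    # anchor the cell lattice at the tibial apex / plateau centroid so that
    # different element sizes place their lattice planes consistently
    # relative to the anatomy
    anchor = np.array([center_xy[0], center_xy[1], tib_top])
    w_lo = anchor - h * np.ceil((anchor - w_lo) / h)

    # cell lattice
    nx, ny, nz = (np.maximum(1, np.ceil((w_hi - w_lo) / h).astype(int))).tolist()
    cx = w_lo[0] + h * (np.arange(nx) + 0.5)
    cy = w_lo[1] + h * (np.arange(ny) + 0.5)
    cz = w_lo[2] + h * (np.arange(nz) + 0.5)
    CX, CY, CZ = np.meshgrid(cx, cy, cz, indexing="ij")
    centers = np.column_stack([CX.ravel(), CY.ravel(), CZ.ravel()])

    # majority vote over a 2x2x2 subsample per cell
    votes = np.zeros((len(centers), 4), dtype=np.int16)  # background + 3 bones
    for ox in (-h / 4, h / 4):
        for oy in (-h / 4, h / 4):
            for oz in (-h / 4, h / 4):
                lab = _sample_labels(labels, volume, centers + np.array([ox, oy, oz]))
                lab = np.where((lab >= 1) & (lab <= 3), lab, 0).astype(np.int64)
                votes[np.arange(len(centers)), lab] += 1
    cell_label = np.argmax(votes[:, 1:], axis=1) + 1
    cell_label[votes[:, 1:].sum(axis=1) < 4] = 0  # less than half bone -> background

    # soft-tissue cylinder fills non-bone cells in the gap region
    r2 = (centers[:, 0] - center_xy[0]) ** 2 + (centers[:, 1] - center_xy[1]) ** 2
    in_cyl = (r2 <= soft_r**2) & (centers[:, 2] >= soft_zlo) & (centers[:, 2] <= soft_zhi)
    soft = in_cyl & (cell_label == 0)
    cell_label[soft] = DOMAIN_CODES["soft_tissue"]

    # crop to the mechanically relevant extents
    if femur_extent is not None:
        cell_label[(cell_label == 2) & (centers[:, 2] > fem_bot + femur_extent)] = 0
    if tibia_extent is not None:
        too_deep = centers[:, 2] < tib_top - tibia_extent
        cell_label[np.isin(cell_label, (1, 3)) & too_deep] = 0

    occupied = np.nonzero(cell_label > 0)[0]
    if len(occupied) == 0:
        raise ValueError("no occupied cells; check mask and element size")
    occ_ijk = np.column_stack(np.unravel_index(occupied, (nx, ny, nz)))

    # node lattice: unique corners of occupied cells
    corner_ids = occ_ijk[:, None, :] + _HEX_OFFSETS[None, :, :]  # (M, 8, 3)
    flat = (
        corner_ids[..., 0] * ((ny + 1) * (nz + 1))
        + corner_ids[..., 1] * (nz + 1)
        + corner_ids[..., 2]
    )
    uniq, inv = np.unique(flat, return_inverse=True)
    elements = inv.reshape(-1, 8).astype(np.int64)
    ux = uniq // ((ny + 1) * (nz + 1))
    uy = (uniq // (nz + 1)) % (ny + 1)
    uz = uniq % (nz + 1)
    nodes = np.column_stack([w_lo[0] + h * ux, w_lo[1] + h * uy, w_lo[2] + h * uz]).astype(float)
    domain = cell_label[occupied].astype(np.int16)

    mesh = FEMesh(
        nodes=nodes,
        elements=elements,
        etype="hex8",
        element_domain=domain,
        element_size=h,
        uniform_cube=not smooth_surface,
        lattice_origin=np.asarray(w_lo, dtype=float),
        cell_index=occ_ijk,
        node_index=np.column_stack([ux, uy, uz]).astype(np.int64),
    )
    _attach_sets(mesh, occ_ijk, domain, h, w_lo, tib_top)
    if smooth_surface:
        _snap_surface_nodes(mesh, mask, volume)
    for _ in range(int(np.log2(subdivide)) if subdivide > 1 else 0):
        mesh = refine_nested(mesh)
    if mode == "tet_quadratic":
        mesh = hex_to_tet10(mesh)
    mesh.validate()
    return mesh


def refine_nested(mesh: FEMesh) -> FEMesh:
    """Split every hex into 8 children with bit-identical trilinear geometry.

    New nodes are placed by trilinear interpolation within each parent hex
    (edge and face nodes depend only on the shared edge/face corners, so the
    child mesh is conforming), which reproduces the parent geometry exactly:
    solving parent and child isolates pure FE discretization error — the
    one-step mesh-refinement study at fixed geometry.
    """
    if mesh.etype != "hex8" or mesh.cell_index is None or mesh.node_index is None:
        raise ValueError("nested refinement requires a hex_voxel mesh with lattice metadata")
    h2 = mesh.element_size / 2.0
    corners = mesh.nodes[mesh.elements]  # (M, 8, 3) in VTK order

    # fine-lattice ids for the 27 lattice points of each parent cell
    offs = np.array([(a, b, c) for a in (0, 1, 2) for b in (0, 1, 2) for c in (0, 1, 2)])
    fine_ijk = 2 * mesh.cell_index[:, None, :] + offs[None, :, :]  # (M, 27, 3)
    dims = fine_ijk.reshape(-1, 3).max(axis=0) + 1
    flat = (fine_ijk[..., 0] * dims[1] + fine_ijk[..., 1]) * dims[2] + fine_ijk[..., 2]

    # trilinear coordinates at xi = offs - 1
    xi = offs - 1.0
    w = np.empty((27, 8))
    for i, s in enumerate(2.0 * _HEX_OFFSETS - 1.0):
        w[:, i] = (1 + s[0] * xi[:, 0]) * (1 + s[1] * xi[:, 1]) * (1 + s[2] * xi[:, 2]) / 8.0
    pts = np.einsum("pk,mkd->mpd", w, corners)  # (M, 27, 3)

    uniq, inv = np.unique(flat.ravel(), return_inverse=True)
    nodes = np.zeros((len(uniq), 3))
    nodes[inv] = pts.reshape(-1, 3)  # shared points agree by construction
    local = inv.reshape(-1, 27)

    # child connectivity: offsets of the 8 sub-cells, VTK corner order
    def pid(a, b, c):
        return (a * 3 + b) * 3 + c

    children = []
    for a in (0, 1):
        for b in (0, 1):
            for c in (0, 1):
                ids = [pid(a + o[0], b + o[1], c + o[2]) for o in _HEX_OFFSETS]
                children.append(local[:, ids])
    elements = np.stack(children, axis=1).reshape(-1, 8)
    domain = np.repeat(mesh.element_domain, 8)
    sub_off = np.array([(a, b, c) for a in (0, 1) for b in (0, 1) for c in (0, 1)])
    cell_index = (2 * mesh.cell_index[:, None, :] + sub_off[None, :, :]).reshape(-1, 3)
    node_index = np.zeros((len(uniq), 3), dtype=np.int64)
    node_index[inv] = fine_ijk.reshape(-1, 3)

    out = FEMesh(
        nodes=nodes,
        elements=elements,
        etype="hex8",
        element_domain=domain.astype(np.int16),
        element_size=h2,
        split_x=mesh.split_x,
        uniform_cube=mesh.uniform_cube,
        lattice_origin=mesh.lattice_origin,
        cell_index=cell_index,
        node_index=node_index,
    )
    # rebuild the named sets on the child lattice
    tib_nodes = np.unique(elements[domain == 1])
    tib_top = float(nodes[tib_nodes, 2].max())
    _attach_sets(out, cell_index, out.element_domain, h2, mesh.lattice_origin, tib_top)
    return out


def _snap_surface_nodes(
    mesh: FEMesh, mask: SegmentationMask, volume: DensityVolume, n_relax: int = 30
) -> None:
    """Project bone-surface nodes onto the smooth segmented surface and
    relax interior nodes to restore element quality.

    The staircase boundary of a voxel mesh perturbs surface fields by O(h)
    and refines into spurious corner singularities; projecting boundary
    nodes along the signed-distance gradient of each bone mask recovers a
    smooth surface with deviation below one voxel (the same contract as
    surface-smoothing in clinical mesh pipelines).  A few Laplacian
    (Jacobi) iterations over the non-snapped, non-boundary nodes spread the
    resulting distortion into the lattice; the whole operation is backed
    off globally if any trilinear corner Jacobian turns non-positive.
    Nodes at the artificial crop planes lie deep inside the masks and are
    never moved.
    """
    from scipy import ndimage as ndi

    h = mesh.element_size
    spacing = volume.spacing
    original = mesh.nodes.copy()
    shift = np.zeros_like(mesh.nodes)
    snapped = np.zeros(mesh.n_nodes, dtype=bool)
    for name, code in (("tibia", 1), ("femur", 2), ("fibula", 3)):
        bone = mask.labels == code
        if not bone.any():
            continue
        psi = ndi.distance_transform_edt(~bone, sampling=spacing) - ndi.distance_transform_edt(
            bone, sampling=spacing
        )
        nids = np.unique(mesh.elements[mesh.element_domain == code])
        idx = volume.world_to_index(mesh.nodes[nids])
        val = ndi.map_coordinates(psi, idx.T, order=1, mode="nearest")
        sel = np.abs(val) < 0.87 * h
        if not sel.any():
            continue
        grads = np.gradient(psi, *spacing)
        g = np.stack(
            [ndi.map_coordinates(gr, idx[sel].T, order=1, mode="nearest") for gr in grads],
            axis=1,
        )
        norm = np.linalg.norm(g, axis=1)
        ok = norm > 1e-6
        d = np.zeros_like(g)
        d[ok] = -val[sel][ok, None] * g[ok] / norm[ok, None] ** 2
        dn = np.linalg.norm(d, axis=1)
        cap = 0.9 * h
        too_far = dn > cap
        d[too_far] *= (cap / dn[too_far])[:, None]
        shift[nids[sel]] += d
        snapped[nids[sel]] = True

    # keep the boundary-condition planes flat: no vertical component there
    for set_name in ("femur_top", "tibia_distal", "fibula_distal"):
        ids = mesh.node_sets.get(set_name)
        if ids is not None and len(ids):
            shift[ids, 2] = 0.0

    # fixed set: snapped surface nodes + every mesh-boundary node (crop
    # planes, soft-cylinder outer wall) — only interior nodes relax
    occ = {}
    dims = mesh.cell_index.max(axis=0) + 2
    occ_arr = np.zeros(tuple(dims), dtype=bool)
    occ_arr[tuple(mesh.cell_index.T)] = True
    ni = mesh.node_index
    interior_lattice = np.ones(mesh.n_nodes, dtype=bool)
    for dx in (0, -1):
        for dy in (0, -1):
            for dz in (0, -1):
                c = ni + np.array([dx, dy, dz])
                inside = np.all((c >= 0) & (c < dims), axis=1)
                hit = np.zeros(mesh.n_nodes, dtype=bool)
                hit[inside] = occ_arr[tuple(c[inside].T)]
                interior_lattice &= hit
    movable = interior_lattice & ~snapped

    # neighbor table along the 6 lattice directions
    key = (ni[:, 0] * (dims[1] + 1) + ni[:, 1]) * (dims[2] + 1) + ni[:, 2]
    lookup = {int(k): i for i, k in enumerate(key)}
    neigh = np.full((mesh.n_nodes, 6), -1, dtype=np.int64)
    for a, (dx, dy, dz) in enumerate(
        [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]
    ):
        nk = ((ni[:, 0] + dx) * (dims[1] + 1) + ni[:, 1] + dy) * (dims[2] + 1) + ni[:, 2] + dz
        for i in np.nonzero(movable)[0]:
            neigh[i, a] = lookup.get(int(nk[i]), -1)

    def relax(pos):
        p = pos.copy()
        mov = np.nonzero(movable)[0]
        nb = neigh[mov]
        for _ in range(n_relax):
            acc = np.zeros((len(mov), 3))
            cntn = np.zeros(len(mov))
            for a in range(6):
                has = nb[:, a] >= 0
                acc[has] += p[nb[has, a]]
                cntn[has] += 1
            good = cntn > 0
            p[mov[good]] = acc[good] / cntn[good][:, None]
        return p

    for scale in (1.0, 0.7, 0.5, 0.3, 0.0):
        mesh.nodes = original + scale * shift
        if scale > 0:
            mesh.nodes = relax(mesh.nodes)
        if _min_corner_jacobian(mesh) > 0.02 * h**3:
            break


def _min_corner_jacobian(mesh: FEMesh) -> float:
    """Minimum trilinear-map Jacobian determinant over all element corners."""
    corners = mesh.nodes[mesh.elements]  # (M, 8, 3)
    signs = 2.0 * _HEX_OFFSETS - 1.0  # corner natural coords, VTK order
    best = np.inf
    for xi in signs:
        g = np.zeros((8, 3))
        for i, s in enumerate(signs):
            g[i, 0] = s[0] * (1 + s[1] * xi[1]) * (1 + s[2] * xi[2]) / 8.0
            g[i, 1] = s[1] * (1 + s[0] * xi[0]) * (1 + s[2] * xi[2]) / 8.0
            g[i, 2] = s[2] * (1 + s[0] * xi[0]) * (1 + s[1] * xi[1]) / 8.0
        J = np.einsum("ka,mkb->mab", g, corners)
        det = np.linalg.det(J) * 8.0  # scale to volume units
        best = min(best, float(det.min()))
    return best


def _attach_sets(mesh, occ_ijk, domain, h, w_lo, tib_top) -> None:
    nodes, elements = mesh.nodes, mesh.elements
    z = nodes[:, 2]

    # the crop planes can be oblique after repositioning noise, so the
    # boundary "sections" span a full element layer plus tolerance
    def top_layer_nodes(dom_code):
        nids = np.unique(elements[domain == dom_code])
        zmax = z[nids].max()
        return nids[z[nids] > zmax - 1.01 * h]

    def bottom_layer_nodes(dom_code):
        nids = np.unique(elements[domain == dom_code])
        zmin = z[nids].min()
        return nids[z[nids] < zmin + 1.01 * h]

    mesh.node_sets["femur_top"] = top_layer_nodes(2)
    mesh.node_sets["tibia_distal"] = bottom_layer_nodes(1)
    if (domain == 3).any():
        mesh.node_sets["fibula_distal"] = bottom_layer_nodes(3)

    # tibial subchondral (plateau) surface: top faces of tibia cells with no
    # tibia cell above, within 12 mm of the tibial apex
    occ_set = {tuple(ijk): i for i, ijk in enumerate(map(tuple, occ_ijk))}
    tib_cells = np.nonzero(domain == 1)[0]
    surf_nodes = []
    surf_elems = []
    for e in tib_cells:
        i, j, k = occ_ijk[e]
        above = occ_set.get((i, j, k + 1))
        if above is None or domain[above] != 1:
            zc = w_lo[2] + h * (k + 0.5)
            if zc >= tib_top - 12.0:
                surf_elems.append(e)
                surf_nodes.extend(elements[e][[4, 5, 6, 7]])  # top face (VTK order)
    surf_nodes = np.unique(np.asarray(surf_nodes, dtype=np.int64))
    split_x = float(nodes[surf_nodes, 0].mean()) if len(surf_nodes) else 0.0
    mesh.split_x = split_x
    medial = surf_nodes[nodes[surf_nodes, 0] >= split_x]
    lateral = surf_nodes[nodes[surf_nodes, 0] < split_x]
    mesh.node_sets["subchondral_surface_medial"] = medial
    mesh.node_sets["subchondral_surface_lateral"] = lateral
    mesh.element_sets["tibia_plateau_surface"] = np.asarray(surf_elems, dtype=np.int64)

    cent = mesh.centroids()
    fem_cells = np.nonzero(domain == 2)[0]
    mesh.element_sets["femur_medial"] = fem_cells[cent[fem_cells, 0] >= split_x]
    mesh.element_sets["femur_lateral"] = fem_cells[cent[fem_cells, 0] < split_x]


def hex_to_tet10(mesh: FEMesh) -> FEMesh:
    """Split each hex into 6 quadratic tets (shared midside nodes)."""
    if mesh.etype != "hex8":
        raise ValueError("expected a hex8 mesh")
    lattice = mesh.elements[:, _LATTICE_TO_VTK]  # corners in lattice-id order
    tets = []
    for t in _KUHN_TETS:
        tets.append(lattice[:, t])
    tet4 = np.stack(tets, axis=1).reshape(-1, 4)  # (6M, 4)
    dom = np.repeat(mesh.element_domain, 6)

    edges = np.array([(0, 1), (1, 2), (0, 2), (0, 3), (1, 3), (2, 3)])
    pairs = np.sort(tet4[:, edges], axis=2).reshape(-1, 2)
    key = pairs[:, 0].astype(np.int64) * len(mesh.nodes) + pairs[:, 1]
    uniq, inv = np.unique(key, return_inverse=True)
    mid_ids = len(mesh.nodes) + inv.reshape(-1, 6)
    a = (uniq // len(mesh.nodes)).astype(np.int64)
    b = (uniq % len(mesh.nodes)).astype(np.int64)
    mid_nodes = 0.5 * (mesh.nodes[a] + mesh.nodes[b])

    elements = np.concatenate([tet4, mid_ids], axis=1)
    nodes = np.vstack([mesh.nodes, mid_nodes])
    node_sets = {}
    for name, ids in mesh.node_sets.items():
        members = np.zeros(len(mesh.nodes), dtype=bool)
        members[ids] = True
        extra = np.nonzero(members[a] & members[b])[0] + len(mesh.nodes)
        node_sets[name] = np.concatenate([ids, extra])
    element_sets = {name: _expand_elem_set(ids) for name, ids in mesh.element_sets.items()}
    return FEMesh(
        nodes=nodes,
        elements=elements,
        etype="tet10",
        element_domain=dom,
        node_sets=node_sets,
        element_sets=element_sets,
        element_size=mesh.element_size,
        split_x=mesh.split_x,
        uniform_cube=False,
        lattice_origin=mesh.lattice_origin,
        cell_index=None if mesh.cell_index is None else np.repeat(mesh.cell_index, 6, axis=0),
    )


def _expand_elem_set(ids: np.ndarray) -> np.ndarray:
    return (np.asarray(ids)[:, None] * 6 + np.arange(6)[None, :]).ravel()


# ---------------------------------------------------------------------------
# material mapping
# ---------------------------------------------------------------------------

def map_materials(
    mesh: FEMesh,
    volume: DensityVolume,
    law: MaterialLaw | None = None,
    e_soft: float = E_SOFT,
    nu_soft: float = NU_SOFT,
    nu_bone: float = NU_BONE,
    e_rigid: float = E_RIGID,
) -> MaterialField:
    """Integration-point density sampling + power-law modulus per element.

    Per-element rho is the mean of the calibrated density sampled at the
    element's integration points (trilinear interpolation).  Soft tissue and
    the rigid femur override the law with fixed constants.
    """
    if volume.units != MG_CM3:
        raise ValueError("volume must be calibrated (mg/cm3) before material mapping")
    law = law or MaterialLaw()

    if mesh.etype == "hex8":
        corners = mesh.nodes[mesh.elements]  # (M, 8, 3)
        cent = corners.mean(axis=1)
        g = 0.5 / np.sqrt(3.0)
        span = corners.max(axis=1) - corners.min(axis=1)
        offs = np.array(
            [[sx, sy, sz] for sx in (-g, g) for sy in (-g, g) for sz in (-g, g)]
        )
        pts = cent[:, None, :] + offs[None, :, :] * span[:, None, :]
    else:
        corners = mesh.nodes[mesh.elements[:, :4]]  # (M, 4, 3)
        a, b = 0.5854101966249685, 0.1381966011250105
        bary = np.full((4, 4), b)
        np.fill_diagonal(bary, a)
        pts = np.einsum("gk,mkd->mgd", bary, corners)

    m, g, _ = pts.shape
    idx = volume.world_to_index(pts.reshape(-1, 3))
    vals = ndimage.map_coordinates(
        volume.data.astype(np.float64), idx.T, order=1, mode="nearest"
    )
    rho = vals.reshape(m, g).mean(axis=1)
    n_clamped = int((rho < 0).sum())
    rho = np.maximum(rho, 0.0)

    E = law(rho)
    nu = np.full(m, nu_bone)
    rigid = np.zeros(m, dtype=bool)

    soft = mesh.domain_mask("soft_tissue")
    E[soft] = e_soft
    nu[soft] = nu_soft
    rho[soft] = 0.0
    fem = mesh.domain_mask("femur")
    E[fem] = e_rigid
    rigid[fem] = True
    return MaterialField(E=E, nu=nu, rho=rho, rigid_flags=rigid, n_clamped_rho=n_clamped)


# ---------------------------------------------------------------------------
# export
# ---------------------------------------------------------------------------

def write_vtk(mesh: FEMesh, path: str, cell_data: dict | None = None) -> None:
    """Legacy ASCII VTK unstructured-grid writer (hex8 or tet10 cells)."""
    cell_data = cell_data or {}
    npe = mesh.elements.shape[1]
    vtk_type = 12 if mesh.etype == "hex8" else 24
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\ntibiamech mesh\nASCII\n")
        fh.write("DATASET UNSTRUCTURED_GRID\n")
        fh.write(f"POINTS {mesh.n_nodes} float\n")
        np.savetxt(fh, mesh.nodes, fmt="%.6g")
        fh.write(f"CELLS {mesh.n_elements} {mesh.n_elements * (npe + 1)}\n")
        conn = np.column_stack([np.full(mesh.n_elements, npe), mesh.elements])
        np.savetxt(fh, conn, fmt="%d")
        fh.write(f"CELL_TYPES {mesh.n_elements}\n")
        np.savetxt(fh, np.full(mesh.n_elements, vtk_type), fmt="%d")
        fields = {"domain": mesh.element_domain, **cell_data}
        fh.write(f"CELL_DATA {mesh.n_elements}\n")
        for name, arr in fields.items():
            arr = np.asarray(arr)
            fh.write(f"SCALARS {name} float 1\nLOOKUP_TABLE default\n")
            np.savetxt(fh, arr.reshape(-1, 1), fmt="%.6g")


def write_inp(
    mesh: FEMesh, materials: MaterialField, path: str, n_bins: int = 100
) -> None:
    """Abaqus INP writer: nodes, C3D8/C3D10 elements, binned solid sections."""
    etype = "C3D8" if mesh.etype == "hex8" else "C3D10"
    E = materials.E
    edges = np.unique(np.quantile(E, np.linspace(0, 1, n_bins + 1)))
    bins = np.clip(np.searchsorted(edges, E, side="right") - 1, 0, len(edges) - 2)
    with open(path, "w") as fh:
        fh.write("*HEADING\ntibiamech export\n")
        fh.write("*NODE\n")
        for i, p in enumerate(mesh.nodes, start=1):
            fh.write(f"{i}, {p[0]:.6g}, {p[1]:.6g}, {p[2]:.6g}\n")
        for b in np.unique(bins):
            ids = np.nonzero(bins == b)[0]
            fh.write(f"*ELEMENT, TYPE={etype}, ELSET=MAT{b + 1}\n")
            for e in ids:
                conn = ", ".join(str(n + 1) for n in mesh.elements[e])
                fh.write(f"{e + 1}, {conn}\n")
        for b in np.unique(bins):
            ids = np.nonzero(bins == b)[0]
            e_mean = float(E[ids].mean())
            nu = float(np.median(materials.nu[ids]))
            fh.write(f"*SOLID SECTION, ELSET=MAT{b + 1}, MATERIAL=M{b + 1}\n")
            fh.write(f"*MATERIAL, NAME=M{b + 1}\n*ELASTIC\n{e_mean:.6g}, {nu:.4g}\n")
        for name, ids in mesh.node_sets.items():
            fh.write(f"*NSET, NSET={name.upper()}\n")
            for chunk in np.array_split(ids + 1, max(1, len(ids) // 12)):
                fh.write(", ".join(map(str, chunk)) + "\n")
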