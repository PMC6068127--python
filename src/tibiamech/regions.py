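"""Regional analysis of the proximal tibia.

Partitions tibial elements into 17 named regions: depth bands measured from
the articular (plateau + intercondylar spine) surface — subchondral cortical
0-2.5 mm, subchondral trabecular 2.5-5 mm, epiphyseal 5-15 mm, metaphyseal
15-35 mm — crossed with medial / central / lateral sectors, plus the outer
cortical wall (peripheral 0-5 mm, then epiphyseal / metaphyseal cortical by
the same axial bands projected onto the periphery).  Depth is the Euclidean
distance transform from the segmented tibial surface computed on the voxel
grid and sampled at element centroids, so region membership is independent
of the FE discretization.

Compartmental (medial / lateral) structural stiffness follows the
two-extra-model procedure: the opposite femoral compartment is softened to
E = 10 MPa so essentially all load passes through the compartment of
interest, and stiffness = vertical reaction force / mean vertical
displacement of that compartment's subchondral surface nodes (N/mm).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .imageproc import SegmentationMask
from .meshmat import FEMesh, MaterialField
from .solver import FieldResult, LoadCase, assemble_and_solve
from .volume import DensityVolume

__all__ = [
    "REGION_NAMES",
    "RegionInputs",
    "RegionMap",
    "derive_region_inputs",
    "assign_regions",
    "aggregate",
    "compartment_stiffness",
]

_BANDS = ("subchondral cortical", "subchondral trabecular", "epiphyseal trabecular", "metaphyseal trabecular")
_WALL = ("peripheral cortical", "epiphyseal cortical", "metaphyseal cortical")

REGION_NAMES = (
    [f"Medial {b}" for b in _WALL + _BANDS]
    + ["Subchondral spine", "Epiphyseal central", "Metaphyseal central"]
    + [f"Lateral {b}" for b in _WALL + _BANDS]
)
REGION_CODES = {name: i + 1 for i, name in enumerate(REGION_NAMES)}
UNASSIGNED = 0

# depth band edges, mm; half-open [lo, hi), deepest band closed at 35
BAND_EDGES = (2.5, 5.0, 15.0, 35.0)
PERIPHERAL_DEPTH = 5.0
CORTICAL_WALL_DEPTH = 2.5
MAX_DEPTH = 35.0


@dataclass
class RegionInputs:
    """Voxel-grid distance fields and split geometry for region assignment."""

    dt_top: np.ndarray  # mm to the articular (plateau+spine) surface
    dt_side: np.ndarray  # mm to the outer cortical wall
    tibia_mask: np.ndarray
    volume: DensityVolume  # grid geometry carrier
    split_x: float  # sagittal plane through the intercondylar spine centroid
    central_halfwidth: float  # half-width of the central sector slab, mm


@dataclass
class RegionMap:
    """Per-element region assignment."""

    region_of_element: np.ndarray  # codes, 0 = unassigned
    depth_of_element: np.ndarray  # mm from the tibial surface
    legend: dict = field(default_factory=lambda: dict(REGION_CODES))

    def name_of(self, code: int) -> str:
        return "unassigned" if code == UNASSIGNED else REGION_NAMES[code - 1]


def derive_region_inputs(
    mask: SegmentationMask,
    volume: DensityVolume,
    plateau_band_mm: float = 12.0,
    central_fraction: float = 0.2,
) -> RegionInputs:
    """Compute the articular/side surface distance fields on the voxel grid.

    The articular surface is the up-exposed tibial surface within
    ``plateau_band_mm`` of the tibial apex (plateau + spine); every other
    surface voxel belongs to the outer cortical wall.  The medial/lateral
    split plane passes through the centroid of the spine (the highest
    articular voxels); the central sector is a sagittal slab of width
    ``central_fraction`` x the mediolateral plateau extent.
    """
    tib = mask.mask("tibia")
    if not tib.any():
        raise ValueError("missing tibia mask")
    spacing = volume.spacing
    surface = tib & ~ndimage.binary_erosion(tib)
    up_exposed = tib.copy()
    up_exposed[:, :, :-1] &= ~tib[:, :, 1:]
    up_exposed[:, :, -1] = tib[:, :, -1]

    zs = np.nonzero(tib.any(axis=(0, 1)))[0]
    z_apex = volume.origin[2] + spacing[2] * zs.max()
    zcoord = volume.origin[2] + spacing[2] * np.arange(tib.shape[2])
    near_top = zcoord >= z_apex - plateau_band_mm
    top_surface = up_exposed & near_top[None, None, :]
    if not top_surface.any():
        raise ValueError("no articular (plateau) surface found")
    side_surface = surface & ~top_surface

    dt_top = ndimage.distance_transform_edt(~top_surface, sampling=spacing)
    dt_side = ndimage.distance_transform_edt(~side_surface, sampling=spacing)

    # spine centroid: highest articular voxels
    ti = np.argwhere(top_surface)
    tz = volume.origin[2] + spacing[2] * ti[:, 2]
    spine = ti[tz >= tz.max() - 2.0]
    split_x = float(volume.origin[0] + spacing[0] * spine[:, 0].mean())
    xw = volume.origin[0] + spacing[0] * ti[:, 0]
    ml_extent = float(xw.max() - xw.min())
    return RegionInputs(
        dt_top=dt_top,
        dt_side=dt_side,
        tibia_mask=tib,
        volume=volume,
        split_x=split_x,
        central_halfwidth=0.5 * central_fraction * ml_extent,
    )


def _band(depths: np.ndarray) -> np.ndarray:
    """0..3 for the four depth bands; -1 beyond 35 mm. Half-open [lo, hi)."""
    b = np.digitize(depths, BAND_EDGES, right=False)
    b = np.where(depths > MAX_DEPTH + 1e-9, -1, np.minimum(b, 3))
    return b


def _region_codes(
    dt_top: np.ndarray,
    dt_side: np.ndarray,
    x: np.ndarray,
    in_tibia: np.ndarray,
    split_x: float,
    central_halfwidth: float,
) -> np.ndarray:
    """Vectorized 17-region coding shared by element and voxel assignment."""
    codes = np.zeros(dt_top.shape, dtype=np.int16)
    medial = x >= split_x + central_halfwidth
    lateral = x <= split_x - central_halfwidth
    central = ~medial & ~lateral
    side_med = x >= split_x  # wall labels split at the plane, no slab

    band = _band(dt_top)
    in_depth = in_tibia & (band >= 0)

    # outer cortical wall takes precedence: peripheral 0-5 mm from the side
    # surface in the 0-5 mm axial band, then epiphyseal/metaphyseal cortical
    # (0-2.5 mm from the side surface) in the deeper axial bands
    peripheral = in_depth & (band <= 1) & (dt_side < PERIPHERAL_DEPTH)
    epi_wall = in_depth & (band == 2) & (dt_side < CORTICAL_WALL_DEPTH)
    meta_wall = in_depth & (band == 3) & (dt_side < CORTICAL_WALL_DEPTH)
    wall = peripheral | epi_wall | meta_wall
    for sel, wname in (
        (peripheral, "peripheral cortical"),
        (epi_wall, "epiphyseal cortical"),
        (meta_wall, "metaphyseal cortical"),
    ):
        codes[sel & side_med] = REGION_CODES[f"Medial {wname}"]
        codes[sel & ~side_med] = REGION_CODES[f"Lateral {wname}"]

    # everything else under the articular surface: depth bands x sectors
    top_col = in_depth & ~wall
    for b, bname in enumerate(_BANDS):
        sel = top_col & (band == b)
        codes[sel & medial] = REGION_CODES[f"Medial {bname}"]
        codes[sel & lateral] = REGION_CODES[f"Lateral {bname}"]
    codes[top_col & central & (band <= 1)] = REGION_CODES["Subchondral spine"]
    codes[top_col & central & (band == 2)] = REGION_CODES["Epiphyseal central"]
    codes[top_col & central & (band == 3)] = REGION_CODES["Metaphyseal central"]
    return codes


def assign_regions(mesh: FEMesh, inputs: RegionInputs) -> RegionMap:
    """Assign each tibial element to one of the 17 regions by centroid depth."""
    cent = mesh.centroids()
    idx = inputs.volume.world_to_index(cent)
    dt_top = ndimage.map_coordinates(inputs.dt_top, idx.T, order=1, mode="nearest")
    dt_side = ndimage.map_coordinates(inputs.dt_side, idx.T, order=1, mode="nearest")
    codes = _region_codes(
        dt_top, dt_side, cent[:, 0], mesh.domain_mask("tibia"),
        inputs.split_x, inputs.central_halfwidth,
    )
    return RegionMap(region_of_element=codes, depth_of_element=np.minimum(dt_top, dt_side))


def voxel_region_codes(inputs: RegionInputs) -> np.ndarray:
    """17-region label per voxel of the segmentation grid."""
    vol = inputs.volume
    x = vol.origin[0] + vol.spacing[0] * np.arange(vol.shape[0])
    X = np.broadcast_to(x[:, None, None], vol.shape)
    return _region_codes(
        inputs.dt_top, inputs.dt_side, X, inputs.tibia_mask,
        inputs.split_x, inputs.central_halfwidth,
    )


def aggregate(result: FieldResult, regmap: RegionMap, volumes: np.ndarray) -> pd.DataFrame:
    """Volume-weighted regional means of the four field metrics.

    Returns a DataFrame indexed by region name with one column per metric
    plus ``element_count`` and ``region_volume`` (mm^3).  Unassigned elements
    are excluded.
    """
    codes = regmap.region_of_element
    volumes = np.asarray(volumes, dtype=float)
    if len(volumes) != len(codes):
        raise ValueError("map and result must share element ids")
    rows = {}
    for name, code in REGION_CODES.items():
        sel = codes == code
        n = int(sel.sum())
        if n == 0:
            continue
        w = volumes[sel]
        row = {"element_count": n, "region_volume": float(w.sum())}
        for metric in FieldResult.METRICS:
            vals = getattr(result, metric)[sel]
            row[metric] = float(np.average(vals, weights=w))
        rows[name] = row
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "region"
    return df


def aggregate_voxel(
    result: FieldResult,
    mesh: FEMesh,
    inputs: RegionInputs,
    volume: DensityVolume | None = None,
    law=None,
    nu_bone: float = 0.3,
) -> pd.DataFrame:
    """Regional means computed on the fixed voxel grid (mesh-independent).

    Element strain tensors are first smoothed to the mesh nodes (mean over
    the tibial elements sharing a node — standard nodal recovery), then
    interpolated trilinearly at the centers of the tibial voxels; scalar
    metrics are evaluated per voxel and averaged within each voxel-coded
    region.  When the calibrated ``volume`` and a density-modulus ``law``
    are given, voxel stress is the sampled strain times the voxel's own
    modulus, so the stress field does not depend on how elements average
    the density.  Because region membership and the averaging weights live
    on the segmentation grid, two meshes of different element size are
    compared over exactly the same region volumes, isolating true field
    convergence from band-membership jitter.
    """
    if mesh.lattice_origin is None or mesh.cell_index is None:
        raise ValueError("mesh carries no lattice metadata (not a hex_voxel mesh)")
    h = mesh.element_size
    origin = mesh.lattice_origin
    tibia_elems = np.nonzero(mesh.domain_mask("tibia"))[0]
    if mesh.etype == "tet10":
        elem_nodes = mesh.elements[tibia_elems][:, :4]
    else:
        elem_nodes = mesh.elements[tibia_elems]

    # volume-weighted nodal recovery over the tibial elements
    evol = mesh.element_volumes()[tibia_elems]
    wrep = np.repeat(evol, elem_nodes.shape[1])
    flat_nodes = elem_nodes.ravel()
    cnt = np.zeros(mesh.n_nodes)
    np.add.at(cnt, flat_nodes, wrep)

    # voxels to sample: region-coded tibia voxels lying inside tibia cells
    vox_codes = voxel_region_codes(inputs)
    sel = np.argwhere(vox_codes > 0)
    w = inputs.volume.index_to_world(sel)
    cell_dims = mesh.cell_index.max(axis=0) + 1
    elem_of_cell = np.full(tuple(cell_dims), -1, dtype=np.int64)
    ci = mesh.cell_index[tibia_elems]
    elem_of_cell[ci[:, 0], ci[:, 1], ci[:, 2]] = tibia_elems
    cv = np.floor((w - origin) / h).astype(np.int64)
    inside = np.all((cv >= 0) & (cv < cell_dims), axis=1)
    ok = inside.copy()
    ok[inside] = elem_of_cell[cv[inside, 0], cv[inside, 1], cv[inside, 2]] >= 0
    sel, w, cv = sel[ok], w[ok], cv[ok]
    codes = vox_codes[sel[:, 0], sel[:, 1], sel[:, 2]]
    eid = elem_of_cell[cv[:, 0], cv[:, 1], cv[:, 2]]

    # exact element-local coordinates of each voxel center: invert the
    # trilinear map by Newton iteration (3 steps suffice; surfaces snapped
    # off-lattice make the naive lattice coordinates systematically wrong)
    enodes = mesh.elements[eid][:, :8] if mesh.etype != "tet10" else None
    if mesh.etype == "tet10":
        raise ValueError("voxel aggregation supports hex_voxel meshes")
    corners = mesh.nodes[enodes]  # (V, 8, 3)
    signs = np.array(
        [(-1, -1, -1), (1, -1, -1), (1, 1, -1), (-1, 1, -1),
         (-1, -1, 1), (1, -1, 1), (1, 1, 1), (-1, 1, 1)], dtype=float
    )
    xi = 2.0 * ((w - origin) / h - cv) - 1.0

    def shape_w(x):
        return np.stack(
            [(1 + s[0] * x[:, 0]) * (1 + s[1] * x[:, 1]) * (1 + s[2] * x[:, 2]) / 8.0
             for s in signs], axis=1
        )

    for _ in range(3):
        N = shape_w(xi)
        x = np.einsum("vk,vkd->vd", N, corners)
        r = x - w
        dN = np.zeros((len(xi), 8, 3))
        for k, s in enumerate(signs):
            dN[:, k, 0] = s[0] * (1 + s[1] * xi[:, 1]) * (1 + s[2] * xi[:, 2]) / 8.0
            dN[:, k, 1] = s[1] * (1 + s[0] * xi[:, 0]) * (1 + s[2] * xi[:, 2]) / 8.0
            dN[:, k, 2] = s[2] * (1 + s[0] * xi[:, 0]) * (1 + s[1] * xi[:, 1]) / 8.0
        J = np.einsum("vka,vkd->vad", dN, corners)  # dx_d / dxi_a
        dxi = np.linalg.solve(np.swapaxes(J, 1, 2), r[:, :, None])[:, :, 0]
        xi = np.clip(xi - dxi, -1.5, 1.5)
    Nw = shape_w(xi)

    def smooth_sample(vals: np.ndarray) -> np.ndarray:
        """Nodal-average an element field and interpolate it at the voxels."""
        acc = np.zeros(mesh.n_nodes)
        np.add.at(acc, flat_nodes, np.repeat(vals, elem_nodes.shape[1]) * wrep)
        nodal = np.zeros(mesh.n_nodes)
        nz = cnt > 0
        nodal[nz] = acc[nz] / cnt[nz]
        return np.einsum("vk,vk->v", Nw, nodal[enodes])

    vox_vol = float(np.prod(inputs.volume.spacing))
    # sample the six centroid strain components (centroids are the accurate
    # evaluation points for trilinear hexes), rebuild per-voxel tensors
    et = result.strain_tensor[tibia_elems]
    comps = [et[:, 0, 0], et[:, 1, 1], et[:, 2, 2], et[:, 0, 1], et[:, 1, 2], et[:, 0, 2]]
    sc = [smooth_sample(c) for c in comps]
    nvox = len(w)
    eps = np.zeros((nvox, 3, 3))
    eps[:, 0, 0], eps[:, 1, 1], eps[:, 2, 2] = sc[0], sc[1], sc[2]
    eps[:, 0, 1] = eps[:, 1, 0] = sc[3]
    eps[:, 1, 2] = eps[:, 2, 1] = sc[4]
    eps[:, 0, 2] = eps[:, 2, 0] = sc[5]
    eps = np.nan_to_num(eps)

    from .solver import elasticity_matrix, principal_and_vm

    mpe, vme = principal_and_vm(eps, "strain")
    if volume is not None and law is not None:
        rho = ndimage.map_coordinates(
            volume.data.astype(np.float64), inputs.volume.world_to_index(w).T, order=1,
            mode="nearest",
        )
        E_vox = law(rho)
        D1 = elasticity_matrix(1.0, nu_bone)
        # tensor shears -> engineering shears for the constitutive product
        e6 = np.stack([sc[0], sc[1], sc[2], 2 * sc[3], 2 * sc[4], 2 * sc[5]], axis=1)
        s6 = np.nan_to_num(e6) @ D1.T * E_vox[:, None]
        sig = np.zeros((nvox, 3, 3))
        sig[:, 0, 0], sig[:, 1, 1], sig[:, 2, 2] = s6[:, 0], s6[:, 1], s6[:, 2]
        sig[:, 0, 1] = sig[:, 1, 0] = s6[:, 3]
        sig[:, 1, 2] = sig[:, 2, 1] = s6[:, 4]
        sig[:, 0, 2] = sig[:, 2, 0] = s6[:, 5]
        mps, vms = principal_and_vm(sig, "stress")
    else:
        mps = smooth_sample(result.min_principal_stress[tibia_elems])
        vms = smooth_sample(result.von_mises_stress[tibia_elems])
    sampled = {
        "min_principal_stress": mps,
        "von_mises_stress": vms,
        "min_principal_strain": mpe * 1e6,
        "von_mises_strain": vme * 1e6,
    }
    rows = {}
    for name, code in REGION_CODES.items():
        m = codes == code
        n = int(m.sum())
        if n == 0:
            continue
        row = {"element_count": n, "region_volume": n * vox_vol}
        for metric in FieldResult.METRICS:
            row[metric] = float(np.nanmean(sampled[metric][m]))
        rows[name] = row
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "region"
    return df


def compartment_stiffness(
    mesh: FEMesh,
    materials: MaterialField,
    load: LoadCase,
    side: str,
    e_soft: float = 10.0,
    nu_soft: float = 0.495,
    method: str = "auto",
) -> float:
    """Structural stiffness (N/mm) of one tibial compartment.

    Re-solves the model with the opposite femoral compartment softened to
    ``e_soft`` so essentially all load passes through the compartment of
    interest; stiffness = vertical reaction / mean |vertical displacement|
    of that side's subchondral surface nodes.
    """
    if side not in ("medial", "lateral"):
        raise ValueError("side must be 'medial' or 'lateral'")
    opposite = "lateral" if side == "medial" else "medial"
    soften = mesh.element_sets[f"femur_{opposite}"]
    E = materials.E.copy()
    nu = materials.nu.copy()
    rigid = materials.rigid_flags.copy()
    E[soften] = e_soft
    nu[soften] = nu_soft
    rigid[soften] = False
    mats = MaterialField(E=E, nu=nu, rho=materials.rho, rigid_flags=rigid)

    result = assemble_and_solve(mesh, mats, load, method=method)
    nodes = mesh.node_sets[f"subchondral_surface_{side}"]
    if len(nodes) == 0:
        raise ValueError(f"empty subchondral node set for side {side!r}")
    uz = result.displacement[nodes, 2]
    mean_disp = abs(float(uz.mean()))
    if mean_disp <= 0:
        raise ValueError("zero mean subchondral displacement")
    return result.reaction_force / mean_disp
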