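"""Shared fixtures: a coarse synthetic knee and its processed image chain.

The coarse phantom (1.5 mm voxels) keeps the suite fast while exercising
every stage at realistic anatomy scale; resolution-sensitive checks build
their own volumes.
"""

import numpy as np
import pytest

from tibiamech import imageproc, meshmat, regions
from tibiamech.meshmat import FEMesh
from tibiamech.phantom import PhantomSpec, generate_knee_phantom

COARSE_VOXEL = 1.5
COARSE_ELEMENT = 4.0


@pytest.fixture(scope="session")
def neutral_phantom():
    """Neutral (180 degree) normal knee at coarse resolution."""
    spec = PhantomSpec(group="normal", body_mass=72.0, varus_angle=180.0,
                       voxel_size=COARSE_VOXEL, seed=3)
    volume, truth = generate_knee_phantom(spec)
    return spec, volume, truth


@pytest.fixture(scope="session")
def varus_phantom():
    """175 degree varus OA knee at coarse resolution."""
    spec = PhantomSpec(group="OA", body_mass=101.0, varus_angle=175.0,
                       density_scale=1.15, voxel_size=COARSE_VOXEL, seed=7)
    volume, truth = generate_knee_phantom(spec)
    return spec, volume, truth


@pytest.fixture(scope="session")
def image_chain(neutral_phantom):
    """Calibrated, segmented, realigned image chain of the neutral phantom."""
    _, volume, truth = neutral_phantom
    cal, model = imageproc.calibrate(volume, truth.rod_masks(), truth.rod_densities)
    peak, bg = imageproc.auto_probe_regions(cal)
    threshold = imageproc.hmh_threshold(cal, peak, bg)
    seg = imageproc.segment_bones(cal, threshold, imageproc.auto_seeds(cal, threshold))
    axes = imageproc.fit_bone_axes(seg, cal)
    cal_r, seg_r, align = imageproc.realign(cal, seg, axes)
    return {
        "truth": truth,
        "calibrated": cal,
        "model": model,
        "threshold": threshold,
        "seg": seg,
        "axes": axes,
        "cal_r": cal_r,
        "seg_r": seg_r,
        "align": align,
    }


@pytest.fixture(scope="session")
def knee_mesh(image_chain):
    mesh = meshmat.build_mesh(
        image_chain["seg_r"], image_chain["cal_r"], element_size=COARSE_ELEMENT
    )
    mats = meshmat.map_materials(mesh, image_chain["cal_r"])
    return mesh, mats


@pytest.fixture(scope="session")
def region_inputs(image_chain):
    return regions.derive_region_inputs(image_chain["seg_r"], image_chain["cal_r"])


def box_mesh(nx: int, ny: int, nz: int, h: float, domain: int = 1) -> FEMesh:
    """Structured box of uniform cube hex8 elements with top/bottom node sets."""
    xs, ys, zs = (np.arange(n + 1) * h for n in (nx, ny, nz))

    def nid(i, j, k):
        return (i * (ny + 1) + j) * (nz + 1) + k

    nodes = np.array([[x, y, z] for x in xs for y in ys for z in zs], dtype=float)
    elems = [
        [nid(i, j, k), nid(i + 1, j, k), nid(i + 1, j + 1, k), nid(i, j + 1, k),
         nid(i, j, k + 1), nid(i + 1, j, k + 1), nid(i + 1, j + 1, k + 1), nid(i, j + 1, k + 1)]
        for i in range(nx) for j in range(ny) for k in range(nz)
    ]
    mesh = FEMesh(
        nodes=nodes,
        elements=np.asarray(elems),
        etype="hex8",
        element_domain=np.full(len(elems), domain, dtype=np.int16),
        element_size=h,
        uniform_cube=True,
    )
    z = nodes[:, 2]
    mesh.node_sets["femur_top"] = np.nonzero(z > zs[-1] - 1e-9)[0]
    mesh.node_sets["tibia_distal"] = np.nonzero(z < 1e-9)[0]
    return mesh
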