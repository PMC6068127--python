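"""Mesh construction, density-modulus law, material mapping, exporters."""

import numpy as np
import pytest

from tibiamech import meshmat
from tibiamech.imageproc import SegmentationMask
from tibiamech.meshmat import (
    build_mesh,
    goulet_modulus,
    hex_to_tet10,
    map_materials,
    refine_nested,
    write_inp,
    write_vtk,
)
from tibiamech.volume import MG_CM3, DensityVolume


class TestGouletModulus:
    def test_zero_density_hits_floor(self):
        assert goulet_modulus(0.0) == pytest.approx(1.0)

    def test_doubling_density_scales_by_two_to_the_2p1(self):
        rho = np.array([300.0, 500.0, 800.0])
        ratio = goulet_modulus(2 * rho) / goulet_modulus(rho)
        assert np.allclose(ratio, 2.0**2.1)
        assert 2.0**2.1 == pytest.approx(4.287, abs=0.001)

    def test_monotone_in_density(self):
        rho = np.linspace(0, 1200, 100)
        E = goulet_modulus(rho)
        assert (np.diff(E) >= 0).all()

    def test_negative_density_clamped(self):
        assert goulet_modulus(-50.0) == goulet_modulus(0.0)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            goulet_modulus(100.0, coeff_a=-1.0)
        with pytest.raises(ValueError):
            goulet_modulus(np.array([1.0, np.nan]))


def _cube_case(n=14, voxel=1.0):
    """A solid cube labeled tibia plus a separated femur block above.

    The 12-voxel block edges land on the anchored 2 mm cell lattice, so the
    coarsened element counts are exact.
    """
    shape = (n, n, 3 * n)
    labels = np.zeros(shape, dtype=np.int16)
    labels[1:13, 1:13, 1:13] = 1  # tibia block, 12 voxels on a side
    labels[1:13, 1:13, 21:33] = 2  # femur block
    data = np.where(labels > 0, 400.0, 0.0)
    vol = DensityVolume(data, spacing=(voxel,) * 3, units=MG_CM3)
    return SegmentationMask(labels=labels, threshold_used=200.0), vol


class TestBuildMesh:
    def test_cube_element_count_matches_coarsening(self):
        seg, vol = _cube_case()
        mesh = build_mesh(seg, vol, element_size=2.0, femur_extent=None,
                          tibia_extent=None, soft_radius_factor=0.01)
        # a lattice-aligned 12-voxel cube coarsens to exactly (12/2)^3 cells
        tib = mesh.domain_mask("tibia").sum()
        assert tib == 6 * 6 * 6

    def test_mesh_volume_matches_mask_volume(self, image_chain, knee_mesh):
        mesh, _ = knee_mesh
        seg_r = image_chain["seg_r"]
        voxel_vol = np.prod(image_chain["cal_r"].spacing)
        vols = mesh.element_volumes()
        # tibia cropped to its proximal extent in the mesh: compare over the
        # meshed z-range only
        zmin = mesh.nodes[np.unique(mesh.elements[mesh.domain_mask("tibia")]), 2].min()
        tib_mask = seg_r.mask("tibia")
        idx = np.argwhere(tib_mask)
        world_z = image_chain["cal_r"].index_to_world(idx)[:, 2]
        mask_vol = (world_z >= zmin - 0.75).sum() * voxel_vol
        mesh_vol = vols[mesh.domain_mask("tibia")].sum()
        assert mesh_vol == pytest.approx(mask_vol, rel=0.03)

    def test_all_jacobians_positive_and_sets_valid(self, knee_mesh):
        mesh, _ = knee_mesh
        mesh.validate()  # raises on any defect
        assert (mesh.element_volumes() > 0).all()
        for name in ("femur_top", "tibia_distal", "subchondral_surface_medial",
                     "subchondral_surface_lateral"):
            assert len(mesh.node_sets[name]) > 0

    def test_subchondral_nodes_lie_on_plateau(self, knee_mesh, image_chain):
        mesh, _ = knee_mesh
        seg_r, cal_r = image_chain["seg_r"], image_chain["cal_r"]
        tib = seg_r.mask("tibia")
        zmax = cal_r.index_to_world(np.argwhere(tib))[:, 2].max()
        for side in ("medial", "lateral"):
            z = mesh.nodes[mesh.node_sets[f"subchondral_surface_{side}"], 2]
            assert (z >= zmax - 14.0).all()

    def test_touching_bones_rejected(self):
        seg, vol = _cube_case()
        seg.labels[5, 5, 11:19] = 2  # bridge the gap with femur voxels
        seg.labels[5, 5, 10] = 1
        with pytest.raises(ValueError, match="gap"):
            build_mesh(seg, vol, element_size=2.0)

    def test_element_size_below_voxel_rejected(self, image_chain):
        with pytest.raises(ValueError, match="voxel"):
            build_mesh(image_chain["seg_r"], image_chain["cal_r"], element_size=0.5)


class TestTetConversion:
    def test_tet_mesh_partitions_hex_volume(self, image_chain):
        mesh = build_mesh(image_chain["seg_r"], image_chain["cal_r"],
                          element_size=5.0, mode="tet_quadratic",
                          smooth_surface=False)
        assert mesh.etype == "tet10"
        assert mesh.n_elements % 6 == 0
        assert (mesh.element_volumes() > 0).all()
        # six tets per hex recompose the cube volume
        h = mesh.element_size
        per_hex = mesh.element_volumes().reshape(-1, 6).sum(axis=1)
        assert np.allclose(per_hex, h**3)

    def test_midside_nodes_at_edge_midpoints(self):
        seg, vol = _cube_case()
        hexm = build_mesh(seg, vol, element_size=2.0, femur_extent=None,
                          tibia_extent=None, soft_radius_factor=0.01)
        tetm = hex_to_tet10(hexm)
        corners = tetm.elements[:, :4]
        mids = tetm.elements[:, 4:]
        edges = [(0, 1), (1, 2), (0, 2), (0, 3), (1, 3), (2, 3)]
        for k, (i, j) in enumerate(edges):
            expected = 0.5 * (tetm.nodes[corners[:, i]] + tetm.nodes[corners[:, j]])
            assert np.allclose(tetm.nodes[mids[:, k]], expected)


class TestNestedRefinement:
    def test_children_preserve_geometry_and_volume(self, knee_mesh):
        mesh, _ = knee_mesh
        fine = refine_nested(mesh)
        assert fine.n_elements == 8 * mesh.n_elements
        assert fine.element_size == pytest.approx(mesh.element_size / 2)
        # volumes agree up to the straight-edge tet proxy used for distorted
        # hexes (exact for unsnapped cubes)
        assert fine.element_volumes().sum() == pytest.approx(
            mesh.element_volumes().sum(), rel=1e-4
        )


class TestMapMaterials:
    def test_uniform_density_gives_identical_bone_moduli(self):
        seg, vol = _cube_case()
        mesh = build_mesh(seg, vol, element_size=2.0, femur_extent=None,
                          tibia_extent=None, soft_radius_factor=0.01)
        mats = map_materials(mesh, vol)
        tib = mesh.domain_mask("tibia")
        # interior elements see the uniform 400 mg/cm3
        interior = tib & (mats.rho > 399.0)
        assert interior.sum() > 0
        assert np.allclose(mats.E[interior], mats.E[interior][0])
        assert np.allclose(mats.nu[tib], 0.3)

    def test_two_phase_volume_gives_bimodal_moduli(self):
        seg, vol = _cube_case()
        half = vol.shape[0] // 2
        vol.data[:half][seg.labels[:half] == 1] = 200.0
        mesh = build_mesh(seg, vol, element_size=2.0, femur_extent=None,
                          tibia_extent=None, soft_radius_factor=0.01)
        mats = map_materials(mesh, vol)
        tib = mesh.domain_mask("tibia")
        E = mats.E[tib]
        lo, hi = goulet_modulus(200.0), goulet_modulus(400.0)
        frac_lo = (np.abs(E - lo) < 0.05 * lo).mean()
        frac_hi = (np.abs(E - hi) < 0.05 * hi).mean()
        assert frac_lo > 0.15 and frac_hi > 0.15
        # boundary elements take intermediate values
        assert ((E > 1.05 * lo) & (E < 0.95 * hi)).any()

    def test_fixed_constants_for_soft_and_rigid_domains(self, knee_mesh):
        mesh, mats = knee_mesh
        soft = mesh.domain_mask("soft_tissue")
        fem = mesh.domain_mask("femur")
        assert np.allclose(mats.E[soft], 10.0)
        assert np.allclose(mats.nu[soft], 0.495)
        assert np.allclose(mats.E[fem], 500_000.0)
        assert mats.rigid_flags[fem].all() and not mats.rigid_flags[~fem].any()

    def test_phantom_moduli_within_reported_envelope(self, knee_mesh):
        mesh, mats = knee_mesh
        bone = ~mesh.domain_mask("soft_tissue") & ~mats.rigid_flags
        assert mats.E[bone].min() >= 1.0
        assert mats.E[bone].max() <= 26_000.0

    def test_permutation_invariance_of_mapping(self, image_chain):
        mesh = build_mesh(image_chain["seg_r"], image_chain["cal_r"], element_size=5.0)
        mats = map_materials(mesh, image_chain["cal_r"])
        rng = np.random.default_rng(0)
        perm = rng.permutation(mesh.n_elements)
        import copy

        mesh2 = copy.deepcopy(mesh)
        mesh2.elements = mesh2.elements[perm]
        mesh2.element_domain = mesh2.element_domain[perm]
        mesh2.cell_index = mesh2.cell_index[perm]
        mats2 = map_materials(mesh2, image_chain["cal_r"])
        assert np.allclose(mats2.E, mats.E[perm])

    def test_uncalibrated_volume_rejected(self, knee_mesh):
        mesh, _ = knee_mesh
        raw = DensityVolume(np.zeros((5, 5, 5)), units="HU")
        with pytest.raises(ValueError, match="calibrated"):
            map_materials(mesh, raw)


class TestExporters:
    def test_vtk_writer_roundtrippable_text(self, tmp_path, knee_mesh):
        mesh, mats = knee_mesh
        path = tmp_path / "mesh.vtk"
        write_vtk(mesh, str(path), cell_data={"E": mats.E})
        text = path.read_text()
        assert "UNSTRUCTURED_GRID" in text
        assert f"POINTS {mesh.n_nodes}" in text
        assert "SCALARS E float" in text

    def test_inp_writer_emits_elements_and_sections(self, tmp_path, image_chain):
        mesh = build_mesh(image_chain["seg_r"], image_chain["cal_r"],
                          element_size=6.0, mode="tet_quadratic")
        mats = map_materials(mesh, image_chain["cal_r"])
        path = tmp_path / "model.inp"
        write_inp(mesh, mats, str(path), n_bins=10)
        text = path.read_text()
        assert "TYPE=C3D10" in text
        assert "*SOLID SECTION" in text
        assert "*NSET, NSET=FEMUR_TOP" in text
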