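"""Region partition, aggregation and compartmental stiffness."""

import numpy as np
import pandas as pd
import pytest

from tibiamech import meshmat, regions, solver
from tibiamech.imageproc import SegmentationMask
from tibiamech.regions import (
    REGION_CODES,
    REGION_NAMES,
    aggregate,
    assign_regions,
    compartment_stiffness,
    derive_region_inputs,
    voxel_region_codes,
)
from tibiamech.solver import FieldResult
from tibiamech.volume import MG_CM3, DensityVolume


def _slab_inputs(depth_vox=80, width=80, voxel=0.5):
    """Flat half-space 'tibia': top surface at the top, walls far away."""
    labels = np.zeros((width, width, depth_vox + 4), dtype=np.int16)
    labels[:, :, : depth_vox] = 1
    vol = DensityVolume(np.zeros(labels.shape), spacing=(voxel,) * 3, units=MG_CM3)
    mask = SegmentationMask(labels=labels, threshold_used=0.0)
    return derive_region_inputs(mask, vol), vol


class TestRegionAssignment:
    def test_slab_band_volumes_proportional_to_thicknesses(self):
        """On a flat half-space the four depth bands tile 2.5/2.5/10/20 mm."""
        inputs, vol = _slab_inputs()
        codes = voxel_region_codes(inputs)
        # central columns only (periphery belongs to wall regions)
        core = codes[30:50, 30:50, :]
        # band thickness ratios 2.5 : 2.5 : 10 : 20 within the core
        band_counts = []
        for code_set, lo, hi in (
            ("subchondral cortical", 0.0, 2.5),
            ("subchondral trabecular", 2.5, 5.0),
            ("epiphyseal trabecular", 5.0, 15.0),
            ("metaphyseal trabecular", 15.0, 35.0),
        ):
            n = 0
            for name, code in REGION_CODES.items():
                if code_set in name.lower():
                    n += (core == code).sum()
            band_counts.append(n)
        ratios = np.array(band_counts, dtype=float) / band_counts[0]
        assert ratios == pytest.approx([1.0, 1.0, 4.0, 8.0], rel=0.21)
        assert band_counts[0] > 0

    def test_depth_bands_contiguous_and_exhaustive_to_35mm(self):
        inputs, vol = _slab_inputs()
        codes = voxel_region_codes(inputs)
        core = codes[15:25, 15:25, :]
        dt = inputs.dt_top[15:25, 15:25, :]
        tib = inputs.tibia_mask[15:25, 15:25, :]
        assigned = core > 0
        within = tib & (dt <= 35.0 + 1e-9)
        assert (assigned == within).all()

    def test_band_boundaries_half_open(self):
        # depth exactly 0 -> subchondral band; exactly 2.5 -> trabecular band
        from tibiamech.regions import _band

        assert _band(np.array([0.0]))[0] == 0
        assert _band(np.array([2.5]))[0] == 1
        assert _band(np.array([5.0]))[0] == 2
        assert _band(np.array([15.0]))[0] == 3
        assert _band(np.array([35.0]))[0] == 3
        assert _band(np.array([35.1]))[0] == -1

    def test_all_17_regions_present_on_phantom(self, region_inputs):
        codes = voxel_region_codes(region_inputs)
        present = {REGION_NAMES[c - 1] for c in np.unique(codes) if c > 0}
        assert present == set(REGION_NAMES)

    def test_region_volumes_sum_to_assigned_volume(self, knee_mesh, region_inputs):
        mesh, _ = knee_mesh
        regmap = assign_regions(mesh, region_inputs)
        vols = mesh.element_volumes()
        assigned = regmap.region_of_element > 0
        res = _fake_result(mesh)
        df = aggregate(res, regmap, vols)
        assert df["region_volume"].sum() == pytest.approx(vols[assigned].sum())
        assert df["element_count"].sum() == assigned.sum()

    def test_missing_tibia_rejected(self):
        labels = np.zeros((10, 10, 10), dtype=np.int16)
        vol = DensityVolume(np.zeros(labels.shape), units=MG_CM3)
        with pytest.raises(ValueError, match="tibia"):
            derive_region_inputs(SegmentationMask(labels=labels, threshold_used=0.0), vol)


def _fake_result(mesh, value=None):
    m = mesh.n_elements
    vals = np.full(m, 1.0) if value is None else value
    zero = np.zeros((m, 3, 3))
    return FieldResult(
        stress_tensor=zero,
        strain_tensor=zero,
        min_principal_stress=vals,
        von_mises_stress=vals,
        min_principal_strain=vals,
        von_mises_strain=vals,
        reaction_force=1.0,
        scale_factor=1.0,
        displacement=np.zeros((mesh.n_nodes, 3)),
    )


class TestAggregate:
    def test_constant_field_every_region_mean_is_constant(self, knee_mesh, region_inputs):
        mesh, _ = knee_mesh
        regmap = assign_regions(mesh, region_inputs)
        df = aggregate(_fake_result(mesh, np.full(mesh.n_elements, 3.25)),
                       regmap, mesh.element_volumes())
        for metric in FieldResult.METRICS:
            assert np.allclose(df[metric], 3.25)

    def test_hand_computed_volume_weighted_mean(self):
        """Four elements split over two regions with hand-set volumes."""
        from tibiamech.regions import RegionMap

        mesh_like = type("M", (), {})()
        codes = np.array([1, 1, 2, 2], dtype=np.int16)
        regmap = RegionMap(region_of_element=codes, depth_of_element=np.zeros(4))
        vols = np.array([1.0, 3.0, 2.0, 2.0])
        vals = np.array([10.0, 20.0, 5.0, 15.0])
        res = FieldResult(
            stress_tensor=np.zeros((4, 3, 3)), strain_tensor=np.zeros((4, 3, 3)),
            min_principal_stress=vals, von_mises_stress=vals,
            min_principal_strain=vals, von_mises_strain=vals,
            reaction_force=1.0, scale_factor=1.0, displacement=np.zeros((1, 3)),
        )
        df = aggregate(res, regmap, vols)
        r1 = REGION_NAMES[0]  # code 1
        r2 = REGION_NAMES[1]  # code 2
        assert df.loc[r1, "min_principal_stress"] == pytest.approx((10 + 3 * 20) / 4)
        assert df.loc[r2, "min_principal_stress"] == pytest.approx((2 * 5 + 2 * 15) / 4)
        # mean lies within [min, max] of contributing elements
        assert 10 <= df.loc[r1, "min_principal_stress"] <= 20

    def test_permutation_invariance(self, knee_mesh, region_inputs):
        mesh, _ = knee_mesh
        regmap = assign_regions(mesh, region_inputs)
        vols = mesh.element_volumes()
        rng = np.random.default_rng(3)
        vals = rng.normal(size=mesh.n_elements)
        df1 = aggregate(_fake_result(mesh, vals), regmap, vols)
        perm = rng.permutation(mesh.n_elements)
        from tibiamech.regions import RegionMap

        regmap2 = RegionMap(region_of_element=regmap.region_of_element[perm],
                            depth_of_element=regmap.depth_of_element[perm])
        df2 = aggregate(_fake_result(mesh, vals[perm]), regmap2, vols[perm])
        pd.testing.assert_frame_equal(df1, df2)

    def test_mismatched_lengths_rejected(self, knee_mesh, region_inputs):
        mesh, _ = knee_mesh
        regmap = assign_regions(mesh, region_inputs)
        with pytest.raises(ValueError, match="share"):
            aggregate(_fake_result(mesh), regmap, np.ones(3))


class TestCompartmentStiffness:
    def test_homogeneous_symmetric_model_medial_close_to_lateral(self):
        # exactly mirror-symmetric homogeneous "joint": two blocks bridged
        # by the soft cylinder
        labels = np.zeros((30, 30, 44), dtype=np.int16)
        labels[3:27, 3:27, 2:16] = 1  # tibia block
        labels[3:27, 3:27, 24:38] = 2  # femur block
        vol = DensityVolume(np.where(labels > 0, 400.0, 0.0),
                            spacing=(1.0, 1.0, 1.0), units=MG_CM3)
        seg = SegmentationMask(labels=labels, threshold_used=200.0)
        mesh = meshmat.build_mesh(seg, vol, element_size=2.0,
                                  femur_extent=None, tibia_extent=None)
        mats = meshmat.map_materials(mesh, vol)
        load = solver.LoadCase.from_body_mass(72.0)
        k_med = compartment_stiffness(mesh, mats, load, "medial")
        k_lat = compartment_stiffness(mesh, mats, load, "lateral")
        assert k_med > 0 and k_lat > 0
        assert abs(k_med - k_lat) / k_lat < 0.05

    def test_doubling_bone_modulus_doubles_stiffness(self, knee_mesh):
        mesh, mats = knee_mesh
        load = solver.LoadCase.from_body_mass(72.0)
        k1 = compartment_stiffness(mesh, mats, load, "medial")
        mats2 = meshmat.MaterialField(
            E=mats.E * 2, nu=mats.nu.copy(), rho=mats.rho, rigid_flags=mats.rigid_flags
        )
        # the softened opposite compartment must scale too for pure linearity
        k2 = compartment_stiffness(mesh, mats2, load, "medial", e_soft=20.0)
        assert k2 == pytest.approx(2 * k1, rel=1e-6)

    def test_invalid_side_rejected(self, knee_mesh):
        mesh, mats = knee_mesh
        with pytest.raises(ValueError, match="side"):
            compartment_stiffness(mesh, mats, solver.LoadCase(), "anterior")
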