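"""Calibration, HMH thresholding, segmentation, axes and re-alignment."""

import numpy as np
import pytest

from tibiamech import imageproc
from tibiamech.imageproc import (
    SegmentationMask,
    calibrate,
    fit_bone_axes,
    hmh_threshold,
    realign,
    realignment_rotation,
    rotation_between,
    segment_bones,
)
from tibiamech.volume import HU, MG_CM3, DensityVolume


def _flat_volume(shape=(20, 20, 20), value=0.0, units=HU):
    return DensityVolume(np.full(shape, value, dtype=float), spacing=(1, 1, 1), units=units)


# ---------------------------------------------------------------------------
# calibration
# ---------------------------------------------------------------------------

class TestCalibrate:
    def _two_rod_volume(self):
        vol = _flat_volume(value=500.0)
        r1 = np.zeros(vol.shape, bool)
        r2 = np.zeros(vol.shape, bool)
        r1[2:6, 2:6, :] = True
        r2[10:14, 10:14, :] = True
        vol.data[r1] = 0.0
        vol.data[r2] = 1000.0
        return vol, [r1, r2]

    def test_two_point_line_is_exact(self):
        vol, rods = self._two_rod_volume()
        cal, model = calibrate(vol, rods, [0.0, 400.0], erode_rods=0)
        assert model.slope == pytest.approx(0.4)
        assert model.intercept == pytest.approx(0.0, abs=1e-9)
        # the 500 HU background voxel maps to 200 mg/cm3
        assert cal.data[0, 0, 0] == pytest.approx(200.0)
        assert cal.units == MG_CM3

    def test_three_noiseless_rods_r_squared_one(self):
        vol = _flat_volume()
        rods, dens = [], [0.0, 200.0, 400.0]
        for i, (x, hu) in enumerate(zip((2, 8, 14), (0.0, 500.0, 1000.0))):
            r = np.zeros(vol.shape, bool)
            r[x : x + 3, 2:5, :] = True
            vol.data[r] = hu
            rods.append(r)
        _, model = calibrate(vol, rods, dens, erode_rods=0)
        assert model.r_squared == pytest.approx(1.0)

    def test_noisy_rods_recover_generative_slope(self):
        rng = np.random.default_rng(0)
        vol, rods = self._two_rod_volume()
        vol.data += rng.normal(0, 5.0, vol.shape)
        _, model = calibrate(vol, rods, [0.0, 400.0], erode_rods=0)
        assert model.slope == pytest.approx(0.4, rel=0.05)

    def test_identical_rod_means_rejected(self):
        vol, rods = self._two_rod_volume()
        vol.data[rods[1]] = 0.0
        with pytest.raises(ValueError, match="singular"):
            calibrate(vol, rods, [0.0, 400.0], erode_rods=0)

    def test_already_calibrated_rejected(self):
        vol, rods = self._two_rod_volume()
        cal, _ = calibrate(vol, rods, [0.0, 400.0], erode_rods=0)
        with pytest.raises(ValueError, match="already calibrated"):
            calibrate(cal, rods, [0.0, 400.0])

    def test_calibrate_then_invert_is_identity(self):
        vol, rods = self._two_rod_volume()
        cal, model = calibrate(vol, rods, [0.0, 400.0], erode_rods=0)
        back = model.invert(cal.data)
        assert np.allclose(back, vol.data, rtol=1e-9, atol=1e-9)


# ---------------------------------------------------------------------------
# HMH threshold
# ---------------------------------------------------------------------------

class TestHMH:
    @pytest.mark.parametrize("bg,peak,expected", [(0.0, 1000.0, 500.0), (20.0, 820.0, 420.0)])
    def test_midpoint(self, bg, peak, expected):
        vol = _flat_volume()
        pr = np.zeros(vol.shape, bool)
        br = np.zeros(vol.shape, bool)
        pr[:5], br[10:] = True, True
        vol.data[pr], vol.data[br] = peak, bg
        assert hmh_threshold(vol, pr, br) == pytest.approx(expected)

    def test_affine_intensity_rescale_invariance(self):
        vol = _flat_volume()
        pr = np.zeros(vol.shape, bool)
        br = np.zeros(vol.shape, bool)
        pr[:5], br[10:] = True, True
        vol.data[pr], vol.data[br] = 800.0, 20.0
        t1 = hmh_threshold(vol, pr, br)
        vol2 = vol.with_data(3.0 * vol.data + 100.0)
        t2 = hmh_threshold(vol2, pr, br)
        assert t2 == pytest.approx(3.0 * t1 + 100.0)

    def test_ramp_edge_localized_at_half_maximum(self):
        """On a linear edge ramp the HMH threshold crosses at the 50% voxel."""
        n = 41
        data = np.zeros((n, 5, 5))
        bg_level, peak_level = 10.0, 810.0
        ramp = np.linspace(bg_level, peak_level, 11)
        data[:15] = bg_level
        data[15:26] = ramp[:, None, None]
        data[26:] = peak_level
        vol = DensityVolume(data, units=MG_CM3)
        pr = np.zeros(data.shape, bool)
        br = np.zeros(data.shape, bool)
        pr[30:], br[:10] = True, True
        thr = hmh_threshold(vol, pr, br)
        crossing = np.argmax(data[:, 2, 2] >= thr)
        # 50% crossing of the ramp is at its midpoint
        assert crossing == pytest.approx(15 + 5, abs=1)

    def test_peak_below_background_rejected(self):
        vol = _flat_volume()
        pr = np.zeros(vol.shape, bool)
        br = np.zeros(vol.shape, bool)
        pr[:5], br[10:] = True, True
        vol.data[pr], vol.data[br] = 10.0, 500.0
        with pytest.raises(ValueError, match="exceed"):
            hmh_threshold(vol, pr, br)


# ---------------------------------------------------------------------------
# segmentation
# ---------------------------------------------------------------------------

class TestSegmentation:
    def test_threshold_above_max_rejected(self):
        vol = _flat_volume(value=100.0, units=MG_CM3)
        with pytest.raises(ValueError, match="threshold"):
            segment_bones(vol, 1e9, {"tibia": (0, 0, 0)})

    def test_seed_in_background_rejected(self):
        vol = _flat_volume(value=0.0, units=MG_CM3)
        vol.data[5:10, 5:10, 5:10] = 900.0
        with pytest.raises(ValueError, match="background"):
            segment_bones(vol, 400.0, {"tibia": (0, 0, 0)})

    def test_interior_holes_retained_in_bone_mask(self):
        vol = _flat_volume(value=0.0, units=MG_CM3)
        vol.data[4:16, 4:16, 4:16] = 900.0
        vol.data[8:12, 8:12, 8:12] = 100.0  # trabecular interior below threshold
        seg = segment_bones(vol, 400.0, {"tibia": (5, 5, 5)})
        assert seg.mask("tibia")[9, 9, 9]

    def test_phantom_dice_against_ground_truth(self, image_chain, neutral_phantom):
        _, _, truth = neutral_phantom
        seg = image_chain["seg"]
        for name, code in (("tibia", 1), ("femur", 2), ("fibula", 3)):
            gt = truth.labels == code
            m = seg.mask(name)
            dice = 2 * (gt & m).sum() / (gt.sum() + m.sum())
            assert dice >= 0.95, f"{name} Dice {dice:.3f}"


# ---------------------------------------------------------------------------
# axes and re-alignment
# ---------------------------------------------------------------------------

def _cylinder_mask_volume(rotation_deg=0.0):
    """Two stacked cylinders (a 'tibia' below and a 'femur' above)."""
    n = 110
    v = 1.2
    coords = (np.arange(n) - n / 2) * v
    X, Y, Z = np.meshgrid(coords, coords, coords, indexing="ij", sparse=True)
    t = np.radians(rotation_deg)
    # rotate about y
    Xr = np.cos(t) * X + np.sin(t) * Z
    Zr = -np.sin(t) * X + np.cos(t) * Z
    r2 = Xr**2 + Y**2
    labels = np.zeros((n, n, n), dtype=np.int16)
    labels[(r2 <= 14**2) & (Zr >= -58) & (Zr <= -8)] = 1
    labels[(r2 <= 14**2) & (Zr >= 4) & (Zr <= 60)] = 2
    vol = DensityVolume(np.zeros((n, n, n)), spacing=(v, v, v),
                        origin=(coords[0],) * 3, units=MG_CM3)
    return SegmentationMask(labels=labels, threshold_used=0.0), vol


class TestAxes:
    def test_vertical_cylinder_axis_is_vertical(self):
        seg, vol = _cylinder_mask_volume(0.0)
        axis_f, axis_t = fit_bone_axes(seg, vol)
        assert abs(axis_t[2]) == pytest.approx(1.0, abs=1e-6)

    def test_rotated_cylinder_axis_recovered(self):
        seg, vol = _cylinder_mask_volume(10.0)
        axis_f, _ = fit_bone_axes(seg, vol)
        angle = np.degrees(np.arccos(np.clip(abs(axis_f[2]), -1, 1)))
        assert angle == pytest.approx(10.0, abs=0.5)

    def test_phantom_axes_within_one_degree(self, image_chain, neutral_phantom):
        _, _, truth = neutral_phantom
        axis_f, axis_t = image_chain["axes"]

        def err(a, b):
            return np.degrees(np.arccos(np.clip(abs(np.dot(a, b)), -1, 1)))

        assert err(axis_f, truth.axis_femur) < 1.0
        assert err(axis_t, truth.axis_tibia) < 1.0


class TestRealign:
    @pytest.mark.parametrize("inter_axis,expected", [(175.0, 2.5), (180.0, 0.0), (170.0, 5.0)])
    def test_axis_average_rule_halves_the_supplement(self, inter_axis, expected):
        d = np.radians(180.0 - inter_axis)
        axis_t = np.array([0.0, 0.0, 1.0])
        axis_f = np.array([np.sin(d), 0.0, np.cos(d)])
        R = realignment_rotation(axis_f, axis_t)
        for a in (axis_f, axis_t):
            v = R @ a
            angle = np.degrees(np.arccos(np.clip(v[2], -1, 1)))
            assert angle == pytest.approx(expected, abs=1e-9)
        assert np.linalg.det(R) == pytest.approx(1.0, abs=1e-9)

    def test_antiparallel_axes_rejected(self):
        with pytest.raises(ValueError, match="ntiparallel"):
            realignment_rotation(np.array([0.0, 0, 1]), np.array([0.0, 0, -1]))

    def test_rotation_between_maps_a_to_b(self):
        rng = np.random.default_rng(4)
        for _ in range(5):
            a = rng.normal(size=3)
            b = rng.normal(size=3)
            a, b = a / np.linalg.norm(a), b / np.linalg.norm(b)
            R = rotation_between(a, b)
            assert np.allclose(R @ a, b, atol=1e-12)
            assert np.linalg.det(R) == pytest.approx(1.0, abs=1e-9)

    def test_realign_image_chain(self, image_chain, neutral_phantom):
        align = image_chain["align"]
        # both axes make the same angle with vertical (1e-6 deg contract)
        assert align.angle_femur_vertical == pytest.approx(
            align.angle_tibia_vertical, abs=1e-6
        )
        # label counts preserved within 2% by resampling
        seg, seg_r = image_chain["seg"], image_chain["seg_r"]
        for name in ("tibia", "femur", "fibula"):
            n0, n1 = seg.mask(name).sum(), seg_r.mask(name).sum()
            assert abs(n1 - n0) / n0 < 0.02
        # inter-axis angle preserved within 0.5 degrees
        f, t = align.axis_femur, align.axis_tibia
        angle = 180.0 - np.degrees(np.arccos(np.clip(np.dot(f, t), -1, 1)))
        f0, t0 = image_chain["axes"]
        angle0 = 180.0 - np.degrees(np.arccos(np.clip(np.dot(f0, t0), -1, 1)))
        assert angle == pytest.approx(angle0, abs=0.5)
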