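"""Synthetic calibrated knee phantom.

Generates a parametric proximal-tibia + distal-femur + fibula volume with a
cortical shell, spatially smooth trabecular density, an in-image multi-rod
calibration phantom, and repeat "scans" under rigid repositioning plus
intensity noise.  The phantom emulates the acquisition conditions of an
in vivo knee QCT precision study (supine scans, 0.625 mm isotropic voxels,
a solid calibration phantom under the limb, OA vs normal cohorts with
different body mass, slight varus alignment and elevated medial density)
so that every downstream stage — calibration, segmentation, re-alignment,
meshing, solving, regional analysis, statistics — is testable without any
patient data.

Geometry is built from implicit primitives (superellipsoid cross-sections,
condylar lobes, an intercondylar spine bump), not an anatomical atlas.  All
randomness flows from a single integer seed; the same spec reproduces a
bit-identical volume.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .volume import HU, DensityVolume

__all__ = [
    "PhantomSpec",
    "RepeatNoiseSpec",
    "GroundTruth",
    "RepeatScan",
    "generate_knee_phantom",
    "generate_repeat_scans",
    "draw_cohort",
]

# Generative HU <-> BMD calibration (mg/cm3 K2HPO4 = SLOPE * HU + INTERCEPT).
GEN_SLOPE = 0.75
GEN_INTERCEPT = 0.0

# Tissue densities, mg/cm3 K2HPO4-equivalent.
CORTICAL_DENSITY = 850.0
CORTICAL_THICKNESS = 3.0  # mm
SOFT_TISSUE_HU = 30.0
PAD_HU = 0.0
AIR_HU = -1000.0

# Label codes in the ground-truth label volume.
LABEL_BG = 0
LABEL_TIBIA = 1
LABEL_FEMUR = 2
LABEL_FIBULA = 3
LABEL_ROD_BASE = 10  # rod i -> LABEL_ROD_BASE + i

# Default cohort parameters: body mass 101 +/- 16 kg (OA) vs 72 +/- 13 kg
# (normal); OA knees slightly varus with mildly elevated medial density.
COHORT_DEFAULTS = {
    "OA": {"mass_mean": 101.0, "mass_sd": 16.0, "varus_angle": 175.0, "density_scale": 1.15},
    "normal": {"mass_mean": 72.0, "mass_sd": 13.0, "varus_angle": 180.0, "density_scale": 1.0},
}


@dataclass
class PhantomSpec:
    """Parameters of one synthetic knee.

    varus_angle is the femoral-tibial inter-axis angle in degrees with both
    axes oriented superiorly; 180 is neutral, values below 180 are varus.
    """

    group: str = "normal"
    body_mass: float = 72.0  # kg
    varus_angle: float = 180.0  # degrees
    density_scale: float = 1.0  # multiplier on the medial tibial density template
    voxel_size: float = 0.625  # mm, isotropic
    side: str = "right"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.group not in ("OA", "normal"):
            raise ValueError(f"group must be 'OA' or 'normal', got {self.group!r}")
        if self.body_mass <= 0:
            raise ValueError("body_mass must be positive")
        if not 150.0 <= self.varus_angle <= 210.0:
            raise ValueError("varus_angle must be within [150, 210] degrees")
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be positive")
        if self.voxel_size > CORTICAL_THICKNESS / 2.0:
            raise ValueError(
                f"voxel_size {self.voxel_size} mm cannot resolve the "
                f"{CORTICAL_THICKNESS} mm cortical shell (< 2 voxels across)"
            )
        if self.side not in ("left", "right"):
            raise ValueError("side must be 'left' or 'right'")


@dataclass
class RepeatNoiseSpec:
    """Repositioning + intensity noise model for repeat scans."""

    translation_sd: float = 1.0  # mm, per axis
    rotation_sd: float = 1.0  # degrees, per axis
    intensity_sd: float = 10.0  # HU, additive white noise
    n_repeats: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.translation_sd, self.rotation_sd, self.intensity_sd) < 0:
            raise ValueError("noise SDs must be >= 0")
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")


@dataclass
class GroundTruth:
    """Generative ground truth saved alongside a phantom volume."""

    labels: np.ndarray  # integer label volume (bones + rods)
    axis_femur: np.ndarray  # unit vector, superior-pointing
    axis_tibia: np.ndarray
    rod_densities: list  # nominal mg/cm3 per rod
    calibration_slope: float = GEN_SLOPE
    calibration_intercept: float = GEN_INTERCEPT
    plateau_z: float = 0.0  # mean tibial plateau surface height, world mm
    spine_center_x: float = 0.0
    condylar_half_width: float = 0.0  # max ML half-extent of the condyles, mm

    def mask(self, label: int) -> np.ndarray:
        return self.labels == label

    @property
    def tibia_mask(self) -> np.ndarray:
        return self.mask(LABEL_TIBIA)

    @property
    def femur_mask(self) -> np.ndarray:
        return self.mask(LABEL_FEMUR)

    @property
    def fibula_mask(self) -> np.ndarray:
        return self.mask(LABEL_FIBULA)

    def rod_masks(self) -> list:
        return [self.mask(LABEL_ROD_BASE + i) for i in range(len(self.rod_densities))]

    def inter_axis_angle(self) -> float:
        """Femoral-tibial inter-axis angle in degrees (180 = parallel axes)."""
        c = float(np.clip(np.dot(self.axis_femur, self.axis_tibia), -1.0, 1.0))
        return 180.0 - np.degrees(np.arccos(c))


@dataclass
class RepeatScan:
    """One repeat acquisition: the resampled volume plus the applied transform."""

    volume: DensityVolume
    labels: np.ndarray  # ground-truth labels carried through the same transform
    rotation_deg: np.ndarray  # (3,) applied rotations about x, y, z
    translation_mm: np.ndarray  # (3,)


# ---------------------------------------------------------------------------
# geometry template (world mm, right knee, +x medial, +z superior,
# origin at the femorotibial gap center)
# ---------------------------------------------------------------------------

_PLATEAU_Z = -4.0  # base tibial plateau surface height
_TIBIA_DISTAL_Z = -92.0
_PLATEAU_A, _PLATEAU_B = 36.0, 24.0  # ML / AP half-widths at the plateau
_SHAFT_A, _SHAFT_B = 14.0, 12.0
_FLARE_LENGTH = 16.0  # metaphyseal flare decay, mm
_CONDYLE_X = 18.0  # tibial condyle dish centers, +/- x
_SPINE_HEIGHT = 5.0
_FEMUR_CONDYLE_X = 17.0
_FEMUR_CONDYLE_CENTER = np.array([0.0, -2.0, 18.0])
_FEMUR_CONDYLE_SEMI = np.array([15.0, 21.0, 13.0])
_FEMUR_SHAFT_A, _FEMUR_SHAFT_B = 17.0, 15.0
_FEMUR_SHAFT_Z = (23.0, 69.0)
_FIBULA_CENTER = (-30.0, -14.0)
_FIBULA_R = 6.0
_FIBULA_Z = (-88.0, -26.0)
_LIMB_A, _LIMB_B = 50.0, 42.0  # soft-tissue envelope half-widths
_LIMB_CENTER_Y = -4.0
_PAD_X, _PAD_Y = (-38.0, 38.0), (-74.0, -50.0)
_ROD_Y = -62.0
_ROD_XS = (-24.0, 0.0, 24.0)
_ROD_R = 5.0
DEFAULT_ROD_DENSITIES = (0.0, 200.0, 400.0)

_EXTENT = {
    "x": (-58.0, 58.0),
    "y": (-78.0, 46.0),
    "z": (-96.0, 73.0),
}


def _tibia_top_surface(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Plateau surface height z_top(x, y): two shallow dishes + spine bump."""
    dish = -1.5 * np.exp(-(((x - _CONDYLE_X) ** 2 + y**2)) / 18.0**2)
    dish += -1.5 * np.exp(-(((x + _CONDYLE_X) ** 2 + y**2)) / 18.0**2)
    spine = _SPINE_HEIGHT * np.exp(-((x / 7.0) ** 2) - (y / 16.0) ** 2)
    return _PLATEAU_Z + dish + spine


def _superellipse(dx, dy, a, b, n=2.5):
    return (np.abs(dx) / a) ** n + (np.abs(dy) / b) ** n


def _tibia_mask(X, Y, Z):
    z_top = _tibia_top_surface(X, Y)
    depth = np.maximum(0.0, _PLATEAU_Z - Z)
    a = _SHAFT_A + (_PLATEAU_A - _SHAFT_A) * np.exp(-depth / _FLARE_LENGTH)
    b = _SHAFT_B + (_PLATEAU_B - _SHAFT_B) * np.exp(-depth / _FLARE_LENGTH)
    inside = _superellipse(X, Y, a, b) <= 1.0
    return inside & (Z <= z_top) & (Z >= _TIBIA_DISTAL_Z)


def _femur_mask(X, Y, Z, tilt_deg: float):
    """Distal femur tilted by tilt_deg about +y around the origin.

    A positive tilt leans the femoral shaft medially (+x), which lowers the
    medial condyle and narrows the medial joint space — the varus loading
    pattern.
    """
    t = np.radians(tilt_deg)
    ct, st = np.cos(t), np.sin(t)
    # rotate world coords into the femur's local (untilted) frame: q = R_y(t)^T p
    xl = ct * X - st * Z
    zl = st * X + ct * Z
    yl = Y
    m = np.zeros(np.broadcast_shapes(X.shape, Y.shape, Z.shape), dtype=bool)
    for sx in (+1.0, -1.0):
        c = _FEMUR_CONDYLE_CENTER + np.array([sx * _FEMUR_CONDYLE_X, 0, 0])
        s = _FEMUR_CONDYLE_SEMI
        m |= ((xl - c[0]) / s[0]) ** 2 + ((yl - c[1]) / s[1]) ** 2 + ((zl - c[2]) / s[2]) ** 2 <= 1.0
    shaft = (_superellipse(xl, yl - _FEMUR_CONDYLE_CENTER[1], _FEMUR_SHAFT_A, _FEMUR_SHAFT_B, 2.0) <= 1.0) & (
        zl >= _FEMUR_SHAFT_Z[0] - 4.0
    ) & (zl <= _FEMUR_SHAFT_Z[1])
    return m | shaft


def _fibula_mask(X, Y, Z):
    r2 = (X - _FIBULA_CENTER[0]) ** 2 + (Y - _FIBULA_CENTER[1]) ** 2
    body = (r2 <= _FIBULA_R**2) & (Z >= _FIBULA_Z[0]) & (Z <= _FIBULA_Z[1] - _FIBULA_R)
    cap = r2 + (Z - (_FIBULA_Z[1] - _FIBULA_R)) ** 2 <= _FIBULA_R**2
    return body | (cap & (Z > _FIBULA_Z[1] - _FIBULA_R))


def _trabecular_density(depth_below_plateau: np.ndarray) -> np.ndarray:
    """Smooth trabecular BMD template: densest under the plateau, lighter in the shaft."""
    return 120.0 + 110.0 * np.exp(-np.maximum(depth_below_plateau, 0.0) / 25.0)


def generate_knee_phantom(spec: PhantomSpec) -> tuple[DensityVolume, GroundTruth]:
    """Rasterize one synthetic knee in HU with in-image calibration rods.

    Returns the raw (uncalibrated) volume and the generative ground truth:
    bone label masks, rod masks with nominal densities, and the femoral and
    tibial long axes realizing ``spec.varus_angle``.
    """
    v = spec.voxel_size
    rng = np.random.default_rng(spec.seed)

    xs = np.arange(_EXTENT["x"][0], _EXTENT["x"][1] + v / 2, v)
    ys = np.arange(_EXTENT["y"][0], _EXTENT["y"][1] + v / 2, v)
    zs = np.arange(_EXTENT["z"][0], _EXTENT["z"][1] + v / 2, v)
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij", sparse=True)

    tilt = 180.0 - spec.varus_angle  # femoral tilt toward lateral, degrees
    tibia = _tibia_mask(X, Y, Z)
    femur = _femur_mask(X, Y, Z, tilt)
    fibula = _fibula_mask(X, Y, Z)
    femur &= ~tibia  # disjoint by construction (gap), but guard anyway
    fibula &= ~(tibia | femur)

    labels = np.zeros(tibia.shape, dtype=np.int16)
    labels[tibia] = LABEL_TIBIA
    labels[femur] = LABEL_FEMUR
    labels[fibula] = LABEL_FIBULA

    # ---- density synthesis (bones) --------------------------------------
    bone = tibia | femur | fibula
    spacing = (v, v, v)
    density = np.zeros(bone.shape, dtype=np.float32)

    depth_below_plateau = np.maximum(0.0, _PLATEAU_Z - Z)
    trab = _trabecular_density(depth_below_plateau)
    density[tibia] = np.broadcast_to(trab, bone.shape)[tibia]
    density[femur] = 200.0
    density[fibula] = 250.0

    # medial density elevation (OA template): smooth sigmoid blend across x=0
    if spec.density_scale != 1.0:
        medial_w = 1.0 / (1.0 + np.exp(-X / 5.0))
        scale = 1.0 + (spec.density_scale - 1.0) * medial_w
        density[tibia] *= np.broadcast_to(scale, bone.shape)[tibia]

    # cortical shell: within CORTICAL_THICKNESS of the bone surface, blended
    # over 1 mm so the field stays smooth
    dist = ndimage.distance_transform_edt(bone, sampling=spacing)
    w = np.clip((CORTICAL_THICKNESS - dist) / 1.0, 0.0, 1.0).astype(np.float32)
    cort = CORTICAL_DENSITY * np.ones_like(density)
    if spec.density_scale != 1.0:
        cort *= np.broadcast_to(scale, bone.shape).astype(np.float32)
    density = np.where(bone, w * cort + (1.0 - w) * density, 0.0)

    # smooth biological heterogeneity: band-limited noise, sd ~15 mg/cm3
    noise = rng.standard_normal(bone.shape).astype(np.float32)
    noise = ndimage.gaussian_filter(noise, sigma=2.0)
    noise *= 15.0 / max(noise.std(), 1e-9)
    density[bone] += noise[bone]

    # ---- compose the HU image -------------------------------------------
    hu = np.full(bone.shape, AIR_HU, dtype=np.float32)
    limb = _superellipse(X, Y - _LIMB_CENTER_Y, _LIMB_A, _LIMB_B, 2.0) <= 1.0
    hu[np.broadcast_to(limb, bone.shape)] = SOFT_TISSUE_HU
    pad = (
        (X >= _PAD_X[0]) & (X <= _PAD_X[1]) & (Y >= _PAD_Y[0]) & (Y <= _PAD_Y[1])
    )
    hu[np.broadcast_to(pad, bone.shape)] = PAD_HU
    rod_densities = list(DEFAULT_ROD_DENSITIES)
    for i, (rx, rho) in enumerate(zip(_ROD_XS, rod_densities)):
        rod = (X - rx) ** 2 + (Y - _ROD_Y) ** 2 <= _ROD_R**2
        rod = np.broadcast_to(rod, bone.shape) & ~bone
        labels[rod] = LABEL_ROD_BASE + i
        hu[rod] = (rho - GEN_INTERCEPT) / GEN_SLOPE
    hu[bone] = (density[bone] - GEN_INTERCEPT) / GEN_SLOPE

    if spec.side == "left":
        hu = hu[::-1].copy()
        labels = labels[::-1].copy()

    volume = DensityVolume(
        data=hu,
        spacing=(v, v, v),
        origin=(float(xs[0]), float(ys[0]), float(zs[0])),
        units=HU,
    )
    t = np.radians(tilt)
    axis_femur = np.array([np.sin(t), 0.0, np.cos(t)])
    axis_tibia = np.array([0.0, 0.0, 1.0])
    if spec.side == "left":
        axis_femur[0] *= -1
    truth = GroundTruth(
        labels=labels,
        axis_femur=axis_femur,
        axis_tibia=axis_tibia,
        rod_densities=rod_densities,
        plateau_z=_PLATEAU_Z,
        spine_center_x=0.0,
        condylar_half_width=max(_PLATEAU_A, _FEMUR_CONDYLE_X + _FEMUR_CONDYLE_SEMI[0]),
    )
    return volume, truth


# ---------------------------------------------------------------------------
# repeat scans
# ---------------------------------------------------------------------------

def _rigid_matrix(rotation_deg: np.ndarray) -> np.ndarray:
    rx, ry, rz = np.radians(rotation_deg)
    cx, sx = np.cos(rx), np.sin(rx)
    cy, sy = np.cos(ry), np.sin(ry)
    cz, sz = np.cos(rz), np.sin(rz)
    Rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    Ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    Rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    return Rz @ Ry @ Rx


def apply_rigid_transform(
    data: np.ndarray,
    spacing: tuple,
    rotation_deg: np.ndarray,
    translation_mm: np.ndarray,
    order: int = 1,
    cval: float = AIR_HU,
) -> np.ndarray:
    """Resample ``data`` under a rigid world-frame transform about the volume center."""
    R = _rigid_matrix(rotation_deg)
    S = np.diag(spacing)
    Sinv = np.diag(1.0 / np.asarray(spacing))
    center = (np.asarray(data.shape) - 1) / 2.0
    # output voxel i -> world -> inverse transform -> input voxel
    M = Sinv @ R.T @ S
    offset = center - M @ center - Sinv @ R.T @ np.asarray(translation_mm)
    return ndimage.affine_transform(
        data, M, offset=offset, order=order, cval=cval, mode="constant", prefilter=False
    )


def generate_repeat_scans(
    volume: DensityVolume, truth: GroundTruth, noise: RepeatNoiseSpec
) -> list[RepeatScan]:
    """Simulate repeat acquisitions: independent rigid repositioning + HU noise.

    Per-repeat RNG streams are derived from ``noise.seed`` by counter, so a
    fixed seed reproduces identical transforms across runs.  With all SDs
    zero the repeats are bit-identical to the source volume.
    """
    out = []
    for i in range(noise.n_repeats):
        rng = np.random.default_rng([int(noise.seed) % (2**31), i])
        rot = rng.normal(0.0, noise.rotation_sd, size=3)
        tra = rng.normal(0.0, noise.translation_sd, size=3)
        if noise.rotation_sd == 0 and noise.translation_sd == 0:
            data = volume.data.copy()
            labels = truth.labels.copy()
        else:
            data = apply_rigid_transform(
                volume.data.astype(np.float32), volume.spacing, rot, tra, order=1
            )
            labels = apply_rigid_transform(
                truth.labels.astype(np.float32), volume.spacing, rot, tra, order=0, cval=0
            ).astype(truth.labels.dtype)
        if noise.intensity_sd > 0:
            data = data + rng.normal(0.0, noise.intensity_sd, size=data.shape).astype(
                np.float32
            )
        out.append(
            RepeatScan(
                volume=volume.with_data(data),
                labels=labels,
                rotation_deg=rot,
                translation_mm=tra,
            )
        )
    return out


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

def draw_cohort(group: str, n: int, seed: int, voxel_size: float = 0.625) -> list[PhantomSpec]:
    """Draw ``n`` subject specs for one group.

    Body mass is sampled from the group's distribution (101 +/- 16 kg OA,
    72 +/- 13 kg normal); OA knees get a 175 degree varus template and a
    medial density elevation, normal knees are neutral.
    """
    params = COHORT_DEFAULTS[group]
    rng = np.random.default_rng([seed % (2**31), 0 if group == "normal" else 1])
    specs = []
    for i in range(n):
        mass = float(rng.normal(params["mass_mean"], params["mass_sd"]))
        mass = max(mass, 35.0)
        varus = float(params["varus_angle"] + rng.normal(0.0, 1.5))
        specs.append(
            PhantomSpec(
                group=group,
                body_mass=mass,
                varus_angle=varus,
                density_scale=params["density_scale"],
                voxel_size=voxel_size,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
        )
    return specs
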