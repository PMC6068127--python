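"""QCT image processing: calibration, segmentation, re-alignment.

Implements the image-analysis front end of the pipeline:

* linear HU -> BMD calibration against in-image reference rods,
* the half-maximum-height (HMH) bone threshold — the density of a voxel
  containing 50% cortical bone and 50% joint space,
* threshold segmentation into tibia / femur / fibula with interior-hole
  retention (trabecular voxels below threshold stay inside the bone mask),
* best-fit long-axis estimation from cross-section centroids, and
* rotation of the knee so the average of the femoral and tibial axes is
  vertical (each axis then makes half the supplement of the inter-axis
  angle with vertical, e.g. 175 degrees -> 2.5 degrees).
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .volume import HU, MG_CM3, DensityVolume

__all__ = [
    "CalibrationModel",
    "SegmentationMask",
    "AlignmentResult",
    "calibrate",
    "hmh_threshold",
    "auto_probe_regions",
    "segment_bones",
    "fit_bone_axes",
    "realign",
    "rotation_between",
]

BONE_NAMES = ("tibia", "femur", "fibula")
BONE_CODES = {"tibia": 1, "femur": 2, "fibula": 3}


@dataclass
class CalibrationModel:
    """Linear HU -> mg/cm3 calibration fitted to reference rods."""

    slope: float  # (mg/cm3) / HU
    intercept: float  # mg/cm3
    r_squared: float
    rod_samples: list  # (mean HU, nominal density) per rod

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValueError("calibration slope must be positive")
        if not 0.0 <= self.r_squared <= 1.0 + 1e-12:
            raise ValueError("r_squared must be within [0, 1]")

    def apply(self, hu: np.ndarray) -> np.ndarray:
        return self.slope * hu + self.intercept

    def invert(self, density: np.ndarray) -> np.ndarray:
        return (density - self.intercept) / self.slope

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "slope": self.slope,
                    "intercept": self.intercept,
                    "r_squared": self.r_squared,
                    "rod_samples": [list(map(float, s)) for s in self.rod_samples],
                },
                fh,
                indent=2,
            )


@dataclass
class SegmentationMask:
    """Bone label volume: 0 background, 1 tibia, 2 femur, 3 fibula."""

    labels: np.ndarray
    threshold_used: float  # mg/cm3
    provenance: str = ""

    def mask(self, name: str) -> np.ndarray:
        return self.labels == BONE_CODES[name]

    @property
    def bone(self) -> np.ndarray:
        return self.labels > 0


@dataclass
class AlignmentResult:
    axis_femur: np.ndarray
    axis_tibia: np.ndarray
    rotation: np.ndarray  # 3x3 proper rotation applied to the image
    angle_femur_vertical: float  # degrees, after rotation
    angle_tibia_vertical: float

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "axis_femur": self.axis_femur.tolist(),
                    "axis_tibia": self.axis_tibia.tolist(),
                    "rotation": self.rotation.tolist(),
                    "angle_femur_vertical": self.angle_femur_vertical,
                    "angle_tibia_vertical": self.angle_tibia_vertical,
                },
                fh,
                indent=2,
            )


# ---------------------------------------------------------------------------
# calibration
# ---------------------------------------------------------------------------

def calibrate(
    volume: DensityVolume,
    rod_regions: list,
    rod_densities: list,
    erode_rods: int = 1,
) -> tuple[DensityVolume, CalibrationModel]:
    """Fit nominal rod density on mean rod HU and convert the whole volume.

    ``rod_regions`` are boolean voxel masks, one per rod; they are eroded by
    ``erode_rods`` voxels to avoid partial-volume rims before averaging.
    """
    if volume.units != HU:
        raise ValueError("volume is already calibrated (units mg_cm3)")
    if len(rod_regions) < 2:
        raise ValueError("at least 2 calibration rods are required")
    if len(rod_regions) != len(rod_densities):
        raise ValueError("one nominal density per rod region is required")

    means = []
    for i, region in enumerate(rod_regions):
        region = np.asarray(region, dtype=bool)
        if erode_rods > 0:
            eroded = ndimage.binary_erosion(region, iterations=erode_rods)
            if eroded.any():
                region = eroded
        if not region.any():
            raise ValueError(f"rod region {i} is empty")
        means.append(float(volume.data[region].mean()))
    for i, region in enumerate(rod_regions):
        for j in range(i + 1, len(rod_regions)):
            if np.asarray(rod_regions[i]).__and__(np.asarray(rod_regions[j])).any():
                raise ValueError(f"rod regions {i} and {j} overlap")

    x = np.asarray(means, dtype=float)
    y = np.asarray(rod_densities, dtype=float)
    if np.ptp(x) < 1e-9:
        raise ValueError("rods have identical mean HU; calibration fit is singular")
    slope, intercept = np.polyfit(x, y, 1)
    yhat = slope * x + intercept
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else max(0.0, 1.0 - ss_res / ss_tot)
    model = CalibrationModel(
        slope=float(slope),
        intercept=float(intercept),
        r_squared=min(1.0, r2),
        rod_samples=list(zip(means, map(float, rod_densities))),
    )
    calibrated = volume.with_data(model.apply(volume.data.astype(np.float64)), units=MG_CM3)
    return calibrated, model


# ---------------------------------------------------------------------------
# HMH threshold
# ---------------------------------------------------------------------------

def hmh_threshold(
    volume: DensityVolume,
    bone_peak_region: np.ndarray,
    background_region: np.ndarray,
) -> float:
    """Half-maximum-height threshold: midway between cortical peak and background.

    Levels are estimated as medians (robust means) of the two probe regions;
    the threshold is ``background + 0.5 * (cortical_peak - background)`` — the
    intensity of a voxel half-filled with cortical bone and half with joint
    space.  Invariant under any affine intensity rescale applied to both
    probes consistently.
    """
    peak_region = np.asarray(bone_peak_region, dtype=bool)
    bg_region = np.asarray(background_region, dtype=bool)
    if not peak_region.any() or not bg_region.any():
        raise ValueError("both probe regions must be non-empty")
    peak = float(np.median(volume.data[peak_region]))
    background = float(np.median(volume.data[bg_region]))
    if peak <= background:
        raise ValueError(
            f"cortical peak level ({peak:.1f}) must exceed background ({background:.1f})"
        )
    return background + 0.5 * (peak - background)


def auto_probe_regions(
    volume: DensityVolume, percentile: float = 99.5, background_band: float = 80.0
) -> tuple[np.ndarray, np.ndarray]:
    """Automatic probe placement for the HMH threshold.

    Cortical probe: voxels above the given intensity percentile (the cortical
    shell dominates the top of the histogram).  Background probe: soft-tissue
    voxels (|value| below ``background_band`` on the calibrated scale) lying
    within 10 mm of the cortical probe, i.e. the joint-space/soft-tissue gap
    adjacent to bone.  Both are operator-overridable by calling
    :func:`hmh_threshold` with explicit masks.
    """
    data = volume.data
    hi = np.percentile(data, percentile)
    peak_region = data >= hi
    near = ndimage.binary_dilation(
        peak_region, iterations=max(1, int(round(10.0 / min(volume.spacing))))
    )
    bg_region = near & (np.abs(data) < background_band)
    if not bg_region.any():
        bg_region = np.abs(data) < background_band
    return peak_region, bg_region


# ---------------------------------------------------------------------------
# segmentation
# ---------------------------------------------------------------------------

def segment_bones(
    volume: DensityVolume,
    threshold: float,
    seeds_per_bone: dict,
    min_component_voxels: int = 64,
) -> SegmentationMask:
    """Threshold + connected components + seed assignment + hole filling.

    ``seeds_per_bone`` maps bone name -> voxel index triple known to lie
    inside that bone.  Interior voxels below threshold (trabecular centers)
    are retained by 3D hole filling, so the mask is the full bone, not just
    the shell.
    """
    data = volume.data
    if data.size == 0:
        raise ValueError("empty volume")
    if threshold > data.max():
        raise ValueError("threshold above the volume maximum; nothing to segment")

    fg = data >= threshold
    structure = np.ones((3, 3, 3), dtype=bool)  # 26-connectivity
    comp, _ = ndimage.label(fg, structure=structure)

    labels = np.zeros(data.shape, dtype=np.int16)
    used = {}
    for name, seed in seeds_per_bone.items():
        if name not in BONE_CODES:
            raise ValueError(f"unknown bone name {name!r}")
        seed = tuple(int(s) for s in seed)
        cid = comp[seed]
        if cid == 0:
            raise ValueError(f"seed for {name} at {seed} falls in background")
        if cid in used:
            import warnings

            warnings.warn(
                f"seeds for {name} and {used[cid]} fall in the same component; "
                "bones may be merged across the joint space"
            )
        used.setdefault(cid, name)
        bone_mask = comp == cid
        # morphological closing (<= 1 voxel surface deviation) then fill
        bone_mask = ndimage.binary_closing(bone_mask, structure=structure, iterations=1)
        bone_mask = ndimage.binary_fill_holes(bone_mask)
        labels[bone_mask & (labels == 0)] = BONE_CODES[name]
    return SegmentationMask(labels=labels, threshold_used=float(threshold), provenance="hmh+cc")


def auto_seeds(volume: DensityVolume, threshold: float) -> dict:
    """Heuristic seed placement on a segmented-threshold image.

    The component reaching highest is the femur; the largest component below
    the femur is the tibia; the next lateral, smaller one is the fibula.
    """
    fg = volume.data >= threshold
    structure = np.ones((3, 3, 3), dtype=bool)
    comp, n = ndimage.label(fg, structure=structure)
    if n < 2:
        raise ValueError("expected at least two bone components")
    sizes = ndimage.sum_labels(fg, comp, index=np.arange(1, n + 1))
    order = np.argsort(sizes)[::-1] + 1
    nz = volume.shape[2]
    big = []
    top = {}
    for cid in order[: min(6, n)]:
        if sizes[cid - 1] <= 200:
            continue
        zs = np.nonzero((comp == cid).any(axis=(0, 1)))[0]
        # calibration-phantom rods run the full scan length; bones do not
        if zs.max() - zs.min() >= 0.9 * (nz - 1):
            continue
        big.append(cid)
        top[cid] = zs.max()
    if len(big) < 2:
        raise ValueError("expected at least two bone components")
    femur_cid = max(big, key=lambda c: top[c])
    rest = [c for c in big if c != femur_cid]
    tibia_cid = max(rest, key=lambda c: sizes[c - 1])
    seeds = {}
    for name, cid in (("tibia", tibia_cid), ("femur", femur_cid)):
        idx = np.argwhere(comp == cid)
        seeds[name] = tuple(idx[len(idx) // 2])
    fib = [c for c in rest if c != tibia_cid]
    if fib:
        fibula_cid = max(fib, key=lambda c: sizes[c - 1])
        idx = np.argwhere(comp == fibula_cid)
        seeds["fibula"] = tuple(idx[len(idx) // 2])
    return seeds


# ---------------------------------------------------------------------------
# axes and re-alignment
# ---------------------------------------------------------------------------

def _slice_centroid(mask: np.ndarray, volume: DensityVolume, z_index: int, halfwidth: int = 1):
    lo, hi = max(0, z_index - halfwidth), min(mask.shape[2], z_index + halfwidth + 1)
    slab = mask[:, :, lo:hi]
    if not slab.any():
        return None
    idx = np.argwhere(slab).astype(float)
    idx[:, 2] += lo
    centroid_idx = idx.mean(axis=0)
    return volume.index_to_world(centroid_idx)[0]


def _fit_line(points: np.ndarray) -> np.ndarray:
    pts = np.asarray(points, dtype=float)
    centered = pts - pts.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    d = vt[0]
    return d if d[2] >= 0 else -d  # orient superiorly


def fit_bone_axes(
    mask: SegmentationMask, volume: DensityVolume
) -> tuple[np.ndarray, np.ndarray]:
    """Best-fit long axes of tibia and femur from cross-section centroids.

    Tibia: centroids at the distal end of the imaged extent, 50%, 66% and the
    proximal shaft (just below the metaphyseal flare).  Femur: up to 32
    cross-sections starting just proximal to the intercondylar fossa
    analogue (where the condylar footprint has narrowed), extending
    proximally.  Both unit vectors point superiorly.
    """
    tib = mask.mask("tibia")
    fem = mask.mask("femur")
    if not tib.any() or not fem.any():
        raise ValueError("both tibia and femur must be present")

    # --- tibia -----------------------------------------------------------
    zt = np.nonzero(tib.any(axis=(0, 1)))[0]
    z0, z1 = int(zt.min()), int(zt.max())
    span = z1 - z0
    if span < 4:
        raise ValueError("tibia axial extent too small for axis fitting")
    levels = [z0 + 1, z0 + int(0.50 * span), z0 + int(0.66 * span), z0 + int(0.80 * span)]
    pts = [c for z in levels if (c := _slice_centroid(tib, volume, z)) is not None]
    if len(pts) < 2:
        raise ValueError("fewer than 2 usable tibial cross-sections")
    axis_tibia = _fit_line(np.array(pts))

    # --- femur -----------------------------------------------------------
    zf = np.nonzero(fem.any(axis=(0, 1)))[0]
    if int(zf.max()) - int(zf.min()) < 4:
        raise ValueError("femur axial extent too small for axis fitting")
    pts_world = volume.index_to_world(np.argwhere(fem))
    axis_femur = _refine_axis_by_slabs(pts_world, np.array([0.0, 0.0, 1.0]))
    return axis_femur, axis_tibia


def _refine_axis_by_slabs(
    points: np.ndarray,
    axis0: np.ndarray,
    n_slabs: int = 32,
    trim: tuple = (0.50, 0.90),
    min_slab: float = 1.5,
) -> np.ndarray:
    """Best-fit line through cross-section centroids taken normal to ``axis0``.

    The point cloud is sliced into up to ``n_slabs`` slabs (each at least
    ``min_slab`` mm thick, so a slab always contains full cross-sections)
    perpendicular to the initial direction — the image vertical, adequate
    for near-vertical limbs — and a line is fit through the slab centroids.
    The extent window drops the condylar mass distally and the obliquely
    clipped image boundary proximally, mirroring a fit through shaft
    cross-sections starting just proximal to the intercondylar fossa.
    """
    axis = np.asarray(axis0, float)
    t = points @ axis
    tmin, tmax = t.min(), t.max()
    lo = tmin + trim[0] * (tmax - tmin)
    hi = tmin + trim[1] * (tmax - tmin)
    n = min(n_slabs, max(4, int((hi - lo) / min_slab)))
    edges = np.linspace(lo, hi, n + 1)
    cents, counts = [], []
    for i in range(n):
        m = (t >= edges[i]) & (t < edges[i + 1])
        if m.sum() >= 5:
            cents.append(points[m].mean(axis=0))
            counts.append(m.sum())
    if len(cents) < 2:
        raise ValueError("fewer than 2 usable femoral cross-sections")
    # drop partially clipped slabs (oblique image boundary) by completeness
    counts = np.asarray(counts, dtype=float)
    keep = counts >= 0.8 * np.median(counts)
    cents = np.asarray(cents)[keep] if keep.sum() >= 2 else np.asarray(cents)
    return _fit_line(cents)


def rotation_between(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Minimal proper rotation taking unit vector a onto unit vector b."""
    a = np.asarray(a, float) / np.linalg.norm(a)
    b = np.asarray(b, float) / np.linalg.norm(b)
    v = np.cross(a, b)
    c = float(np.dot(a, b))
    if np.linalg.norm(v) < 1e-12:
        if c > 0:
            return np.eye(3)
        raise ValueError("antiparallel vectors: rotation is not unique")
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx * (1.0 / (1.0 + c))


def realignment_rotation(axis_femur: np.ndarray, axis_tibia: np.ndarray) -> np.ndarray:
    """Rotation making the normalized average of the two axes vertical."""
    f = np.asarray(axis_femur, float) / np.linalg.norm(axis_femur)
    t = np.asarray(axis_tibia, float) / np.linalg.norm(axis_tibia)
    avg = f + t
    n = np.linalg.norm(avg)
    if n < 1e-9:
        raise ValueError("antiparallel axes: average direction undefined")
    return rotation_between(avg / n, np.array([0.0, 0.0, 1.0]))


def realign(
    volume: DensityVolume,
    mask: SegmentationMask,
    axes: tuple[np.ndarray, np.ndarray],
) -> tuple[DensityVolume, SegmentationMask, AlignmentResult]:
    """Rotate image + labels so the average of the two bone axes is vertical.

    After the rotation both axes make equal angles with vertical — half the
    supplement of the inter-axis angle.  An additional in-plane (axial twist)
    rotation aligns the medial-lateral condylar axis of the tibial plateau
    with +x, making medial/lateral splits deterministic.  Density is
    resampled linearly, labels with nearest neighbour.
    """
    axis_femur, axis_tibia = (np.asarray(a, float) for a in axes)
    for a in (axis_femur, axis_tibia):
        if a[2] <= 0:
            raise ValueError("axes must point superiorly")
    R1 = realignment_rotation(axis_femur, axis_tibia)

    # axial twist: principal ML direction of the proximal tibial footprint -> +x
    tib = mask.mask("tibia")
    idx = np.argwhere(tib)
    world = volume.index_to_world(idx)
    zs = world[:, 2]
    band = world[zs >= zs.max() - 12.0]
    xy = (R1 @ band.T).T[:, :2]
    xy = xy - xy.mean(axis=0)
    _, _, vt = np.linalg.svd(xy, full_matrices=False)
    ml = vt[0]
    if ml[0] < 0:
        ml = -ml
    ang = np.arctan2(ml[1], ml[0])
    ca, sa = np.cos(-ang), np.sin(-ang)
    R2 = np.array([[ca, -sa, 0], [sa, ca, 0], [0, 0, 1.0]])
    R = R2 @ R1

    # resample about the volume center (world frame)
    cval = -1000.0 if volume.units == HU else 0.0
    data = _resample_rotation(volume.data, volume.spacing, R, order=1, cval=cval)
    labels = _resample_rotation(
        mask.labels.astype(np.float32), volume.spacing, R, order=0, cval=0
    ).astype(mask.labels.dtype)

    f2, t2 = R @ axis_femur / np.linalg.norm(axis_femur), R @ axis_tibia / np.linalg.norm(axis_tibia)
    ang_f = float(np.degrees(np.arccos(np.clip(f2[2], -1, 1))))
    ang_t = float(np.degrees(np.arccos(np.clip(t2[2], -1, 1))))
    result = AlignmentResult(
        axis_femur=f2,
        axis_tibia=t2,
        rotation=R,
        angle_femur_vertical=ang_f,
        angle_tibia_vertical=ang_t,
    )
    out_mask = SegmentationMask(
        labels=labels, threshold_used=mask.threshold_used, provenance=mask.provenance + "+realigned"
    )
    return volume.with_data(data), out_mask, result


def _rotation_to_euler(R: np.ndarray) -> np.ndarray:
    sy = np.hypot(R[0, 0], R[1, 0])
    if sy > 1e-9:
        return np.degrees(
            [np.arctan2(R[2, 1], R[2, 2]), np.arctan2(-R[2, 0], sy), np.arctan2(R[1, 0], R[0, 0])]
        )
    return np.degrees([np.arctan2(-R[1, 2], R[1, 1]), np.arctan2(-R[2, 0], sy), 0.0])


def _resample_rotation(data, spacing, R, order, cval):
    """Rotate a volume about its center in the world frame."""
    S = np.diag(spacing)
    Sinv = np.diag(1.0 / np.asarray(spacing))
    center = (np.asarray(data.shape) - 1) / 2.0
    M = Sinv @ R.T @ S
    offset = center - M @ center
    return ndimage.affine_transform(
        data, M, offset=offset, order=order, cval=cval, mode="constant", prefilter=False
    )
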