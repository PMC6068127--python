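"""Calibrated density volumes.

The pipeline's image container is a 3D scalar grid with physical metadata.
Axis order is (x, y, z) with +z superior; the world frame is RAS-like with
+x toward the medial side of the scanned knee (left knees are mirrored at
load time so downstream logic is side-agnostic).  Intensities are either
raw CT Hounsfield units (``HU``) or calibrated equivalent volumetric bone
mineral density in mg/cm^3 K2HPO4 (``mg_cm3``).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

HU = "HU"
MG_CM3 = "mg_cm3"

__all__ = ["DensityVolume", "HU", "MG_CM3"]


@dataclass
class DensityVolume:
    """A 3D scalar volume with spacing, origin, orientation and units.

    Parameters
    ----------
    data:
        3D float array, axis order (x, y, z).
    spacing:
        Voxel size per axis in mm, all > 0.
    origin:
        World coordinate of voxel (0, 0, 0) center, mm.
    orientation:
        3x3 direction-cosine matrix (orthonormal).
    units:
        ``"HU"`` for raw CT intensities, ``"mg_cm3"`` once calibrated.
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    orientation: np.ndarray = field(default_factory=lambda: np.eye(3))
    units: str = HU

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D array, got shape {self.data.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive, got {self.spacing}")
        self.origin = tuple(float(o) for o in self.origin)
        self.orientation = np.asarray(self.orientation, dtype=float)
        if self.orientation.shape != (3, 3):
            raise ValueError("orientation must be 3x3")
        if abs(abs(np.linalg.det(self.orientation)) - 1.0) > 1e-6:
            raise ValueError("orientation must be orthonormal (|det| = 1)")
        if self.units not in (HU, MG_CM3):
            raise ValueError(f"unknown units {self.units!r}")

    # -- geometry ---------------------------------------------------------
    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def affine(self) -> np.ndarray:
        """4x4 voxel-index -> world-mm affine."""
        A = np.eye(4)
        A[:3, :3] = self.orientation @ np.diag(self.spacing)
        A[:3, 3] = self.origin
        return A

    def index_to_world(self, idx: np.ndarray) -> np.ndarray:
        idx = np.atleast_2d(np.asarray(idx, dtype=float))
        return idx @ (self.orientation @ np.diag(self.spacing)).T + np.asarray(self.origin)

    def world_to_index(self, xyz: np.ndarray) -> np.ndarray:
        xyz = np.atleast_2d(np.asarray(xyz, dtype=float))
        inv = np.linalg.inv(self.orientation @ np.diag(self.spacing))
        return (xyz - np.asarray(self.origin)) @ inv.T

    def axis_coords(self, axis: int) -> np.ndarray:
        """World coordinate of voxel centers along one axis (identity orientation)."""
        return self.origin[axis] + self.spacing[axis] * np.arange(self.shape[axis])

    def with_data(self, data: np.ndarray, units: str | None = None) -> "DensityVolume":
        return replace(self, data=data, units=self.units if units is None else units)

    # -- I/O --------------------------------------------------------------
    def to_nifti(self, path: str) -> None:
        import nibabel as nib

        img = nib.Nifti1Image(np.asarray(self.data, dtype=np.float32), self.affine)
        img.header.set_xyzt_units("mm")
        img.header["descrip"] = self.units.encode()
        nib.save(img, path)

    @classmethod
    def from_nifti(cls, path: str, units: str | None = None) -> "DensityVolume":
        import nibabel as nib

        img = nib.load(path)
        A = img.affine
        M = A[:3, :3]
        spacing = np.linalg.norm(M, axis=0)
        orientation = M / spacing
        if units is None:
            descrip = bytes(img.header["descrip"]).split(b"\x00")[0].decode() or HU
            units = descrip if descrip in (HU, MG_CM3) else HU
        return cls(
            data=np.asarray(img.dataobj, dtype=np.float64),
            spacing=tuple(spacing),
            origin=tuple(A[:3, 3]),
            orientation=orientation,
            units=units,
        )
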