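"""Core imaging containers: 3-D volumes and rigid (6-DOF) transforms.

A :class:`Volume` is the unit of all imaging I/O in this package: a 3-D
real-valued grid plus voxel spacing and world origin, read from / written to
NIfTI-1 via nibabel.  Orientation is fixed to a single right-handed RAS-like
convention with a diagonal voxel-to-world affine; files whose affine is not
diagonal-positive are reoriented on read.

A :class:`RigidTransform` has exactly six degrees of freedom (three Euler
rotations in degrees, three translations in mm) about an explicit rotation
center, and maps *moving*-space world coordinates into *fixed*-space world
coordinates:  ``x_fixed = R (x - c) + c + t``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy.spatial.transform import Rotation

__all__ = ["Volume", "RigidTransform"]


@dataclass
class Volume:
    """A 3-D intensity grid with spacing/origin metadata."""

    data: np.ndarray
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"Volume data must be 3-D, got shape {self.data.shape}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("Volume data must contain finite values only")
        spacing = tuple(float(s) for s in self.spacing_mm)
        if any(s <= 0 for s in spacing):
            raise ValueError(f"spacing must be positive, got {spacing}")
        self.spacing_mm = spacing
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def affine(self) -> np.ndarray:
        """Diagonal voxel-to-world affine (4x4)."""
        aff = np.eye(4)
        aff[:3, :3] = np.diag(self.spacing_mm)
        aff[:3, 3] = self.origin
        return aff

    def world_center(self) -> np.ndarray:
        """World coordinates of the geometric grid center."""
        idx = (np.asarray(self.shape, dtype=float) - 1.0) / 2.0
        return idx * np.asarray(self.spacing_mm) + np.asarray(self.origin)

    def like(self, data: np.ndarray) -> "Volume":
        """A new volume with the same grid metadata but different data."""
        return Volume(np.asarray(data), self.spacing_mm, self.origin)

    def copy(self) -> "Volume":
        return replace(self, data=self.data.copy())

    # ---- NIfTI-1 I/O -----------------------------------------------------

    def to_nifti(self) -> nib.Nifti1Image:
        return nib.Nifti1Image(np.asarray(self.data, dtype=np.float32), self.affine)

    def save(self, path: str | Path) -> None:
        nib.save(self.to_nifti(), str(path))

    @classmethod
    def load(cls, path: str | Path) -> "Volume":
        img = nib.load(str(path))
        img = nib.as_closest_canonical(img)  # fixed RAS orientation convention
        data = np.asarray(img.dataobj, dtype=np.float64)
        if data.ndim == 4 and data.shape[3] == 1:
            data = data[..., 0]
        aff = img.affine
        spacing = tuple(float(s) for s in np.abs(np.diag(aff)[:3]))
        origin = tuple(float(o) for o in aff[:3, 3])
        return cls(data, spacing, origin)


@dataclass(frozen=True)
class RigidTransform:
    """6-DOF rigid transform: x_fixed = R (x - center) + center + t (world/mm)."""

    rotations_deg: tuple[float, float, float] = (0.0, 0.0, 0.0)
    translations_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    center: tuple[float, float, float] = (0.0, 0.0, 0.0)

    @property
    def rotation_matrix(self) -> np.ndarray:
        return Rotation.from_euler("xyz", self.rotations_deg, degrees=True).as_matrix()

    def matrix(self) -> np.ndarray:
        """Homogeneous 4x4 world-coordinate matrix."""
        R = self.rotation_matrix
        c = np.asarray(self.center, dtype=float)
        t = np.asarray(self.translations_mm, dtype=float)
        m = np.eye(4)
        m[:3, :3] = R
        m[:3, 3] = c + t - R @ c
        return m

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Apply to an (n, 3) array of world coordinates."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        R = self.rotation_matrix
        c = np.asarray(self.center, dtype=float)
        t = np.asarray(self.translations_mm, dtype=float)
        return (pts - c) @ R.T + c + t

    def inverse(self) -> "RigidTransform":
        """The exact inverse rigid transform (same rotation center)."""
        R_inv = self.rotation_matrix.T
        angles = Rotation.from_matrix(R_inv).as_euler("xyz", degrees=True)
        t_inv = -R_inv @ np.asarray(self.translations_mm, dtype=float)
        return RigidTransform(tuple(angles), tuple(t_inv), self.center)

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self ∘ other: apply `other` first, then `self` (shared center kept from self)."""
        m = self.matrix() @ other.matrix()
        R = m[:3, :3]
        angles = Rotation.from_matrix(R).as_euler("xyz", degrees=True)
        c = np.asarray(self.center, dtype=float)
        # Solve t from m[:3,3] = c + t - R c
        t = m[:3, 3] - c + R @ c
        return RigidTransform(tuple(angles), tuple(t), self.center)

    @property
    def params(self) -> np.ndarray:
        return np.asarray(self.rotations_deg + self.translations_mm, dtype=float)

    @classmethod
    def from_params(
        cls, params: np.ndarray, center: tuple[float, float, float] = (0.0, 0.0, 0.0)
    ) -> "RigidTransform":
        p = np.asarray(params, dtype=float)
        return cls(tuple(p[:3]), tuple(p[3:6]), center)

    def is_identity(self, tol: float = 1e-12) -> bool:
        return bool(np.all(np.abs(self.params) < tol))
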