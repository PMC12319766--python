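"""Rigid transforms (in-plane rotation about the volume centre + 3D shift).

Conventions (used package-wide):

* voxel indices are 0-based; the rotation axis is the slice (z) axis and
  the rotation centre is the volume centre ``(n-1)/2`` in voxels;
* a transform acts as the *pull-back* point map ``out(r) = img(T(r))``
  with ``T(r) = R (r - c) + c + t``, matching
  ``scipy.ndimage.affine_transform`` semantics;
* translations are stored in mm and converted with the voxel size at
  application time (in-plane spacing must be isotropic).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = ["RigidTransform"]


@dataclass
class RigidTransform:
    """In-plane rotation (degrees, about the volume centre) + mm translation."""

    angle_deg: float = 0.0
    translation_mm: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.translation_mm = np.asarray(self.translation_mm, dtype=float)
        if self.translation_mm.shape != (3,):
            raise ValueError("translation_mm must have 3 components")

    # ---- group algebra -------------------------------------------------
    def rotation_matrix(self) -> np.ndarray:
        th = np.deg2rad(self.angle_deg)
        c, s = np.cos(th), np.sin(th)
        return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self o other (apply ``other`` first in the point-map sense)."""
        r = self.rotation_matrix()
        return RigidTransform(
            angle_deg=self.angle_deg + other.angle_deg,
            translation_mm=r @ other.translation_mm + self.translation_mm,
        )

    def inverse(self) -> "RigidTransform":
        r_inv = self.rotation_matrix().T
        return RigidTransform(
            angle_deg=-self.angle_deg,
            translation_mm=-(r_inv @ self.translation_mm),
        )

    def half(self) -> "RigidTransform":
        """Transform h with h o h = self (screw-motion halving)."""
        h_angle = self.angle_deg / 2.0
        r_h = RigidTransform(angle_deg=h_angle).rotation_matrix()
        t_h = np.linalg.solve(r_h + np.eye(3), self.translation_mm)
        return RigidTransform(angle_deg=h_angle, translation_mm=t_h)

    def is_identity(self, tol: float = 1e-12) -> bool:
        return abs(self.angle_deg) < tol and np.all(np.abs(self.translation_mm) < tol)

    # ---- application ---------------------------------------------------
    def apply(
        self,
        volume: np.ndarray,
        voxel_size_mm: tuple[float, float, float] = (1.0, 1.0, 1.0),
        order: int = 1,
        cval: float = 0.0,
    ) -> np.ndarray:
        """Resample ``volume`` under the pull-back map (linear by default).

        Complex input is resampled on real and imaginary parts separately.
        """
        vox = np.asarray(voxel_size_mm, dtype=float)
        if not np.isclose(vox[0], vox[1]):
            raise ValueError("in-plane voxel size must be isotropic for rotation")
        if np.iscomplexobj(volume):
            re = self.apply(volume.real, voxel_size_mm, order, cval)
            im = self.apply(volume.imag, voxel_size_mm, order, cval)
            return re + 1j * im
        center = (np.asarray(volume.shape, dtype=float) - 1) / 2.0
        r = self.rotation_matrix()
        t_vox = self.translation_mm / vox
        offset = center - r @ center + t_vox
        return ndimage.affine_transform(
            volume, r, offset=offset, order=order, mode="constant", cval=cval
        )

    def map_points_mm(
        self,
        points_mm: np.ndarray,
        shape: tuple[int, int, int],
        voxel_size_mm: tuple[float, float, float] = (1.0, 1.0, 1.0),
    ) -> np.ndarray:
        """Apply the point map T(p) = R (p - c) + c + t to mm coordinates."""
        vox = np.asarray(voxel_size_mm, dtype=float)
        p_vox = np.asarray(points_mm, dtype=float) / vox[None]
        center = (np.asarray(shape, dtype=float) - 1) / 2.0
        r = self.rotation_matrix()
        q = (p_vox - center) @ r.T + center + self.translation_mm / vox
        return q * vox[None]

    def as_dict(self) -> dict:
        return {
            "angle_deg": float(self.angle_deg),
            "translation_mm": self.translation_mm.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RigidTransform":
        return cls(angle_deg=d["angle_deg"], translation_mm=np.asarray(d["translation_mm"]))

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls()
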