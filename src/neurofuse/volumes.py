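"""Volume data model and I/O shared by every other module.

A :class:`VolumeImage` is a dense 3D (X, Y, Z) or 4D (X, Y, Z, T) voxel grid
together with a 4x4 voxel-to-world affine in millimetres.  Volumes loaded from
disk are reoriented to canonical RAS axis order, so downstream code can rely on
a fixed anatomical convention: sagittal slices vary along x, coronal along y,
axial along z.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
from PIL import Image
from scipy import ndimage

__all__ = [
    "VolumeImage",
    "RigidTransform",
    "RoiAtlas",
    "load_nifti",
    "save_nifti",
    "resample_rigid",
    "export_png",
    "load_png",
]

PLANE_AXES = {"sagittal": 0, "coronal": 1, "axial": 2}


@dataclass
class VolumeImage:
    """Dense voxel grid with world geometry.

    Parameters
    ----------
    data:
        Array of shape (X, Y, Z) or (X, Y, Z, T).
    affine:
        4x4 voxel-to-world map (mm).
    tr:
        Repetition time in seconds; required for 4D data.
    """

    data: np.ndarray
    affine: np.ndarray
    tr: float | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim not in (3, 4):
            raise ValueError(f"volume must be 3D or 4D, got ndim={self.data.ndim}")
        if any(s < 1 for s in self.data.shape):
            raise ValueError("all dimensions must be >= 1")
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValueError("affine is singular")
        if self.data.ndim == 4 and self.tr is None:
            raise ValueError("4D volume requires a repetition time (tr)")

    @property
    def voxel_size(self) -> np.ndarray:
        """Voxel edge lengths in mm (column norms of the affine)."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def n_frames(self) -> int:
        return self.data.shape[3] if self.data.ndim == 4 else 1

    def frame(self, t: int) -> "VolumeImage":
        """Extract a single 3D frame of a 4D volume."""
        if self.data.ndim != 4:
            raise ValueError("frame() requires a 4D volume")
        return VolumeImage(self.data[..., t], self.affine)

    def world_center(self) -> np.ndarray:
        """World coordinates (mm) of the grid centre."""
        c_vox = (np.asarray(self.data.shape[:3]) - 1) / 2.0
        return self.affine[:3, :3] @ c_vox + self.affine[:3, 3]


@dataclass
class RigidTransform:
    """Rigid-body map: extrinsic x-y-z rotations (rad) plus translation (mm).

    The map acts on world coordinates as ``w -> R (w - c) + c + t`` where the
    rotation centre ``c`` defaults to the origin.
    """

    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))
    rotation: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.translation = np.asarray(self.translation, dtype=float).reshape(3)
        self.rotation = np.asarray(self.rotation, dtype=float).reshape(3)

    def rotation_matrix(self) -> np.ndarray:
        ax, ay, az = self.rotation
        cx, sx = np.cos(ax), np.sin(ax)
        cy, sy = np.cos(ay), np.sin(ay)
        cz, sz = np.cos(az), np.sin(az)
        rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
        ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
        rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
        # extrinsic x-y-z order: Rz @ Ry @ Rx
        return rz @ ry @ rx

    def matrix(self, center: np.ndarray | None = None) -> np.ndarray:
        """Homogeneous 4x4 world-to-world matrix about ``center``."""
        c = np.zeros(3) if center is None else np.asarray(center, float)
        r = self.rotation_matrix()
        m = np.eye(4)
        m[:3, :3] = r
        m[:3, 3] = c - r @ c + self.translation
        return m

    def inverse(self) -> "RigidTransform":
        """Exact inverse (rotation centre at origin).

        For a centred application use ``matrix(center)`` and invert that; this
        convenience inverse satisfies compose(t, t.inverse()) == identity.
        """
        r = self.rotation_matrix()
        inv = RigidTransform()
        inv.translation = -(r.T @ self.translation)
        # recover extrinsic x-y-z angles from R^T
        rt = r.T
        ay = np.arcsin(np.clip(-rt[2, 0], -1.0, 1.0))
        ax = np.arctan2(rt[2, 1], rt[2, 2])
        az = np.arctan2(rt[1, 0], rt[0, 0])
        inv.rotation = np.array([ax, ay, az])
        return inv

    @property
    def params(self) -> np.ndarray:
        return np.concatenate([self.translation, self.rotation])

    @classmethod
    def from_params(cls, p) -> "RigidTransform":
        p = np.asarray(p, float).reshape(6)
        return cls(translation=p[:3], rotation=p[3:])


@dataclass
class RoiAtlas:
    """Integer label grid aligned with a volume grid; 0 is background."""

    labels: np.ndarray
    n_rois: int

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("atlas labels must be integer-valued")
        present = np.unique(self.labels)
        if present.min() < 0 or present.max() > self.n_rois:
            raise ValueError("labels must lie in {0..n_rois}")
        for r in range(1, self.n_rois + 1):
            if not (self.labels == r).any():
                raise ValueError(f"ROI {r} is empty")

    def voxels(self, roi: int) -> np.ndarray:
        """Voxel index array (N, 3) of one ROI."""
        return np.argwhere(self.labels == roi)


def load_nifti(path: str | Path) -> VolumeImage:
    """Load a NIfTI image, reoriented to canonical RAS axis order.

    The repetition time is read from the header for 4D images.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    img = nib.as_closest_canonical(img)
    data = np.asarray(img.dataobj, dtype=np.float64)
    if data.ndim not in (3, 4):
        raise ValueError(f"expected a 3D or 4D NIfTI payload, got ndim={data.ndim}")
    tr = None
    if data.ndim == 4:
        zooms = img.header.get_zooms()
        tr = float(zooms[3]) if len(zooms) > 3 else 1.0
    return VolumeImage(data=data, affine=np.asarray(img.affine, float), tr=tr)


def save_nifti(vol: VolumeImage, path: str | Path) -> None:
    """Write a volume as NIfTI-1 (.nii or .nii.gz), preserving tr for 4D."""
    img = nib.Nifti1Image(np.asarray(vol.data, dtype=np.float32), vol.affine)
    if vol.data.ndim == 4:
        zooms = list(img.header.get_zooms())
        zooms[3] = vol.tr
        img.header.set_zooms(zooms)
    nib.save(img, str(path))


def resample_rigid(
    moving: VolumeImage,
    transform: RigidTransform,
    target_shape: tuple[int, int, int],
    target_affine: np.ndarray,
    center: np.ndarray | None = None,
) -> VolumeImage:
    """Resample ``moving`` onto a target grid under a rigid world map.

    ``transform`` maps moving-space world coordinates to target-space world
    coordinates; the output voxel at index v holds the trilinearly interpolated
    moving intensity at ``T^{-1}(A_t v)``.  Voxels that fall outside the moving
    field of view are zero.  ``center`` is the world rotation centre and
    defaults to the target grid centre.
    """
    target_affine = np.asarray(target_affine, float)
    if center is None:
        c_vox = (np.asarray(target_shape, float) - 1) / 2.0
        center = target_affine[:3, :3] @ c_vox + target_affine[:3, 3]
    t_world = transform.matrix(center)
    combined = np.linalg.inv(moving.affine) @ np.linalg.inv(t_world) @ target_affine
    if abs(np.linalg.det(combined[:3, :3])) < 1e-12:
        raise ValueError("combined resampling map is singular")
    out = ndimage.affine_transform(
        np.asarray(moving.data, float),
        combined[:3, :3],
        offset=combined[:3, 3],
        output_shape=tuple(target_shape),
        order=1,
        mode="constant",
        cval=0.0,
    )
    return VolumeImage(out, target_affine)


def export_png(slice_2d: np.ndarray, path: str | Path) -> None:
    """Save a 2D array as an 8-bit grayscale PNG, min-max scaled to [0, 255].

    A constant slice maps to an all-zero image.
    """
    arr = np.asarray(slice_2d, dtype=float)
    if arr.ndim != 2:
        raise ValueError("export_png expects a 2D array")
    if not np.all(np.isfinite(arr)):
        raise ValueError("slice contains NaN or Inf")
    lo, hi = arr.min(), arr.max()
    if hi > lo:
        scaled = np.round((arr - lo) / (hi - lo) * 255.0)
    else:
        scaled = np.zeros_like(arr)
    # PIL expects (rows, cols); keep array axes as-is
    Image.fromarray(scaled.astype(np.uint8), mode="L").save(str(path))


def load_png(path: str | Path) -> np.ndarray:
    """Load an 8-bit grayscale PNG back into a float array in [0, 255]."""
    with Image.open(str(path)) as im:
        return np.asarray(im.convert("L"), dtype=float)
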