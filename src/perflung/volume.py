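"""Volumetric data model, grid geometry, resampling and NIfTI IO.

All images live on axis-aligned grids in a right-handed world space
measured in millimetres: voxel index ``(i, j, k)`` (0-based) has its
centre at ``origin + index * spacing``.  Cross-grid operations resample
onto the planning (dose/structure) grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy.ndimage import map_coordinates

__all__ = [
    "ROLES",
    "ImageVolume",
    "GridSpec",
    "StructureSet",
    "RigidTransform",
    "read_volume",
    "write_volume",
    "resample_to_grid",
    "mask_volume_ml",
]

ROLES = ("dose_gy", "spect_counts", "mask", "hu")


@dataclass(frozen=True)
class GridSpec:
    """Geometry of an axis-aligned sampling grid (shape, spacing mm, origin mm)."""

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if len(self.shape) != 3:
            raise ValueError("grid must be 3D")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing components must be strictly positive")

    @property
    def voxel_volume_ml(self) -> float:
        return float(np.prod(self.spacing)) / 1000.0

    def index_to_world(self, idx: np.ndarray) -> np.ndarray:
        """Map (possibly fractional) voxel indices (..., 3) to world mm."""
        return np.asarray(idx, dtype=float) * np.asarray(self.spacing) + np.asarray(
            self.origin
        )

    def world_to_index(self, xyz: np.ndarray) -> np.ndarray:
        return (np.asarray(xyz, dtype=float) - np.asarray(self.origin)) / np.asarray(
            self.spacing
        )

    def coordinate_grids(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """World coordinates of every voxel centre, one array per axis."""
        axes = [
            self.origin[a] + self.spacing[a] * np.arange(self.shape[a])
            for a in range(3)
        ]
        return tuple(np.meshgrid(*axes, indexing="ij"))


@dataclass
class ImageVolume:
    """A 3D scalar grid with geometry and a semantic role.

    Parameters
    ----------
    data : ndarray, shape (nx, ny, nz)
        Voxel values: Gy for ``dose_gy``, counts for ``spect_counts``,
        {0, 1} for ``mask``.
    spacing : tuple of float
        Per-axis voxel size in mm; strictly positive.
    origin : tuple of float
        World position (mm) of the centre of voxel (0, 0, 0).
    role : str
        One of ``dose_gy``, ``spect_counts``, ``mask``, ``hu``.
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    role: str = "hu"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D array, got {self.data.ndim}D")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing components must be strictly positive")
        if self.role not in ROLES:
            raise ValueError(f"role must be one of {ROLES}, got {self.role!r}")
        if self.role == "mask":
            vals = np.unique(self.data)
            if not np.all(np.isin(vals, (0, 1))):
                raise ValueError("mask volumes must contain only 0/1 values")
        if self.role == "spect_counts" and np.any(self.data < 0):
            raise ValueError("spect_counts volumes must be non-negative")
        if not (np.isfinite(self.voxel_volume_ml) and self.voxel_volume_ml > 0):
            raise ValueError("voxel volume must be finite and positive")

    @property
    def grid(self) -> GridSpec:
        return GridSpec(tuple(self.data.shape), self.spacing, self.origin)

    @property
    def voxel_volume_ml(self) -> float:
        return float(np.prod(self.spacing)) / 1000.0

    def same_grid(self, other: "ImageVolume", tol: float = 1e-6) -> bool:
        return (
            self.data.shape == other.data.shape
            and np.allclose(self.spacing, other.spacing, atol=tol)
            and np.allclose(self.origin, other.origin, atol=tol)
        )

    def with_data(self, data: np.ndarray, role: str | None = None) -> "ImageVolume":
        return replace(self, data=data, role=role or self.role)


@dataclass
class StructureSet:
    """Named binary masks sharing one reference (planning) grid.

    ``central_airways`` holds trachea plus proximal bronchial tree.
    """

    lungs: ImageVolume
    gtv_itv: ImageVolume
    ptv: ImageVolume
    central_airways: ImageVolume

    def __post_init__(self) -> None:
        ref = self.lungs
        for name in ("lungs", "gtv_itv", "ptv", "central_airways"):
            vol = getattr(self, name)
            if vol.role != "mask":
                raise ValueError(f"structure {name!r} must have role 'mask'")
            if not ref.same_grid(vol):
                raise ValueError(f"structure {name!r} is not on the reference grid")

    @property
    def grid(self) -> GridSpec:
        return self.lungs.grid


@dataclass
class RigidTransform:
    """Rigid motion ``x ↦ R x + t`` in world (mm) coordinates."""

    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float).reshape(3)
        if self.rotation.shape != (3, 3):
            raise ValueError("rotation must be 3x3")
        err = np.abs(self.rotation @ self.rotation.T - np.eye(3)).max()
        if err > 1e-8:
            raise ValueError(f"rotation is not orthonormal (max error {err:.2e})")
        if not np.isclose(np.linalg.det(self.rotation), 1.0, atol=1e-8):
            raise ValueError("rotation must be proper (determinant +1)")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls()

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        out = pts @ self.rotation.T + self.translation
        return out.reshape(np.shape(points))

    def inverse(self) -> "RigidTransform":
        rt = self.rotation.T
        return RigidTransform(rt, -rt @ self.translation)

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return the transform ``x ↦ self(other(x))``."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )


def _affine_from_geometry(spacing, origin) -> np.ndarray:
    aff = np.eye(4)
    aff[:3, :3] = np.diag(spacing)
    aff[:3, 3] = origin
    return aff


def read_volume(path: str | Path, role: str) -> ImageVolume:
    """Read a NIfTI-1 volume as an :class:`ImageVolume`.

    Spacing is recovered as the column norms of the affine and the origin
    as its translation column; oblique rotations are not represented on
    the axis-aligned grid model.  Mask roles are binarised at 0.5.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file: {path}")
    try:
        img = nib.load(str(path))
    except Exception as exc:  # pragma: no cover - nibabel error text varies
        raise IOError(f"could not read NIfTI file {path}: {exc}") from exc
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"expected a 3D NIfTI image, got {data.ndim}D: {path}")
    aff = img.affine
    spacing = tuple(float(np.linalg.norm(aff[:3, a])) for a in range(3))
    origin = tuple(float(v) for v in aff[:3, 3])
    if role == "mask":
        data = (data > 0.5).astype(np.uint8)
    else:
        data = np.asarray(data, dtype=np.float32)
    return ImageVolume(data=data, spacing=spacing, origin=origin, role=role)


def write_volume(volume: ImageVolume, path: str | Path) -> Path:
    """Write an :class:`ImageVolume` to NIfTI-1 (.nii or .nii.gz)."""
    path = Path(path)
    data = volume.data
    if volume.role == "mask":
        data = data.astype(np.uint8)
    else:
        data = data.astype(np.float32)
    img = nib.Nifti1Image(data, _affine_from_geometry(volume.spacing, volume.origin))
    nib.save(img, str(path))
    return path


def resample_to_grid(
    src: ImageVolume,
    target_geometry: GridSpec,
    transform: RigidTransform | None = None,
    interpolation: str | None = None,
) -> ImageVolume:
    """Resample ``src`` onto ``target_geometry`` under a rigid transform.

    ``transform`` maps source-world points into target-world points (the
    motion that aligns the moving image with the target frame).  Each
    target voxel centre is pulled back through the inverse transform and
    interpolated in the source; points outside the source extent get 0.

    Masks must use (and default to) nearest-neighbour interpolation so
    the output stays binary; scalar volumes default to trilinear.
    """
    if transform is None:
        transform = RigidTransform.identity()
    if interpolation is None:
        interpolation = "nearest" if src.role == "mask" else "trilinear"
    if interpolation not in ("trilinear", "nearest"):
        raise ValueError(f"unknown interpolation {interpolation!r}")
    if src.role == "mask" and interpolation != "nearest":
        raise ValueError("mask volumes must be resampled with nearest-neighbour")

    # Fast path: identity transform on an identical grid.
    if (
        np.allclose(transform.rotation, np.eye(3))
        and np.allclose(transform.translation, 0)
        and tuple(src.data.shape) == tuple(target_geometry.shape)
        and np.allclose(src.spacing, target_geometry.spacing)
        and np.allclose(src.origin, target_geometry.origin)
    ):
        return ImageVolume(
            src.data.copy(), target_geometry.spacing, target_geometry.origin, src.role
        )

    xs, ys, zs = GridSpec(
        target_geometry.shape, target_geometry.spacing, target_geometry.origin
    ).coordinate_grids()
    world = np.stack([xs, ys, zs], axis=-1).reshape(-1, 3)
    src_world = transform.inverse().apply(world)
    src_idx = src.grid.world_to_index(src_world).T  # (3, N)

    order = 1 if interpolation == "trilinear" else 0
    vals = map_coordinates(
        src.data.astype(float), src_idx, order=order, mode="constant", cval=0.0
    )
    out = vals.reshape(target_geometry.shape)
    if src.role == "mask":
        out = (out > 0.5).astype(np.uint8)
    return ImageVolume(
        out, target_geometry.spacing, target_geometry.origin, role=src.role
    )


def mask_volume_ml(mask: ImageVolume) -> float:
    """Physical volume (ml) of a binary mask: voxel count × voxel volume."""
    if mask.role != "mask":
        raise ValueError("mask_volume_ml requires a volume with role='mask'")
    vals = np.unique(mask.data)
    if not np.all(np.isin(vals, (0, 1))):
        raise ValueError("mask contains non-binary values")
    return float(np.count_nonzero(mask.data)) * mask.voxel_volume_ml
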