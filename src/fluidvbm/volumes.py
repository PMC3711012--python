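"""Grid data model, NIfTI-1 I/O and interpolation primitives.

Two containers underpin the whole package:

``ScalarVolume``
    a 3D scalar grid (probability map, t map, Jacobian map) with voxel size
    in mm and a world-space origin.  Voxel indices are 0-based; world
    coordinates in mm appear only at the I/O boundary and for fiducials.

``VectorField``
    three scalar grids of identical shape holding one vector per voxel, in
    voxel units.  The same container serves as a displacement field u (the
    warp, Eulerian convention: the deformed position of grid point x is
    x - u(x)), a velocity field v, a force field F or a perturbation field R.

All interpolation is trilinear.  Out-of-bounds samples read 0, the
background value of a probability map.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
from scipy.ndimage import map_coordinates


class DimensionError(ValueError):
    """Raised when grid shapes are incompatible or an input is not 3D."""


@dataclass
class ScalarVolume:
    """A 3D scalar grid with voxel-size metadata.

    Parameters
    ----------
    data : ndarray, shape (nx, ny, nz)
        Scalar values; cast to float64.
    voxel_size : array-like of 3 floats
        Voxel edge lengths in mm, all strictly positive.
    origin : array-like of 3 floats, optional
        World offset (mm) of voxel index (0, 0, 0).
    """

    data: np.ndarray
    voxel_size: np.ndarray = (1.0, 1.0, 1.0)
    origin: np.ndarray = (0.0, 0.0, 0.0)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise DimensionError(
                f"expected a 3D grid, got shape {self.data.shape}"
            )
        if min(self.data.shape) < 2:
            raise DimensionError(
                f"grid dimensions must be >= 2 along every axis, got {self.data.shape}"
            )
        self.voxel_size = np.asarray(self.voxel_size, dtype=np.float64).reshape(3)
        if not np.all(self.voxel_size > 0):
            raise ValueError(f"voxel_size must be strictly positive, got {self.voxel_size}")
        self.origin = np.asarray(self.origin, dtype=np.float64).reshape(3)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.voxel_size))

    def copy(self) -> "ScalarVolume":
        return ScalarVolume(self.data.copy(), self.voxel_size.copy(), self.origin.copy())

    def with_data(self, data: np.ndarray) -> "ScalarVolume":
        """New volume with the same geometry and different values."""
        return ScalarVolume(np.asarray(data), self.voxel_size.copy(), self.origin.copy())


@dataclass
class VectorField:
    """Three co-registered scalar grids holding one 3-vector per voxel.

    ``field`` has shape (3, nx, ny, nz); components are in voxel units.
    Finite everywhere by construction.
    """

    field: np.ndarray
    voxel_size: np.ndarray = (1.0, 1.0, 1.0)

    def __post_init__(self):
        self.field = np.asarray(self.field, dtype=np.float64)
        if self.field.ndim != 4 or self.field.shape[0] != 3:
            raise DimensionError(
                f"vector field must have shape (3, nx, ny, nz), got {self.field.shape}"
            )
        if not np.all(np.isfinite(self.field)):
            raise ValueError("vector field contains non-finite values")
        self.voxel_size = np.asarray(self.voxel_size, dtype=np.float64).reshape(3)

    @classmethod
    def zeros(cls, shape, voxel_size=(1.0, 1.0, 1.0)) -> "VectorField":
        return cls(np.zeros((3, *shape)), voxel_size)

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.field.shape[1:]

    def norms(self) -> np.ndarray:
        """Per-voxel Euclidean vector norm."""
        return np.sqrt(np.sum(self.field ** 2, axis=0))

    def max_norm(self) -> float:
        return float(self.norms().max())

    def copy(self) -> "VectorField":
        return VectorField(self.field.copy(), self.voxel_size.copy())


# The displacement field u and any sampled vector field (v, F, R) share one
# memory layout; the aliases keep call signatures self-documenting.
DisplacementField = VectorField
VectorFieldSample = VectorField


def _check_same_shape(a_shape, b_shape, what: str):
    if tuple(a_shape) != tuple(b_shape):
        raise DimensionError(f"{what}: shape {tuple(a_shape)} != {tuple(b_shape)}")


def load_volume(path) -> ScalarVolume:
    """Read a NIfTI-1 volume; the header voxel dimensions are authoritative.

    Raises ``FileNotFoundError`` for missing files and ``DimensionError``
    for non-3D images (e.g. 4D time series).
    """
    if not os.path.exists(path):
        raise FileNotFoundError(f"no such file: {path}")
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    data = np.squeeze(data) if data.ndim > 3 and all(s == 1 for s in data.shape[3:]) else data
    if data.ndim != 3:
        raise DimensionError(f"expected a 3D volume, file has shape {data.shape}")
    zooms = img.header.get_zooms()[:3]
    origin = np.asarray(img.affine[:3, 3], dtype=np.float64)
    return ScalarVolume(data.astype(np.float64), np.asarray(zooms), origin)


def save_volume(vol: ScalarVolume, path) -> None:
    """Write a ScalarVolume as single-file NIfTI-1 (.nii or .nii.gz)."""
    affine = np.diag([*vol.voxel_size, 1.0])
    affine[:3, 3] = vol.origin
    img = nib.Nifti1Image(vol.data.astype(np.float32), affine)
    img.header.set_zooms(tuple(vol.voxel_size))
    nib.save(img, str(path))


def save_displacement_field(u: VectorField, path, voxel_size=None) -> None:
    """Serialize a displacement field as a 4D NIfTI (3 volumes = components).

    Components are stored in voxel units; the Eulerian x - u(x) convention is
    recorded in the header description field.
    """
    vs = np.asarray(voxel_size if voxel_size is not None else u.voxel_size, dtype=float)
    affine = np.diag([*vs, 1.0])
    data = np.moveaxis(u.field, 0, -1).astype(np.float32)
    img = nib.Nifti1Image(data, affine)
    img.header["descrip"] = b"displacement u, voxel units, warp x -> x - u(x)"
    nib.save(img, str(path))


def load_displacement_field(path) -> VectorField:
    """Read a displacement field written by :func:`save_displacement_field`."""
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    data = np.squeeze(data)
    if data.ndim != 4 or data.shape[-1] != 3:
        raise DimensionError(f"expected a (nx, ny, nz, 3) field, got {data.shape}")
    return VectorField(np.moveaxis(data, -1, 0).astype(np.float64),
                       np.asarray(img.header.get_zooms()[:3]))


def resample_isotropic(vol: ScalarVolume, target_mm: float) -> ScalarVolume:
    """Reslice to isotropic voxels of ``target_mm`` by trilinear interpolation.

    The world-space field of view is preserved to within one voxel.  A volume
    already at the target resolution is returned value-identical.
    """
    t = float(target_mm)
    if t <= 0:
        raise ValueError(f"target_mm must be positive, got {target_mm}")
    old_shape = np.array(vol.shape)
    scale = vol.voxel_size / t
    new_shape = np.maximum(2, np.round(old_shape * scale).astype(int))
    # new voxel j sits at world j*t; old coordinate = j*t / old_voxel
    grids = np.meshgrid(*[np.arange(n) for n in new_shape], indexing="ij")
    coords = [g * (t / vs) for g, vs in zip(grids, vol.voxel_size)]
    data = map_coordinates(vol.data, coords, order=1, mode="constant", cval=0.0)
    return ScalarVolume(data, (t, t, t), vol.origin)


def sample_warped(vol: ScalarVolume, u: DisplacementField) -> ScalarVolume:
    """Warp ``vol`` by displacement ``u``: output[x] = vol(x - u(x)).

    Trilinear interpolation; coordinates outside the grid read 0
    (probability-map background).
    """
    _check_same_shape(vol.shape, u.grid_shape, "sample_warped")
    idx = np.indices(vol.shape, dtype=np.float64)
    coords = idx - u.field
    data = map_coordinates(vol.data, coords, order=1, mode="constant", cval=0.0)
    return vol.with_data(data)


def spatial_gradient(vol: ScalarVolume) -> VectorFieldSample:
    """Gradient in intensity-per-voxel units.

    Central differences in the interior, one-sided at the boundary faces.
    Exact on quadratics at interior voxels.
    """
    g = np.gradient(vol.data)
    return VectorFieldSample(np.stack(g), vol.voxel_size)
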