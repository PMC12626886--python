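"""Density volumes, rigid poses, missing-wedge models and MRC2014 I/O.

Conventions used throughout the package:

* lengths are Å; voxel size is isotropic;
* coordinate vectors are ordered like grid axes ``(axis0, axis1, axis2)``;
* the pore / symmetry axis is axis 2, the tomographic tilt axis is axis 1;
* rotations are 3x3 right-handed orthonormal matrices, optionally expressed
  as intrinsic ZYZ Euler angles in degrees ("Z" = axis 2, "Y" = axis 1);
* volumes are resampled with trilinear interpolation.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial.transform import Rotation

__all__ = [
    "DensityVolume",
    "Pose",
    "WedgeModel",
    "MRCFormatError",
    "ValidationError",
    "read_mrc",
    "write_mrc",
    "rotation_zyz",
    "euler_zyz",
    "rotation_about_axis2",
    "transform_volume",
    "wedge_mask",
    "apply_wedge",
    "rotate_fourier_mask",
    "lowpass",
]


class ValidationError(ValueError):
    """An input violates a documented precondition."""


class MRCFormatError(IOError):
    """The file is not a readable MRC2014 volume."""


# --------------------------------------------------------------------------
# core data types
# --------------------------------------------------------------------------

@dataclass
class DensityVolume:
    """A 3D intensity grid with physical voxel size and origin.

    ``origin`` is the physical position (Å) of the centre of voxel (0,0,0).
    """

    grid: np.ndarray
    voxel_size: float
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid)
        if self.grid.ndim != 3:
            raise ValidationError("grid must be a 3D array")
        if not np.all(np.isfinite(self.grid)):
            raise ValidationError("grid contains non-finite values")
        if not self.voxel_size > 0:
            raise ValidationError(f"voxel_size must be > 0, got {self.voxel_size}")
        self.origin = np.asarray(self.origin, dtype=float)
        if self.origin.shape != (3,):
            raise ValidationError("origin must be a 3-vector")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.grid.shape

    @property
    def is_cubic(self) -> bool:
        return len(set(self.grid.shape)) == 1

    def box_extent(self) -> np.ndarray:
        """Physical edge lengths of the box in Å."""
        return np.asarray(self.grid.shape, dtype=float) * self.voxel_size

    def copy(self) -> "DensityVolume":
        return DensityVolume(self.grid.copy(), self.voxel_size, self.origin.copy())

    def require_cubic(self) -> None:
        if not self.is_cubic:
            raise ValidationError(
                f"operation requires a cubic grid, got shape {self.grid.shape}"
            )

    def same_geometry(self, other: "DensityVolume", tol: float = 1e-6) -> bool:
        return self.grid.shape == other.grid.shape and abs(
            self.voxel_size - other.voxel_size
        ) <= tol * max(self.voxel_size, other.voxel_size)


def _snap(matrix: np.ndarray) -> np.ndarray:
    """Snap ~1e-16 trigonometric residue to exact 0/±1 so that on-grid
    rotations (multiples of 90°) resample without boundary artefacts."""
    out = np.where(np.abs(matrix) < 1e-12, 0.0, matrix)
    out = np.where(np.abs(np.abs(matrix) - 1.0) < 1e-12,
                   np.sign(matrix), out)
    return out


def rotation_zyz(phi: float, theta: float, psi: float) -> np.ndarray:
    """Rotation matrix for intrinsic ZYZ Euler angles in degrees."""
    return _snap(Rotation.from_euler("ZYZ", [phi, theta, psi],
                                     degrees=True).as_matrix())


def euler_zyz(matrix: np.ndarray) -> tuple[float, float, float]:
    """Inverse of :func:`rotation_zyz` (degrees); gimbal-locked poses
    (theta = 0 or 180) use the psi = 0 convention."""
    import warnings

    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="Gimbal lock")
        phi, theta, psi = Rotation.from_matrix(matrix).as_euler(
            "ZYZ", degrees=True)
    return float(phi), float(theta), float(psi)


def rotation_about_axis2(angle_deg: float) -> np.ndarray:
    """Right-handed rotation about the pore axis (axis 2)."""
    return _snap(Rotation.from_euler("Z", angle_deg, degrees=True).as_matrix())


@dataclass
class Pose:
    """Rigid transform: rotate about a reference centre, then shift (Å)."""

    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))
    shift: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.shift = np.asarray(self.shift, dtype=float)
        if self.rotation.shape != (3, 3):
            raise ValidationError("rotation must be 3x3")
        err = np.linalg.norm(self.rotation.T @ self.rotation - np.eye(3))
        if err > 1e-6:
            raise ValidationError(f"rotation is not orthonormal (|R'R-I|={err:.2e})")
        det = np.linalg.det(self.rotation)
        if abs(det - 1.0) > 1e-6:
            raise ValidationError(f"rotation must be proper (det={det:.6f})")
        if self.shift.shape != (3,):
            raise ValidationError("shift must be a 3-vector")

    @classmethod
    def identity(cls) -> "Pose":
        return cls()

    @classmethod
    def from_euler_zyz(cls, phi: float, theta: float, psi: float,
                       shift=(0.0, 0.0, 0.0)) -> "Pose":
        return cls(rotation_zyz(phi, theta, psi), np.asarray(shift, dtype=float))

    def euler_zyz(self) -> tuple[float, float, float]:
        return euler_zyz(self.rotation)

    def compose(self, other: "Pose") -> "Pose":
        """self applied after other."""
        return Pose(self.rotation @ other.rotation,
                    self.rotation @ other.shift + self.shift)

    def inverse(self) -> "Pose":
        rt = self.rotation.T
        return Pose(rt, -rt @ self.shift)

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Apply to (N,3) points about the origin."""
        return np.asarray(points) @ self.rotation.T + self.shift

    def angle_to(self, other: "Pose") -> float:
        """Residual rotation angle (degrees) between two poses."""
        r = self.rotation.T @ other.rotation
        c = np.clip((np.trace(r) - 1.0) / 2.0, -1.0, 1.0)
        return float(np.degrees(np.arccos(c)))

    def isclose(self, other: "Pose", rot_tol: float = 1e-6,
                shift_tol: float = 1e-6) -> bool:
        return (np.abs(self.rotation - other.rotation).max() < rot_tol
                and np.abs(self.shift - other.shift).max() < shift_tol)


@dataclass(frozen=True)
class WedgeModel:
    """Single-tilt-axis missing wedge, tilt axis along grid axis 1."""

    tilt_min: float
    tilt_max: float

    def __post_init__(self) -> None:
        if not (-90.0 < self.tilt_min < self.tilt_max < 90.0):
            raise ValidationError(
                f"need -90 < tilt_min < tilt_max < 90, got "
                f"({self.tilt_min}, {self.tilt_max})"
            )

    @property
    def is_full_range(self) -> bool:
        # (-90, 90) open interval cannot be represented exactly; treat a
        # span within float spacing of 180 as "no wedge"
        return self.tilt_max - self.tilt_min >= 180.0 - 1e-9


# --------------------------------------------------------------------------
# MRC2014 I/O (mode 2 only; minimal but standard-compliant)
# --------------------------------------------------------------------------

_HEADER_SIZE = 1024


def write_mrc(volume: DensityVolume, path) -> None:
    """Write a volume as MRC2014 mode 2 (little-endian float32).

    Grid axis 0 maps to MRC sections (Z), axis 2 to the fast axis (X).
    """
    grid = np.ascontiguousarray(volume.grid, dtype="<f4")
    n0, n1, n2 = grid.shape
    vx = float(volume.voxel_size)
    header = bytearray(_HEADER_SIZE)
    struct.pack_into("<3i", header, 0, n2, n1, n0)          # nx ny nz
    struct.pack_into("<i", header, 12, 2)                   # mode 2
    struct.pack_into("<3i", header, 28, n2, n1, n0)         # mx my mz
    struct.pack_into("<3f", header, 40, n2 * vx, n1 * vx, n0 * vx)  # cella
    struct.pack_into("<3f", header, 52, 90.0, 90.0, 90.0)   # cellb
    struct.pack_into("<3i", header, 64, 1, 2, 3)            # mapc mapr maps
    struct.pack_into("<3f", header, 76, float(grid.min()), float(grid.max()),
                     float(grid.mean()))
    struct.pack_into("<i", header, 88, 1)                   # ispg (volume)
    struct.pack_into("<3f", header, 196,
                     float(volume.origin[2]), float(volume.origin[1]),
                     float(volume.origin[0]))               # ORIGIN (x y z)
    header[208:212] = b"MAP "
    header[212:216] = bytes([0x44, 0x44, 0x00, 0x00])       # little-endian stamp
    struct.pack_into("<f", header, 216, float(grid.std()))
    with open(path, "wb") as fh:
        fh.write(bytes(header))
        fh.write(grid.tobytes())


def read_mrc(path) -> DensityVolume:
    """Read an MRC2014 mode-2 volume written by any standard tool."""
    with open(path, "rb") as fh:
        header = fh.read(_HEADER_SIZE)
        if len(header) < _HEADER_SIZE:
            raise MRCFormatError(
                f"truncated header: {len(header)} bytes < {_HEADER_SIZE}"
            )
        if header[208:212] not in (b"MAP ", b"MAP\x00"):
            raise MRCFormatError("missing 'MAP ' identifier at word 53")
        nx, ny, nz = struct.unpack_from("<3i", header, 0)
        mode, = struct.unpack_from("<i", header, 12)
        if mode != 2:
            raise MRCFormatError(
                f"unsupported MRC mode {mode}; only mode 2 (float32) is supported"
            )
        mx, my, mz = struct.unpack_from("<3i", header, 28)
        xlen, ylen, zlen = struct.unpack_from("<3f", header, 40)
        ox, oy, oz = struct.unpack_from("<3f", header, 196)
        nsymbt, = struct.unpack_from("<i", header, 92)
        if nsymbt:
            fh.read(nsymbt)
        n_values = nx * ny * nz
        data = np.frombuffer(fh.read(n_values * 4), dtype="<f4")
        if data.size != n_values:
            raise MRCFormatError(
                f"truncated data section: expected {n_values} values, "
                f"got {data.size}"
            )
    voxel = xlen / mx if mx else 1.0
    grid = data.reshape(nz, ny, nx)
    return DensityVolume(grid.copy(), float(voxel), np.array([oz, oy, ox]))


# --------------------------------------------------------------------------
# resampling and Fourier helpers
# --------------------------------------------------------------------------

def _volume_centre(shape) -> np.ndarray:
    return (np.asarray(shape, dtype=float) - 1.0) / 2.0


def transform_volume(grid: np.ndarray, rotation: np.ndarray,
                     shift_vox=(0.0, 0.0, 0.0)) -> np.ndarray:
    """Apply pose (rotation about the geometric centre, then shift in voxels).

    ``out(x) = in(R^T (x - c - t) + c)``, trilinear interpolation, zero fill.
    """
    r = np.asarray(rotation, dtype=float)
    t = np.asarray(shift_vox, dtype=float)
    c = _volume_centre(grid.shape)
    matrix = r.T
    offset = c - matrix @ (c + t)
    return ndimage.affine_transform(grid.astype(float, copy=False), matrix,
                                    offset=offset, order=1, mode="constant",
                                    cval=0.0, prefilter=False)


def transform_density(volume: DensityVolume, pose: Pose) -> DensityVolume:
    """Pose a :class:`DensityVolume`; pose shift is in Å."""
    out = transform_volume(volume.grid, pose.rotation,
                           pose.shift / volume.voxel_size)
    return DensityVolume(out, volume.voxel_size, volume.origin.copy())


def wedge_mask(shape, wedge: WedgeModel) -> np.ndarray:
    """Boolean sampled-region mask in ``np.fft.fftn`` layout.

    A component is *sampled* iff the signed angle of its (axis0, axis2)
    projection from the axis-2 direction lies within [tilt_min, tilt_max];
    the complement is the missing wedge. The mask is Friedel-symmetric.
    """
    f0 = np.fft.fftfreq(shape[0])[:, None, None]
    f2 = np.fft.fftfreq(shape[2])[None, None, :]
    ang = np.degrees(np.arctan2(f0, f2))
    ang = ((ang + 90.0) % 180.0) - 90.0          # fold to line orientation
    sampled = (ang >= wedge.tilt_min) & (ang <= wedge.tilt_max)
    sampled = sampled | ((f0 == 0) & (f2 == 0))  # tilt axis itself always seen
    sampled = np.broadcast_to(sampled, shape).copy()
    # Nyquist bins on even grids alias +/-0.5 and can break conjugate
    # symmetry for asymmetric tilt ranges; keep the inversion-symmetric core
    inv = np.ix_(*[(-np.arange(n)) % n for n in shape])
    return sampled & sampled[inv]


def apply_wedge(grid: np.ndarray, wedge: WedgeModel | None) -> np.ndarray:
    """Zero the Fourier components inside the missing wedge."""
    if wedge is None or wedge.is_full_range:
        return np.asarray(grid, dtype=float).copy()
    f = np.fft.fftn(grid)
    f[~wedge_mask(grid.shape, wedge)] = 0.0
    return np.fft.ifftn(f).real


def rotate_fourier_mask(mask: np.ndarray, rotation: np.ndarray) -> np.ndarray:
    """Rotate a Fourier-layout boolean mask about the DC component.

    Returns the support of a volume whose real-space copy was resampled by
    ``transform_volume(..., rotation)``.
    """
    shifted = np.fft.fftshift(mask).astype(float)
    c = np.array([n // 2 for n in mask.shape], dtype=float)
    matrix = np.asarray(rotation, dtype=float).T
    offset = c - matrix @ c
    rotated = ndimage.affine_transform(shifted, matrix, offset=offset, order=1,
                                       mode="constant", cval=0.0,
                                       prefilter=False)
    return np.fft.ifftshift(rotated > 0.5)


def lowpass(grid: np.ndarray, voxel_size: float,
            cutoff_angstrom: float | None) -> np.ndarray:
    """Sharp spherical low-pass at ``cutoff_angstrom`` (None = no filtering)."""
    if cutoff_angstrom is None:
        return np.asarray(grid, dtype=float).copy()
    if cutoff_angstrom <= 0:
        raise ValidationError("low-pass cutoff must be positive (Å)")
    freqs = np.meshgrid(*[np.fft.fftfreq(n, d=voxel_size) for n in grid.shape],
                        indexing="ij")
    radius = np.sqrt(sum(f ** 2 for f in freqs))
    f = np.fft.fftn(grid)
    f[radius > 1.0 / cutoff_angstrom] = 0.0
    return np.fft.ifftn(f).real
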