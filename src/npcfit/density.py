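"""Volumetric data model and Fourier-space primitives.

Conventions used throughout the package
---------------------------------------
* Grids are 3-D numpy arrays indexed ``values[i, j, k]`` with array axes
  0, 1, 2 corresponding to physical x, y, z.  The z axis (array axis 2)
  is the nucleocytoplasmic / C8 symmetry axis of all NPC phantoms.
* Voxels are cubes of edge ``voxel_size`` nanometres; the physical
  coordinate of voxel ``(i, j, k)`` is ``origin + voxel_size * (i, j, k)``
  (0-based indices, voxel-centre convention).
* Rotations are intrinsic ZYZ Euler angles in degrees (``Pose``); all
  geometric operations rotate about the physical centre of the grid and
  then translate.
* Trilinear interpolation is used for resampling; it is exact for
  identity and axis-permutation transforms.
"""

from __future__ import annotations

import copy as _copy
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial.transform import Rotation

__all__ = [
    "DensityMap",
    "WedgeDescriptor",
    "Pose",
    "MapFormatError",
    "read_map",
    "write_map",
    "lowpass_filter",
    "symmetrize",
    "transform_map",
    "apply_wedge",
    "wedge_mask",
    "fsc",
    "resolution_at",
]


class MapFormatError(ValueError):
    """Raised when a volume file header is inconsistent or unsupported."""


@dataclass
class DensityMap:
    """A 3-D scalar field on a regular grid with physical metadata.

    Parameters
    ----------
    values
        3-D array of densities.
    voxel_size
        Isotropic voxel edge length in nm (> 0).
    origin
        Physical position (nm) of the centre of voxel (0, 0, 0).
    meta
        Free-form provenance dictionary carried through operations.
    """

    values: np.ndarray
    voxel_size: float
    origin: np.ndarray = None  # type: ignore[assignment]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3 or min(self.values.shape) < 1:
            raise ValueError("values must be a 3-D grid with dimensions >= 1")
        if not np.isfinite(self.voxel_size) or self.voxel_size <= 0:
            raise ValueError(f"voxel_size must be > 0, got {self.voxel_size}")
        if self.origin is None:
            self.origin = np.zeros(3)
        self.origin = np.asarray(self.origin, dtype=float)

    # -- geometry helpers -------------------------------------------------
    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def center(self) -> np.ndarray:
        """Physical coordinate of the grid centre (rotation pivot)."""
        return self.origin + self.voxel_size * (np.array(self.shape) - 1) / 2.0

    @property
    def box_nm(self) -> np.ndarray:
        return self.voxel_size * np.array(self.shape)

    def physical_to_index(self, xyz: np.ndarray) -> np.ndarray:
        return (np.asarray(xyz, dtype=float) - self.origin) / self.voxel_size

    def index_to_physical(self, ijk: np.ndarray) -> np.ndarray:
        return self.origin + self.voxel_size * np.asarray(ijk, dtype=float)

    def copy(self) -> "DensityMap":
        return DensityMap(
            self.values.copy(), self.voxel_size, self.origin.copy(), _copy.deepcopy(self.meta)
        )

    def with_values(self, values: np.ndarray, **meta) -> "DensityMap":
        m = dict(self.meta)
        m.update(meta)
        return DensityMap(values, self.voxel_size, self.origin.copy(), m)


def centered_map(values: np.ndarray, voxel_size: float, **meta) -> DensityMap:
    """Grid whose physical centre is the coordinate origin."""
    origin = -voxel_size * (np.array(values.shape) - 1) / 2.0
    return DensityMap(values, voxel_size, origin, dict(meta))


def assert_same_grid(a: DensityMap, b: DensityMap) -> None:
    if a.shape != b.shape:
        raise ValueError(f"grid shape mismatch: {a.shape} vs {b.shape}")
    if not np.isclose(a.voxel_size, b.voxel_size, rtol=1e-6):
        raise ValueError(f"voxel size mismatch: {a.voxel_size} vs {b.voxel_size}")


@dataclass(frozen=True)
class WedgeDescriptor:
    """Missing-wedge geometry of single-axis tomography.

    The tilt axis lies in the specimen plane; the electron beam is along
    z.  Tilting from ``tilt_min`` to ``tilt_max`` degrees sweeps central
    sections through Fourier space, leaving a wedge-shaped unsampled
    region around the beam axis.
    """

    tilt_min: float
    tilt_max: float
    tilt_axis: int = 1

    def __post_init__(self) -> None:
        if not (-90 <= self.tilt_min < self.tilt_max <= 90):
            raise ValueError("require -90 <= tilt_min < tilt_max <= 90 degrees")
        if self.tilt_axis not in (0, 1, 2):
            raise ValueError("tilt_axis must be 0, 1 or 2")

    @property
    def is_full(self) -> bool:
        return self.tilt_min <= -90 and self.tilt_max >= 90

    def missing_fraction(self) -> float:
        """Analytic fraction of Fourier space inside the missing wedge."""
        return max(0.0, 180.0 - (self.tilt_max - self.tilt_min)) / 180.0


@dataclass(frozen=True)
class Pose:
    """Rigid-body transform: intrinsic ZYZ Euler rotation (degrees) about
    the grid centre, followed by a translation in nm."""

    euler_deg: tuple[float, float, float] = (0.0, 0.0, 0.0)
    translation: tuple[float, float, float] = (0.0, 0.0, 0.0)

    @staticmethod
    def identity() -> "Pose":
        return Pose()

    @staticmethod
    def from_matrix(R: np.ndarray, t=(0.0, 0.0, 0.0)) -> "Pose":
        import warnings as _w

        with _w.catch_warnings():
            # beta ~ 0 makes alpha/gamma degenerate; any representative is fine
            _w.simplefilter("ignore", UserWarning)
            ang = Rotation.from_matrix(R).as_euler("ZYZ", degrees=True)
        return Pose(tuple(float(a) for a in ang), tuple(float(x) for x in t))

    @property
    def rotation(self) -> Rotation:
        return Rotation.from_euler("ZYZ", self.euler_deg, degrees=True)

    @property
    def matrix(self) -> np.ndarray:
        return self.rotation.as_matrix()

    @property
    def t(self) -> np.ndarray:
        return np.asarray(self.translation, dtype=float)

    def compose(self, other: "Pose") -> "Pose":
        """``self.compose(other)`` applies ``other`` first, then ``self``."""
        R = self.matrix @ other.matrix
        t = self.matrix @ other.t + self.t
        return Pose.from_matrix(R, t)

    def inverse(self) -> "Pose":
        Rinv = self.matrix.T
        return Pose.from_matrix(Rinv, -Rinv @ self.t)

    def rotation_angle_deg(self) -> float:
        """Magnitude of the rotation (degrees)."""
        return float(np.degrees(self.rotation.magnitude()))


def rotation_distance_deg(a: Rotation | np.ndarray, b: Rotation | np.ndarray) -> float:
    """Geodesic angle between two rotations, degrees."""
    Ra = a if isinstance(a, Rotation) else Rotation.from_matrix(a)
    Rb = b if isinstance(b, Rotation) else Rotation.from_matrix(b)
    return float(np.degrees((Ra * Rb.inv()).magnitude()))


# ----------------------------------------------------------------------
# File I/O (MRC2014 / CCP4 mode-2 maps via gemmi; lengths stored in A)
# ----------------------------------------------------------------------

def write_map(dmap: DensityMap, path) -> None:
    """Write a map as MRC2014 mode-2 (float32), voxel size and origin in
    the header (internally in Angstrom; the API stays in nm)."""
    import gemmi

    m = gemmi.Ccp4Map()
    m.grid = gemmi.FloatGrid(np.ascontiguousarray(dmap.values, dtype=np.float32))
    n = dmap.shape
    a = dmap.voxel_size * 10.0  # nm -> A
    m.grid.unit_cell = gemmi.UnitCell(n[0] * a, n[1] * a, n[2] * a, 90, 90, 90)
    m.update_ccp4_header()
    for w, x in zip((50, 51, 52), dmap.origin):
        m.set_header_float(w, float(x) * 10.0)
    m.write_ccp4_map(str(path))


def read_map(path) -> DensityMap:
    import gemmi

    try:
        m = gemmi.read_ccp4_map(str(path))
    except (RuntimeError, ValueError) as exc:
        raise MapFormatError(f"cannot parse map header of {path}: {exc}") from exc
    values = np.array(m.grid, copy=True)
    sp = np.array(m.grid.spacing) / 10.0  # A -> nm
    if np.any(sp <= 0):
        raise MapFormatError(f"voxel_size must be positive, header gives {sp} nm")
    if not np.allclose(sp, sp[0], rtol=1e-4):
        raise MapFormatError(f"anisotropic voxel size {sp} nm is not supported")
    origin = np.array([m.header_float(w) for w in (50, 51, 52)]) / 10.0
    return DensityMap(values, float(sp[0]), origin)


# ----------------------------------------------------------------------
# Fourier-space filters
# ----------------------------------------------------------------------

def _freq_grids(shape, voxel_size):
    fx, fy, fz = (np.fft.fftfreq(n, d=voxel_size) for n in shape)
    return np.meshgrid(fx, fy, fz, indexing="ij", sparse=True)


def lowpass_filter(dmap: DensityMap, cutoff_nm: float) -> DensityMap:
    """Soft low-pass filter with a raised-cosine edge.

    The pass band is unity up to one frequency shell below the cutoff
    ``1 / cutoff_nm``; a half-cosine ramp brings the weight to exactly
    zero at the cutoff, so all power beyond the cutoff frequency is
    removed while ringing stays negligible.  The map mean (DC term) is
    preserved.
    """
    if cutoff_nm < 2 * dmap.voxel_size:
        raise ValueError(
            f"cutoff {cutoff_nm} nm is below the Nyquist limit "
            f"{2 * dmap.voxel_size} nm for voxel size {dmap.voxel_size} nm"
        )
    kx, ky, kz = _freq_grids(dmap.shape, dmap.voxel_size)
    f = np.sqrt(kx**2 + ky**2 + kz**2)
    fc = 1.0 / cutoff_nm
    width = 1.0 / (max(dmap.shape) * dmap.voxel_size)  # one frequency shell
    w = np.clip((fc - f) / width, 0.0, 1.0)
    w = 0.5 - 0.5 * np.cos(np.pi * w)
    out = np.fft.ifftn(np.fft.fftn(dmap.values) * w).real
    return dmap.with_values(out.astype(dmap.values.dtype, copy=False), lowpass_nm=cutoff_nm)


def wedge_mask(shape, wedge: WedgeDescriptor, rotation: np.ndarray | None = None) -> np.ndarray:
    """Boolean mask of the *sampled* Fourier region for a tilt wedge.

    ``rotation`` (3x3, real-space) optionally rotates the wedge, as needed
    when a particle has been resampled into a new frame; Fourier space
    rotates with real space.
    """
    if wedge.is_full and rotation is None:
        return np.ones(shape, dtype=bool)
    grids = _freq_grids(shape, 1.0)
    if rotation is not None:
        # rotating the data by R rotates its spectrum by R: the mask in the
        # new frame is the original mask evaluated at R^-1 k
        k = np.stack(np.broadcast_arrays(*grids), axis=-1) @ rotation  # R^T k
        comp = [k[..., i] for i in range(3)]
    else:
        comp = list(np.broadcast_arrays(*grids))
    beam = 2 if wedge.tilt_axis != 2 else 1
    spec = ({0, 1, 2} - {wedge.tilt_axis, beam}).pop()
    psi = np.degrees(np.arctan2(comp[beam], comp[spec]))
    psi = np.where(psi > 90.0, psi - 180.0, psi)
    psi = np.where(psi <= -90.0, psi + 180.0, psi)
    mask = (psi >= wedge.tilt_min) & (psi <= wedge.tilt_max)
    mask.flat[0] = True  # DC is always measured
    return mask


def apply_wedge(dmap: DensityMap, wedge: WedgeDescriptor,
                rotation: np.ndarray | None = None) -> DensityMap:
    """Zero the Fourier coefficients inside the missing wedge."""
    mask = wedge_mask(dmap.shape, wedge, rotation)
    out = np.fft.ifftn(np.fft.fftn(dmap.values) * mask).real
    return dmap.with_values(out.astype(dmap.values.dtype, copy=False))


# ----------------------------------------------------------------------
# Real-space geometry
# ----------------------------------------------------------------------

def transform_map(dmap: DensityMap, pose: Pose, order: int = 1) -> DensityMap:
    """Resample the map under a rigid-body pose.

    The object is rotated about the grid centre and then translated, i.e.
    ``out(x) = in(R^-1 (x - c - t) + c)``.  Trilinear interpolation,
    zero fill outside the grid.  The identity pose returns the input
    values exactly.
    """
    R = pose.matrix
    if np.allclose(R, np.eye(3)) and np.allclose(pose.t, 0):
        return dmap.copy()
    c = (np.array(dmap.shape) - 1) / 2.0  # centre in index units
    t_idx = pose.t / dmap.voxel_size
    Rinv = R.T
    offset = c - Rinv @ (c + t_idx)
    Rint, oint = np.rint(Rinv), np.rint(offset)
    if (np.allclose(Rinv, Rint, atol=1e-9) and np.allclose(offset, oint, atol=1e-9)
            and np.all(np.abs(Rint).sum(axis=1) == 1)):
        # lattice symmetry (axis permutation / flip + integer shift): index
        # directly so the result is exact, with no boundary round-off
        idx = np.indices(dmap.shape)
        src = np.einsum("ab,b...->a...", Rint.astype(int), idx) + oint.astype(int)[:, None, None, None]
        valid = np.all((src >= 0) & (src < np.array(dmap.shape)[:, None, None, None]), axis=0)
        out = np.zeros(dmap.shape, dtype=float)
        sv = tuple(np.clip(src[a], 0, dmap.shape[a] - 1) for a in range(3))
        out[valid] = dmap.values[sv][valid]
        return dmap.with_values(out.astype(dmap.values.dtype, copy=False))
    out = ndimage.affine_transform(
        dmap.values.astype(float, copy=False), Rinv, offset=offset, order=order,
        mode="constant", cval=0.0, prefilter=order > 1,
    )
    return dmap.with_values(out.astype(dmap.values.dtype, copy=False))


def rotate_about_axis(dmap: DensityMap, angle_deg: float, axis: int = 2,
                      order: int = 1) -> DensityMap:
    vec = np.zeros(3)
    vec[axis] = 1.0
    R = Rotation.from_rotvec(np.radians(angle_deg) * vec).as_matrix()
    return transform_map(dmap, Pose.from_matrix(R), order=order)


def symmetrize(dmap: DensityMap, order: int, axis: int = 2) -> DensityMap:
    """Impose C\\ :sub:`n` symmetry by averaging the ``order`` rotated
    copies about ``axis`` through the grid centre."""
    if int(order) < 1 or order != int(order):
        raise ValueError(f"symmetry order must be an integer >= 1, got {order}")
    order = int(order)
    if order == 1:
        return dmap.copy()
    acc = dmap.values.astype(float).copy()
    for k in range(1, order):
        acc += rotate_about_axis(dmap, 360.0 * k / order, axis=axis).values
    return dmap.with_values((acc / order).astype(dmap.values.dtype, copy=False),
                            symmetry=order)


# ----------------------------------------------------------------------
# Fourier shell correlation
# ----------------------------------------------------------------------

def _shell_index(shape):
    idx = [np.fft.fftfreq(n) * n for n in shape]  # integer frequency units
    kx, ky, kz = np.meshgrid(*idx, indexing="ij", sparse=True)
    r = np.sqrt(kx**2 + ky**2 + kz**2)
    return np.rint(r).astype(int)


def fsc(map_a: DensityMap, map_b: DensityMap) -> tuple[np.ndarray, np.ndarray]:
    """Fourier shell correlation between two maps on the same grid.

    Returns ``(freq, curve)`` where ``freq`` is the spatial frequency of
    each shell in nm^-1 and ``curve`` the normalized per-shell
    correlation in [-1, 1].  Shell 0 (DC) is included with value 1.
    """
    assert_same_grid(map_a, map_b)
    A = np.fft.fftn(map_a.values)
    B = np.fft.fftn(map_b.values)
    shell = _shell_index(map_a.shape)
    n_shell = min(map_a.shape) // 2 + 1
    sel = shell < n_shell
    s, a2, b2, ab = shell[sel], np.abs(A[sel]) ** 2, np.abs(B[sel]) ** 2, (A[sel] * np.conj(B[sel])).real
    num = np.bincount(s, weights=ab, minlength=n_shell)
    den = np.sqrt(np.bincount(s, weights=a2, minlength=n_shell)
                  * np.bincount(s, weights=b2, minlength=n_shell))
    with np.errstate(invalid="ignore", divide="ignore"):
        curve = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
    freq = np.arange(n_shell) / (min(map_a.shape) * map_a.voxel_size)
    return freq, np.clip(curve, -1.0, 1.0)


def resolution_at(curve: tuple[np.ndarray, np.ndarray], threshold: float = 0.143) -> float:
    """Resolution (nm) at the first crossing of the FSC curve below
    ``threshold``, linearly interpolated between shells.  Returns the
    Nyquist resolution if the curve never drops below the threshold."""
    freq, vals = curve
    for i in range(1, len(vals)):
        if vals[i] < threshold <= vals[i - 1]:
            f = freq[i - 1] + (freq[i] - freq[i - 1]) * (vals[i - 1] - threshold) / (
                vals[i - 1] - vals[i]
            )
            return float(1.0 / f)
    return float(1.0 / freq[-1])
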