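"""Volumetric grids, rigid world transforms, NIfTI I/O and probe-eye reformatting.

Conventions used throughout the package
---------------------------------------
* Voxel indices are 0-based and a voxel's world position is its **center**.
* The affine maps homogeneous voxel indices ``(i, j, k, 1)`` to world
  millimetres (RAS+ for everything the phantom generator writes).
* All distances, radii and arc lengths are world millimetres, which keeps the
  geometry exact on anisotropic grids (e.g. a 0.43 x 0.43 x 0.75 mm DSA grid).
* Samples that fall outside a volume read as background (0), so trajectories
  near the volume edge remain reviewable instead of raising.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage

from .errors import GeometryError, ParameterError, VolumeParseError

__all__ = [
    "VolumeGrid",
    "RigidTransform",
    "read_volume",
    "write_volume",
    "resample_to_reference",
    "probe_eye_slices",
    "ProbeEyeStack",
]


@dataclass
class VolumeGrid:
    """A 3D scalar field together with its voxel-to-world affine."""

    values: np.ndarray
    affine: np.ndarray
    modality_label: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise GeometryError(f"expected a 3D array, got ndim={self.values.ndim}")
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise GeometryError(f"affine must be 4x4, got {self.affine.shape}")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise GeometryError("affine is not invertible")

    # -- geometry ---------------------------------------------------------
    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def voxel_size(self) -> np.ndarray:
        """Physical voxel edge lengths in mm, one per axis."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    def voxel_to_world(self, indices: np.ndarray) -> np.ndarray:
        idx = np.atleast_2d(np.asarray(indices, dtype=float))
        pts = idx @ self.affine[:3, :3].T + self.affine[:3, 3]
        return pts if np.asarray(indices).ndim > 1 else pts[0]

    def world_to_voxel(self, points: np.ndarray) -> np.ndarray:
        inv = np.linalg.inv(self.affine)
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        idx = pts @ inv[:3, :3].T + inv[:3, 3]
        return idx if np.asarray(points).ndim > 1 else idx[0]

    def sample(self, points: np.ndarray, order: int = 1, cval: float = 0.0) -> np.ndarray:
        """Interpolate the field at world-mm points (out-of-field reads cval)."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        vox = self.world_to_voxel(pts)
        out = ndimage.map_coordinates(
            self.values.astype(float, copy=False), vox.T, order=order,
            mode="constant", cval=cval,
        )
        return out if np.asarray(points).ndim > 1 else float(out[0])

    def with_values(self, values: np.ndarray, modality_label: str | None = None) -> "VolumeGrid":
        return VolumeGrid(
            values,
            self.affine.copy(),
            self.modality_label if modality_label is None else modality_label,
        )


@dataclass
class RigidTransform:
    """A rigid world-mm to world-mm map stored as a 4x4 homogeneous matrix."""

    matrix: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (4, 4):
            raise GeometryError(f"transform must be 4x4, got {self.matrix.shape}")
        rot = self.matrix[:3, :3]
        if not np.allclose(rot @ rot.T, np.eye(3), atol=1e-6):
            raise GeometryError("rotation block is not orthonormal")
        if np.linalg.det(rot) < 0:
            raise GeometryError("rotation block has determinant -1 (reflection)")
        if not np.allclose(self.matrix[3], [0, 0, 0, 1], atol=1e-9):
            raise GeometryError("last row must be [0, 0, 0, 1]")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(4))

    @classmethod
    def from_rotation_translation(cls, rotation: np.ndarray, translation: np.ndarray) -> "RigidTransform":
        m = np.eye(4)
        m[:3, :3] = rotation
        m[:3, 3] = translation
        return cls(m)

    @classmethod
    def from_text(cls, path: str | Path) -> "RigidTransform":
        return cls(np.loadtxt(path).reshape(4, 4))

    def to_text(self, path: str | Path) -> None:
        np.savetxt(path, self.matrix, fmt="%.12g")

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        out = pts @ self.matrix[:3, :3].T + self.matrix[:3, 3]
        return out if np.asarray(points).ndim > 1 else out[0]

    def inverse(self) -> "RigidTransform":
        return RigidTransform(np.linalg.inv(self.matrix))


# ---------------------------------------------------------------------------
# NIfTI I/O
# ---------------------------------------------------------------------------

def read_volume(path: str | Path, modality_label: str = "") -> VolumeGrid:
    """Load a NIfTI-1 volume as a :class:`VolumeGrid`."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such volume: {path}")
    try:
        img = nib.load(str(path))
        values = np.asanyarray(img.dataobj)
        affine = img.affine
    except Exception as exc:  # nibabel raises several unrelated types
        raise VolumeParseError(f"cannot parse {path} as NIfTI-1: {exc}") from exc
    if affine is None:
        raise VolumeParseError(f"{path}: header carries no affine")
    return VolumeGrid(values, affine, modality_label or path.name)


def write_volume(vol: VolumeGrid, path: str | Path) -> None:
    """Write a :class:`VolumeGrid` as NIfTI-1 (.nii or .nii.gz)."""
    values = vol.values
    if values.dtype == bool:
        values = values.astype(np.uint8)
    img = nib.Nifti1Image(values, vol.affine)
    img.header.set_qform(vol.affine, code=1)
    img.header.set_sform(vol.affine, code=1)
    nib.save(img, str(path))


# ---------------------------------------------------------------------------
# Resampling
# ---------------------------------------------------------------------------

_INTERP_ORDER = {"nearest": 0, "linear": 1}


def resample_to_reference(
    moving: VolumeGrid,
    transform: RigidTransform,
    reference: VolumeGrid,
    interpolation: str = "linear",
) -> VolumeGrid:
    """Resample ``moving`` onto the grid of ``reference``.

    ``transform`` maps moving-world coordinates to reference-world
    coordinates (the direction a registration solver would report).  Masks
    should use ``interpolation='nearest'`` so they stay binary.
    """
    if interpolation not in _INTERP_ORDER:
        raise ParameterError(f"interpolation must be one of {sorted(_INTERP_ORDER)}")
    order = _INTERP_ORDER[interpolation]
    # output (reference) voxel index -> moving voxel index
    m = (
        np.linalg.inv(moving.affine)
        @ np.linalg.inv(transform.matrix)
        @ reference.affine
    )
    was_bool = moving.values.dtype == bool
    src = moving.values.astype(float, copy=False)
    out = ndimage.affine_transform(
        src, m[:3, :3], offset=m[:3, 3], output_shape=reference.shape,
        order=order, mode="constant", cval=0.0,
    )
    if was_bool:
        out = out > 0.5
    return VolumeGrid(out, reference.affine.copy(), moving.modality_label)


# ---------------------------------------------------------------------------
# Probe-eye view
# ---------------------------------------------------------------------------


@dataclass
class ProbeEyeStack:
    """Ordered stack of 2D planes orthogonal to a trajectory.

    ``planes[k]`` is sampled on an in-plane grid spanned by two unit vectors
    orthogonal to the local tangent; ``centers[k]`` lies on the trajectory.
    """

    planes: np.ndarray       # (K, n, n)
    centers: np.ndarray      # (K, 3) world mm
    tangents: np.ndarray     # (K, 3) unit vectors
    arc_lengths: np.ndarray  # (K,) mm from trajectory start
    pixel_size: float        # mm


def _polyline_point(traj: np.ndarray, cum: np.ndarray, s: float) -> tuple[np.ndarray, np.ndarray]:
    """Position and unit tangent at arc length ``s`` along a polyline."""
    s = min(max(s, 0.0), float(cum[-1]))
    seg = int(np.searchsorted(cum, s, side="right") - 1)
    seg = min(seg, len(traj) - 2)
    seg_len = cum[seg + 1] - cum[seg]
    t = (s - cum[seg]) / seg_len if seg_len > 0 else 0.0
    pos = traj[seg] * (1 - t) + traj[seg + 1] * t
    tangent = traj[seg + 1] - traj[seg]
    return pos, tangent / np.linalg.norm(tangent)


def probe_eye_slices(
    vol: VolumeGrid,
    trajectory: np.ndarray,
    step: float,
    fov: float,
    pixel_size: float | None = None,
    interpolation: str = "linear",
) -> ProbeEyeStack:
    """Reformat ``vol`` into slices perpendicular to a trajectory polyline.

    One plane is produced per ``step`` mm of arc length from the first to the
    last trajectory point (``floor(L / step) + 1`` planes).  The in-plane
    frame is parallel-transported along the trajectory so consecutive slices
    do not spin about the electrode axis.
    """
    traj = np.atleast_2d(np.asarray(trajectory, dtype=float))
    if traj.shape[0] < 2 or traj.shape[1] != 3:
        raise GeometryError("trajectory needs at least two 3D points")
    if step <= 0:
        raise ParameterError("step must be positive")
    if pixel_size is None:
        pixel_size = float(vol.voxel_size.min())
    if fov < float(vol.voxel_size.min()):
        raise ParameterError("fov is smaller than one voxel")
    order = _INTERP_ORDER[interpolation]

    seg_lens = np.linalg.norm(np.diff(traj, axis=0), axis=1)
    if np.any(seg_lens == 0):
        keep = np.concatenate([[True], seg_lens > 0])
        traj = traj[keep]
        seg_lens = np.linalg.norm(np.diff(traj, axis=0), axis=1)
        if traj.shape[0] < 2:
            raise GeometryError("trajectory is degenerate (zero length)")
    cum = np.concatenate([[0.0], np.cumsum(seg_lens)])
    total = float(cum[-1])
    n_planes = int(np.floor(total / step + 1e-9)) + 1

    n_pix = int(np.floor(fov / pixel_size)) + 1
    offsets = (np.arange(n_pix) - (n_pix - 1) / 2.0) * pixel_size

    planes = np.empty((n_planes, n_pix, n_pix))
    centers = np.empty((n_planes, 3))
    tangents = np.empty((n_planes, 3))
    arcs = np.arange(n_planes) * step

    u_prev: np.ndarray | None = None
    aa, bb = np.meshgrid(offsets, offsets, indexing="ij")
    for k in range(n_planes):
        pos, tangent = _polyline_point(traj, cum, float(arcs[k]))
        if u_prev is None:
            helper = np.eye(3)[np.argmin(np.abs(tangent))]
            u = np.cross(tangent, helper)
        else:
            u = u_prev - np.dot(u_prev, tangent) * tangent
            if np.linalg.norm(u) < 1e-9:
                helper = np.eye(3)[np.argmin(np.abs(tangent))]
                u = np.cross(tangent, helper)
        u = u / np.linalg.norm(u)
        v = np.cross(tangent, u)
        pts = pos + aa[..., None] * u + bb[..., None] * v
        planes[k] = vol.sample(pts.reshape(-1, 3), order=order).reshape(n_pix, n_pix)
        centers[k] = pos
        tangents[k] = tangent
        u_prev = u
    return ProbeEyeStack(planes, centers, tangents, arcs, pixel_size)
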