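"""Tubular-structure enhancement, vessel segmentation and distance geometry.

The extraction filter is the standard multiscale Hessian tube measure: at each
scale the image is smoothed with an anisotropy-aware Gaussian, the Hessian is
formed in world-mm units and scale-normalized, and a tube response built from
its eigenvalue ratios; the voxelwise maximum over scales is the vesselness.
Bright tubes on a darker background (contrast-filled vessels) require the two
large-magnitude eigenvalues to be negative.

The symmetric 3x3 eigenvalues are computed with a closed-form trigonometric
solver (vectorized over the whole volume); the unit tests check it against
``numpy.linalg.eigvalsh``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import NoVesselAtPointError, ParameterError
from .volume import VolumeGrid

__all__ = [
    "VesselSegmentation",
    "DistanceField",
    "vesselness_filter",
    "segment_vessels",
    "distance_field",
    "local_diameter",
]


# ---------------------------------------------------------------------------
# Closed-form symmetric 3x3 eigenvalues
# ---------------------------------------------------------------------------

def symmetric_eigenvalues(
    xx: np.ndarray, yy: np.ndarray, zz: np.ndarray,
    xy: np.ndarray, xz: np.ndarray, yz: np.ndarray,
) -> np.ndarray:
    """Eigenvalues of fields of symmetric 3x3 matrices, shape (..., 3), unsorted.

    Trigonometric closed form; numerically safe for (near-)isotropic matrices.
    """
    q = (xx + yy + zz) / 3.0
    p2 = (xx - q) ** 2 + (yy - q) ** 2 + (zz - q) ** 2 + 2.0 * (xy**2 + xz**2 + yz**2)
    p = np.sqrt(np.maximum(p2 / 6.0, 0.0))
    safe_p = np.where(p > 0, p, 1.0)
    bxx, byy, bzz = (xx - q) / safe_p, (yy - q) / safe_p, (zz - q) / safe_p
    bxy, bxz, byz = xy / safe_p, xz / safe_p, yz / safe_p
    # det(B)/2 for B = (A - qI)/p
    detb = (
        bxx * (byy * bzz - byz**2)
        - bxy * (bxy * bzz - byz * bxz)
        + bxz * (bxy * byz - byy * bxz)
    )
    r = np.clip(detb / 2.0, -1.0, 1.0)
    phi = np.arccos(r) / 3.0
    e1 = q + 2.0 * p * np.cos(phi)
    e3 = q + 2.0 * p * np.cos(phi + 2.0 * np.pi / 3.0)
    e2 = 3.0 * q - e1 - e3
    out = np.stack([e1, e2, e3], axis=-1)
    degenerate = p <= 0
    if np.any(degenerate):
        out[degenerate] = q[degenerate][..., None]
    return out


def _hessian_mm(img: np.ndarray, sigma_vox: np.ndarray, voxel_size: np.ndarray):
    """Six unique Hessian components of the Gaussian-smoothed image, mm units."""
    orders = {
        "xx": (2, 0, 0), "yy": (0, 2, 0), "zz": (0, 0, 2),
        "xy": (1, 1, 0), "xz": (1, 0, 1), "yz": (0, 1, 1),
    }
    scale_mm = {
        "xx": voxel_size[0] ** 2, "yy": voxel_size[1] ** 2, "zz": voxel_size[2] ** 2,
        "xy": voxel_size[0] * voxel_size[1],
        "xz": voxel_size[0] * voxel_size[2],
        "yz": voxel_size[1] * voxel_size[2],
    }
    return {
        key: ndimage.gaussian_filter(img, sigma_vox, order=order) / scale_mm[key]
        for key, order in orders.items()
    }


def vesselness_filter(
    vol: VolumeGrid,
    scales: list[float],
    alpha: float = 0.5,
    beta: float = 0.5,
    gamma: float | None = None,
    bright: bool = True,
) -> VolumeGrid:
    """Multiscale Hessian tube measure in [0, 1], maximum over scales.

    Parameters
    ----------
    scales
        Tube radii to probe, in mm.  Scales smaller than half the finest
        voxel dimension cannot be resolved and are dropped with a warning.
    alpha, beta
        Plate/blob discrimination constants of the tube measure.
    gamma
        Structure-sensitivity constant; defaults to half the volume's robust
        intensity range (0.1th-99.9th percentile).  Tying the constant to
        the intensity range rather than to the per-scale maximum Hessian
        norm keeps a featureless (noise-only) volume from normalizing its
        own noise into structure.
    """
    scales = [float(s) for s in scales]
    if not scales or any(s <= 0 for s in scales):
        raise ParameterError("at least one positive scale is required")
    voxel_size = vol.voxel_size
    min_scale = 0.5 * float(voxel_size.min())
    usable = []
    for s in scales:
        if s < min_scale:
            warnings.warn(
                f"scale {s} mm is below half a voxel ({min_scale} mm); dropped",
                stacklevel=2,
            )
        else:
            usable.append(s)
    if not usable:
        raise ParameterError("all scales are below half a voxel; nothing to compute")

    img = vol.values.astype(float, copy=False)
    # remove the DC level: the truncated second-derivative kernel does not
    # sum exactly to zero, so a constant offset would leak into the Hessian
    img = img - img.mean()
    response = np.zeros(vol.shape)
    polarity = -1.0 if bright else 1.0
    if gamma is None:
        lo_i, hi_i = np.percentile(img, [0.1, 99.9])
        gamma_used = 0.5 * float(hi_i - lo_i)
    else:
        gamma_used = float(gamma)
    for s in usable:
        sigma_vox = s / voxel_size
        h = _hessian_mm(img, sigma_vox, voxel_size)
        eig = symmetric_eigenvalues(h["xx"], h["yy"], h["zz"], h["xy"], h["xz"], h["yz"])
        eig *= s**2  # scale normalization
        order = np.argsort(np.abs(eig), axis=-1)
        eig = np.take_along_axis(eig, order, axis=-1)
        l1, l2, l3 = eig[..., 0], eig[..., 1], eig[..., 2]

        tube = (polarity * l2 > 0) & (polarity * l3 > 0)
        s2 = l1**2 + l2**2 + l3**2
        c = gamma_used
        if c <= 0:  # featureless volume
            continue
        with np.errstate(divide="ignore", invalid="ignore"):
            ra2 = (l2 / l3) ** 2
            rb2 = l1**2 / np.abs(l2 * l3)
            v = (
                (1.0 - np.exp(-ra2 / (2.0 * alpha**2)))
                * np.exp(-rb2 / (2.0 * beta**2))
                * (1.0 - np.exp(-s2 / (2.0 * c**2)))
            )
        v = np.where(tube, np.nan_to_num(v, nan=0.0), 0.0)
        np.maximum(response, v, out=response)
    return vol.with_values(np.clip(response, 0.0, 1.0), modality_label=f"vesselness({vol.modality_label})")


# ---------------------------------------------------------------------------
# Segmentation
# ---------------------------------------------------------------------------


@dataclass
class VesselSegmentation:
    """Binary vessel mask plus the vesselness (or normalized-intensity) map."""

    mask: VolumeGrid
    vesselness: VolumeGrid
    source_modality: str = ""
    threshold: float = float("nan")
    # lazy caches for distance-based measurements
    _inner_edt: np.ndarray | None = field(default=None, repr=False, compare=False)
    _nearest_idx: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.mask.values.dtype != bool:
            self.mask = self.mask.with_values(self.mask.values.astype(bool))


def segment_vessels(
    vesselness: VolumeGrid,
    threshold: float,
    min_component_voxels: int = 1,
    source_modality: str = "",
) -> VesselSegmentation:
    """Threshold a vesselness map and drop small connected components.

    An empty mask is a legal outcome (e.g. an avascular field of view).
    Components use 26-connectivity.
    """
    if not (0.0 < threshold <= 1.0):
        raise ParameterError("threshold must lie in (0, 1]")
    if min_component_voxels < 1:
        raise ParameterError("min_component_voxels must be >= 1")
    mask = vesselness.values >= threshold
    if min_component_voxels > 1 and mask.any():
        structure = ndimage.generate_binary_structure(3, 3)
        labels, n = ndimage.label(mask, structure=structure)
        if n:
            counts = np.bincount(labels.ravel())
            small = np.flatnonzero(counts < min_component_voxels)
            mask &= ~np.isin(labels, small[small > 0])
    return VesselSegmentation(
        mask=vesselness.with_values(mask, modality_label=f"mask({source_modality})"),
        vesselness=vesselness,
        source_modality=source_modality or vesselness.modality_label,
        threshold=threshold,
    )


# ---------------------------------------------------------------------------
# Distance field
# ---------------------------------------------------------------------------


@dataclass
class DistanceField:
    """Per-voxel Euclidean distance (mm) to the nearest segmented vessel voxel.

    ``empty`` flags a segmentation with no vessels; the field is then the
    +infinity sentinel everywhere and downstream profiles propagate the flag.
    """

    grid: VolumeGrid
    empty: bool = False

    def sample(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        if self.empty:
            out = np.full(pts.shape[0], np.inf)
        else:
            # outside the field of view there is no recorded vasculature
            out = np.asarray(
                ndimage.map_coordinates(
                    self.grid.values, self.grid.world_to_voxel(pts).T,
                    order=1, mode="nearest",
                )
            )
        return out if np.asarray(points).ndim > 1 else out[0]


def distance_field(seg: VesselSegmentation) -> DistanceField:
    """Exact anisotropy-aware Euclidean distance transform of the vessel mask."""
    mask = seg.mask.values
    if not mask.any():
        values = np.full(mask.shape, np.inf)
        return DistanceField(seg.mask.with_values(values, "distance"), empty=True)
    dist = ndimage.distance_transform_edt(~mask, sampling=seg.mask.voxel_size)
    return DistanceField(seg.mask.with_values(dist, "distance"), empty=False)


# ---------------------------------------------------------------------------
# Local diameter
# ---------------------------------------------------------------------------

_NEIGHBOR_OFFSETS = np.array(
    [(i, j, k) for i in (-1, 0, 1) for j in (-1, 0, 1) for k in (-1, 0, 1)
     if (i, j, k) != (0, 0, 0)]
)


def _ensure_diameter_caches(seg: VesselSegmentation) -> None:
    if seg._inner_edt is None:
        mask = seg.mask.values
        sampling = seg.mask.voxel_size
        seg._inner_edt = ndimage.distance_transform_edt(mask, sampling=sampling)
        _, idx = ndimage.distance_transform_edt(
            ~mask, sampling=sampling, return_indices=True
        )
        seg._nearest_idx = idx


def local_diameter(
    seg: VesselSegmentation,
    point: np.ndarray,
    capture_radius: float = 2.0,
) -> float:
    """Inscribed-sphere vessel diameter (mm) at a conflict site.

    Walks from the mask voxel nearest ``point`` uphill on the interior
    distance transform to the local medial ridge; the diameter is twice the
    inscribed radius there.  No boundary correction is applied: the EDT
    overshoots the true boundary (it measures to background voxel centers)
    by about as much as the ridge voxel center undershoots the true axis,
    and the two discretization errors cancel to well under a voxel.
    """
    if not seg.mask.values.any():
        raise NoVesselAtPointError("segmentation is empty")
    _ensure_diameter_caches(seg)
    inner = seg._inner_edt
    nearest = seg._nearest_idx
    assert inner is not None and nearest is not None

    vox = np.clip(
        np.round(seg.mask.world_to_voxel(np.asarray(point, dtype=float))).astype(int),
        0, np.array(seg.mask.shape) - 1,
    )
    if seg.mask.values[tuple(vox)]:
        start = vox
    else:
        start = nearest[:, vox[0], vox[1], vox[2]]
    start_world = seg.mask.voxel_to_world(start.astype(float))
    if np.linalg.norm(start_world - np.asarray(point, dtype=float)) > capture_radius:
        raise NoVesselAtPointError(
            f"no vessel within {capture_radius} mm of {np.asarray(point)}"
        )

    shape = np.array(seg.mask.shape)
    current = np.asarray(start, dtype=int)
    for _ in range(10_000):
        neigh = current + _NEIGHBOR_OFFSETS
        ok = np.all((neigh >= 0) & (neigh < shape), axis=1)
        neigh = neigh[ok]
        vals = inner[neigh[:, 0], neigh[:, 1], neigh[:, 2]]
        best = int(np.argmax(vals))
        if vals[best] <= inner[tuple(current)]:
            break
        current = neigh[best]
    radius = float(inner[tuple(current)])
    return max(2.0 * radius, float(seg.mask.voxel_size.min()))
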