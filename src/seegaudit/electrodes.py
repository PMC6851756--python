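"""Electrode contact localization, grouping and trajectory reconstruction.

Contacts appear as bright blobs on the post-implantation CT.  Each electrode
is reconstructed as a piecewise-linear chain through its ordered contact
centroids (depth electrodes bend only slightly, and only that bending is
honored — no spline).  The trajectory is extended proximally to the brain
entry point so that conflicts in the radiotransparent shaft region between
and above contacts are still audited, and the depth coordinate is the arc
length from the brain-mask entry.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
from scipy import ndimage

from .errors import GeometryError, ParameterError
from .volume import VolumeGrid

__all__ = [
    "Electrode",
    "TrajectorySample",
    "Trajectory",
    "segment_contacts",
    "group_into_electrodes",
    "interpolate_trajectory",
]

DEFAULT_ELECTRODE_RADIUS = 0.4  # mm, generic depth-electrode shaft radius


@dataclass
class Electrode:
    """Ordered contact centroids (tip first) plus the shaft radius in mm."""

    label: str
    contacts: np.ndarray  # (n, 3) world mm, tip first
    radius: float = DEFAULT_ELECTRODE_RADIUS

    def __post_init__(self) -> None:
        self.contacts = np.atleast_2d(np.asarray(self.contacts, dtype=float))
        if self.contacts.shape[0] < 2 or self.contacts.shape[1] != 3:
            raise GeometryError("an electrode needs at least two 3D contacts")
        spacing = np.linalg.norm(np.diff(self.contacts, axis=0), axis=1)
        if np.any(spacing <= 0):
            raise GeometryError("consecutive contacts must be distinct")
        if self.radius < 0:
            raise GeometryError("electrode radius cannot be negative")

    @property
    def polyline(self) -> np.ndarray:
        """The piecewise-linear chain through the contacts (tip first)."""
        return self.contacts

    @property
    def length(self) -> float:
        return float(np.linalg.norm(np.diff(self.contacts, axis=0), axis=1).sum())


class TrajectorySample(NamedTuple):
    position: np.ndarray          # world mm
    arc_length_from_entry: float  # mm; 0 at the first sample inside the brain
    tangent: np.ndarray           # unit vector, pointing tip-ward


@dataclass
class Trajectory:
    """Uniform arc-length samples along an electrode, entry to tip."""

    electrode: Electrode
    positions: np.ndarray    # (k, 3)
    arc_lengths: np.ndarray  # (k,) from brain entry
    tangents: np.ndarray     # (k, 3)
    entry_point: np.ndarray  # world mm, on the brain-mask boundary
    step: float

    def __iter__(self):
        for p, s, t in zip(self.positions, self.arc_lengths, self.tangents):
            yield TrajectorySample(p, float(s), t)

    def __len__(self) -> int:
        return len(self.arc_lengths)


# ---------------------------------------------------------------------------
# Contact segmentation
# ---------------------------------------------------------------------------

def segment_contacts(ct: VolumeGrid, intensity_threshold: float) -> np.ndarray:
    """Intensity-weighted centroids of supra-threshold components, world mm.

    Returns an (n, 3) array; empty when nothing exceeds the threshold (the
    caller decides whether that is an error).
    """
    above = ct.values > intensity_threshold
    if not above.any():
        return np.empty((0, 3))
    structure = ndimage.generate_binary_structure(3, 3)
    labels, n = ndimage.label(above, structure=structure)
    weights = np.where(above, ct.values.astype(float) - intensity_threshold, 0.0)
    coms = ndimage.center_of_mass(weights, labels, index=range(1, n + 1))
    return ct.voxel_to_world(np.asarray(coms, dtype=float))


# ---------------------------------------------------------------------------
# Grouping contacts into electrodes
# ---------------------------------------------------------------------------


def _line_residuals(points: np.ndarray, origin: np.ndarray, direction: np.ndarray) -> np.ndarray:
    rel = points - origin
    along = rel @ direction
    perp = rel - np.outer(along, direction)
    return np.linalg.norm(perp, axis=1)


def _fit_line(points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    centroid = points.mean(axis=0)
    _, _, vt = np.linalg.svd(points - centroid, full_matrices=False)
    return centroid, vt[0]


@dataclass
class GroupingResult:
    electrodes: list[Electrode]
    unassigned: np.ndarray  # (m, 3) centroids no line could claim


def group_into_electrodes(
    centroids: np.ndarray,
    expected_spacing: float,
    collinearity_tol: float = 1.0,
    brain_mask: VolumeGrid | None = None,
    label_prefix: str = "E",
) -> GroupingResult:
    """Partition contact centroids into regularly spaced collinear chains.

    Spacing-aware chain growing: every unclaimed centroid pair at roughly
    one contact spacing seeds a chain, which is extended in both directions
    by predicting the next contact one spacing ahead along the local
    direction (one missing contact may be skipped).  The longest chain is
    claimed first, and the process repeats until only isolated centroids
    remain — those are reported as unassigned, never silently dropped.
    Requiring candidates to sit in a predicted slot (within
    ``collinearity_tol``) makes the grouping robust to contacts of crossing
    electrodes that happen to lie near the line but off the contact grid.

    With ``brain_mask`` given, contacts are ordered tip first (the fully
    intracerebral end; the proximal end carries extracerebral contacts);
    otherwise ordering along the fitted axis is deterministic but arbitrary.
    """
    pts = np.atleast_2d(np.asarray(centroids, dtype=float))
    if pts.shape[0] < 2:
        raise ParameterError("need at least two centroids to group")
    if expected_spacing <= 0:
        raise ParameterError("expected_spacing must be positive")
    # contact centroids localize to a small fraction of a voxel, so the slot
    # tolerance can sit well below the contact spacing without losing bends
    slot_tol = max(0.5 * collinearity_tol, 0.1 * expected_spacing)

    def _grow(chain: list[int], claimed: set) -> list[int]:
        """Extend a chain at both ends by spacing-slot prediction."""
        for _end in (1, 0):
            while True:
                if _end:
                    p_prev, p_last = pts[chain[-2]], pts[chain[-1]]
                else:
                    p_prev, p_last = pts[chain[1]], pts[chain[0]]
                direction = p_last - p_prev
                direction = direction / np.linalg.norm(direction)
                found = None
                for mult in (1.0, 2.0):  # allow one missing contact
                    predicted = p_last + mult * expected_spacing * direction
                    cand = [
                        j for j in range(pts.shape[0])
                        if j not in claimed and j not in chain
                        and np.linalg.norm(pts[j] - predicted) <= slot_tol
                    ]
                    if cand:
                        dists = [np.linalg.norm(pts[j] - predicted) for j in cand]
                        found = cand[int(np.argmin(dists))]
                        break
                if found is None:
                    break
                chain.append(found) if _end else chain.insert(0, found)
        return chain

    claimed: set = set()
    groups: list[list[int]] = []
    while True:
        seeds = [
            (i, j)
            for i in range(pts.shape[0]) if i not in claimed
            for j in range(pts.shape[0]) if j > i and j not in claimed
            and abs(np.linalg.norm(pts[j] - pts[i]) - expected_spacing)
            <= 0.25 * expected_spacing
        ]
        best: list[int] = []
        for i, j in seeds:
            chain = _grow([i, j], claimed)
            if len(chain) > len(best):
                best = chain
        if len(best) < 2:
            break
        groups.append(best)
        claimed.update(best)
    remaining = [i for i in range(pts.shape[0]) if i not in claimed]

    electrodes = []
    depth = None
    if brain_mask is not None:
        depth_arr = ndimage.distance_transform_edt(
            brain_mask.values.astype(bool), sampling=brain_mask.voxel_size
        )
        depth = brain_mask.with_values(depth_arr)
    for gi, idxs in enumerate(groups):
        members = pts[idxs]
        origin, direction = _fit_line(members)
        along = (members - origin) @ direction
        members = members[np.argsort(along)]
        if depth is not None:
            depths = depth.sample(members, order=1)
            outside = depths <= 1e-6
            lead = int(np.argmax(~outside)) if not outside.all() else 0
            trail = int(np.argmax(~outside[::-1])) if not outside.all() else 0
            if lead != trail:
                # the proximal end carries contacts outside the brain mask
                # (the shaft continues through the skull); the tip end is
                # fully intracerebral and goes first
                if lead > trail:
                    members = members[::-1]
            else:
                # fall back: the tip half of the chain lies deeper than the
                # proximal half
                half = max(len(members) // 2, 1)
                if depths[:half].mean() < depths[-half:].mean():
                    members = members[::-1]
        elif tuple(members[0]) > tuple(members[-1]):
            members = members[::-1]
        electrodes.append(Electrode(f"{label_prefix}{gi:02d}", members))
    return GroupingResult(electrodes=electrodes, unassigned=pts[remaining])


# ---------------------------------------------------------------------------
# Trajectory interpolation
# ---------------------------------------------------------------------------


def interpolate_trajectory(
    electrode: Electrode,
    step: float,
    brain_mask: VolumeGrid,
    proximal_extension: float = 60.0,
) -> Trajectory:
    """Sample the electrode at uniform arc-length steps from brain entry to tip.

    The piecewise-linear contact chain is extended proximally (beyond the
    shallowest contact, along its segment direction) so the entry point on
    the brain-mask boundary is always part of the sampled path; arc length 0
    is the first sample inside the mask.
    """
    if step <= 0:
        raise ParameterError("step must be positive")
    chain = electrode.contacts[::-1]  # proximal -> tip
    prox_dir = chain[0] - chain[1]
    prox_dir = prox_dir / np.linalg.norm(prox_dir)
    extended = np.vstack([chain[0] + proximal_extension * prox_dir, chain])

    seg_lens = np.linalg.norm(np.diff(extended, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg_lens)])
    total = float(cum[-1])

    def point_at(s: np.ndarray) -> np.ndarray:
        return np.stack(
            [np.interp(s, cum, extended[:, d]) for d in range(3)], axis=-1
        )

    # locate the entry: first fine sample inside the brain mask
    fine = np.arange(0.0, total + 1e-9, min(step, float(brain_mask.voxel_size.min()) / 2.0))
    inside = brain_mask.sample(point_at(fine), order=0) > 0.5
    if not inside.any():
        raise GeometryError(f"electrode {electrode.label} lies entirely outside the brain mask")
    s_entry = float(fine[int(np.argmax(inside))])

    s_vals = np.arange(s_entry, total + 1e-9, step)
    positions = point_at(s_vals)
    seg_idx = np.clip(np.searchsorted(cum, s_vals, side="right") - 1, 0, len(seg_lens) - 1)
    tangents = np.diff(extended, axis=0)[seg_idx]
    tangents = tangents / np.linalg.norm(tangents, axis=1, keepdims=True)
    return Trajectory(
        electrode=electrode,
        positions=positions,
        arc_lengths=s_vals - s_entry,
        tangents=tangents,
        entry_point=point_at(np.array([s_entry]))[0],
        step=step,
    )
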