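"""Seed-reproducible multi-modal phantoms with a ground-truth conflict manifest.

The phantom emulates the data structure of a multi-modal SEEG vascular audit
without any patient data:

* a spherical brain with a sinusoidally folded cortical sheet, so the gyral
  crown, sulcal depths and gray/white boundaries are known in closed form;
* a vascular bed of capsule segments (bifurcating trees, Murray-law radius
  decay) whose diameters follow a lognormal law concentrated around
  1-1.5 mm, with smaller calibers biased into the sulcal depths;
* modality volumes that render a vessel only when its diameter reaches that
  modality's visibility threshold (the DSA-like channel sees the smallest
  vessels, the T1+Gad-like channel only the largest);
* electrodes planted so that their straight trajectories pass through chosen
  vessels at drawn depths (median 31 mm from the cortical surface), rendered
  as bright contact blobs on a CT-like volume;
* a manifest listing *every* electrode-vessel conflict — planted and
  incidental — each checkable by analytic point-to-segment geometry.

All randomness flows through one seeded generator; identical specs and seeds
give bit-identical volumes and manifests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np

from .electrodes import Electrode
from .errors import InfeasibleTrajectoryError, ParameterError, PhantomSizingError
from .volume import VolumeGrid, write_volume

__all__ = [
    "PhantomSpec",
    "VesselSegment",
    "PlantedConflict",
    "GroundTruth",
    "Phantom",
    "generate_phantom",
    "plant_conflicting_electrode",
    "write_phantom",
]

MODALITIES = ("dsa", "mrv", "t1_gad")


# ---------------------------------------------------------------------------
# Specification
# ---------------------------------------------------------------------------


def sample_law(law: tuple, rng: np.random.Generator, size: int) -> np.ndarray:
    """Draw from a named scalar law: lognormal (median+iqr or mu+sigma),
    uniform, or constant."""
    name, params = law
    if name == "lognormal":
        if "mu" in params:
            mu, sigma = float(params["mu"]), float(params["sigma"])
        else:
            mu = np.log(float(params["median"]))
            lo, hi = params["iqr"]
            # IQR ratio pins sigma: ln(q75/q25) = 2 * 0.6745 * sigma
            sigma = np.log(hi / lo) / (2.0 * 0.6744897501960817)
        return rng.lognormal(mu, sigma, size)
    if name == "uniform":
        return rng.uniform(float(params["low"]), float(params["high"]), size)
    if name == "constant":
        return np.full(size, float(params["value"]))
    raise ParameterError(f"unknown law {name!r}")


@dataclass
class PhantomSpec:
    """Study conditions for one synthetic phantom."""

    grid_shape: tuple[int, int, int] = (128, 128, 128)
    voxel_size: tuple[float, float, float] = (0.5, 0.5, 0.5)
    n_vessels: int = 40
    # vessel *diameter* law, mm (the quantity whose median the study reports)
    radius_law: tuple = ("lognormal", {"median": 1.3, "iqr": (1.0, 1.5)})
    modality_visibility: dict = field(
        default_factory=lambda: {"dsa": 0.5, "mrv": 2.0, "t1_gad": 2.5}
    )
    n_electrodes: int = 10
    contacts_per_electrode: int = 12  # maximum; shallow trajectories carry fewer
    contact_spacing: float = 5.0  # mm
    fold_wavelength: float = 12.0  # mm along the surface
    fold_amplitude: float = 6.0    # mm sulcal depth below the gyral crown
    noise_sd: float = 2.0          # intensity units (vessel contrast = 100)
    seed: int = 0

    # secondary structure
    brain_radius: Optional[float] = None   # mm; default 0.875 * half-extent
    cortical_thickness: float = 3.0        # mm
    n_folds: Optional[int] = None          # None = folds over the whole sphere
    electrode_radius: float = 0.4          # mm shaft radius
    conflicts_per_electrode: int = 1
    depth_law: tuple = ("lognormal", {"median": 31.0, "iqr": (14.3, 45.0)})
    sulcal_fraction: float = 0.5           # vessels seeded into the sulcal depths
    sulcal_caliber_cap: float = 1.25       # mm; sulcal vessels are usually smaller
    electrode_separation: float = 2.5      # mm minimum between trajectory axes
    min_tip_depth: float = 2.5             # mm below the surface; no grazing chords
    bifurcation_levels: int = 1
    radius_decay: float = 0.79             # Murray-law cube-root per generation
    vessel_intensity: float = 100.0
    contact_intensity: float = 1000.0
    ct_noise_sd: float = 1.0
    tip_overshoot: float = 3.0             # mm of shaft beyond the deepest conflict
    dsa_dilation_mm: float = 0.0           # emulated extraction-filter dilation

    def __post_init__(self) -> None:
        self.grid_shape = tuple(int(s) for s in self.grid_shape)
        if np.isscalar(self.voxel_size):
            self.voxel_size = (float(self.voxel_size),) * 3
        self.voxel_size = tuple(float(v) for v in self.voxel_size)
        self.validate()

    def validate(self) -> None:
        if len(self.grid_shape) != 3 or any(s < 32 for s in self.grid_shape):
            raise ParameterError("grid_shape must be at least 32 voxels per axis")
        if any(v <= 0 for v in self.voxel_size):
            raise ParameterError("voxel_size must be positive")
        if self.contact_spacing <= 0:
            raise ParameterError("contact_spacing must be positive")
        if self.contacts_per_electrode < 2:
            raise ParameterError("an electrode needs at least two contacts")
        vis = self.modality_visibility
        if any(t <= 0 for t in vis.values()):
            raise ParameterError("visibility thresholds must be positive")
        if "dsa" in vis and vis["dsa"] != min(vis.values()):
            raise ParameterError(
                "the DSA-like modality must see the smallest vessels "
                "(its visibility threshold must be the minimum)"
            )
        extent = np.array(self.grid_shape) * np.array(self.voxel_size)
        chain = (self.contacts_per_electrode - 1) * self.contact_spacing
        if chain + self.tip_overshoot > float(np.linalg.norm(extent)):
            raise PhantomSizingError(
                f"electrode span {chain + self.tip_overshoot:.1f} mm exceeds the "
                f"grid diagonal {np.linalg.norm(extent):.1f} mm; enlarge the grid "
                "or reduce contacts_per_electrode x contact_spacing"
            )
        if self.brain_radius is not None and self.brain_radius >= extent.min() / 2:
            raise PhantomSizingError(
                f"brain_radius {self.brain_radius} mm does not fit inside the "
                f"grid half-extent {extent.min() / 2:.1f} mm"
            )

    @property
    def resolved_brain_radius(self) -> float:
        if self.brain_radius is not None:
            return float(self.brain_radius)
        # 25% margin keeps skull and extracerebral contact blobs on the grid
        extent = np.array(self.grid_shape) * np.array(self.voxel_size)
        return 0.75 * float(extent.min()) / 2.0

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PhantomSpec":
        d = dict(d)
        for key in ("radius_law", "depth_law"):
            if key in d and isinstance(d[key], (list, tuple)):
                name, params = d[key]
                d[key] = (name, dict(params))
        if "grid_shape" in d:
            d["grid_shape"] = tuple(d["grid_shape"])
        return cls(**d)


# ---------------------------------------------------------------------------
# Ground truth
# ---------------------------------------------------------------------------


@dataclass
class VesselSegment:
    start: np.ndarray    # world mm
    end: np.ndarray      # world mm
    radius: float        # geometric radius, mm
    visibility: dict     # modality -> bool (diameter >= threshold)

    @property
    def diameter(self) -> float:
        return 2.0 * self.radius

    def axis_distance(self, points: np.ndarray) -> np.ndarray:
        """Euclidean distance from world points to the segment axis."""
        p = np.atleast_2d(np.asarray(points, dtype=float))
        d = self.end - self.start
        len2 = float(d @ d)
        t = np.clip((p - self.start) @ d / len2, 0.0, 1.0) if len2 > 0 else np.zeros(p.shape[0])
        closest = self.start + t[:, None] * d
        out = np.linalg.norm(p - closest, axis=1)
        return out if np.asarray(points).ndim > 1 else out[0]


@dataclass
class PlantedConflict:
    electrode_label: str
    position: np.ndarray  # world mm, on the electrode axis at closest approach
    vessel_radius: float  # mm
    vessel_diameter: float  # mm
    depth: float          # mm from the brain-mask entry along the trajectory
    in_sulcus: bool
    visible_in: dict      # modality -> bool
    planted: bool = True  # False for incidental crossings found by geometry


@dataclass
class GroundTruth:
    vessel_segments: list[VesselSegment] = field(default_factory=list)
    planted_conflicts: list[PlantedConflict] = field(default_factory=list)

    def conflict_positions(self) -> np.ndarray:
        if not self.planted_conflicts:
            return np.empty((0, 3))
        return np.array([c.position for c in self.planted_conflicts])

    def to_json(self, path: str | Path) -> None:
        payload = {
            "vessel_segments": [
                {
                    "start": np.asarray(s.start).tolist(),
                    "end": np.asarray(s.end).tolist(),
                    "radius": s.radius,
                    "visibility": s.visibility,
                }
                for s in self.vessel_segments
            ],
            "planted_conflicts": [
                {
                    "electrode": c.electrode_label,
                    "position": np.asarray(c.position).tolist(),
                    "vessel_radius": c.vessel_radius,
                    "vessel_diameter": c.vessel_diameter,
                    "depth": c.depth,
                    "in_sulcus": c.in_sulcus,
                    "visible_in": c.visible_in,
                    "planted": c.planted,
                }
                for c in self.planted_conflicts
            ],
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        payload = json.loads(Path(path).read_text())
        segs = [
            VesselSegment(
                np.array(s["start"]), np.array(s["end"]), s["radius"], s["visibility"]
            )
            for s in payload["vessel_segments"]
        ]
        conflicts = [
            PlantedConflict(
                c["electrode"], np.array(c["position"]), c["vessel_radius"],
                c["vessel_diameter"], c["depth"], c["in_sulcus"], c["visible_in"],
                c.get("planted", True),
            )
            for c in payload["planted_conflicts"]
        ]
        return cls(segs, conflicts)


@dataclass
class Phantom:
    spec: PhantomSpec
    masks: dict           # brain / gm / wm / skull -> VolumeGrid (bool)
    modalities: dict      # modality -> VolumeGrid
    electrodes_ct: VolumeGrid
    electrodes: list[Electrode]
    entries: dict         # electrode label -> entry point on the brain surface
    truth: GroundTruth


# ---------------------------------------------------------------------------
# Geometry helpers (closed-form cortical sheet)
# ---------------------------------------------------------------------------


class _SphereModel:
    """Analytic description of the folded cortical sheet."""

    def __init__(self, spec: PhantomSpec):
        self.radius = spec.resolved_brain_radius
        self.thickness = spec.cortical_thickness
        self.amplitude = spec.fold_amplitude
        self.wavelength = spec.fold_wavelength
        self.n_folds = spec.n_folds

    def pial_radius(self, theta: np.ndarray) -> np.ndarray:
        """Radius of the pial (outer GM) surface at polar angle theta."""
        arc = self.radius * np.asarray(theta, dtype=float)
        phase = 2.0 * np.pi * arc / self.wavelength
        fold = 0.5 * self.amplitude * (1.0 - np.cos(phase))
        if self.n_folds is not None:
            fold = np.where(arc <= self.n_folds * self.wavelength, fold, 0.0)
        return self.radius - fold

    def classify(self, points: np.ndarray):
        """Return (rho, in_gm, in_sulcal) for world points."""
        p = np.atleast_2d(np.asarray(points, dtype=float))
        rho = np.linalg.norm(p, axis=1)
        with np.errstate(invalid="ignore"):
            theta = np.arccos(np.clip(np.divide(p[:, 2], np.where(rho > 0, rho, 1.0)), -1, 1))
        rp = self.pial_radius(theta)
        in_gm = (rho <= rp) & (rho > rp - self.thickness)
        in_sulcal = in_gm & ((self.radius - rho) > self.thickness)
        return rho, in_gm, in_sulcal


def _center_affine(spec: PhantomSpec) -> np.ndarray:
    vox = np.asarray(spec.voxel_size)
    shape = np.asarray(spec.grid_shape)
    affine = np.diag([*vox, 1.0])
    affine[:3, 3] = -(shape - 1) / 2.0 * vox  # world origin at the grid center
    return affine


def _rasterize_capsule(
    values: np.ndarray,
    affine: np.ndarray,
    start: np.ndarray,
    end: np.ndarray,
    radius: float,
    intensity: float,
) -> None:
    """Additively render a capsule (max-composited, antialiased edge)."""
    vox = np.diag(affine)[:3]
    origin = affine[:3, 3]
    lo_w = np.minimum(start, end) - (radius + 2.0 * vox.max())
    hi_w = np.maximum(start, end) + (radius + 2.0 * vox.max())
    lo = np.maximum(np.floor((lo_w - origin) / vox).astype(int), 0)
    hi = np.minimum(np.ceil((hi_w - origin) / vox).astype(int) + 1, values.shape)
    if np.any(lo >= hi):
        return
    grids = np.meshgrid(
        *(origin[a] + vox[a] * np.arange(lo[a], hi[a]) for a in range(3)),
        indexing="ij",
    )
    pts = np.stack(grids, axis=-1)
    d = end - start
    len2 = float(d @ d)
    rel = pts - start
    if len2 > 0:
        t = np.clip(np.tensordot(rel, d, axes=([-1], [0])) / len2, 0.0, 1.0)
        closest = start + t[..., None] * d
    else:
        closest = np.broadcast_to(start, pts.shape)
    dist = np.linalg.norm(pts - closest, axis=-1)
    edge = float(vox.mean())
    coverage = np.clip((radius - dist) / edge + 0.5, 0.0, 1.0)
    patch = values[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
    np.maximum(patch, coverage * intensity, out=patch)


def _rasterize_blob(
    values: np.ndarray, affine: np.ndarray, center: np.ndarray,
    sigma: float, intensity: float,
) -> None:
    vox = np.diag(affine)[:3]
    origin = affine[:3, 3]
    half = 4.0 * sigma
    lo = np.maximum(np.floor((center - half - origin) / vox).astype(int), 0)
    hi = np.minimum(np.ceil((center + half - origin) / vox).astype(int) + 1, values.shape)
    if np.any(lo >= hi):
        return
    grids = np.meshgrid(
        *(origin[a] + vox[a] * np.arange(lo[a], hi[a]) for a in range(3)),
        indexing="ij",
    )
    pts = np.stack(grids, axis=-1)
    d2 = np.sum((pts - center) ** 2, axis=-1)
    patch = values[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
    np.maximum(patch, intensity * np.exp(-d2 / (2.0 * sigma**2)), out=patch)


# ---------------------------------------------------------------------------
# Vessel trees
# ---------------------------------------------------------------------------


def _visibility(diameter: float, spec: PhantomSpec) -> dict:
    return {m: bool(diameter >= t) for m, t in sorted(spec.modality_visibility.items())}


def _random_tangent(direction: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    v -= np.dot(v, direction) * direction
    n = np.linalg.norm(v)
    while n < 1e-9:
        v = rng.normal(size=3)
        v -= np.dot(v, direction) * direction
        n = np.linalg.norm(v)
    return v / n


def _grow_tree(
    start: np.ndarray,
    direction: np.ndarray,
    length: float,
    radius: float,
    levels: int,
    spec: PhantomSpec,
    rng: np.random.Generator,
    model: _SphereModel,
    out: list[VesselSegment],
) -> None:
    max_rho = model.radius - 0.5
    end = start + length * direction
    if np.linalg.norm(end) > max_rho:
        # shorten to stay intracerebral
        lo, hi = 0.0, length
        for _ in range(40):
            mid = 0.5 * (lo + hi)
            if np.linalg.norm(start + mid * direction) > max_rho:
                hi = mid
            else:
                lo = mid
        length = lo
        end = start + length * direction
    if length < 2.0:
        return
    out.append(VesselSegment(start.copy(), end.copy(), radius, _visibility(2 * radius, spec)))
    if levels <= 0:
        return
    for _ in range(2):
        angle = np.deg2rad(rng.uniform(20.0, 50.0))
        axis = _random_tangent(direction, rng)
        child_dir = np.cos(angle) * direction + np.sin(angle) * axis
        child_dir /= np.linalg.norm(child_dir)
        _grow_tree(
            end, child_dir, length * 0.7, radius * spec.radius_decay,
            levels - 1, spec, rng, model, out,
        )


def _seed_vessels(spec: PhantomSpec, rng: np.random.Generator, model: _SphereModel) -> list[VesselSegment]:
    segments: list[VesselSegment] = []
    radius = model.radius
    thickness = model.thickness
    for _ in range(spec.n_vessels):
        sulcal = rng.uniform() < spec.sulcal_fraction
        diameter = float(sample_law(spec.radius_law, rng, 1)[0])
        if sulcal:
            diameter = min(diameter, spec.sulcal_caliber_cap)
        # radial band: sulcal/medullary vessels run deep below the crown
        # (which is where deep conflicts happen), cortical ones hug it
        if sulcal:
            rho0 = rng.uniform(0.35 * radius, radius - thickness)
        else:
            rho0 = rng.uniform(radius - thickness - 1.0, radius - 1.0)
        direction_r = _random_unit(rng)
        start = rho0 * direction_r
        tangent = _random_tangent(direction_r, rng)
        # mostly surface-parallel course with a mild radial component
        course = tangent + rng.uniform(-0.3, 0.3) * direction_r
        course /= np.linalg.norm(course)
        length = rng.uniform(10.0, 25.0)
        _grow_tree(
            start, course, length, diameter / 2.0,
            spec.bifurcation_levels, spec, rng, model, segments,
        )
    return segments


def _random_unit(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    n = np.linalg.norm(v)
    while n < 1e-12:
        v = rng.normal(size=3)
        n = np.linalg.norm(v)
    return v / n


# ---------------------------------------------------------------------------
# Electrode planting
# ---------------------------------------------------------------------------


def _mask_entry_depth(
    brain: VolumeGrid, point: np.ndarray, direction: np.ndarray, max_back: float = 120.0
) -> tuple[np.ndarray, float]:
    """March backwards from ``point`` along ``-direction`` to the mask entry.

    Returns (entry point, arc length from entry to ``point``).  The crossing
    is refined by bisection to 0.01 mm.
    """
    step = 0.5 * float(brain.voxel_size.min())
    s_vals = np.arange(0.0, max_back + step, step)
    pts = point - s_vals[:, None] * direction
    inside = brain.sample(pts, order=0) > 0.5
    if not inside[0]:
        raise InfeasibleTrajectoryError("conflict point lies outside the brain mask")
    if inside.all():
        raise InfeasibleTrajectoryError("trajectory never exits the brain mask")
    first_out = int(np.argmin(inside))
    lo, hi = s_vals[first_out - 1], s_vals[first_out]  # inside at lo, outside at hi
    for _ in range(30):
        mid = 0.5 * (lo + hi)
        if brain.sample(point - mid * direction, order=0) > 0.5:
            lo = mid
        else:
            hi = mid
    depth = 0.5 * (lo + hi)
    return point - depth * direction, float(depth)


def plant_conflicting_electrode(
    truth: GroundTruth,
    masks: dict,
    target_vessel: int,
    spec: PhantomSpec,
    rng: np.random.Generator | None = None,
    label: str = "E00",
    max_tries: int = 400,
) -> tuple[Electrode, np.ndarray, PlantedConflict]:
    """Plant a straight electrode whose axis crosses the target vessel axis.

    The conflict point P is drawn on the vessel axis; the conflict depth is
    drawn from the spec's depth law; the electrode direction is solved on
    the cone of directions whose brain-surface entry lies exactly that far
    from P (a spherical-brain construction, then refined against the actual
    mask by marching).  Returns the electrode, its entry point and the
    manifest record; the caller appends both to the phantom.

    Raises :class:`InfeasibleTrajectoryError` when the vessel lies outside
    the brain mask or no compatible straight path exists.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    if not 0 <= target_vessel < len(truth.vessel_segments):
        raise ParameterError(f"no vessel with index {target_vessel}")
    seg = truth.vessel_segments[target_vessel]
    brain: VolumeGrid = masks["brain"]

    # sphere parameters estimated from the mask (exact for phantom brains)
    idx = np.argwhere(brain.values.astype(bool))
    if idx.size == 0:
        raise InfeasibleTrajectoryError("brain mask is empty")
    center = brain.voxel_to_world(idx.astype(float)).mean(axis=0)
    voxel_volume = float(np.prod(brain.voxel_size))
    sphere_r = (3.0 * idx.shape[0] * voxel_volume / (4.0 * np.pi)) ** (1.0 / 3.0)

    # the target vessel must run through the brain
    t_probe = np.linspace(0.05, 0.95, 19)
    axis_pts = seg.start + t_probe[:, None] * (seg.end - seg.start)
    inside = brain.sample(axis_pts, order=0) > 0.5
    if not inside.any():
        raise InfeasibleTrajectoryError(
            f"target vessel {target_vessel} lies outside the brain mask"
        )
    usable_t = t_probe[inside]
    vessel_dir = seg.end - seg.start
    vessel_dir = vessel_dir / np.linalg.norm(vessel_dir)

    spacing = spec.contact_spacing
    max_chain = (spec.contacts_per_electrode - 1) * spacing
    for _ in range(max_tries):
        t = rng.uniform(usable_t.min(), usable_t.max())
        p = seg.start + t * (seg.end - seg.start)
        if not brain.sample(p, order=0) > 0.5:
            continue
        rel = p - center
        rho = float(np.linalg.norm(rel))
        depth = float(sample_law(spec.depth_law, rng, 1)[0])
        if rho < 1e-6 or not (sphere_r - rho <= depth <= sphere_r + rho):
            continue
        # the contact chain must span from beyond the entry down to the tip
        if depth + spec.tip_overshoot + spacing > max_chain:
            continue
        cos_beta = (rho**2 + depth**2 - sphere_r**2) / (2.0 * depth * rho)
        if abs(cos_beta) > 1.0:
            continue
        w = rel / rho
        e_perp = _random_tangent(w, rng)
        direction = cos_beta * w + np.sqrt(max(1.0 - cos_beta**2, 0.0)) * e_perp
        direction /= np.linalg.norm(direction)
        # direction points from entry toward P (tip-ward); oblique to the vessel
        if abs(np.dot(direction, vessel_dir)) > np.cos(np.deg2rad(20.0)):
            continue
        try:
            entry, depth_actual = _mask_entry_depth(brain, p, direction)
        except InfeasibleTrajectoryError:
            continue
        overshoot = spec.tip_overshoot
        tip = p + overshoot * direction
        while overshoot > 0.5 and not brain.sample(tip, order=0) > 0.5:
            overshoot *= 0.5
            tip = p + overshoot * direction
        if not brain.sample(tip, order=0) > 0.5:
            continue
        # implanted tips dive into the parenchyma; grazing chords whose tip
        # skims the surface are not plausible trajectories
        if sphere_r - float(np.linalg.norm(tip - center)) < spec.min_tip_depth:
            continue
        # electrodes come in varying lengths: use just enough contacts for
        # the chain to clear the entry point by up to ~one spacing
        tip_depth = depth_actual + overshoot
        n_contacts = int(
            np.clip(np.floor((tip_depth + 6.0) / spacing) + 1, 2,
                    spec.contacts_per_electrode)
        )
        contacts = tip - np.arange(n_contacts)[:, None] * spacing * direction
        electrode = Electrode(label, contacts, radius=spec.electrode_radius)
        conflict = PlantedConflict(
            electrode_label=label,
            position=p.copy(),
            vessel_radius=seg.radius,
            vessel_diameter=seg.diameter,
            depth=depth_actual,
            in_sulcus=False,  # assigned analytically by the generator's sweep
            visible_in=dict(seg.visibility),
            planted=True,
        )
        truth.planted_conflicts.append(conflict)
        return electrode, entry, conflict
    raise InfeasibleTrajectoryError(
        f"no feasible straight path through vessel {target_vessel} after {max_tries} tries"
    )


def _plant_safe_electrode(
    brain: VolumeGrid, spec: PhantomSpec, rng: np.random.Generator, label: str
) -> tuple[Electrode, np.ndarray]:
    """A random chord electrode with no targeted conflict."""
    idx = np.argwhere(brain.values.astype(bool))
    center = brain.voxel_to_world(idx.astype(float)).mean(axis=0)
    voxel_volume = float(np.prod(brain.voxel_size))
    sphere_r = (3.0 * idx.shape[0] * voxel_volume / (4.0 * np.pi)) ** (1.0 / 3.0)
    for _ in range(200):
        direction = _random_unit(rng)
        entry_dir = _random_unit(rng)
        target = center + rng.uniform(0.0, 10.0) * direction
        heading = target - (center + 60.0 * entry_dir)
        heading /= np.linalg.norm(heading)
        try:
            entry, depth = _mask_entry_depth(brain, target, heading)
        except InfeasibleTrajectoryError:
            continue
        tip_depth = min(depth, rng.uniform(20.0, 45.0))
        tip = entry + tip_depth * heading
        if sphere_r - float(np.linalg.norm(tip - center)) < spec.min_tip_depth:
            continue
        n_contacts = int(
            np.clip(np.floor((tip_depth + 6.0) / spec.contact_spacing) + 1, 2,
                    spec.contacts_per_electrode)
        )
        contacts = tip - np.arange(n_contacts)[:, None] \
            * spec.contact_spacing * heading
        return Electrode(label, contacts, radius=spec.electrode_radius), entry
    raise InfeasibleTrajectoryError("could not place a conflict-free electrode")


# ---------------------------------------------------------------------------
# Manifest completion: every conflict, planted or incidental
# ---------------------------------------------------------------------------


def _segment_segment_closest(
    a0: np.ndarray, a1: np.ndarray, b0: np.ndarray, b1: np.ndarray
) -> tuple[float, float, float]:
    """(distance, s on A in [0,1], t on B in [0,1]) between two segments."""
    d1 = a1 - a0
    d2 = b1 - b0
    r = a0 - b0
    a = float(d1 @ d1)
    e = float(d2 @ d2)
    f = float(d2 @ r)
    if a <= 1e-12 and e <= 1e-12:
        return float(np.linalg.norm(r)), 0.0, 0.0
    if a <= 1e-12:
        s, t = 0.0, np.clip(f / e, 0.0, 1.0)
    else:
        c = float(d1 @ r)
        if e <= 1e-12:
            t = 0.0
            s = np.clip(-c / a, 0.0, 1.0)
        else:
            b = float(d1 @ d2)
            denom = a * e - b * b
            s = np.clip((b * f - c * e) / denom, 0.0, 1.0) if denom > 1e-12 else 0.0
            t = (b * s + f) / e
            if t < 0.0:
                t, s = 0.0, np.clip(-c / a, 0.0, 1.0)
            elif t > 1.0:
                t, s = 1.0, np.clip((b - c) / a, 0.0, 1.0)
    closest_a = a0 + s * d1
    closest_b = b0 + t * d2
    return float(np.linalg.norm(closest_a - closest_b)), float(s), float(t)


def _build_manifest(
    truth: GroundTruth,
    electrodes: list[Electrode],
    entries: dict,
    intended: dict,
    spec: PhantomSpec,
    model: _SphereModel,
    merge_gap: float = 2.0,
    sweep_step: float = 0.1,
) -> None:
    """Enumerate every electrode-vessel conflict by an analytic arc sweep.

    Mirrors the detector's run semantics exactly: along each (straight)
    trajectory, the arc positions where the electrode surface touches some
    vessel (axis distance <= electrode radius + vessel radius) form contact
    runs; runs separated by less than ``merge_gap`` coalesce into one
    conflict, located at the run's closest surface approach and attributed
    to the vessel touched there.  Without this the manifest would count a
    bifurcating tree crossed near its branch point twice while any detector
    faithful to the overlap definition reports one event.

    ``intended`` maps electrode label -> list of deliberately targeted
    positions; runs containing one are flagged ``planted=True``.
    """
    for electrode in electrodes:
        entry = entries[electrode.label]
        tip = electrode.contacts[0]
        length = float(np.linalg.norm(tip - entry))
        direction = (tip - entry) / length
        # prefilter vessels that can touch this trajectory at all
        near = [
            seg for seg in truth.vessel_segments
            if _segment_segment_closest(entry, tip, seg.start, seg.end)[0]
            <= spec.electrode_radius + seg.radius
        ]
        if not near:
            continue
        s_grid = np.arange(0.0, length + sweep_step, sweep_step)
        pts = entry + s_grid[:, None] * direction
        surface = np.stack(
            [seg.axis_distance(pts) - seg.radius for seg in near]
        )  # distance from electrode axis to each vessel surface
        below = (surface <= spec.electrode_radius).any(axis=0)
        if not below.any():
            continue
        idx = np.flatnonzero(below)
        runs: list[list[int]] = [[int(idx[0])]]
        for prev, cur in zip(idx[:-1], idx[1:]):
            if (cur - prev) * sweep_step < merge_gap:
                runs[-1].append(int(cur))
            else:
                runs.append([int(cur)])
        targets = intended.get(electrode.label, [])
        for run in runs:
            run_arr = np.arange(run[0], run[-1] + 1)
            best_flat = int(np.argmin(surface[:, run_arr]))
            v_i, s_i = divmod(best_flat, run_arr.size)
            s_star = float(s_grid[run_arr[s_i]])
            seg = near[v_i]
            pos = entry + s_star * direction
            planted = any(
                run[0] <= int(round(np.dot(tp - entry, direction) / sweep_step)) <= run[-1]
                for tp in targets
            )
            _, _, in_sulcal = model.classify(pos[None, :])
            truth.planted_conflicts.append(
                PlantedConflict(
                    electrode_label=electrode.label,
                    position=pos,
                    vessel_radius=seg.radius,
                    vessel_diameter=seg.diameter,
                    depth=s_star,
                    in_sulcus=bool(in_sulcal[0]),
                    visible_in=dict(seg.visibility),
                    planted=planted,
                )
            )


# ---------------------------------------------------------------------------
# Generator
# ---------------------------------------------------------------------------


def generate_phantom(spec: PhantomSpec) -> Phantom:
    """Build the full multi-modal phantom for one seed.

    Returns masks (brain/gm/wm/skull), one vascular volume per modality, a
    CT-like electrode volume, the electrode geometries and the ground-truth
    manifest.  Identical specs give bit-identical outputs.
    """
    rng = np.random.default_rng(spec.seed)
    affine = _center_affine(spec)
    model = _SphereModel(spec)
    radius = model.radius

    # closed-form masks -----------------------------------------------------
    shape = spec.grid_shape
    vox = np.asarray(spec.voxel_size)
    coords = [affine[a, 3] + vox[a] * np.arange(shape[a]) for a in range(3)]
    xx, yy, zz = np.meshgrid(*coords, indexing="ij")
    rho = np.sqrt(xx**2 + yy**2 + zz**2)
    with np.errstate(invalid="ignore", divide="ignore"):
        theta = np.arccos(np.clip(np.where(rho > 0, zz / np.where(rho > 0, rho, 1.0), 1.0), -1, 1))
    rp = model.pial_radius(theta)

    brain = rho <= radius
    gm = (rho <= rp) & (rho > rp - model.thickness)
    wm = rho <= rp - model.thickness
    skull = (rho >= radius + 1.0) & (rho <= radius + 4.0)
    masks = {
        "brain": VolumeGrid(brain, affine, "brain_mask"),
        "gm": VolumeGrid(gm, affine, "gm_mask"),
        "wm": VolumeGrid(wm, affine, "wm_mask"),
        "skull": VolumeGrid(skull, affine, "skull_mask"),
    }

    # vasculature -----------------------------------------------------------
    truth = GroundTruth(vessel_segments=_seed_vessels(spec, rng, model))

    # electrodes ------------------------------------------------------------
    electrodes: list[Electrode] = []
    entries: dict[str, np.ndarray] = {}
    intended: dict[str, list[np.ndarray]] = {}
    axes = []  # (entry, tip) of accepted electrodes, for separation checks

    def _separated(entry: np.ndarray, tip: np.ndarray) -> float:
        if not axes:
            return np.inf
        return min(
            _segment_segment_closest(entry, tip, e0, e1)[0] for e0, e1 in axes
        )

    for k in range(spec.n_electrodes):
        label = f"E{k:02d}"
        want = spec.conflicts_per_electrode if truth.vessel_segments else 0
        best = None
        # implantations keep trajectories apart (electrode-electrode
        # avoidance is a planning constraint); retry until separated
        for _attempt in range(30):
            if want <= 0:
                electrode, entry = _plant_safe_electrode(masks["brain"], spec, rng, label)
                conflict = None
            else:
                # targeted conflicts involve reference-visible vessels (a
                # raw-reference reviewer must be able to verify them)
                ref_mod = min(spec.modality_visibility, key=spec.modality_visibility.get)
                candidates = [
                    i for i, s in enumerate(truth.vessel_segments)
                    if s.visibility.get(ref_mod, True)
                ]
                if not candidates:
                    electrode, entry = _plant_safe_electrode(masks["brain"], spec, rng, label)
                    conflict = None
                    sep = _separated(entry, electrode.contacts[0])
                    if best is None or sep > best[0]:
                        best = (sep, electrode, entry, conflict)
                    if sep >= spec.electrode_separation:
                        break
                    continue
                target = int(candidates[rng.integers(0, len(candidates))])
                try:
                    electrode, entry, conflict = plant_conflicting_electrode(
                        truth, masks, target, spec, rng=rng, label=label,
                        max_tries=80,
                    )
                except InfeasibleTrajectoryError:
                    continue  # that vessel admits no trajectory; draw another
                truth.planted_conflicts.pop()  # manifest is rebuilt by the sweep
            sep = _separated(entry, electrode.contacts[0])
            if best is None or sep > best[0]:
                best = (sep, electrode, entry, conflict)
            if sep >= spec.electrode_separation:
                break
        if best is None:  # every sampled target proved infeasible
            electrode, entry = _plant_safe_electrode(masks["brain"], spec, rng, label)
            best = (np.inf, electrode, entry, None)
        _, electrode, entry, conflict = best
        if conflict is not None:
            truth.planted_conflicts.append(conflict)
            intended[label] = [conflict.position]
            # additional conflicts: plant small crossing vessels on the shaft
            for _extra in range(want - 1):
                extra = _plant_crossing_vessel(truth, electrode, entry, spec, rng, model)
                intended[label].append(extra.position)
        electrodes.append(electrode)
        entries[label] = entry
        axes.append((entry, electrode.contacts[0]))

    # the manifest is rebuilt wholesale by the analytic sweep so that it
    # lists exactly the distinguishable conflicts (planted and incidental)
    truth.planted_conflicts = []
    _build_manifest(truth, electrodes, entries, intended, spec, model)

    # modality volumes ------------------------------------------------------
    modalities: dict[str, VolumeGrid] = {}
    for modality in sorted(spec.modality_visibility):
        vol = np.zeros(shape)
        for seg in truth.vessel_segments:
            if not seg.visibility[modality]:
                continue
            r = seg.radius + (spec.dsa_dilation_mm if modality == "dsa" else 0.0)
            _rasterize_capsule(vol, affine, seg.start, seg.end, r, spec.vessel_intensity)
        if spec.noise_sd > 0:
            vol += rng.normal(0.0, spec.noise_sd, size=shape)
        modalities[modality] = VolumeGrid(vol, affine, modality)

    # post-implant CT -------------------------------------------------------
    ct = np.zeros(shape)
    # one full voxel keeps every blob's sampled peak above half its nominal
    # amplitude regardless of subvoxel contact position
    sigma = float(vox.min())
    for electrode in electrodes:
        for contact in electrode.contacts:
            _rasterize_blob(ct, affine, contact, sigma, spec.contact_intensity)
    if spec.ct_noise_sd > 0:
        ct += rng.normal(0.0, spec.ct_noise_sd, size=shape)
    electrodes_ct = VolumeGrid(ct, affine, "post_implant_ct")

    return Phantom(
        spec=spec,
        masks=masks,
        modalities=modalities,
        electrodes_ct=electrodes_ct,
        electrodes=electrodes,
        entries=entries,
        truth=truth,
    )


def _plant_crossing_vessel(
    truth: GroundTruth,
    electrode: Electrode,
    entry: np.ndarray,
    spec: PhantomSpec,
    rng: np.random.Generator,
    model: _SphereModel,
    max_tries: int = 100,
) -> PlantedConflict:
    """Add a vessel crossing an existing electrode at a drawn depth."""
    tip = electrode.contacts[0]
    direction = tip - entry
    total = float(np.linalg.norm(direction))
    direction /= total
    existing = [c for c in truth.planted_conflicts if c.electrode_label == electrode.label]
    for _ in range(max_tries):
        depth = float(sample_law(spec.depth_law, rng, 1)[0])
        if depth >= total - 1.0:
            continue
        pos = entry + depth * direction
        if np.linalg.norm(pos) > model.radius - 1.5:
            continue
        if any(abs(depth - c.depth) < 4.0 for c in existing):
            continue
        diameter = float(sample_law(spec.radius_law, rng, 1)[0])
        axis = _random_tangent(direction, rng)
        half_len = rng.uniform(4.0, 8.0)
        seg = VesselSegment(
            pos - half_len * axis, pos + half_len * axis,
            diameter / 2.0, _visibility(diameter, spec),
        )
        truth.vessel_segments.append(seg)
        _, _, in_sulcal = model.classify(pos[None, :])
        conflict = PlantedConflict(
            electrode_label=electrode.label,
            position=pos,
            vessel_radius=seg.radius,
            vessel_diameter=seg.diameter,
            depth=depth,
            in_sulcus=bool(in_sulcal[0]),
            visible_in=dict(seg.visibility),
            planted=True,
        )
        truth.planted_conflicts.append(conflict)
        existing.append(conflict)
        return conflict
    raise InfeasibleTrajectoryError(
        f"could not plant an extra crossing vessel on {electrode.label}"
    )


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------


def write_phantom(phantom: Phantom, outdir: str | Path) -> None:
    """Write all phantom volumes (NIfTI-1, RAS+), the manifest and geometry."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name, vol in phantom.masks.items():
        write_volume(vol, outdir / f"mask_{name}.nii.gz")
    for name, vol in phantom.modalities.items():
        write_volume(vol, outdir / f"{name}.nii.gz")
    write_volume(phantom.electrodes_ct, outdir / "post_implant_ct.nii.gz")
    phantom.truth.to_json(outdir / "ground_truth.json")
    geometry = {
        "spec": phantom.spec.to_dict(),
        "electrodes": [
            {
                "label": e.label,
                "contacts": e.contacts.tolist(),
                "radius": e.radius,
                "entry": phantom.entries[e.label].tolist(),
            }
            for e in phantom.electrodes
        ],
    }
    (outdir / "electrodes.json").write_text(json.dumps(geometry, indent=1, sort_keys=True))
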