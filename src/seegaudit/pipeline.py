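"""End-to-end phantom audit: segmentation, conflicts, sulcal model, tables.

This is the glue that reproduces the study's workflow on a phantom:

1. enhance and segment each modality's vascular volume, build its distance
   field in reference space;
2. reconstruct electrodes from the CT-like volume (contact centroids ->
   grouping -> linear interpolation to the brain entry);
3. audit every trajectory against every modality's distance field, detect
   overlap conflicts and characterize them (diameter on the raw DSA-like
   full-width-half-maximum caliber mask, depth from cortical entry, sulcal
   membership);
4. cross-reference each modality's detections against the ground-truth
   manifest and compare modalities with Bonferroni-adjusted chi-squares.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .audit import (
    AuditReport,
    ConflictEvent,
    characterize_conflict,
    detect_conflicts,
    distance_profile,
)
from .comparison import (
    ComparisonResult,
    DetectionTable,
    chi_square_compare,
    match_conflicts,
    sulcal_union,
)
from .electrodes import group_into_electrodes, interpolate_trajectory, segment_contacts
from .errors import GeometryError
from .phantom import Phantom
from .sulcal import SulcalModel, build_sulcal_model, estimate_thickness
from .vessels import (
    DistanceField,
    VesselSegmentation,
    distance_field,
    segment_vessels,
    vesselness_filter,
)

__all__ = ["AuditConfig", "PipelineResult", "audit_phantom"]


@dataclass
class AuditConfig:
    """Tunable pipeline parameters (defaults match the audited workflow)."""

    vesselness_scales: tuple = (0.25, 0.5, 1.0, 1.5, 2.0)  # mm
    vesselness_threshold: float = 0.05
    vesselness_gamma: float | None = None  # None: half the reference volume's robust range
    min_component_voxels: int = 8
    caliber_halfmax: float = 0.5        # FWHM threshold on normalized raw intensity
    contact_threshold_fraction: float = 0.5  # of the CT intensity maximum
    sample_step: float = 0.5            # mm along trajectories
    conflict_threshold: float = 0.0     # mm; 0 = overlap
    merge_gap: float = 2.0              # mm
    safety_margin: float = 3.0          # mm
    match_tolerance: float = 3.0        # mm, conflict cross-referencing
    n_thickness_rays: int = 400
    sulcal_margin_factor: float = 1.0
    thickness_seed: int = 12345
    reference_modality: str = "dsa"


@dataclass
class PipelineResult:
    segmentations: dict                 # modality -> VesselSegmentation
    fields: dict                        # modality -> DistanceField
    caliber_seg: VesselSegmentation     # raw-image FWHM mask of the reference modality
    sulcal_model: SulcalModel
    mean_thickness: float
    trajectories: list
    events: dict                        # modality -> list[ConflictEvent]
    report: AuditReport                 # reference-modality audit
    tables: dict                        # (modality, variant) -> DetectionTable
    comparisons: list[ComparisonResult]


def _event_positions(events: list[ConflictEvent]) -> np.ndarray:
    if not events:
        return np.empty((0, 3))
    return np.array([e.position for e in events])


def audit_phantom(phantom: Phantom, config: AuditConfig | None = None) -> PipelineResult:
    config = config or AuditConfig()
    brain = phantom.masks["brain"]
    gm = phantom.masks["gm"]

    # 1. vascular models ----------------------------------------------------
    # one structure-sensitivity constant for the whole study, set from the
    # reference modality's contrast: a modality showing no vessel must not
    # normalize its own noise into structure
    gamma = config.vesselness_gamma
    if gamma is None:
        ref_int = phantom.modalities[config.reference_modality].values
        lo_i, hi_i = np.percentile(ref_int, [0.1, 99.9])
        gamma = 0.5 * float(hi_i - lo_i)
    segs: dict[str, VesselSegmentation] = {}
    fields: dict[str, DistanceField] = {}
    for modality in sorted(phantom.modalities):
        vol = phantom.modalities[modality]
        vness = vesselness_filter(vol, list(config.vesselness_scales), gamma=gamma)
        seg = segment_vessels(
            vness, config.vesselness_threshold, config.min_component_voxels,
            source_modality=modality,
        )
        segs[modality] = seg
        fields[modality] = distance_field(seg)

    # caliber mask: the paper measures diameters on the raw reference image,
    # not on the (filter-dilated) segmentation
    ref_vol = phantom.modalities[config.reference_modality]
    peak = float(np.percentile(ref_vol.values, 99.9))
    norm = ref_vol.with_values(
        np.clip(ref_vol.values / peak, 0.0, 1.0) if peak > 0 else np.zeros(ref_vol.shape),
        modality_label=f"norm({config.reference_modality})",
    )
    caliber_seg = segment_vessels(
        norm, config.caliber_halfmax, config.min_component_voxels,
        source_modality=f"{config.reference_modality}_raw",
    )

    # 2. sulcal model -------------------------------------------------------
    thickness = estimate_thickness(
        gm, brain, n_rays=config.n_thickness_rays, seed=config.thickness_seed
    )
    sulcal = build_sulcal_model(
        brain, gm, thickness, margin_factor=config.sulcal_margin_factor
    )

    # 3. electrode reconstruction ------------------------------------------
    ct = phantom.electrodes_ct
    threshold = config.contact_threshold_fraction * float(ct.values.max())
    centroids = segment_contacts(ct, threshold)
    grouping = group_into_electrodes(
        centroids, expected_spacing=phantom.spec.contact_spacing,
        collinearity_tol=1.0, brain_mask=brain,
    )
    trajectories = []
    for e in grouping.electrodes:
        try:
            trajectories.append(interpolate_trajectory(e, config.sample_step, brain))
        except GeometryError:
            # a fully extracerebral chain is a reconstruction fragment
            # (e.g. proximal contacts split off), not an implanted electrode
            continue

    # 4. conflict audit per modality ---------------------------------------
    events: dict[str, list[ConflictEvent]] = {m: [] for m in segs}
    for modality, dfield in fields.items():
        for traj in trajectories:
            profile = distance_profile(
                traj, dfield, safety_margin=config.safety_margin
            )
            found = detect_conflicts(
                profile, config.conflict_threshold, config.merge_gap
            )
            for ev in found:
                characterize_conflict(ev, caliber_seg, brain, sulcal)
                ev.detected_by[modality] = True
            events[modality].extend(found)

    report = AuditReport(
        events=events[config.reference_modality],
        n_electrodes=len(trajectories),
    )

    # 5. cross-referencing against the manifest -----------------------------
    # the reference set holds what a reviewer of the raw reference images
    # could verify: conflicts whose vessel is visible on the raw reference
    ref_conflicts = [
        c for c in phantom.truth.planted_conflicts
        if c.visible_in.get(config.reference_modality, True)
    ]
    ref_positions = (
        np.array([c.position for c in ref_conflicts])
        if ref_conflicts else np.empty((0, 3))
    )
    ref_sulcal = np.array(
        [c.in_sulcus for c in ref_conflicts], dtype=bool
    ) if ref_conflicts else np.empty(0, dtype=bool)
    tables: dict[tuple, DetectionTable] = {}
    for modality in sorted(segs):
        table = match_conflicts(
            ref_positions, _event_positions(events[modality]),
            tolerance=config.match_tolerance,
            modality=modality, variant="segmentation",
        )
        # raw-visibility bookkeeping from the manifest
        raw_visible = np.array(
            [c.visible_in.get(modality, False) for c in ref_conflicts],
            dtype=bool,
        ) if ref_conflicts else np.empty(0, dtype=bool)
        table.n_raw_visible = int(raw_visible.sum())
        if table.detected_mask is not None and raw_visible.size:
            table.n_raw_missed_by_seg = int((raw_visible & ~table.detected_mask).sum())
        tables[(modality, "segmentation")] = table
        if ref_sulcal.size:
            tables[(modality, "segmentation+sulcal")] = sulcal_union(table, ref_sulcal)

    # 6. pairwise chi-squares with Bonferroni -------------------------------
    seg_tables = [tables[(m, "segmentation")] for m in sorted(segs)]
    pairs = [
        (a, b) for i, a in enumerate(seg_tables) for b in seg_tables[i + 1:]
    ]
    comparisons = [
        chi_square_compare(a, b, bonferroni_m=len(pairs)) for a, b in pairs
    ]

    return PipelineResult(
        segmentations=segs,
        fields=fields,
        caliber_seg=caliber_seg,
        sulcal_model=sulcal,
        mean_thickness=thickness.mean_thickness,
        trajectories=trajectories,
        events=events,
        report=report,
        tables=tables,
        comparisons=comparisons,
    )
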