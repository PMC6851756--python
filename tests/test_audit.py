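"""Distance profiles, conflict detection/characterization and risk metrics."""

import numpy as np
import pytest

from seegaudit import (
    Electrode,
    VolumeGrid,
    characterize_conflict,
    detect_conflicts,
    distance_field,
    distance_profile,
    interpolate_trajectory,
    risk_metrics,
    segment_vessels,
)
from seegaudit.audit import ConflictEvent, DistanceProfile
from seegaudit.errors import GeometryError

from conftest import make_grid, sphere_mask, world_coords


def _tube_segmentation(axis_point, axis_dir, radius, voxel=0.25, shape=(96, 96, 96)):
    affine = make_grid(shape, (voxel,) * 3)
    x, y, z = world_coords(shape, affine)
    pts = np.stack([x, y, z], axis=-1) - np.asarray(axis_point, float)
    d = np.asarray(axis_dir, float)
    d = d / np.linalg.norm(d)
    along = pts @ d
    perp = pts - along[..., None] * d
    dist = np.linalg.norm(perp, axis=-1)
    grid = VolumeGrid((dist <= radius).astype(float), affine)
    return segment_vessels(grid, 0.5)


def _radial_trajectory(mask, n=5, spacing=5.0, tip=(0.0, 0.0, 4.0)):
    tip = np.asarray(tip)
    contacts = tip - spacing * np.arange(n)[:, None] * np.array([0, 0, 1.0])
    e = Electrode("E00", contacts, radius=0.4)
    return interpolate_trajectory(e, step=0.5, brain_mask=mask)


class TestDistanceProfile:
    def test_parallel_vessel_plateau_at_three_mm(self):
        """Electrode and vessel parallel at 4 mm axis offset, radii 0.4 +
        0.6 mm: the profile must plateau at 3.0 mm.  The pair is tilted off
        the grid axes so the samples average over lattice phases instead of
        all sitting on the worst-case one."""
        mask = sphere_mask(10.0, voxel=0.25, shape=(96, 96, 96))
        d = np.array([0.18, 0.11, 1.0])
        d /= np.linalg.norm(d)
        offset = np.cross(d, [0.0, 1.0, 0.0])
        offset = 4.0 * offset / np.linalg.norm(offset)
        seg = _tube_segmentation(offset, d, radius=0.6)
        field = distance_field(seg)
        tip = 6.0 * d
        contacts = tip - 5.0 * np.arange(4)[:, None] * d
        e = Electrode("E00", contacts, radius=0.4)
        traj = interpolate_trajectory(e, step=0.5, brain_mask=mask)
        profile = distance_profile(traj, field, electrode_radius=0.4)
        interior = (traj.arc_lengths > 3) & (traj.arc_lengths < traj.arc_lengths[-1] - 3)
        plateau = profile.distances[interior]
        assert np.abs(plateau - 3.0).max() <= 0.1

    def test_through_vessel_min_distance_zero_single_conflict(self):
        mask = sphere_mask(10.0, voxel=0.25, shape=(96, 96, 96))
        seg = _tube_segmentation([0.0, 0.0, -2.0], [1.0, 0, 0], radius=0.6)
        field = distance_field(seg)
        traj = _radial_trajectory(mask)
        profile = distance_profile(traj, field)
        assert profile.distances.min() == 0.0
        events = detect_conflicts(profile)
        assert len(events) == 1
        assert events[0].min_distance == 0.0

    def test_no_vasculature_flag_propagates(self):
        mask = sphere_mask(10.0, voxel=0.5, shape=(48, 48, 48))
        empty = _tube_segmentation([0, 0, 0], [0, 0, 1.0], radius=0.5,
                                   voxel=0.5, shape=(48, 48, 48))
        empty.mask.values[:] = False
        field = distance_field(empty)
        traj = _radial_trajectory(mask)
        profile = distance_profile(traj, field)
        assert profile.no_vasculature
        assert detect_conflicts(profile) == []


class _FakeTrajectory:
    """Minimal stand-in for run-detection logic tests."""

    def __init__(self, arc, positions):
        self.arc_lengths = arc
        self.positions = positions
        self.electrode = Electrode("F", np.array([[0.0, 0, 0], [0, 0, 5.0]]))


def _profile_from_distances(arc, dist):
    arc = np.asarray(arc, float)
    positions = np.stack([arc, np.zeros_like(arc), np.zeros_like(arc)], axis=1)
    return DistanceProfile(
        trajectory=_FakeTrajectory(arc, positions),
        arc_lengths=arc,
        distances=np.asarray(dist, float),
    )


class TestDetectConflicts:
    def test_all_above_threshold_is_empty(self):
        p = _profile_from_distances(np.arange(10.0), np.full(10, 5.0))
        assert detect_conflicts(p, conflict_threshold=0.0) == []

    def test_two_runs_ten_mm_apart_stay_separate(self):
        """Hand-enumerated profile: zeros at arcs {2,3} and {13,14}, gap
        10 mm >> merge gap 2 mm -> exactly two events at the run minima."""
        arc = np.arange(0.0, 20.0, 1.0)
        dist = np.full_like(arc, 4.0)
        dist[[2, 3]] = 0.0
        dist[[13, 14]] = 0.0
        events = detect_conflicts(_profile_from_distances(arc, dist),
                                  conflict_threshold=0.0, merge_gap=2.0)
        assert len(events) == 2
        assert events[0].arc_length in (2.0, 3.0)
        assert events[1].arc_length in (13.0, 14.0)

    def test_close_runs_merge(self):
        arc = np.arange(0.0, 10.0, 0.5)
        dist = np.full_like(arc, 4.0)
        dist[[4, 5]] = 0.0   # arcs 2.0, 2.5
        dist[[8, 9]] = 0.0   # arcs 4.0, 4.5 -> gap 1.5 mm < 2 mm
        events = detect_conflicts(_profile_from_distances(arc, dist),
                                  conflict_threshold=0.0, merge_gap=2.0)
        assert len(events) == 1

    def test_safety_margin_threshold_flags_submargin_dip(self):
        """With the threshold raised to the 3 mm safety margin, a profile
        dipping below the margin (e.g. to 0.92 mm) yields an event there."""
        arc = np.arange(0.0, 30.0, 1.0)
        dist = np.full_like(arc, 5.0)
        dist[21] = 0.92
        events = detect_conflicts(_profile_from_distances(arc, dist),
                                  conflict_threshold=3.0)
        assert len(events) == 1
        assert events[0].arc_length == 21.0
        assert events[0].min_distance == pytest.approx(0.92)


class TestCharacterize:
    def test_planted_vessel_diameter_recovered(self):
        """A 0.65 mm radius vessel crossed by the electrode reads a
        diameter of 1.3 mm within a two-voxel tolerance."""
        mask = sphere_mask(10.0, voxel=0.25, shape=(96, 96, 96))
        seg = _tube_segmentation([0.0, 0.0, -2.0], [1.0, 0, 0], radius=0.65)
        field = distance_field(seg)
        traj = _radial_trajectory(mask)
        profile = distance_profile(traj, field)
        events = detect_conflicts(profile)
        assert len(events) == 1
        ev = characterize_conflict(events[0], seg, mask)
        assert ev.diameter == pytest.approx(1.3, abs=0.5)
        assert ev.depth == pytest.approx(8.0, abs=0.75)  # entry at z=-10

    def test_conflict_at_entry_has_depth_zero(self):
        ev = ConflictEvent("E", np.zeros(3), arc_length=0.0, min_distance=0.0,
                           run_start=0.0, run_end=0.0)
        mask = sphere_mask(10.0, voxel=0.5, shape=(48, 48, 48))
        seg = _tube_segmentation([0, 0, -10.0], [1.0, 0, 0], radius=1.0,
                                 voxel=0.5, shape=(48, 48, 48))
        out = characterize_conflict(ev, seg, mask)
        assert out.depth == 0.0

    def test_unresolved_diameter_kept(self):
        ev = ConflictEvent("E", np.array([8.0, 8.0, 8.0]), arc_length=5.0,
                           min_distance=0.0, run_start=5.0, run_end=5.0)
        mask = sphere_mask(10.0, voxel=0.5, shape=(48, 48, 48))
        seg = _tube_segmentation([0, 0, 0], [1.0, 0, 0], radius=0.6,
                                 voxel=0.5, shape=(48, 48, 48))
        out = characterize_conflict(ev, seg, mask, capture_radius=2.0)
        assert out.diameter is None
        assert out.depth == 5.0


class TestRiskMetrics:
    def _setting(self):
        shape, voxel = (64, 64, 64), 0.5
        affine = make_grid(shape, (voxel,) * 3)
        x, y, z = world_coords(shape, affine)
        rho = np.sqrt(x**2 + y**2 + z**2)
        brain = VolumeGrid(rho <= 12.0, affine)
        gm = VolumeGrid((rho <= 12.0) & (rho > 9.0), affine)
        wm = VolumeGrid(rho <= 9.0, affine)
        skull = VolumeGrid((rho >= 13.0) & (rho <= 15.0), affine)
        traj = _radial_trajectory(brain, tip=(0.0, 0.0, 6.0))
        return brain, gm, wm, skull, traj

    def test_risk_score_zero_iff_profile_clears_margin(self):
        brain, gm, wm, skull, traj = self._setting()
        safe = _profile_from_distances(traj.arc_lengths, np.full(len(traj), 5.0))
        safe.trajectory = traj
        m = risk_metrics(traj, safe, skull, gm, wm, brain)
        assert m.risk_score == 0.0

    def test_risk_score_one_for_zero_profile(self):
        brain, gm, wm, skull, traj = self._setting()
        hot = _profile_from_distances(traj.arc_lengths, np.zeros(len(traj)))
        hot.trajectory = traj
        m = risk_metrics(traj, hot, skull, gm, wm, brain)
        assert m.risk_score == 1.0

    def test_radial_trajectory_is_orthogonal_to_skull(self):
        """A trajectory along the local skull normal scores the planning
        ideal of 90 degrees."""
        brain, gm, wm, skull, traj = self._setting()
        p = _profile_from_distances(traj.arc_lengths, np.full(len(traj), 5.0))
        p.trajectory = traj
        m = risk_metrics(traj, p, skull, gm, wm, brain)
        assert m.angle_to_skull == pytest.approx(90.0, abs=5.0)
        assert m.intracerebral_length > 0
        assert m.gw_ratio >= 0

    def test_monotone_in_distances(self):
        brain, gm, wm, skull, traj = self._setting()
        near = _profile_from_distances(traj.arc_lengths, np.full(len(traj), 1.0))
        far = _profile_from_distances(traj.arc_lengths, np.full(len(traj), 2.0))
        near.trajectory = far.trajectory = traj
        m_near = risk_metrics(traj, near, skull, gm, wm, brain)
        m_far = risk_metrics(traj, far, skull, gm, wm, brain)
        assert m_near.risk_score >= m_far.risk_score
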