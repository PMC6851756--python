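"""Phantom generator: determinism, planted laws, visibility and geometry."""

import numpy as np
import pytest

from seegaudit import (
    GroundTruth,
    PhantomSpec,
    VesselSegment,
    generate_phantom,
    plant_conflicting_electrode,
)
from seegaudit.errors import (
    InfeasibleTrajectoryError,
    ParameterError,
    PhantomSizingError,
)
from seegaudit.phantom import sample_law

from conftest import sphere_mask


SMALL = dict(grid_shape=(64, 64, 64), voxel_size=(0.75, 0.75, 0.75),
             n_vessels=8, n_electrodes=3)


class TestSpecValidation:
    def test_grid_minimum_enforced(self):
        with pytest.raises(ParameterError):
            PhantomSpec(grid_shape=(16, 64, 64))

    def test_dsa_must_see_smallest_vessels(self):
        with pytest.raises(ParameterError):
            PhantomSpec(modality_visibility={"dsa": 3.0, "mrv": 1.0, "t1_gad": 2.0})

    def test_electrode_span_must_fit_grid(self):
        with pytest.raises(PhantomSizingError):
            PhantomSpec(grid_shape=(32, 32, 32), voxel_size=(0.5, 0.5, 0.5),
                        contacts_per_electrode=18, contact_spacing=10.0)

    def test_brain_radius_must_fit(self):
        with pytest.raises(PhantomSizingError):
            PhantomSpec(grid_shape=(64, 64, 64), voxel_size=(0.5, 0.5, 0.5),
                        brain_radius=30.0)

    def test_round_trips_through_dict(self):
        spec = PhantomSpec(**SMALL, seed=4)
        again = PhantomSpec.from_dict(spec.to_dict())
        assert again == spec


class TestDeterminism:
    def test_same_seed_bit_identical(self):
        a = generate_phantom(PhantomSpec(**SMALL, seed=21))
        b = generate_phantom(PhantomSpec(**SMALL, seed=21))
        for name in a.modalities:
            np.testing.assert_array_equal(
                a.modalities[name].values, b.modalities[name].values
            )
        np.testing.assert_array_equal(a.electrodes_ct.values, b.electrodes_ct.values)
        assert len(a.truth.planted_conflicts) == len(b.truth.planted_conflicts)
        for ca, cb in zip(a.truth.planted_conflicts, b.truth.planted_conflicts):
            np.testing.assert_array_equal(ca.position, cb.position)
            assert ca.depth == cb.depth

    def test_different_seed_differs(self):
        a = generate_phantom(PhantomSpec(**SMALL, seed=21))
        b = generate_phantom(PhantomSpec(**SMALL, seed=22))
        assert not np.array_equal(a.modalities["dsa"].values, b.modalities["dsa"].values)


class TestVesselLaws:
    def test_no_vessels_means_background_only(self):
        spec = PhantomSpec(grid_shape=(64, 64, 64), voxel_size=(0.75,) * 3,
                           n_vessels=0, n_electrodes=2, noise_sd=0.0, seed=1)
        ph = generate_phantom(spec)
        for vol in ph.modalities.values():
            assert float(np.abs(vol.values).max()) == 0.0
        assert ph.truth.planted_conflicts == []

    def test_lognormal_caliber_median_within_order_statistic_bounds(self):
        """n=200 draws from lognormal(median 1.3, IQR ratio 1.5): the
        sample median must fall in [1.15, 1.45] (binomial order-statistic
        band verified by direct Monte Carlo of the same law)."""
        law = ("lognormal", {"median": 1.3, "iqr": (1.0, 1.5)})
        rng = np.random.default_rng(33)
        draws = sample_law(law, rng, 200)
        assert 1.15 <= np.median(draws) <= 1.45
        # oracle: the law itself, resampled many times
        oracle_rng = np.random.default_rng(77)
        medians = [
            np.median(sample_law(law, oracle_rng, 200)) for _ in range(200)
        ]
        assert np.percentile(medians, 1) > 1.15
        assert np.percentile(medians, 99) < 1.45

    def test_visibility_monotone_in_threshold(self):
        ph = generate_phantom(PhantomSpec(**SMALL, seed=5))
        for seg in ph.truth.vessel_segments:
            assert seg.visibility["dsa"] >= seg.visibility["mrv"] >= seg.visibility["t1_gad"]
        visible = {
            m: {i for i, s in enumerate(ph.truth.vessel_segments) if s.visibility[m]}
            for m in ("dsa", "mrv", "t1_gad")
        }
        assert visible["t1_gad"] <= visible["mrv"] <= visible["dsa"]

    def test_vessel_intensity_present_iff_visible(self):
        spec = PhantomSpec(**SMALL, noise_sd=0.0, seed=6)
        ph = generate_phantom(spec)
        for m, vol in ph.modalities.items():
            for seg in ph.truth.vessel_segments:
                mid = 0.5 * (seg.start + seg.end)
                val = vol.sample(mid)
                if seg.visibility[m]:
                    assert val > 10.0
        if not any(s.visibility["mrv"] for s in ph.truth.vessel_segments):
            assert float(ph.modalities["mrv"].values.max()) == 0.0


class TestGeometryConsistency:
    def test_every_conflict_touches_electrode_and_vessel(self):
        """Brute-force point-to-segment distances confirm the conflict
        condition for every manifest entry."""
        ph = generate_phantom(PhantomSpec(**SMALL, seed=9))
        assert ph.truth.planted_conflicts, "phantom should plant conflicts"
        for c in ph.truth.planted_conflicts:
            vessel_gap = min(
                s.axis_distance(c.position) - s.radius
                for s in ph.truth.vessel_segments
            )
            assert vessel_gap <= ph.spec.electrode_radius + 1e-6
            e = next(e for e in ph.electrodes if e.label == c.electrode_label)
            entry = ph.entries[c.electrode_label]
            axis = VesselSegment(entry, e.contacts[0], 0.0, {})
            assert axis.axis_distance(c.position) <= 1e-6

    def test_depth_equals_entry_to_position_arc(self):
        ph = generate_phantom(PhantomSpec(**SMALL, seed=9))
        for c in ph.truth.planted_conflicts:
            entry = ph.entries[c.electrode_label]
            assert c.depth == pytest.approx(np.linalg.norm(c.position - entry), abs=0.2)


class TestPlanting:
    def _setting(self, vessel_start, vessel_end, radius=0.65):
        spec = PhantomSpec(grid_shape=(96, 96, 96), voxel_size=(0.5,) * 3,
                           n_vessels=0, n_electrodes=0, seed=2)
        ph = generate_phantom(spec)
        truth = GroundTruth(vessel_segments=[
            VesselSegment(np.asarray(vessel_start, float),
                          np.asarray(vessel_end, float), radius,
                          {"dsa": True, "mrv": False, "t1_gad": False})
        ])
        return spec, ph, truth

    def test_planted_depth_matches_analytic_line_oracle(self):
        """The manifest depth must equal the entry-to-closest-approach arc
        computed by analytic line geometry."""
        spec, ph, truth = self._setting([-8.0, -4.0, 2.0], [8.0, -4.0, 2.0])
        rng = np.random.default_rng(12)
        e, entry, conflict = plant_conflicting_electrode(
            truth, ph.masks, 0, spec, rng=rng, label="T"
        )
        direction = e.contacts[0] - entry
        direction /= np.linalg.norm(direction)
        # closest approach of the electrode line to the vessel axis
        seg = truth.vessel_segments[0]
        t_grid = np.linspace(0, 60, 6001)
        pts = entry + t_grid[:, None] * direction
        d = seg.axis_distance(pts)
        t_star = t_grid[int(np.argmin(d))]
        assert conflict.depth == pytest.approx(t_star, abs=0.2)
        assert d.min() <= 2e-2  # axis crossing, up to entry-bisection residue

    def test_updated_ground_truth_contains_conflict(self):
        spec, ph, truth = self._setting([-8.0, 0.0, 0.0], [8.0, 0.0, 0.0])
        plant_conflicting_electrode(truth, ph.masks, 0, spec,
                                    rng=np.random.default_rng(3), label="T")
        assert len(truth.planted_conflicts) == 1
        assert truth.planted_conflicts[0].planted

    def test_vessel_outside_brain_is_infeasible(self):
        spec, ph, truth = self._setting([40.0, 40.0, 40.0], [45.0, 40.0, 40.0])
        with pytest.raises(InfeasibleTrajectoryError):
            plant_conflicting_electrode(truth, ph.masks, 0, spec,
                                        rng=np.random.default_rng(4), label="T")

    def test_unknown_vessel_index_rejected(self):
        spec, ph, truth = self._setting([-8.0, 0.0, 0.0], [8.0, 0.0, 0.0])
        with pytest.raises(ParameterError):
            plant_conflicting_electrode(truth, ph.masks, 5, spec,
                                        rng=np.random.default_rng(5))

    def test_zero_radius_degenerate_still_axis_intersection(self):
        """With electrode and vessel radii both zero, a recorded conflict
        can only arise from exact axis intersection."""
        spec, ph, truth = self._setting([-8.0, -4.0, 2.0], [8.0, -4.0, 2.0],
                                        radius=0.0)
        spec.electrode_radius = 0.0
        rng = np.random.default_rng(6)
        e, entry, conflict = plant_conflicting_electrode(
            truth, ph.masks, 0, spec, rng=rng, label="T"
        )
        seg = truth.vessel_segments[0]
        assert seg.axis_distance(conflict.position) <= 1e-6


class TestSerialization:
    def test_truth_json_round_trip(self, tmp_path):
        ph = generate_phantom(PhantomSpec(**SMALL, seed=13))
        path = tmp_path / "truth.json"
        ph.truth.to_json(path)
        back = GroundTruth.from_json(path)
        assert len(back.vessel_segments) == len(ph.truth.vessel_segments)
        assert len(back.planted_conflicts) == len(ph.truth.planted_conflicts)
        np.testing.assert_allclose(
            back.planted_conflicts[0].position,
            ph.truth.planted_conflicts[0].position,
        )

    def test_write_phantom_produces_files(self, tmp_path):
        from seegaudit import write_phantom

        ph = generate_phantom(PhantomSpec(**SMALL, seed=13))
        write_phantom(ph, tmp_path)
        assert (tmp_path / "dsa.nii.gz").exists()
        assert (tmp_path / "mask_brain.nii.gz").exists()
        assert (tmp_path / "ground_truth.json").exists()
        assert (tmp_path / "electrodes.json").exists()
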