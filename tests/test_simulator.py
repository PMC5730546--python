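"""Simulator: renewal-process kinematics, Hill draws, rendering, assays."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from daphtox.simulator import (
    PHASE_IMMOBILE,
    AnimalGroundTruth,
    ChamberSpec,
    LocomotionParams,
    ToxicantEffect,
    apply_dose,
    chamber_background,
    generate_assay,
    hill_probability,
    render_clip,
    sample_immobilization,
    sample_separated_trajectories,
    sample_trajectory,
)


class TestChamberSpec:
    def test_rendered_dimensions_follow_calibration(self):
        ch = ChamberSpec(mm_per_px=13.0 / 512.0)
        assert ch.shape_px == (512, int(np.ceil(8.0 / (13.0 / 512.0))))

    @pytest.mark.parametrize("field", ["length_mm", "width_mm", "depth_mm", "mm_per_px"])
    def test_nonpositive_dimensions_rejected(self, field):
        with pytest.raises(ValueError, match=field):
            ChamberSpec(**{field: 0.0})


class TestLocomotionParams:
    @pytest.mark.parametrize(
        "field,value",
        [
            ("hop_rate_hz", -1.0),
            ("hop_rate_hz", np.nan),
            ("hop_length_mm_mean", -0.1),
            ("sink_speed_mm_s", -0.5),
            ("upward_bias", 1.5),
            ("body_length_mm", 0.0),
        ],
    )
    def test_invalid_values_rejected_naming_field(self, field, value):
        with pytest.raises(ValueError, match=field):
            LocomotionParams(**{field: value})

    def test_expected_distance_closed_form(self):
        p = LocomotionParams(hop_rate_hz=2.0, hop_length_mm_mean=1.5)
        assert p.expected_distance_mm_per_s == pytest.approx(3.0)


class TestSampleTrajectory:
    def test_degenerate_rates_give_constant_position(self, chamber):
        p = LocomotionParams(hop_rate_hz=0.0, sink_speed_mm_s=0.0)
        tr = sample_trajectory(p, chamber, duration_s=10, fps=30, seed=0)
        assert tr.path_length_mm == 0.0
        assert np.all(tr.x_mm == tr.x_mm[0])
        assert np.all(tr.y_mm == tr.y_mm[0])

    def test_pure_sedimentation_descends_at_sink_speed(self, chamber):
        p = LocomotionParams(hop_rate_hz=0.0, sink_speed_mm_s=0.5)
        y0 = chamber.length_mm / 2
        tr = sample_trajectory(
            p, chamber, duration_s=10, fps=30, seed=0, start_xy=(4.0, y0)
        )
        # descends sink_speed * t along gravity (+y), sampled to the last frame
        expected = y0 + 0.5 * tr.t_s[-1]
        assert tr.y_mm[-1] == pytest.approx(expected, abs=1e-9)
        assert np.all(np.diff(tr.y_mm) >= 0)

    def test_sedimentation_stops_at_chamber_floor(self, chamber):
        p = LocomotionParams(hop_rate_hz=0.0, sink_speed_mm_s=2.0)
        tr = sample_trajectory(
            p, chamber, duration_s=30, fps=30, seed=0, start_xy=(4.0, 6.0)
        )
        assert tr.y_mm[-1] <= chamber.length_mm
        assert tr.y_mm[-1] >= chamber.bottom_band_y_mm

    def test_mean_swim_distance_matches_renewal_expectation(self, chamber):
        """Monte-Carlo mean vs closed form hop_rate * duration * hop_length."""
        p = LocomotionParams(
            hop_rate_hz=1.0, hop_length_mm_mean=2.0, hop_length_mm_sd=0.0,
            sink_speed_mm_s=0.0,
        )
        dist = np.array(
            [
                sample_trajectory(p, chamber, 30, 30, seed=i).swim_distance_mm
                for i in range(500)
            ]
        )
        expected = 1.0 * 30.0 * 2.0
        se = dist.std() / np.sqrt(len(dist))
        assert abs(dist.mean() - expected) < 3 * se

    @pytest.mark.parametrize("seed", [0, 1, 99])
    def test_positions_stay_inside_chamber(self, chamber, params, seed):
        tr = sample_trajectory(params, chamber, 30, 30, seed=seed)
        assert np.all(chamber.contains(tr.x_mm, tr.y_mm))

    def test_reproducible_from_seed(self, chamber, params):
        a = sample_trajectory(params, chamber, 10, 30, seed=7)
        b = sample_trajectory(params, chamber, 10, 30, seed=7)
        assert np.array_equal(a.x_mm, b.x_mm)
        assert np.array_equal(a.y_mm, b.y_mm)
        assert np.array_equal(a.phase, b.phase)

    def test_immobile_animal_rests_in_bottom_band(self, chamber, params):
        tr = sample_trajectory(params, chamber, 15, 10, seed=3, immobile=True)
        assert tr.immobile
        assert np.all(tr.phase == PHASE_IMMOBILE)
        assert tr.y_mm[-1] >= chamber.bottom_band_y_mm
        assert tr.path_length_mm == 0.0

    def test_frame_count_is_fps_times_duration(self, chamber, params):
        tr = sample_trajectory(params, chamber, duration_s=2.5, fps=30, seed=0)
        assert tr.n_frames == 75

    def test_seed_required(self, chamber, params):
        with pytest.raises(ValueError, match="seed"):
            sample_trajectory(params, chamber, 10, 30, seed=None)


class TestSeparatedTrajectories:
    def test_lanes_guarantee_pairwise_separation(self, chamber, params):
        truths = sample_separated_trajectories(
            5, params, chamber, duration_s=5, fps=30, seed=1, lane_margin_mm=0.75
        )
        ys = np.stack([t.y_mm for t in truths])
        xs = np.stack([t.x_mm for t in truths])
        for i in range(5):
            for j in range(i + 1, 5):
                d = np.hypot(xs[i] - xs[j], ys[i] - ys[j])
                assert d.min() >= 1.5  # 2 * lane_margin


class TestApplyDose:
    def test_zero_concentration_is_identity(self, params):
        eff = ToxicantEffect(ec50=1.0, hill_slope=2.0, activity_curve=lambda c, t: 0.1)
        for t in (0.0, 1.0, 24.0):
            assert apply_dose(params, eff, 0.0, t) == params

    def test_multiplier_scales_hop_rate_only(self, params):
        eff = ToxicantEffect(ec50=1.0, hill_slope=2.0, activity_curve=lambda c, t: 0.4)
        dosed = apply_dose(params, eff, 1.0, 1.0)
        assert dosed.hop_rate_hz == pytest.approx(0.4 * params.hop_rate_hz)
        assert dataclasses.replace(dosed, hop_rate_hz=params.hop_rate_hz) == params

    def test_onset_lag_delays_modulation(self, params):
        eff = ToxicantEffect(
            ec50=1.0, hill_slope=2.0, activity_curve=lambda c, t: 0.4, onset_lag_h=2.0
        )
        assert apply_dose(params, eff, 1.0, 1.0) == params
        assert apply_dose(params, eff, 1.0, 2.0).hop_rate_hz < params.hop_rate_hz

    def test_negative_multiplier_rejected(self, params):
        eff = ToxicantEffect(ec50=1.0, hill_slope=2.0, activity_curve=lambda c, t: -1.0)
        with pytest.raises(ValueError, match="multiplier"):
            apply_dose(params, eff, 1.0, 1.0)


class TestImmobilization:
    def test_zero_concentration_never_immobilizes(self):
        eff = ToxicantEffect(ec50=0.5, hill_slope=2.0)
        assert not any(sample_immobilization(eff, 0.0, 1000, seed=0))

    def test_hill_midpoint_is_exactly_half(self):
        for ec50, h in [(0.15, 2.0), (1.7, 1.0), (210.8, 3.5)]:
            assert hill_probability(ec50, ec50, h) == pytest.approx(0.5, abs=1e-12)

    def test_immobile_fraction_matches_hill_value(self):
        # p = 0.45^2 / (0.15^2 + 0.45^2) = 0.9
        eff = ToxicantEffect(ec50=0.15, hill_slope=2.0)
        n = 10_000
        frac = np.mean(sample_immobilization(eff, 0.45, n, seed=11))
        sigma = np.sqrt(0.9 * 0.1 / n)
        assert abs(frac - 0.9) < 3 * sigma

    def test_hill_curve_matched_across_concentration_grid(self):
        eff = ToxicantEffect(ec50=1.0, hill_slope=2.0)
        n = 2000
        for i, c in enumerate(np.geomspace(0.1, 10, 7)):
            p = hill_probability(c, 1.0, 2.0)
            frac = np.mean(sample_immobilization(eff, c, n, seed=100 + i))
            sigma = np.sqrt(max(p * (1 - p), 1e-9) / n)
            assert abs(frac - p) <= 4 * sigma + 1e-9

    @given(st.floats(0.01, 100.0))
    def test_hill_probability_bounded(self, c):
        p = hill_probability(c, 1.0, 2.0)
        assert 0.0 <= p <= 1.0


class TestRenderClip:
    def test_empty_scene_is_background_plus_noise(self, chamber):
        clip = render_clip([], chamber, fps=10, noise_sd=2.0, blur_px=1.0, seed=0)
        bg = chamber_background(chamber, blur_px=1.0)
        assert np.abs(clip.frames[0].astype(float) - bg).max() < 12  # ~5 sigma

    def test_centered_animal_centroid_within_half_pixel(self, chamber, params):
        p = LocomotionParams(hop_rate_hz=0.0, sink_speed_mm_s=0.0)
        tr = sample_trajectory(
            p, chamber, 1.0, 10, seed=0, start_xy=(4.0, 6.5)
        )
        clip = render_clip([tr], chamber, noise_sd=0.0, blur_px=1.0, seed=0)
        # brute-force center of mass of the thresholded dark mask
        frame = clip.frames[0].astype(float)
        mask = frame < 128
        rows, cols = np.nonzero(mask)
        cy, cx = rows.mean(), cols.mean()
        assert abs(cx - 4.0 / chamber.mm_per_px) < 0.5
        assert abs(cy - 6.5 / chamber.mm_per_px) < 0.5

    def test_separated_animals_render_distinct_components(self, lane_clip):
        from scipy import ndimage

        frame = lane_clip.frames[0].astype(float)
        interior = frame[4:-4, 4:-4]
        _, n = ndimage.label(interior < 128)
        assert n == 5

    def test_animal_outside_chamber_rejected(self, chamber):
        t = np.arange(10) / 10.0
        bad = AnimalGroundTruth(
            0, t, np.full(10, -1.0), np.full(10, 5.0),
            np.zeros(10, dtype=np.uint8), False,
        )
        with pytest.raises(ValueError, match="bounds"):
            render_clip([bad], chamber)

    def test_pixels_reproducible_from_seed(self, chamber, params):
        tr = sample_trajectory(params, chamber, 1.0, 10, seed=5)
        a = render_clip([tr], chamber, seed=9)
        b = render_clip([tr], chamber, seed=9)
        assert np.array_equal(a.frames, b.frames)


class TestGenerateAssay:
    DESIGN = {
        "groups": [{"name": "control", "concentration": 0.0}]
        + [{"name": f"c{i}", "concentration": 0.1 * 2**i} for i in range(7)],
        "replicates": 3,
        "animals_per_chamber": 2,
        "duration_s": 1.0,
        "fps": 10.0,
        "sampling_times_h": [1.0],
        "render": False,
        "effect": {"ec50": 1.0, "hill_slope": 2.0},
    }

    def test_eight_groups_of_three_mirror_the_chip(self):
        ds = generate_assay(self.DESIGN, seed=1)
        assert len(ds.chambers()) == 24

    def test_missing_control_group_rejected(self):
        design = dict(self.DESIGN)
        design["groups"] = [{"name": "c1", "concentration": 1.0}]
        with pytest.raises(ValueError, match="control"):
            generate_assay(design, seed=1)

    def test_empty_replicate_group_rejected(self):
        design = dict(self.DESIGN)
        design["groups"] = self.DESIGN["groups"][:1] + [
            {"name": "bad", "concentration": 1.0, "replicates": 0}
        ]
        with pytest.raises(ValueError, match="replicates"):
            generate_assay(design, seed=1)

    def test_same_seed_gives_bit_identical_dataset(self):
        design = dict(self.DESIGN, render=True, groups=self.DESIGN["groups"][:2])
        a = generate_assay(design, seed=3)
        b = generate_assay(design, seed=3)
        for oa, ob in zip(a.observations, b.observations):
            assert np.array_equal(oa.clip.frames, ob.clip.frames)
            for ta, tb in zip(oa.truths, ob.truths):
                assert np.array_equal(ta.x_mm, tb.x_mm)
            assert oa.immobile == ob.immobile

    def test_animal_count_constant_within_chamber(self):
        ds = generate_assay(self.DESIGN, seed=2)
        for obs in ds.observations:
            assert len(obs.truths) == 2
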