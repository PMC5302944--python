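"""Nucleus segmentation, focus quantification, repair kinetics, correlation."""

import numpy as np
import pytest

from radioqc import foci as fx
from radioqc import synthetic
from radioqc.foci import (
    FociStats,
    correlate_with_survival,
    detect_foci,
    foci_statistics,
    qc_filter_nuclei,
    repair_kinetics,
    segment_nuclei,
)


def disc_image(radius_px, shape=(160, 160), amplitude=100.0, noise=2.0, seed=0, center=None):
    rng = np.random.default_rng(seed)
    cy, cx = center if center is not None else (shape[0] / 2, shape[1] / 2)
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    img = amplitude * (((yy - cy) ** 2 + (xx - cx) ** 2) <= radius_px**2) + 10.0
    return img + rng.normal(0, noise, shape)


class TestSegmentation:
    def test_disc_area_recovered_within_5_percent(self):
        px = 0.322
        for seed, r_px in enumerate((8, 12, 18, 25)):
            img = disc_image(r_px, seed=seed)
            seg = segment_nuclei(img, px, rolling_ball_radius=30, min_area=1.0)
            assert len(seg.nuclei) == 1
            true_area = np.pi * (r_px * px) ** 2
            assert seg.nuclei[0].area == pytest.approx(true_area, rel=0.05)

    def test_touching_discs_split_by_watershed(self):
        r = 14
        img = (disc_image(r, center=(80, 68), noise=0.0)
               + disc_image(r, center=(80, 68 + int(1.8 * r)), noise=0.0) - 20.0)
        img += np.random.default_rng(0).normal(0, 2.0, img.shape)
        seg = segment_nuclei(img, 0.322, rolling_ball_radius=30, min_area=1.0,
                             marker_min_distance_um=3.0)
        assert len(seg.nuclei) == 2

    def test_blank_image_gives_empty_list(self):
        with pytest.warns(UserWarning):
            seg = segment_nuclei(np.zeros((64, 64)), 0.322)
        assert seg.nuclei == []

    def test_generator_round_trip_counts_and_areas(self):
        scen = synthetic.generate_cell_layer(10, (70, 70), seed=4, background_foci_rate=0)
        seg = segment_nuclei(scen.dapi, scen.pixel_size, rolling_ball_radius=25)
        assert len(seg.nuclei) == 10
        gt = np.sort([(scen.truth.nucleus_masks == l).sum() * scen.pixel_size**2
                      for l in range(1, 11)])
        measured = np.sort([n.area for n in seg.nuclei])
        assert np.max(np.abs(measured - gt) / gt) < 0.05

    def test_empty_stack_rejected(self):
        with pytest.raises(ValueError):
            segment_nuclei(np.zeros((0, 4, 4)), 0.322)


class TestFocusDetection:
    def make_scene(self, seed=3):
        tracks = synthetic.SyntheticGroundTruth(
            spot_positions=np.array([[21.0, 24.0], [27.0, 24.0], [24.0, 21.0],
                                     [24.0, 27.0], [24.0, 24.0]]),
            spot_classes=["primary"] * 5,
        )
        return synthetic.generate_cell_layer(
            [250.0], (48, 48), tracks=tracks, foci_per_track=1.0,
            translation=(0.0, 0.0), background_foci_rate=0.0,
            poisson_foci=False, nucleus_centers=[(24.0, 24.0)], seed=seed,
        )

    def test_five_generated_foci_all_detected(self):
        scen = self.make_scene()
        seg = segment_nuclei(scen.dapi, scen.pixel_size, rolling_ball_radius=25)
        assert len(detect_foci(scen.foci, seg)) == 5

    def test_zero_signal_channel_gives_no_foci(self):
        scen = self.make_scene()
        seg = segment_nuclei(scen.dapi, scen.pixel_size, rolling_ball_radius=25)
        blank = np.zeros_like(scen.foci)
        assert detect_foci(blank, seg) == []

    def test_counts_invariant_under_intensity_scaling(self):
        scen = self.make_scene()
        seg = segment_nuclei(scen.dapi, scen.pixel_size, rolling_ball_radius=25)
        n = len(detect_foci(scen.foci, seg))
        assert len(detect_foci(scen.foci * 11.7, seg)) == n

    def test_focus_area_scales_with_generated_radius(self):
        """Doubling the generated radius quadruples the measured area."""
        mean_area = {}
        for radius in (0.4, 0.8):
            areas = []
            for seed in range(4):
                tracks = synthetic.SyntheticGroundTruth(
                    spot_positions=np.array([[12.0, 12.0], [28.0, 28.0]]),
                    spot_classes=["primary"] * 2,
                )
                scen = synthetic.generate_cell_layer(
                    [120.0] * 2, (40, 40), tracks=tracks, foci_per_track=1.0,
                    focus_radius=radius, translation=(0.0, 0.0), pixel_size=0.1,
                    background_foci_rate=0.0, poisson_foci=False,
                    nucleus_centers=[(12.0, 12.0), (28.0, 28.0)], seed=seed,
                )
                seg = segment_nuclei(scen.dapi, scen.pixel_size, rolling_ball_radius=25)
                areas += [f.area for f in detect_foci(scen.foci, seg, rolling_ball_radius=32)]
            mean_area[radius] = np.mean(areas)
        assert 3.5 <= mean_area[0.8] / mean_area[0.4] <= 4.5

    def test_mismatched_grids_rejected(self):
        scen = self.make_scene()
        seg = segment_nuclei(scen.dapi, scen.pixel_size, rolling_ball_radius=25)
        with pytest.raises(ValueError, match="do not match"):
            detect_foci(scen.foci[:, :-5, :-5], seg)


class TestQcFilter:
    def test_pan_stained_nucleus_flagged_normal_unflagged(self):
        scen = TestFocusDetection().make_scene()  # nucleus with 5 punctate foci
        other = synthetic.generate_cell_layer(
            [150.0], (48, 48), background_foci_rate=0.0,
            nucleus_centers=[(12.0, 12.0)], seed=8,
        )
        dapi = np.maximum(scen.dapi, other.dapi)
        chan = scen.foci.copy()
        seg = segment_nuclei(dapi, scen.pixel_size, rolling_ball_radius=25)
        assert len(seg.nuclei) == 2
        # paint the second nucleus uniformly bright in the focus channel
        second = min(seg.nuclei, key=lambda n: n.centroid[0]).label
        chan[:, seg.labels == second] = 150.0
        seg = qc_filter_nuclei(seg, chan)
        flags = {n.label: n.qc_flags for n in seg.nuclei}
        assert "pan_stained" in flags[second]
        normal = [l for l in flags if l != second][0]
        assert "pan_stained" not in flags[normal] and "apoptotic" not in flags[normal]

    def test_small_nucleus_flagged_apoptotic(self):
        scen = synthetic.generate_cell_layer([18.0], (30, 30), seed=0,
                                             background_foci_rate=0.0,
                                             nucleus_centers=[(15.0, 15.0)])
        seg = segment_nuclei(scen.dapi, scen.pixel_size, rolling_ball_radius=25,
                             min_area=5.0)
        seg = qc_filter_nuclei(seg, scen.foci)
        assert "apoptotic" in seg.nuclei[0].qc_flags

    def test_empty_segmentation_passes_through(self):
        seg = fx.NucleusSegmentation(np.zeros((16, 16), np.int32), [], 0.322)
        assert qc_filter_nuclei(seg, np.zeros((16, 16))).nuclei == []


class TestStatistics:
    def test_background_subtraction(self):
        s = FociStats.from_counts(np.full(200, 5.16), background_per_nucleus=0.16)
        assert s.mean_foci_per_nucleus == pytest.approx(5.0)
        assert not s.floored

    def test_floor_at_zero_flagged(self):
        s = FociStats.from_counts(np.full(150, 0.10), background_per_nucleus=0.16)
        assert s.mean_foci_per_nucleus == 0.0
        assert s.floored

    def test_zero_background_is_identity(self):
        counts = np.random.default_rng(0).poisson(4.0, 150)
        s = FociStats.from_counts(counts, background_per_nucleus=0.0)
        assert s.mean_foci_per_nucleus == pytest.approx(counts.mean())

    def test_all_flagged_nuclei_rejected(self):
        seg = fx.NucleusSegmentation(np.zeros((8, 8), np.int32), [], 0.322)
        with pytest.raises(ValueError):
            foci_statistics([], seg)


class TestRepairKinetics:
    def test_residual_fraction_is_ratio_to_baseline(self):
        stats = {
            0.5: FociStats.from_counts(np.full(150, 20.16)),
            72.0: FociStats.from_counts(np.full(150, 3.22)),
        }
        res = repair_kinetics(stats)
        assert res[72.0] == pytest.approx(0.153, abs=1e-3)
        assert res[0.5] == pytest.approx(1.0)

    def test_constant_counts_give_full_residual(self):
        stats = {t: FociStats.from_counts(np.full(120, 10.16)) for t in (0.5, 24.0, 72.0)}
        assert all(v == pytest.approx(1.0) for v in repair_kinetics(stats).values())

    def test_missing_baseline_rejected(self):
        with pytest.raises(ValueError, match="baseline"):
            repair_kinetics({24.0: FociStats.from_counts(np.full(150, 5.0))})

    @pytest.mark.parametrize("residual", [0.023, 0.153, 0.176])
    def test_generator_round_trip(self, residual):
        """Residual fractions recovered within +-0.03 from Poisson counts."""
        estimates = []
        for seed in range(30):
            tc = synthetic.generate_timecourse(residual_fraction=residual, seed=seed)
            stats = {t: FociStats.from_counts(c) for t, c in tc.items()}
            estimates.append(repair_kinetics(stats)[72.0])
        assert abs(np.mean(estimates) - residual) < 0.03


class TestSurvivalCorrelation:
    def test_collinear_input_gives_r2_one(self):
        metric = np.array([1.0, 2.0, 3.0, 4.0])
        res = correlate_with_survival(metric, 0.9 - 0.1 * metric)
        assert res.r_squared == pytest.approx(1.0)
        assert res.slope == pytest.approx(-0.1)

    def test_recovers_true_r2_in_simulation(self):
        rng = np.random.default_rng(0)
        r2s = []
        for _ in range(50):
            x = np.linspace(5, 20, 5)
            y = 0.9 - 0.04 * x
            y_noisy = y + rng.normal(0, 0.033, 5)
            r2s.append(correlate_with_survival(x, y_noisy).r_squared)
        # analytic R2_true = var(signal)/(var(signal)+noise^2) ~ 0.95
        signal_var = np.var(0.04 * np.linspace(5, 20, 5))
        r2_true = signal_var / (signal_var + 0.033**2)
        assert abs(np.mean(r2s) - r2_true) < 0.05

    def test_constant_metric_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            correlate_with_survival([2.0, 2.0, 2.0], [0.1, 0.2, 0.3])

    def test_too_few_conditions_rejected(self):
        with pytest.raises(ValueError):
            correlate_with_survival([1.0, 2.0], [0.5, 0.4])
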