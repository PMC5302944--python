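"""Ground-truth generators: determinism, closed forms, study-scale checks."""

import numpy as np
import pytest

from radioqc import synthetic
from radioqc.synthetic import (
    expected_timecourse,
    generate_cell_layer,
    generate_fntd_image,
    generate_nuclear_areas,
    generate_survival_table,
    generate_timecourse,
)


class TestSurvivalTable:
    def test_zero_dose_sf_is_one(self):
        data = generate_survival_table(0.173, 0.032, [0.0, 2.0], noise=False)
        assert np.all(data.sf[data.dose == 0] == 1.0)

    def test_noise_free_matches_hand_computed_lq(self):
        # exp(-0.173*4 - 0.032*16) = exp(-1.204) = 0.2999...
        data = generate_survival_table(0.173, 0.032, [4.0], noise=False)
        assert data.sf[data.dose == 4.0][0] == pytest.approx(0.300, abs=5e-4)

    def test_noise_free_matches_hand_computed_linear(self):
        # exp(-0.332*2) = exp(-0.664) = 0.5149...
        data = generate_survival_table(0.332, 0.0, [2.0], noise=False)
        assert data.sf[data.dose == 2.0][0] == pytest.approx(0.515, abs=5e-4)

    def test_deterministic_given_seed(self):
        a = generate_survival_table(0.2, 0.03, [1, 2, 4], seed=42)
        b = generate_survival_table(0.2, 0.03, [1, 2, 4], seed=42)
        assert np.array_equal(a.sf, b.sf)

    def test_counting_noise_present_and_unbiased(self):
        sfs = [
            generate_survival_table(0.3, 0.0, [2.0], seed=s).sf[-3:].mean()
            for s in range(100)
        ]
        truth = np.exp(-0.6)
        assert np.std(sfs) > 0
        assert np.mean(sfs) == pytest.approx(truth, rel=0.02)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            generate_survival_table(np.nan, 0.0, [1, 2])
        with pytest.raises(ValueError):
            generate_survival_table(-0.1, 0.0, [1, 2])
        with pytest.raises(ValueError):
            generate_survival_table(0.1, 0.0, [1, 2], plating_efficiency=0.0)


class TestNuclearAreas:
    def test_degenerate_cv_zero(self):
        areas = generate_nuclear_areas(1000, 90.0, 0.0)
        assert np.all(areas == 90.0)

    def test_large_sample_mean_and_cv(self):
        areas = generate_nuclear_areas(100_000, 90.0, 0.3, seed=0)
        assert areas.mean() == pytest.approx(90.0, rel=0.01)
        assert areas.std() / areas.mean() == pytest.approx(0.3, rel=0.05)
        assert np.all(areas > 0)

    def test_right_skew(self):
        areas = generate_nuclear_areas(50_000, 90.0, 0.3, seed=1)
        assert np.mean(((areas - areas.mean()) / areas.std()) ** 3) > 0.5

    def test_study_scale_mean_hits(self):
        """Fluence x mean area ~ 3.4 hits at the carbon-beam settings."""
        areas = generate_nuclear_areas(1239, 89.5, 0.3, seed=2)
        assert 3.8e6 * areas.mean() * 1e-8 == pytest.approx(3.4, abs=0.1)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            generate_nuclear_areas(0, 90.0, 0.3)
        with pytest.raises(ValueError):
            generate_nuclear_areas(10, -5.0, 0.3)
        with pytest.raises(ValueError):
            generate_nuclear_areas(10, 90.0, np.inf)


class TestFntdImage:
    def test_zero_fluence_blank(self):
        image, truth = generate_fntd_image(0.0, field_um=(30, 30), seed=0, noise=False)
        assert len(truth.spot_positions) == 0
        assert np.ptp(image.data) == 0

    def test_expected_spot_count_unit_conversion(self):
        """Poisson mean = fluence x area: ~1717 spots on the full field."""
        counts = [
            len(generate_fntd_image(3.8e6, seed=s)[1].spot_positions)
            for s in range(30)
        ]
        expected = 3.8e6 * (212.55e-4) ** 2
        assert expected == pytest.approx(1717, abs=1)
        assert np.mean(counts) == pytest.approx(expected, rel=0.02)

    def test_grid_positions_have_isolated_maxima(self):
        pos = np.array([[10.0 + 20 * i, 10.0 + 20 * j] for i in range(3) for j in range(3)])
        image, truth = generate_fntd_image(0.0, field_um=(80, 80), positions=pos,
                                           seed=0, noise=False)
        from scipy.ndimage import maximum_filter

        data = image.data
        local_max = (data == maximum_filter(data, size=9)) & (data > data.min() + 1)
        assert local_max.sum() == 9

    def test_deterministic_given_seed(self):
        a, _ = generate_fntd_image(1e6, field_um=(40, 40), seed=5)
        b, _ = generate_fntd_image(1e6, field_um=(40, 40), seed=5)
        assert np.array_equal(a.data, b.data)

    def test_bimodal_rates_and_fragment_fraction(self):
        _, truth = generate_fntd_image(3.8e6, seed=1)
        frac = np.mean([c == "fragment" for c in truth.spot_classes])
        assert 0.04 < frac < 0.13
        rates = truth.spot_rates
        prim = rates[np.array(truth.spot_classes) == "primary"]
        frag = rates[np.array(truth.spot_classes) == "fragment"]
        assert prim.mean() > frag.mean() + 2.0

    def test_sub_pixel_field_rejected(self):
        with pytest.raises(ValueError, match="smaller than one pixel"):
            generate_fntd_image(1e6, field_um=(0.01, 0.01), pixel_size=0.5)


class TestCellLayer:
    def test_no_tracks_no_background_gives_empty_focus_truth(self):
        scen = generate_cell_layer(4, (40, 40), background_foci_rate=0.0, seed=0)
        assert len(scen.truth.focus_positions) == 0

    def test_translation_recorded_and_applied_exactly(self):
        tracks = synthetic.SyntheticGroundTruth(
            spot_positions=np.array([[15.0, 20.0], [25.0, 20.0]]),
            spot_classes=["primary", "primary"],
        )
        scen = generate_cell_layer(
            [150.0], (40, 40), tracks=tracks, translation=(3.0, 0.0),
            background_foci_rate=0.0, foci_per_track=1.0, poisson_foci=False,
            nucleus_centers=[(20.0, 20.0)], seed=1,
        )
        assert scen.truth.translation == (3.0, 0.0)
        for (fx, fy), src in zip(scen.truth.focus_positions, scen.truth.focus_sources):
            sx, sy = tracks.spot_positions[src]
            assert np.hypot(fx - sx, fy - sy) == pytest.approx(3.0, abs=1e-9)

    def test_nucleus_masks_match_requested_areas(self):
        areas = [80.0, 120.0, 160.0]
        scen = generate_cell_layer(areas, (60, 60), seed=2)
        for lab, req in enumerate(areas, start=1):
            measured = (scen.truth.nucleus_masks == lab).sum() * scen.pixel_size**2
            assert measured == pytest.approx(req, rel=0.05)

    def test_unplaceable_nuclei_reported(self):
        with pytest.raises(ValueError, match="without overlap|larger than the field"):
            generate_cell_layer([400.0] * 20, (25, 25), seed=3)

    def test_background_foci_rate(self):
        n_bg = [
            len(generate_cell_layer(10, (80, 80), background_foci_rate=0.5, seed=s
                                    ).truth.focus_positions)
            for s in range(30)
        ]
        assert np.mean(n_bg) == pytest.approx(5.0, rel=0.25)


class TestTimecourse:
    def test_expected_value_closed_forms(self):
        assert expected_timecourse(20.0, 0.0, 6.0, 0.0) == 20.0
        assert expected_timecourse(20.0, 0.0, 6.0, 6.0) == pytest.approx(10.0)
        # residual plateau at late times
        assert expected_timecourse(20.0, 0.153, 6.0, 1e6) / 20.0 == pytest.approx(0.153)

    def test_noise_free_mode_emits_expected_values(self):
        tc = generate_timecourse(20.0, 0.2, 6.0, [0.5, 72.0], n_nuclei=5,
                                 background_per_nucleus=0.0, noise=False)
        assert np.allclose(tc[0.5], expected_timecourse(20.0, 0.2, 6.0, 0.5))

    def test_poisson_counts_deterministic_and_unbiased(self):
        a = generate_timecourse(seed=9)
        b = generate_timecourse(seed=9)
        for t in a:
            assert np.array_equal(a[t], b[t])
        tc = generate_timecourse(20.0, 0.153, 6.0, [0.5], n_nuclei=20000,
                                 background_per_nucleus=0.16, seed=0)
        mu = expected_timecourse(20.0, 0.153, 6.0, 0.5) + 0.16
        assert tc[0.5].mean() == pytest.approx(mu, rel=0.01)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            generate_timecourse(residual_fraction=1.2)
        with pytest.raises(ValueError):
            generate_timecourse(halflife=0.0)
        with pytest.raises(ValueError):
            generate_timecourse(timepoints=[-1.0])
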