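"""Densitometry: lane extraction, two-Gaussian fitting, f_FL, aggregation."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from forceprofile.densitometry import (
    FflMeasurement,
    FitConfig,
    LaneProfile,
    aggregate_replicates,
    compute_ffl,
    extract_lane_profile,
    fit_two_bands,
)
from forceprofile.synthsim import (
    expected_band_separation,
    render_gel_image,
    render_lane,
)


def gaussian(x, c, s, area):
    return area / (s * np.sqrt(2 * np.pi)) * np.exp(-0.5 * ((x - c) / s) ** 2)


def two_band_profile(fl_area, a_area, fl_c=120.0, a_c=160.0, sigma=4.0,
                     offset=10.0, slope=0.0, n=300, noise=0.0, seed=0):
    x = np.arange(n, dtype=float)
    y = offset + slope * x + gaussian(x, fl_c, sigma, fl_area) + gaussian(
        x, a_c, sigma, a_area
    )
    if noise > 0:
        y = y + np.random.default_rng(seed).normal(0, noise * y.max(), n)
    return LaneProfile(positions=x, intensities=y, construct_name="c", replicate_id="r1")


class TestExtractLaneProfile:
    def test_uniform_region_sums_across_width(self):
        img = np.full((40, 30), 3.0)
        prof = extract_lane_profile(img, (0, 40, 5, 15))
        assert np.allclose(prof.intensities, 30.0)  # width 10 * value 3

    def test_width_one_region_is_the_pixel_column(self):
        img = np.arange(1200, dtype=float).reshape(40, 30)
        prof = extract_lane_profile(img, (10, 30, 7, 8))
        assert np.allclose(prof.intensities, img[10:30, 7])

    def test_round_trip_with_rendered_gel(self, full_construct, noiseless_render, rng):
        prof, _ = render_lane(0.4, full_construct, noiseless_render, rng)
        img = render_gel_image([prof], lane_width=10, gap=5)
        extracted = extract_lane_profile(img.astype(float), (0, len(prof), 5, 15))
        # image is rescaled to uint16; f_FL is scale-invariant so compare shape
        a, b = extracted.intensities, prof.intensities
        corr = np.corrcoef(a, b)[0, 1]
        assert corr > 0.9999

    def test_out_of_bounds_region_rejected(self):
        with pytest.raises(ValueError):
            extract_lane_profile(np.zeros((10, 10)), (0, 20, 0, 5))


class TestFitTwoBands:
    def test_noiseless_recovery_exact(self):
        prof = two_band_profile(300.0, 100.0)
        fit = fit_two_bands(prof, expected_separation=40.0)
        assert fit.converged
        assert fit.fl_band.area == pytest.approx(300.0, rel=1e-3)
        assert fit.a_band.area == pytest.approx(100.0, rel=1e-3)
        # parameter recovery to optimizer tolerance
        assert fit.fl_band.center == pytest.approx(120.0, rel=1e-6)
        assert fit.fl_band.sigma == pytest.approx(4.0, rel=1e-6)

    def test_close_bands_noiseless_still_exact(self):
        # separation 2 sigma: a single merged maximum, yet the seeded
        # shared-width refit resolves both areas exactly without noise
        prof = two_band_profile(300.0, 100.0, fl_c=140.0, a_c=148.0)
        fit = fit_two_bands(prof, expected_separation=8.0)
        assert fit.fl_band.area == pytest.approx(300.0, rel=1e-3)
        assert fit.a_band.area == pytest.approx(100.0, rel=1e-3)

    def test_close_bands_with_noise(self):
        # separation 2 sigma at 2% noise: band overlap makes per-lane areas
        # intrinsically uncertain (even fits with the width fixed at truth
        # show ~3% median error); assert the achievable accuracy
        rel_errors, f_errors = [], []
        for seed in range(20):
            prof = two_band_profile(
                300.0, 100.0, fl_c=140.0, a_c=148.0, noise=0.02, seed=seed
            )
            fit = fit_two_bands(prof, expected_separation=8.0)
            rel_errors.append(
                max(
                    abs(fit.fl_band.area - 300.0) / 300.0,
                    abs(fit.a_band.area - 100.0) / 100.0,
                )
            )
            f_errors.append(abs(compute_ffl(fit).f_fl - 0.75))
        assert np.median(rel_errors) <= 0.08
        assert np.median(f_errors) <= 0.02

    def test_band_ordering_invariant(self):
        fit = fit_two_bands(two_band_profile(100.0, 300.0), expected_separation=40.0)
        assert fit.fl_band.center < fit.a_band.center

    def test_single_band_defaults_to_arrested(self):
        prof = two_band_profile(0.0, 400.0)
        with pytest.warns(UserWarning, match="arrested"):
            fit = fit_two_bands(prof, expected_separation=40.0)
        assert fit.single_band
        assert fit.fl_band.area == 0.0
        assert fit.a_band.area == pytest.approx(400.0, rel=1e-3)

    def test_single_band_identified_by_expected_centers(self):
        prof = two_band_profile(400.0, 0.0)  # lone band at the FL position
        cfg = FitConfig(expected_centers=(120.0, 160.0))
        with pytest.warns(UserWarning, match="full-length"):
            fit = fit_two_bands(prof, expected_separation=40.0, config=cfg)
        assert compute_ffl(fit).f_fl == 1.0

    def test_area_conservation_noiseless(self):
        prof = two_band_profile(300.0, 100.0, slope=0.05)
        fit = fit_two_bands(prof, expected_separation=40.0)
        b0, b1 = fit.baseline
        above = np.trapezoid(
            prof.intensities - (b0 + b1 * prof.positions), prof.positions
        )
        assert fit.fl_band.area + fit.a_band.area == pytest.approx(above, rel=0.01)

    def test_flat_profile_rejected(self):
        flat = LaneProfile(np.arange(50.0), np.full(50, 7.0))
        with pytest.raises(ValueError):
            fit_two_bands(flat, expected_separation=10.0)


class TestComputeFfl:
    @pytest.mark.parametrize(
        "fl_area, a_area, expected", [(1500.0, 500.0, 0.75), (0.0, 5.0, 0.0), (5.0, 0.0, 1.0)]
    )
    def test_ratio(self, fl_area, a_area, expected):
        prof = two_band_profile(max(fl_area, 1e-9), max(a_area, 1e-9))
        # bypass fitting: construct areas directly through a synthetic fit
        from forceprofile.densitometry import BandFit, TwoBandFit

        s = 4.0
        amp = lambda area: area / (s * np.sqrt(2 * np.pi))
        fit = TwoBandFit(
            fl_band=BandFit(120.0, s, amp(fl_area)),
            a_band=BandFit(160.0, s, amp(a_area)),
            baseline=(0.0, 0.0),
            residual_rms=0.0,
            converged=True,
        )
        assert compute_ffl(fit).f_fl == pytest.approx(expected, abs=1e-12)

    def test_zero_total_area_is_an_error(self):
        from forceprofile.densitometry import BandFit, TwoBandFit

        fit = TwoBandFit(
            fl_band=BandFit(120.0, 4.0, 0.0),
            a_band=BandFit(160.0, 4.0, 0.0),
            baseline=(0.0, 0.0),
            residual_rms=0.0,
            converged=True,
        )
        with pytest.raises(ValueError):
            compute_ffl(fit)

    @given(st.floats(min_value=1e-3, max_value=1e6))
    def test_scale_invariance(self, scale):
        prof = two_band_profile(300.0, 100.0)
        scaled = LaneProfile(prof.positions, prof.intensities * scale)
        f1 = compute_ffl(fit_two_bands(prof, 40.0)).f_fl
        f2 = compute_ffl(fit_two_bands(scaled, 40.0)).f_fl
        assert f2 == pytest.approx(f1, abs=1e-6)


class TestAggregate:
    def test_two_point_mean_and_se(self):
        agg = aggregate_replicates(
            [FflMeasurement(0.70, "c"), FflMeasurement(0.80, "c")]
        )
        assert agg.mean == pytest.approx(0.75)
        assert agg.se == pytest.approx(0.05)
        assert agg.n == 2

    def test_single_measurement_flags_se_unavailable(self):
        agg = aggregate_replicates([FflMeasurement(0.6, "c")])
        assert agg.mean == 0.6 and agg.se is None and not agg.se_available

    def test_identical_replicates_have_zero_se(self):
        agg = aggregate_replicates([FflMeasurement(0.6, "c")] * 3)
        assert agg.se == 0.0

    def test_empty_and_mixed_inputs_rejected(self):
        with pytest.raises(ValueError):
            aggregate_replicates([])
        with pytest.raises(ValueError, match="mixed"):
            aggregate_replicates([FflMeasurement(0.5, "a"), FflMeasurement(0.5, "b")])
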