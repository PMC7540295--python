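"""The unmixing model, its oracle, and the wavelength-mode fallback."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import specunmix as su


def processed_mixture(pair, x, sigma=0.0, scale=1.0, seed=0):
    s = su.simulate_mixture(pair, x, noise_sigma_au=sigma, scale=scale, seed=seed)
    proc, _ = su.preprocess_sample(s, pair)
    return proc


class TestUnmixSpectrum:
    def test_pure_nucleoside_is_zero_conversion(self, thymidine_pair):
        res = su.unmix_spectrum(processed_mixture(thymidine_pair, 0.0), thymidine_pair)
        assert res.conversion == pytest.approx(0.0, abs=1e-12)
        assert res.residual_rms == pytest.approx(0.0, abs=1e-12)

    def test_constructed_mixture_recovered(self, thymidine_pair):
        res = su.unmix_spectrum(processed_mixture(thymidine_pair, 0.7), thymidine_pair)
        assert res.conversion == pytest.approx(0.7, abs=1e-12)
        assert res.coef_sum == pytest.approx(1.0, abs=1e-12)
        assert res.coeff_nucleoside == pytest.approx(0.3, abs=1e-12)

    def test_noisy_mixture_matches_grid_oracle(self, thymidine_pair):
        proc = processed_mixture(thymidine_pair, 0.55, sigma=0.002, seed=7)
        res = su.unmix_spectrum(proc, thymidine_pair)
        oracle = su.brute_force_unmix(proc, thymidine_pair, grid_step=1e-4)
        assert res.conversion == pytest.approx(oracle.conversion, abs=1e-3)

    def test_all_zero_sample_rejected(self, thymidine_pair):
        zero = su.Spectrum(thymidine_pair.grid_nm, np.zeros(thymidine_pair.grid_nm.size))
        with pytest.raises(su.SpecUnmixError, match="zero"):
            su.unmix_spectrum(zero, thymidine_pair)

    def test_collinear_references_rejected(self):
        with pytest.raises(su.SpecUnmixError, match="degenerate|indistinguishable"):
            pair = su.generate_reference_pair(
                su.SyntheticScenario(
                    nucleoside_bands=(su.GaussianBand(270.0, 12.0, 1.0),),
                    nucleobase_bands=(su.GaussianBand(270.5, 12.0, 0.9),),
                    target_isosbestic_nm=270.2,
                )
            )
            su.unmix_spectrum(processed_mixture(pair, 0.5), pair)

    def test_poor_fit_flag_on_unmodelled_background(self, thymidine_pair):
        s = su.simulate_mixture(thymidine_pair, 0.5, noise_sigma_au=0.0)
        bg = su.generate_background("solvent", {"amplitude": 0.4}, s.wavelengths_nm)
        spiked = s.with_absorbance(s.absorbance_au + bg.absorbance_au)
        proc, _ = su.preprocess_sample(spiked, thymidine_pair)
        res = su.unmix_spectrum(proc, thymidine_pair)
        assert "poor_fit" in res.flags

    def test_clean_fit_never_flags(self, thymidine_pair):
        res = su.unmix_spectrum(
            processed_mixture(thymidine_pair, 0.5, sigma=0.002, seed=3), thymidine_pair
        )
        assert not res.flags

    def test_standard_errors_cover_truth_roughly(self, thymidine_pair):
        res = su.unmix_spectrum(
            processed_mixture(thymidine_pair, 0.5, sigma=0.002, seed=11), thymidine_pair
        )
        assert np.all(np.isfinite(res.bse))
        assert 0 < res.conversion_se < 0.05
        assert abs(res.conversion - 0.5) < 5 * res.conversion_se

    def test_residual_not_beaten_by_random_candidates(self, thymidine_pair, rng):
        proc = processed_mixture(thymidine_pair, 0.4, sigma=0.002, seed=5)
        model = su.UnmixingModel(proc, thymidine_pair)
        res = model.fit()
        y, X = model.endog, model.exog
        best_rss = res.residual_rms**2 * y.size
        for _ in range(200):
            cand = rng.uniform(0, 1.5, size=2)
            rss = float(np.sum((y - X @ cand) ** 2))
            assert rss >= best_rss - 1e-12

    def test_offset_term_absorbs_flat_shift(self, thymidine_pair):
        s = su.simulate_mixture(thymidine_pair, 0.3, noise_sigma_au=0.0)
        shifted = s.with_absorbance(s.absorbance_au + 0.05)
        res = su.unmix_spectrum(shifted, thymidine_pair, fit_offset=True)
        assert res.offset == pytest.approx(0.05, abs=1e-9)
        assert res.conversion == pytest.approx(0.3, abs=1e-9)

    def test_summary_mentions_key_quantities(self, thymidine_pair):
        text = su.unmix_spectrum(
            processed_mixture(thymidine_pair, 0.25), thymidine_pair
        ).summary()
        for token in ("conversion", "nucleoside", "residual", "nnls"):
            assert token in text

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(x=st.floats(0.0, 1.0))
    def test_noiseless_exactness_property(self, thymidine_pair, x):
        res = su.unmix_spectrum(processed_mixture(thymidine_pair, x), thymidine_pair)
        assert abs(res.conversion - x) <= 1e-9

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(x=st.floats(0.0, 1.0), seed=st.integers(0, 10_000))
    def test_swap_symmetry_property(self, thymidine_pair, x, seed):
        """Swapping the references maps conversion x -> 1 - x."""
        s = su.simulate_mixture(thymidine_pair, x, noise_sigma_au=0.002, seed=seed)
        swapped_pair = thymidine_pair.swapped()
        proc, _ = su.preprocess_sample(s, thymidine_pair)
        forward = su.unmix_spectrum(proc, thymidine_pair).conversion
        backward = su.unmix_spectrum(proc, swapped_pair).conversion
        assert backward == pytest.approx(1.0 - forward, abs=1e-9)


class TestUnmixSeries:
    def test_pure_endpoints(self, thymidine_pair):
        series = su.unmix_series(
            [processed_mixture(thymidine_pair, 0.0), processed_mixture(thymidine_pair, 1.0)],
            thymidine_pair,
        )
        assert [r.conversion for r in series] == pytest.approx([0.0, 1.0], abs=1e-12)

    def test_eleven_noiseless_mixtures_exact(self, thymidine_pair):
        xs = np.round(np.linspace(0, 1, 11), 10)
        res = su.unmix_series(
            [processed_mixture(thymidine_pair, float(x)) for x in xs], thymidine_pair
        )
        np.testing.assert_allclose([r.conversion for r in res], xs, atol=1e-9)

    def test_empty_list_rejected(self, thymidine_pair):
        with pytest.raises(su.SpecUnmixError, match="empty"):
            su.unmix_series([], thymidine_pair)

    def test_stability_window_flagging(self):
        pair = su.generate_reference_pair(
            su.thymidine_like_scenario(stability_window_s=600.0)
        )
        fresh = processed_mixture(pair, 0.5)
        stale = fresh.replace(meta={**fresh.meta, "age_since_quench_s": 900.0})
        results = su.unmix_series([fresh, stale], pair)
        assert "stability" not in results[0].flags
        assert "stability" in results[1].flags


class TestBruteForce:
    def test_agrees_with_model_on_random_noiseless_mixtures(self, thymidine_pair, rng):
        for _ in range(20):
            x = float(rng.uniform())
            proc = processed_mixture(thymidine_pair, x)
            b = su.brute_force_unmix(proc, thymidine_pair, grid_step=1e-3)
            m = su.unmix_spectrum(proc, thymidine_pair)
            assert abs(b.conversion - m.conversion) <= 1e-3

    def test_pure_nucleobase(self, thymidine_pair):
        b = su.brute_force_unmix(processed_mixture(thymidine_pair, 1.0), thymidine_pair)
        assert b.conversion == pytest.approx(1.0)

    def test_coarse_grid_snaps_to_nearest_optimum(self, thymidine_pair):
        b = su.brute_force_unmix(
            processed_mixture(thymidine_pair, 0.7), thymidine_pair, grid_step=0.5
        )
        assert b.conversion in (0.5, 1.0)


class TestWavelengthMode:
    def test_pure_nucleobase_at_two_wavelengths(self, thymidine_pair):
        s = su.simulate_mixture(thymidine_pair, 1.0, noise_sigma_au=0.0)
        calib = su.WavelengthModeCalibration.from_pair(thymidine_pair, (266.0, 290.0))
        res = su.unmix_wavelength_mode(s, calib)
        assert res.conversion == pytest.approx(1.0, abs=1e-12)

    def test_matches_full_spectrum_on_noiseless_fixture(self):
        pair = su.generate_reference_pair(su.no_isosbestic_scenario())
        calib = su.WavelengthModeCalibration.from_pair(pair, (252.0, 262.0))
        for x in (0.0, 0.33, 0.8, 1.0):
            s = su.simulate_mixture(pair, x, noise_sigma_au=0.0)
            full = su.unmix_spectrum(s.restrict(*pair.fit_range_nm), pair).conversion
            two = su.unmix_wavelength_mode(s, calib).conversion
            assert two == pytest.approx(full, abs=1e-9)

    def test_proportional_responses_rejected(self):
        with pytest.raises(su.SpecUnmixError, match="singular"):
            su.WavelengthModeCalibration((260.0, 261.0), [[0.5, 0.25], [0.4, 0.2]])

    def test_single_wavelength_needs_total(self, thymidine_pair):
        s = su.simulate_mixture(thymidine_pair, 0.6, noise_sigma_au=0.0)
        calib = su.WavelengthModeCalibration.from_pair(thymidine_pair, (266.0,))
        with pytest.raises(su.SpecUnmixError, match="total"):
            su.unmix_wavelength_mode(s, calib)
        res = su.unmix_wavelength_mode(s, calib, total_amount=1.0)
        assert res.conversion == pytest.approx(0.6, abs=1e-9)

    def test_negative_amount_clipped_and_flagged(self, thymidine_pair):
        calib = su.WavelengthModeCalibration.from_pair(thymidine_pair, (266.0, 290.0))
        rn = thymidine_pair.nucleoside.spectrum
        # a spectrum below the pure-nucleoside response at 290 forces c_B < 0
        s = rn.with_absorbance(rn.absorbance_au - 0.2 * thymidine_pair.nucleobase.spectrum.absorbance_au)
        res = su.unmix_wavelength_mode(s, calib)
        assert "clipped" in res.flags
        assert res.conversion == pytest.approx(0.0)
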