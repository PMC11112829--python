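import math

import numpy as np
import pytest

from cdh_prospector import biochem as bc
from cdh_prospector.synthetic_data import (simulate_assay,
                                           simulate_purification,
                                           simulate_spectrum)


class TestVolumetricActivity:
    def test_zero_slope_gives_zero(self):
        m = bc.AssayMeasurement(slope_au_per_min=0.0)
        assert bc.volumetric_activity(m, bc.DCIP_520) == 0.0

    def test_hand_calculation(self):
        # slope/epsilon: 0.069 / 6.9 = 0.01 mM/min = 0.01 U/mL
        m = bc.AssayMeasurement(slope_au_per_min=0.069)
        assert bc.volumetric_activity(m, bc.DCIP_520) == pytest.approx(0.01)

    def test_linear_in_slope_and_dilution(self):
        base = bc.volumetric_activity(
            bc.AssayMeasurement(slope_au_per_min=0.05), bc.CYTC_550)
        doubled = bc.volumetric_activity(
            bc.AssayMeasurement(slope_au_per_min=0.10), bc.CYTC_550)
        diluted = bc.volumetric_activity(
            bc.AssayMeasurement(slope_au_per_min=0.05, dilution=10),
            bc.CYTC_550)
        assert doubled == pytest.approx(2 * base)
        assert diluted == pytest.approx(10 * base)

    def test_noisy_trace_recovers_truth_within_two_percent(self):
        for seed in range(5):
            m, truth = simulate_assay(0.4, bc.DCIP_520, noise_sd=0.002,
                                      seed=seed)
            got = bc.volumetric_activity(m, bc.DCIP_520)
            assert got == pytest.approx(
                truth.data["true_activity_U_per_ml"], rel=0.02)

    def test_negative_slope_clips_to_zero_with_warning(self):
        m = bc.AssayMeasurement(slope_au_per_min=-0.05)
        with pytest.warns(UserWarning, match="negative"):
            assert bc.volumetric_activity(m, bc.DCIP_520) == 0.0

    def test_nonlinear_trace_warns(self):
        t = np.linspace(0, 3, 10)
        m = bc.AssayMeasurement(time_min=t, absorbance=np.sin(t * 5))
        with pytest.warns(UserWarning, match="nonlinearity"):
            bc.volumetric_activity(m, bc.DCIP_520)


class TestLimitOfQuantification:
    def test_identical_blanks_give_zero(self):
        assert bc.limit_of_quantification([2.0, 2.0, 2.0]) == 0.0

    def test_unit_standard_deviation(self):
        assert bc.limit_of_quantification([1, 2, 3]) == pytest.approx(10.0)

    def test_gaussian_blanks_approach_ten_sigma(self):
        rng = np.random.default_rng(12)
        sigma = 0.03
        blanks = rng.normal(0.0, sigma, size=50)
        loq = bc.limit_of_quantification(blanks)
        assert abs(loq - 10 * sigma) / (10 * sigma) < 0.3

    def test_too_few_blanks_rejected(self):
        with pytest.raises(ValueError):
            bc.limit_of_quantification([1.0, 2.0])


class TestPurificationTable:
    def _steps(self):
        return [
            bc.PurificationStep("supernatant", 4500, 1310 / 4500,
                                {"dcip": 946.0, "cytc": 47.0}),
            bc.PurificationStep("hic", 750, 598 / 750,
                                {"dcip": 542.0, "cytc": 14.0}),
            bc.PurificationStep("aex", 15, 68 / 15,
                                {"dcip": 111.0, "cytc": 8.0}),
        ]

    def test_reference_row_is_unit(self):
        df = bc.purification_table(self._steps())
        ref = df.loc["supernatant"]
        assert ref["yield_pct[dcip]"] == pytest.approx(100.0)
        assert ref["purification_factor[dcip]"] == pytest.approx(1.0)

    def test_derived_columns_match_closed_form(self):
        df = bc.purification_table(self._steps())
        assert df.loc["aex", "specific_activity_U_mg[dcip]"] == \
            pytest.approx(111.0 / 68.0)
        assert df.loc["hic", "yield_pct[dcip]"] == \
            pytest.approx(100 * 542 / 946)
        assert df.loc["aex", "purification_factor[dcip]"] == \
            pytest.approx((111 / 68) / (946 / 1310))

    def test_yields_scale_invariant(self):
        steps = self._steps()
        scaled = [bc.PurificationStep(
            s.label, s.volume_ml, s.protein_conc_mg_ml,
            {a: v * 7.5 for a, v in s.activities.items()})
            for s in steps]
        a = bc.purification_table(steps)
        b = bc.purification_table(scaled)
        for col in ("yield_pct[dcip]", "purification_factor[dcip]"):
            assert np.allclose(a[col], b[col])

    def test_bdl_propagates_without_coercion(self):
        steps = self._steps()
        steps[2].activities["cytc"] = None
        df = bc.purification_table(steps)
        assert math.isnan(df.loc["aex", "yield_pct[cytc]"])
        shown = bc.format_table(df)
        assert shown.loc["aex", "yield_pct[cytc]"] == "b.d.l."
        # other cells unaffected
        assert shown.loc["hic", "yield_pct[cytc]"] != "b.d.l."

    def test_zero_reference_activity_rejected(self):
        steps = self._steps()
        steps[0].activities["dcip"] = 0.0
        with pytest.raises(ValueError):
            bc.purification_table(steps)

    def test_simulated_scenarios_match_truth(self):
        for seed in range(100):
            rng = np.random.default_rng(seed)
            n = int(rng.integers(1, 5))
            recov = rng.uniform(0.3, 0.95, size=n)
            purity = np.sort(rng.uniform(1.0, 30.0, size=n))
            steps, truth = simulate_purification(recov, purity, seed=seed)
            df = bc.purification_table(steps)
            for row in truth.data["steps"]:
                got = df.loc[row["label"]]
                for assay, y in row["yield_pct"].items():
                    assert got[f"yield_pct[{assay}]"] == pytest.approx(y)
                assert got["purification_factor[dcip]"] == pytest.approx(
                    row["purification_factor_primary"])


class TestConcentration:
    def test_epsilon_formula(self):
        assert bc.epsilon280_from_sequence("AAAA") == 0.0
        assert bc.epsilon280_from_sequence("WY") == 6990.0
        assert bc.epsilon280_from_sequence("CC") == 125.0
        assert bc.epsilon280_from_sequence("CC", cysteines="reduced") == 0.0

    def test_epsilon_matches_protparam_oracle(self):
        from Bio.SeqUtils.ProtParam import ProteinAnalysis

        rng = np.random.default_rng(31)
        aas = list("ACDEFGHIKLMNPQRSTVWY")
        for _ in range(5):
            seq = "".join(rng.choice(aas, 300))
            reduced, oxidized = ProteinAnalysis(
                seq).molar_extinction_coefficient()
            assert bc.epsilon280_from_sequence(
                seq, cysteines="reduced") == pytest.approx(reduced)
            assert bc.epsilon280_from_sequence(seq) == pytest.approx(
                oxidized)

    def test_protein_conc_units(self):
        out = bc.protein_conc(100185 * 1e-6, 100185, 90000)
        assert out.molar_M == pytest.approx(1e-6)
        assert out.mass_g_per_L == pytest.approx(0.09)


class TestFadOccupancy:
    def test_full_loading(self):
        p = 0.004  # mM
        occ = bc.fad_occupancy(p * 11.3, p * 100.185)
        assert occ == pytest.approx(1.0)

    def test_apo_protein(self):
        assert bc.fad_occupancy(0.0, 1.0) == 0.0

    def test_forward_model_inversion_with_flavin_correction(self):
        p, occ_true, eps_f280 = 0.006, 0.09, 22.0
        a450 = occ_true * p * 11.3
        a280 = p * 100.185 + occ_true * p * eps_f280
        occ = bc.fad_occupancy(a450, a280, eps_fad280_mM=eps_f280)
        assert abs(occ - occ_true) < 1e-6

    def test_overloading_warns_and_clips(self):
        p = 0.004
        with pytest.warns(UserWarning, match="clipped"):
            occ = bc.fad_occupancy(1.5 * p * 11.3, p * 100.185)
        assert occ == pytest.approx(1.05)

    def test_normalization_identity_and_monotonicity(self):
        assert bc.normalize_to_full_fad(5.0, 1.0) == 5.0
        values = [bc.normalize_to_full_fad(5.0, o)
                  for o in (0.2, 0.4, 0.8, 1.0)]
        assert values == sorted(values, reverse=True)
        with pytest.raises(ValueError):
            bc.normalize_to_full_fad(5.0, 0.0)

    def test_normalization_error_propagation(self):
        value, sd = bc.normalize_to_full_fad(9.4, 0.44, activity_sd=0.2)
        assert value == pytest.approx(9.4 / 0.44)
        assert sd == pytest.approx(value * 0.2 / 9.4)


class TestSpectralFeatures:
    def test_soret_shift_recovered_from_simulated_pair(self):
        ox, _ = simulate_spectrum(state="oxidized", seed=1)
        red, _ = simulate_spectrum(state="reduced", seed=1)
        feats = bc.spectral_features(ox, red)
        assert feats.has_soret
        assert feats.soret_shift_nm == pytest.approx(9.0, abs=1.0)
        assert feats.alpha_band_nm == pytest.approx(562.0, abs=2.0)
        assert feats.beta_band_nm == pytest.approx(533.0, abs=2.0)

    def test_heme_free_sample_has_no_soret(self):
        ox, _ = simulate_spectrum(state="oxidized", heme=0.0, occupancy=0.5)
        red, _ = simulate_spectrum(state="reduced", heme=0.0, occupancy=0.5)
        feats = bc.spectral_features(ox, red)
        assert not feats.has_soret

    def test_flat_spectrum_has_no_soret(self):
        grid = np.arange(250.0, 701.0)
        flat = bc.Spectrum(grid, np.ones_like(grid))
        feats = bc.spectral_features(flat, flat)
        assert not feats.has_soret
        assert feats.rz == pytest.approx(1.0)

    def test_rz_is_ratio_of_oxidized_absorbances(self):
        ox, truth = simulate_spectrum(heme=1.0, seed=2)
        red, _ = simulate_spectrum(heme=1.0, state="reduced", seed=2)
        feats = bc.spectral_features(ox, red)
        assert feats.rz == pytest.approx(ox.at(420) / ox.at(280))

    def test_rz_monotone_in_heme_content(self):
        rzs = []
        for heme in (0.2, 0.5, 1.0):
            ox, _ = simulate_spectrum(heme=heme)
            red, _ = simulate_spectrum(heme=heme, state="reduced")
            rzs.append(bc.spectral_features(ox, red).rz)
        assert rzs == sorted(rzs)

    def test_difference_spectrum_on_common_grid(self):
        ox, _ = simulate_spectrum(state="oxidized")
        red, _ = simulate_spectrum(state="reduced")
        feats = bc.spectral_features(ox, red)
        at_429 = feats.difference_au[feats.difference_nm == 429.0]
        assert at_429[0] > 0  # reduced Soret gain

    def test_insufficient_coverage_rejected(self):
        grid = np.arange(300.0, 501.0)
        s = bc.Spectrum(grid, np.ones_like(grid))
        with pytest.raises(ValueError):
            bc.spectral_features(s, s)
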