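"""Density, gas fraction, attenuation, model fits, AICc, thresholds."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from lungaerate import reference_data
from lungaerate.exvivo import (aicc, attenuation_table, compute_attenuation,
                               compute_density, compute_gas_fraction,
                               derive_thresholds, descriptive_stats,
                               fit_attenuation_line, fit_attenuation_points,
                               fit_density_signal_model, mean_sd_population,
                               read_sample_table,
                               sample_size_for_correlation)
from lungaerate.synthetic import (ExvivoConfig, generate_attenuation_records,
                                  generate_exvivo_table)


class TestElementaryQuantities:
    @pytest.mark.parametrize("mass,vol,rho", [
        (100.0, 100.0, 1.0), (93.6, 120.0, 0.78), (150.0, 300.0, 0.5)])
    def test_density(self, mass, vol, rho):
        assert compute_density(mass, vol) == pytest.approx(rho)

    def test_density_rejects_nonpositive_volume(self):
        with pytest.raises(ValueError):
            compute_density(10.0, 0.0)

    @pytest.mark.parametrize("v,v0,gasf", [
        (100.0, 100.0, 0.0), (200.0, 100.0, 0.5),
        (1000.0 / 9.0, 100.0, 0.1)])  # solves (V - 100)/V = 0.1
    def test_gas_fraction(self, v, v0, gasf):
        assert compute_gas_fraction(v, v0) == pytest.approx(gasf)

    def test_attenuation(self):
        assert compute_attenuation(75.0, 75.0) == 1.0
        assert compute_attenuation(37.5, 75.0) == 0.5
        with pytest.raises(ValueError):
            compute_attenuation(10.0, 0.0)

    def test_attenuation_invariant_to_common_normalization(self):
        # dividing both signals by a shared reference cancels exactly
        assert compute_attenuation(60.0 / 200.0, 80.0 / 200.0) == \
            pytest.approx(compute_attenuation(60.0, 80.0))


class TestAicc:
    def test_worked_example(self):
        assert aicc(0.0, 2, 44) == pytest.approx(4.0 + 12.0 / 41.0)

    def test_limits(self):
        assert aicc(-10.0, 2, 10 ** 7) == pytest.approx(24.0, abs=1e-4)
        assert aicc(-3.0, 0, 5) == 6.0

    def test_small_sample_guard(self):
        with pytest.raises(ValueError):
            aicc(0.0, 5, 6)


class TestSampleSize:
    def test_fisher_z_values(self):
        # independent oracle: n = ceil(((z_a/2 + z_b)/atanh r)^2 + 3)
        z = stats.norm.ppf(0.975) + stats.norm.ppf(0.9)
        for r, expected in ((0.8, 12), (0.99, 5)):
            assert math.ceil((z / math.atanh(r)) ** 2 + 3) == expected
            assert sample_size_for_correlation(r) == expected

    def test_monotone_in_power(self):
        assert sample_size_for_correlation(0.8, power=0.5) < \
            sample_size_for_correlation(0.8, power=0.9)

    def test_invalid_r(self):
        with pytest.raises(ValueError):
            sample_size_for_correlation(1.0)


class TestDescriptives:
    def test_study_sample_table(self):
        masses = reference_data.SAMPLE_MASSES_G
        mean, sd = mean_sd_population(masses)
        assert round(mean, 1) == 131.4
        assert round(sd, 1) == 34.6           # population convention
        assert np.std(masses, ddof=1) == pytest.approx(36.3, abs=0.05)
        evlw_mean, evlw_sd = mean_sd_population(reference_data.EVLW_FRACTIONS)
        assert round(evlw_mean, 2) == 0.33
        assert round(evlw_sd, 2) == 0.02

    def test_from_sample_table(self):
        rec, _ = generate_exvivo_table(ExvivoConfig(), seed=9)
        d = descriptive_stats(rec)
        assert d["n_samples"] == 11
        per_sample = rec.drop_duplicates("sample_id")
        assert d["mass_mean_g"] == pytest.approx(per_sample["mass_g"].mean())
        assert d["evlw_mean_g_per_g"] == pytest.approx(
            per_sample[per_sample.group == "injured"]["evlw_fraction"].mean())


class TestDensitySignalModel:
    def test_noiseless_quadratic_recovery(self, noiseless_exvivo_config):
        rec, _ = generate_exvivo_table(noiseless_exvivo_config, seed=1)
        curve = fit_density_signal_model(rec, "quadratic", "none")
        assert curve.a == pytest.approx(noiseless_exvivo_config.coef_a, rel=1e-6)
        assert curve.b == pytest.approx(noiseless_exvivo_config.coef_b, rel=1e-6)
        assert np.isfinite(curve.aicc_value)

    def test_quadratic_preferred_on_quadratic_data(self):
        rec, _ = generate_exvivo_table(ExvivoConfig(), seed=2)
        lin = fit_density_signal_model(rec, "linear", "muscle")
        quad = fit_density_signal_model(rec, "quadratic", "muscle")
        assert quad.aicc_value < lin.aicc_value

    def test_injury_offset_detected(self):
        cfg = ExvivoConfig(injury_density_offset=0.1)
        rec, _ = generate_exvivo_table(cfg, seed=3)
        curve = fit_density_signal_model(rec, "quadratic", "muscle")
        assert curve.evlw_effect_p < 0.05
        assert curve.injury_offset == pytest.approx(0.1, abs=0.05)

    def test_too_few_samples_rejected(self):
        rec, _ = generate_exvivo_table(ExvivoConfig(n_healthy=2, n_injured=0),
                                       seed=0)
        with pytest.raises(ValueError, match=">= 3 samples"):
            fit_density_signal_model(rec)


class TestAttenuationLine:
    def test_proportional_signal_closed_form(self, noiseless_exvivo_config):
        # signal proportional to density => MRI_ATT = V0/V = 1 - GAS_F
        cfg = noiseless_exvivo_config
        cfg.signal_mode = "linear"
        rec, _ = generate_exvivo_table(cfg, seed=4)
        fit = fit_attenuation_line(rec, "muscle")
        assert fit.slope == pytest.approx(-1.0, abs=1e-9)
        assert fit.intercept == pytest.approx(1.0, abs=1e-9)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-9)

    def test_attenuation_is_one_at_zero_pressure(self):
        rec, _ = generate_exvivo_table(ExvivoConfig(), seed=5)
        table = attenuation_table(rec, "muscle")
        at0 = table[table.cpap_cmh2o == 0]
        assert np.allclose(at0["mri_att"], 1.0)
        assert np.allclose(at0["gas_fraction"], 0.0)

    def test_r_squared_at_study_noise_level(self):
        # residual sd 0.07 puts the population R^2 at ~0.93 for the default
        # gas-fraction design (analytic variance ratio)
        r2 = []
        for seed in range(1, 21):
            pts = generate_attenuation_records(noise_sd=0.07, seed=seed)
            r2.append(fit_attenuation_points(pts).r_squared)
        assert np.mean(r2) == pytest.approx(0.93, abs=0.05)

    def test_degenerate_gas_fraction_rejected(self):
        pts = pd.DataFrame({
            "sample_id": ["a", "a", "b", "b", "c", "c"],
            "gas_fraction": [0.3] * 6,
            "mri_att": [0.5, 0.52, 0.49, 0.51, 0.5, 0.5]})
        with pytest.raises(ValueError, match="degenerate"):
            fit_attenuation_points(pts)


class TestThresholds:
    def test_analytic_thresholds(self, noiseless_exvivo_config):
        cfg = noiseless_exvivo_config
        cfg.signal_mode = "linear"
        rec, _ = generate_exvivo_table(cfg, seed=6)
        fit = derive_thresholds(fit_attenuation_line(rec, "water"),
                                n_boot=200, seed=0)
        assert fit.threshold_nonaerated == pytest.approx(0.9, abs=1e-9)
        assert fit.threshold_poor == pytest.approx(0.5, abs=1e-9)

    def test_study_line_reproduces_printed_thresholds(self):
        # slope -1.05, intercept 0.805 evaluated at cut-offs 0.1 / 0.5
        assert -1.05 * 0.1 + 0.805 == pytest.approx(0.70)
        assert -1.05 * 0.5 + 0.805 == pytest.approx(0.28)
        pts = generate_attenuation_records(noise_sd=0.0, sample_intercept_sd=0.0,
                                           gasf_jitter_sd=0.0, seed=0)
        fit = derive_thresholds(fit_attenuation_points(pts), n_boot=200, seed=1)
        assert fit.threshold_nonaerated == pytest.approx(0.70, abs=1e-9)
        assert fit.threshold_poor == pytest.approx(0.28, abs=1e-9)

    def test_ci_contains_point_estimate_and_ordering(self):
        pts = generate_attenuation_records(seed=11)
        fit = derive_thresholds(fit_attenuation_points(pts), n_boot=500, seed=2)
        lo, hi = fit.ci_nonaerated
        assert lo <= fit.threshold_nonaerated <= hi
        lo, hi = fit.ci_poor
        assert lo <= fit.threshold_poor <= hi
        assert fit.threshold_nonaerated > fit.threshold_poor

    def test_bootstrap_deterministic_under_seed(self):
        pts = generate_attenuation_records(seed=12)
        base = fit_attenuation_points(pts)
        a = derive_thresholds(base, n_boot=300, seed=5)
        b = derive_thresholds(base, n_boot=300, seed=5)
        assert a.ci_nonaerated == b.ci_nonaerated

    def test_invalid_cutoff_rejected(self):
        pts = generate_attenuation_records(seed=13)
        fit = fit_attenuation_points(pts)
        with pytest.raises(ValueError, match="cut-off"):
            derive_thresholds(fit, cutoffs=(0.1, 1.5))


class TestSampleTableIO:
    def test_round_trip_and_missing_column(self, tmp_path):
        rec, _ = generate_exvivo_table(ExvivoConfig(), seed=14)
        path = tmp_path / "samples.csv"
        rec.to_csv(path, index=False)
        back = read_sample_table(path)
        assert back.shape[0] == rec.shape[0]
        rec.drop(columns=["mass_g"]).to_csv(path, index=False)
        with pytest.raises(ValueError, match="mass_g"):
            read_sample_table(path)

    def test_missing_deflated_scan_rejected(self, tmp_path):
        rec, _ = generate_exvivo_table(ExvivoConfig(), seed=15)
        rec = rec[~((rec.sample_id == "S01") & (rec.cpap_cmh2o == 0))]
        path = tmp_path / "samples.csv"
        rec.to_csv(path, index=False)
        with pytest.raises(ValueError, match="0 cmH2O"):
            read_sample_table(path)
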