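"""Synthetic-data generator: determinism, noise model, injected truths."""

import numpy as np
import pandas as pd
import pytest

from pkbioval import bateman, simulate, validation
from pkbioval.config import SimulationConfig
from pkbioval.nca import profiles_to_frame


class TestProfiles:
    def test_noise_free_profiles_follow_the_bateman_curve(self, noise_free_config):
        profiles = simulate.simulate_profiles(noise_free_config)
        k_ab, k_el, cmax = noise_free_config.pk_params_per_group[1]
        group2 = [p for p in profiles if p.dose_mg_per_kg == 40.0]
        assert len(group2) == 3
        amp = bateman.amplitude_for_cmax(cmax, k_ab, k_el)
        expected = bateman.bateman(group2[0].times, amp, k_ab, k_el)
        for p in group2:
            np.testing.assert_allclose(p.concentrations, expected, rtol=1e-12)
        # the sampled maximum sits at the grid neighbour of the analytic t_max
        t_star = bateman.t_max(k_ab, k_el)
        i_max = int(np.argmax(group2[0].concentrations))
        assert abs(group2[0].times[i_max] - t_star) <= 0.5 * np.diff(group2[0].times).max()

    def test_predose_sample_is_exactly_zero_and_blq(self, default_config):
        for p in simulate.simulate_profiles(default_config):
            assert p.times[0] == 0.0
            assert p.concentrations[0] == 0.0
            assert p.blq_flags[0]

    def test_blq_flag_iff_below_lloq(self, default_config):
        for p in simulate.simulate_profiles(default_config):
            np.testing.assert_array_equal(
                p.blq_flags, p.concentrations < default_config.lloq_ng_ml
            )
            assert np.all(p.concentrations >= 0)

    def test_fixed_seed_reproduces_tables_exactly(self, default_config):
        a = profiles_to_frame(simulate.simulate_profiles(default_config))
        b = profiles_to_frame(simulate.simulate_profiles(default_config))
        pd.testing.assert_frame_equal(a, b)

    def test_noise_cv_matches_target_in_monte_carlo(self):
        # 1000 subjects at 10% CV: empirical CV near the peak within ±0.01
        cfg = SimulationConfig(
            seed=11,
            n_subjects_per_group=1000,
            doses=(40.0,),
            pk_params_per_group=((0.81, 0.62, 2079.87),),
            residual_cv=0.10,
        )
        profiles = simulate.simulate_profiles(cfg)
        t_star = bateman.t_max(0.81, 0.62)
        idx = int(np.argmin(np.abs(profiles[0].times - t_star)))
        peaks = np.array([p.concentrations[idx] for p in profiles])
        cv = peaks.std(ddof=1) / peaks.mean()
        assert 0.09 <= cv <= 0.11

    def test_equal_rates_use_degenerate_limit_with_warning(self):
        cfg = SimulationConfig(
            seed=3,
            doses=(40.0,),
            pk_params_per_group=((0.7, 0.7, 1000.0),),
            residual_cv=0.0,
        )
        with pytest.warns(UserWarning, match="degenerate"):
            profiles = simulate.simulate_profiles(cfg)
        t = profiles[0].times[1:]
        k = 0.7
        peak = (1.0 / k) * np.exp(-1.0)  # limit-form maximum at t = 1/k
        expected = t * np.exp(-k * t) * (1000.0 / peak)
        np.testing.assert_allclose(profiles[0].concentrations[1:], expected, rtol=1e-9)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"doses": (-20.0, 40.0, 80.0)},
            {"residual_cv": 1.5},
            {"sampling_times_h": (1.0, 2.0)},
            {"sampling_times_h": (0.0, 2.0, 2.0)},
            {"pk_params_per_group": ((0.0, 0.5, 100.0),) * 3},
            {"area_per_conc": 0.0},
            {"n_subjects_per_group": 0},
        ],
    )
    def test_invalid_configs_are_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SimulationConfig(**kwargs)


class TestCalibrationRun:
    def test_zero_cv_round_trips_through_a_fitted_line(self, default_config):
        from pkbioval.calibration import fit_calibration, standards_from_frame

        df = simulate.simulate_calibration_run(default_config, cv=0.0, is_cv=0.0)
        curve = fit_calibration(standards_from_frame(df))
        np.testing.assert_allclose(curve.back_calculated, curve.nominal, rtol=1e-9)

    def test_blank_and_zero_records(self, default_config):
        df = simulate.simulate_calibration_run(default_config)
        blank = df.query("sample_type == 'blank'")
        zero = df.query("sample_type == 'zero'")
        assert (blank[["analyte_area", "is_area"]] == 0).all().all()
        assert (zero["analyte_area"] == 0).all()
        assert (zero["is_area"] > 0).all()

    def test_r_squared_gate_holds_in_monte_carlo(self):
        # at 3% response CV essentially every run clears r² >= 0.99
        from pkbioval.calibration import fit_calibration, standards_from_frame

        passes = 0
        n_runs = 500
        cfg = SimulationConfig(seed=2)
        df = simulate.simulate_calibration_run(cfg, n_runs=n_runs, cv=0.03)
        for _, sub in df.groupby("run_id"):
            curve = fit_calibration(standards_from_frame(sub))
            passes += curve.r_squared >= 0.99
        assert passes / n_runs >= 0.95


class TestValidationSets:
    def test_injected_recovery_is_recovered(self, default_config):
        sets = simulate.simulate_validation_sets(
            default_config, recovery=0.88, cv=0.02
        )
        tbl = validation.recovery_table(sets["recovery"])
        assert tbl["recovery_pct"].mean() == pytest.approx(88.0, abs=3.0)

    def test_injected_carryover_fraction_is_recovered(self, default_config):
        sets = simulate.simulate_validation_sets(
            default_config, carryover_fraction=0.047, cv=0.0
        )
        co = sets["carry_over"]
        res = validation.carry_over(
            co.query("sample == 'blank'")["analyte_area"],
            co.query("sample == 'lloq'")["analyte_area"].mean(),
        )
        assert res.analyte_pct == pytest.approx(4.7, rel=1e-9)

    def test_noise_free_truths_are_exact(self, default_config):
        sets = simulate.simulate_validation_sets(
            default_config,
            cv=0.0,
            matrix_suppression=0.08,
            recovery=0.8775,
            stability_change=-0.0842,
        )
        me = validation.matrix_effect_table(sets["matrix_effect"])
        np.testing.assert_allclose(me["matrix_effect_pct"], 8.0, rtol=1e-6)
        rec = validation.recovery_table(sets["recovery"])
        np.testing.assert_allclose(rec["recovery_pct"], 87.75, rtol=1e-6)
        st = validation.stability_table(sets["stability"])
        np.testing.assert_allclose(st["change_pct"], -8.42, rtol=1e-6)

    def test_design_shape_matches_the_study(self, default_config):
        sets = simulate.simulate_validation_sets(default_config)
        pa = sets["precision_accuracy"]
        assert set(pa["level"]) == {"LLOQ", "LQC", "IQC", "MQC", "HQC"}
        assert pa.groupby(["level", "day"]).size().eq(6).all()
        assert pa["day"].nunique() == 3
        me = sets["matrix_effect"]
        assert me.groupby(["matrix", "level", "arm"]).size().eq(6).all()
        co = sets["carry_over"]
        assert co.groupby("sample").size().eq(6).all()

    def test_bundle_is_deterministic(self, default_config):
        a = simulate.simulate_validation_sets(default_config)
        b = simulate.simulate_validation_sets(default_config)
        for key in a:
            pd.testing.assert_frame_equal(a[key], b[key])
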