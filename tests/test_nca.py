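"""Noncompartmental analysis: trapezoids, terminal slope, derived parameters."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from pkbioval import bateman, nca
from tests.conftest import make_profile


class TestTrapezoids:
    def test_hand_computed_auc(self):
        p = make_profile([0, 1, 2], [0, 10, 5])
        assert nca.auc_linear_trapezoid(p) == pytest.approx(12.5, rel=1e-12)

    def test_hand_computed_aumc(self):
        # t*C = [0, 10, 10] -> trapezoid 15
        p = make_profile([0, 1, 2], [0, 10, 5])
        assert nca.aumc_linear_trapezoid(p) == pytest.approx(15.0, rel=1e-12)

    def test_constant_profile_is_a_rectangle(self):
        p = make_profile([0, 2, 5, 8], [40.0] * 4)
        assert nca.auc_linear_trapezoid(p) == pytest.approx(40.0 * 8, rel=1e-12)

    def test_zero_profile_has_zero_aumc(self):
        p = make_profile([0, 1, 2], [0.0, 0.0, 0.0])
        assert nca.aumc_linear_trapezoid(p) == 0.0

    def test_too_few_points_raise(self):
        with pytest.raises(ValueError):
            nca.auc_linear_trapezoid(make_profile([0.0], [0.0]))

    def test_dense_bateman_matches_closed_form_integrals(self):
        amp, k_ab, k_el, T = 3000.0, 0.81, 0.62, 11.0
        t = np.arange(0, T + 1e-9, 0.001)
        p = make_profile(t, bateman.bateman(t, amp, k_ab, k_el))
        assert nca.auc_linear_trapezoid(p) == pytest.approx(
            bateman.auc_0_T(amp, k_ab, k_el, T), rel=1e-4
        )
        assert nca.aumc_linear_trapezoid(p) == pytest.approx(
            bateman.aumc_0_T(amp, k_ab, k_el, T), rel=1e-4
        )

    @given(split=st.integers(min_value=1, max_value=10))
    @settings(deadline=None, max_examples=10)
    def test_auc_additivity_over_a_split(self, split):
        rng = np.random.default_rng(4)
        t = np.arange(12.0)
        c = np.abs(rng.normal(100, 30, len(t)))
        whole = nca.auc_linear_trapezoid(make_profile(t, c))
        left = np.trapezoid(c[: split + 1], t[: split + 1])
        right = np.trapezoid(c[split:], t[split:])
        assert whole == pytest.approx(left + right, rel=1e-12)


class TestMrt:
    def test_ratio_and_errors(self):
        assert nca.mrt(878.74, 5935.97) == pytest.approx(5935.97 / 878.74, rel=1e-12)
        assert nca.mrt(2.0, 2.0) == 1.0
        with pytest.raises(ValueError):
            nca.mrt(0.0, 1.0)


class TestTerminalSlope:
    def test_exact_monoexponential_recovery(self):
        t = np.arange(0.0, 12.0)
        c = 100.0 * np.exp(-0.62 * t)
        c[0] = 0.0  # pre-dose
        term = nca.terminal_slope(make_profile(t, c))
        assert term.k_el == pytest.approx(0.62, abs=1e-10)
        assert term.t_half == pytest.approx(math.log(2) / 0.62, abs=1e-10)
        assert round(term.t_half, 2) == 1.12

    def test_window_choice_matches_exhaustive_oracle(self):
        rng = np.random.default_rng(12)
        t = np.arange(12.0)
        amp = bateman.amplitude_for_cmax(2000.0, 0.81, 0.62)
        c = bateman.bateman(t, amp, 0.81, 0.62) * np.exp(rng.normal(0, 0.1, len(t)))
        c[0] = 0.0
        p = make_profile(t, c)
        term = nca.terminal_slope(p)

        # oracle: brute-force every suffix window of post-peak points
        i_max = int(np.argmax(c))
        tt, cc = t[i_max + 1:], c[i_max + 1:]
        best = None
        for s in range(len(tt) - 2):
            res = stats.linregress(tt[s:], np.log(cc[s:]))
            n = len(tt[s:])
            adj = 1 - (1 - res.rvalue**2) * (n - 1) / (n - 2)
            if best is None or adj > best[0] + 1e-12:
                best = (adj, n, -res.slope)
        assert term.n_points == best[1]
        assert term.k_el == pytest.approx(best[2], rel=1e-12)

    def test_fixed_window_size(self):
        t = np.arange(12.0)
        c = 100.0 * np.exp(-0.5 * t)
        c[0] = 0.0
        term = nca.terminal_slope(make_profile(t, c), n_points=4)
        assert term.n_points == 4
        assert term.window_times == tuple(t[-4:])

    def test_too_few_post_peak_points(self):
        p = make_profile([0, 1, 2, 3], [0, 10, 20, 30])
        with pytest.raises(ValueError):
            nca.terminal_slope(p)


class TestBlqPolicy:
    def test_leading_blq_kept_as_zero_embedded_and_trailing_excluded(self):
        p = make_profile(
            [0, 1, 2, 3, 4, 5, 6],
            [2.0, 50.0, 8.0, 200.0, 100.0, 50.0, 3.0],
            blq=[True, False, True, False, False, False, True],
        )
        t, c = p.usable_points()
        np.testing.assert_array_equal(t, [0, 1, 3, 4, 5])
        assert c[0] == 0.0  # leading BLQ zeroed
        np.testing.assert_array_equal(c[1:], [50.0, 200.0, 100.0, 50.0])


class TestSummary:
    def _bateman_profile(self, cmax=2000.0, k_ab=0.81, k_el=0.62, dose=40.0, weight=58.3):
        t = np.arange(12.0)
        amp = bateman.amplitude_for_cmax(cmax, k_ab, k_el)
        return make_profile(t, bateman.bateman(t, amp, k_ab, k_el),
                            dose=dose, weight=weight)

    def test_internal_identities_hold(self):
        res = nca.nca_summary(self._bateman_profile())
        assert res.mrt_0_t == pytest.approx(res.aumc_0_t / res.auc_0_t, abs=1e-9)
        assert res.t_half_el == pytest.approx(math.log(2) / res.k_el, abs=1e-9)
        assert res.vd_area_over_f == pytest.approx(res.cl_over_f / res.k_el, abs=1e-9)
        assert res.t_max <= res.t_last

    def test_dose_accounting(self):
        res = nca.nca_summary(self._bateman_profile(dose=40.0, weight=58.3))
        dose_ug = 40.0 * 58.3 * 1000.0
        assert res.cl_over_f == pytest.approx(dose_ug / res.auc_0_t, rel=1e-12)

    def test_cmax_is_grid_neighbor_of_analytic_tmax(self):
        res = nca.nca_summary(self._bateman_profile())
        assert abs(res.t_max - bateman.t_max(0.81, 0.62)) <= 0.5

    def test_tmax_first_occurrence_on_ties(self):
        p = make_profile([0, 1, 2, 3, 4, 5], [0, 100, 100, 50, 25, 12])
        t, c = p.usable_points()
        assert t[int(np.argmax(c))] == 1.0

    def test_scaling_concentrations_scales_areas_not_times(self):
        base = nca.nca_summary(self._bateman_profile(cmax=2000.0))
        scaled = nca.nca_summary(self._bateman_profile(cmax=6000.0))
        assert scaled.auc_0_t == pytest.approx(3 * base.auc_0_t, rel=1e-9)
        assert scaled.aumc_0_t == pytest.approx(3 * base.aumc_0_t, rel=1e-9)
        assert scaled.c_max == pytest.approx(3 * base.c_max, rel=1e-9)
        assert scaled.mrt_0_t == pytest.approx(base.mrt_0_t, rel=1e-9)
        assert scaled.k_el == pytest.approx(base.k_el, rel=1e-9)
        assert scaled.t_half_el == pytest.approx(base.t_half_el, rel=1e-9)

    def test_group_summary_shape(self):
        results = [
            nca.nca_summary(self._bateman_profile(cmax=c)) for c in (1800.0, 2000.0)
        ]
        results[0].group = results[1].group = "g1"
        df = nca.group_summary(results)
        assert list(df["group"]) == ["g1"]
        assert "auc_0_t_mean" in df.columns and "auc_0_t_sd" in df.columns


class TestRoundTrip:
    def test_frame_round_trip_preserves_profiles(self):
        t = np.arange(12.0)
        amp = bateman.amplitude_for_cmax(500.0, 0.81, 0.62)
        p = make_profile(t, bateman.bateman(t, amp, 0.81, 0.62))
        df = nca.profiles_to_frame([p])
        back = nca.profiles_from_frame(df)[0]
        np.testing.assert_allclose(back.concentrations, p.concentrations)
        assert back.subject_id == p.subject_id
        assert back.dose_mg_per_kg == p.dose_mg_per_kg
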