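import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import bsfopt as B
from bsfopt.model import initial_state, rhs

SMOOTH = B.NumericsConfig()
HARD = B.NumericsConfig(hard_mode=True)
P = B.ModelParameters()


class TestSwitches:
    def test_smooth_switch_midpoint(self):
        assert B.smooth_switch(0.0, SMOOTH) == pytest.approx(0.5)

    @pytest.mark.parametrize("x,expected", [(-1.0, 0.0), (0.0, 0.0), (1.0, 1.0)])
    def test_hard_switch_is_exact_step(self, x, expected):
        assert B.smooth_switch(x, HARD) == expected

    def test_smooth_matches_hard_far_from_origin(self):
        # ½(1 − tanh(10)) ≈ 2.06e-9: negligible once |x| ≥ 10/k
        k = SMOOTH.switch_steepness
        for x in (10.0 / k, -10.0 / k):
            assert abs(
                B.smooth_switch(x, SMOOTH) - B.smooth_switch(x, HARD)
            ) <= 2.1e-9

    @pytest.mark.parametrize(
        "x,cfg,expected", [(-5.0, HARD, 0.0), (3.0, HARD, 3.0), (0.0, SMOOTH, 0.0)]
    )
    def test_smooth_max0(self, x, cfg, expected):
        assert B.smooth_max0(x, cfg) == pytest.approx(expected)

    def test_non_finite_input_rejected(self):
        with pytest.raises(ValueError):
            B.smooth_switch(float("nan"), SMOOTH)
        with pytest.raises(ValueError):
            B.smooth_max0(float("inf"), HARD)


class TestResponseCurves:
    def test_light_response_anchors(self):
        assert B.xi_light(0.0, P) == 0.0
        assert B.xi_light(1e6, P) == pytest.approx(P.a1)
        assert B.xi_light(16.0, P) == pytest.approx(0.983266299038678, abs=1e-12)

    def test_light_response_rejects_negative_photoperiod(self):
        with pytest.raises(ValueError):
            B.xi_light(-1.0, P)

    @given(st.floats(0.0, 24.0), st.floats(0.001, 23.9))
    @settings(max_examples=50, deadline=None)
    def test_light_response_monotone_and_bounded(self, u, du):
        lo, hi = B.xi_light(u, P), B.xi_light(min(u + du, 24.0), P)
        assert 0.0 <= lo <= hi <= P.a1

    def test_fecundity_peak_location_and_values(self):
        vertex = -P.k_T_ovi_1 / (2.0 * P.k_T_ovi_2)
        assert vertex == pytest.approx(28.6, rel=1e-12)
        assert B.xi_temp_fecundity(28.6, P) == pytest.approx(0.9198, abs=1e-9)
        assert B.xi_temp_fecundity(25.0, P) == pytest.approx(0.855, abs=1e-9)

    def test_fecundity_clipping_option(self):
        assert B.xi_temp_fecundity(5.0, P) < 0
        assert B.xi_temp_fecundity(5.0, P, clip=True) == 0.0

    def test_mortality_curve_values_and_convexity(self):
        assert B.xi_temp_mortality(25.0, P) == pytest.approx(1.0425, abs=1e-9)
        vertex = -P.k_T_mu_1 / (2.0 * P.k_T_mu_2)
        assert vertex == pytest.approx(25.1515, abs=1e-3)
        v = B.xi_temp_mortality(vertex, P)
        assert B.xi_temp_mortality(20.0, P) > v
        assert B.xi_temp_mortality(37.0, P) > v

    def test_mortality_positive_on_admissible_box(self):
        temps = np.linspace(20.0, 37.0, 200)
        assert np.all(B.xi_temp_mortality(temps, P) > 0)


class TestStageGates:
    @pytest.mark.parametrize(
        "T_sum,expected",
        [
            (0.0, (0.0, 0.0, 0.0)),     # below both thresholds
            (40.0, (0.28, 0.0, 0.0)),   # past mating gate only
            (100.0, (0.28, 0.55, 5.9)),  # all gates open
        ],
    )
    def test_hard_gate_levels(self, T_sum, expected):
        gates = B.stage_gates(T_sum, P, HARD)
        assert tuple(float(g) for g in gates) == pytest.approx(expected)


class TestRhs:
    def test_initial_state_derivative(self):
        dy = rhs(initial_state(P), 25.0, 16.0, P, HARD)
        assert np.allclose(dy[:4], 0.0)          # gates closed, no deaths yet
        assert dy[4] == pytest.approx(13.0)      # degree-day accumulation
        assert dy[5] == pytest.approx(1.0425 * 0.0183)
        assert dy[6] == 0.0

    def test_egg_production_term(self):
        # fertilized females laying at 25 °C with depleted-reserve state 0
        y = np.array([0.0, 0.0, 10.0, 0.0, 60.0, 0.0, 0.0])
        dy = rhs(y, 25.0, 16.0, P, HARD)
        assert dy[6] == pytest.approx(0.855 * 5.9 * 10.0)

    def test_development_halts_below_base_temperature(self):
        dy = rhs(initial_state(P), 12.0, 16.0, P, HARD)
        assert dy[4] == 0.0

    @given(
        st.floats(0.0, 50.0), st.floats(0.0, 50.0), st.floats(0.0, 50.0),
        st.floats(0.0, 50.0), st.floats(0.0, 200.0), st.floats(-0.2, 0.4),
        st.floats(20.0, 37.0), st.floats(2.0, 24.0),
    )
    @settings(max_examples=100, deadline=None)
    def test_transition_terms_cancel_in_total_population(
        self, ny, na, nf, no, ts, mu, u_T, u_L
    ):
        y = np.array([ny, na, nf, no, ts, mu, 0.0])
        for cfg in (SMOOTH, HARD):
            dy = rhs(y, u_T, u_L, P, cfg)
            death = B.smooth_max0(mu, cfg)
            expected = -(P.k_mu_N * (ny + na + nf) + P.k_mu_old * no) * death
            assert float(dy[:4].sum()) == pytest.approx(
                float(expected), rel=1e-12, abs=1e-9
            )

    def test_no_deaths_while_reserves_remain(self):
        y = np.array([10.0, 20.0, 5.0, 3.0, 80.0, -0.05, 10.0])
        dy = rhs(y, 30.0, 16.0, P, HARD)
        assert float(dy[:4].sum()) == 0.0

    def test_mu_growth_positive_on_admissible_temperatures(self):
        temps = np.linspace(20.0, 37.0, 50)
        y = np.tile(initial_state(P)[:, None], (1, temps.size))
        dy = rhs(y, temps, 16.0, P, SMOOTH)
        assert np.all(dy[5] > 0)

    def test_smooth_and_hard_rhs_agree_away_from_switch_points(self):
        # switched arguments ≥ 0.5 units from zero: gates far open/closed,
        # mu clearly negative
        y = np.array([30.0, 10.0, 5.0, 2.0, 70.0, -0.08, 25.0])
        d_smooth = rhs(y, 28.0, 12.0, P, SMOOTH)
        d_hard = rhs(y, 28.0, 12.0, P, HARD)
        for a, b in zip(d_smooth, d_hard):
            assert float(a) == pytest.approx(float(b), rel=0.01, abs=1e-9)

    def test_rhs_broadcasts_over_batches(self):
        y = np.tile(initial_state(P)[:, None], (1, 3))
        u = np.array([22.0, 25.0, 30.0])
        dy = rhs(y, u, 16.0, P, SMOOTH)
        assert dy.shape == (7, 3)
        single = rhs(initial_state(P), 25.0, 16.0, P, SMOOTH)
        assert np.allclose(dy[:, 1], single)
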