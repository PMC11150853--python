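import math

import numpy as np
import pandas as pd
import pytest

import bsfopt as B
from bsfopt.simulate import DEFAULT_DT

P = B.ModelParameters()
HARD = B.NumericsConfig(hard_mode=True)


class TestControlSchedule:
    def test_constant_constructor(self):
        s = B.ControlSchedule.constant(25.0, 16.0, 14.0)
        assert s.horizon == 14.0
        assert s.u_T.size == 14 * 24
        assert s.values_at(3.7) == (25.0, 16.0)

    def test_integrals(self):
        s = B.ControlSchedule.constant(25.0, 16.0, 14.0)
        sum_uT, sum_uL = s.integrals_up_to(10.0)
        assert sum_uT == pytest.approx(250.0)
        assert sum_uL == pytest.approx(160.0)

    @pytest.mark.parametrize(
        "grid,u_T,u_L",
        [
            ([0.0], [], []),                      # too few edges
            ([0.0, 1.0, 0.5], [25, 25], [16, 16]),  # not increasing
            ([0.5, 1.0], [25], [16]),             # does not start at 0
            ([0.0, 1.0], [25, 25], [16, 16]),     # wrong level count
            ([0.0, 1.0], [math.nan], [16]),       # non-finite level
        ],
    )
    def test_invalid_schedules_rejected(self, grid, u_T, u_L):
        with pytest.raises(ValueError):
            B.ControlSchedule(np.array(grid), np.array(u_T), np.array(u_L))

    def test_schedule_shorter_than_horizon_rejected(self):
        s = B.ControlSchedule.constant(25.0, 16.0, 7.0)
        with pytest.raises(ValueError):
            B.simulate(P, s, horizon=14.0)


class TestSimulate:
    def test_initial_condition(self, benchmark_traj):
        y0 = benchmark_traj.states[0]
        assert y0[0] == P.N_y0
        assert np.all(y0[1:5] == 0.0)
        assert y0[5] == P.mu0
        assert y0[6] == 0.0

    def test_development_and_eggs_halt_below_base_temperature(self):
        traj = B.simulate(P, B.ControlSchedule.constant(12.0, 16.0, 14.0))
        assert np.all(traj.column("T_sum") == 0.0)
        assert np.all(traj.egg_mass == 0.0)

    def test_monotone_cumulative_states(self, benchmark_traj):
        assert np.all(np.diff(benchmark_traj.column("T_sum")) >= 0)
        assert np.all(np.diff(benchmark_traj.egg_mass) >= -1e-9)

    def test_total_population_nonincreasing(
        self, benchmark_traj_40d, benchmark_traj_40d_hard
    ):
        # exact with hard switches; the tanh death surrogate admits a
        # sub-percent creep while mu approaches zero from below
        assert np.all(np.diff(benchmark_traj_40d_hard.total_population) <= 1e-9)
        tot = benchmark_traj_40d.total_population
        assert tot.max() <= P.N_y0 * 1.005
        assert np.all(np.diff(tot)[tot[:-1] < 0.9 * P.N_y0] <= 1e-9)

    def test_population_conserved_while_reserves_remain(self):
        traj = B.simulate(P, B.ControlSchedule.constant(25.0, 16.0, 14.0), cfg=HARD)
        mu = traj.column("mu")
        tot = traj.total_population
        before_starvation = mu < 0
        assert np.allclose(tot[before_starvation], P.N_y0, rtol=1e-12)

    def test_integrator_cross_check(self, benchmark_traj):
        adaptive = B.simulate(
            P, B.ControlSchedule.constant(25.0, 16.0, 14.0), method="adaptive"
        )
        final_rk4 = benchmark_traj.states[-1]
        final_ada = adaptive.states[-1]
        assert np.allclose(final_rk4, final_ada, rtol=5e-3, atol=1e-8)

    def test_step_halving_convergence(self, benchmark_traj):
        halved = B.simulate(
            P, B.ControlSchedule.constant(25.0, 16.0, 14.0), substeps=2
        )
        m1, m2 = benchmark_traj.final_egg_mass(), halved.final_egg_mass()
        assert abs(m2 - m1) / m1 < 1e-3

    def test_table_round_trip(self, benchmark_traj, tmp_path):
        path = tmp_path / "traj.tsv"
        benchmark_traj.write_table(path)
        df = pd.read_csv(path, sep="\t")
        assert list(df.columns) == [
            "t_days", "N_y", "N_act", "N_fert", "N_old", "T_sum", "mu", "m_e"
        ]
        assert df["m_e"].iloc[-1] == pytest.approx(
            benchmark_traj.final_egg_mass(), rel=1e-9
        )


class TestEventMetrics:
    @pytest.mark.parametrize("u_T", [25.0, 30.0, 35.0])
    def test_first_oviposition_matches_ramp_oracle(self, u_T):
        # constant temperature: T_sum is a linear ramp crossing the
        # threshold at k_sum_ovi / (u_T - base)
        traj = B.simulate(P, B.ControlSchedule.constant(u_T, 16.0, 14.0), cfg=HARD)
        oracle = P.k_sum_ovi / (u_T - P.k_T_sum_min)
        assert B.first_oviposition_time(traj) == pytest.approx(oracle, rel=0.01)

    def test_first_oviposition_sentinel(self):
        traj = B.simulate(P, B.ControlSchedule.constant(13.0, 16.0, 14.0))
        assert B.first_oviposition_time(traj) == math.inf

    def test_longevity_ordering(self, benchmark_traj_40d):
        half = B.halving_time(benchmark_traj_40d)
        five = B.longevity_5pct(benchmark_traj_40d)
        assert math.isfinite(half) and math.isfinite(five)
        assert five >= half

    def test_cycle_metrics_benchmark(self, benchmark_traj):
        m = B.cycle_metrics(benchmark_traj, abort_fraction=0.9)
        assert m.egg_mass_at_abort == pytest.approx(0.9 * m.final_egg_mass, rel=1e-6)
        assert m.egg_mass_at_abort <= m.final_egg_mass
        # constant inputs: accumulated inputs are level x abort time
        assert m.sum_uT == pytest.approx(25.0 * m.abort_time, rel=1e-9)
        assert m.sum_uL == pytest.approx(16.0 * m.abort_time, rel=1e-9)

    def test_abort_fraction_one_is_horizon(self, benchmark_traj):
        m = B.cycle_metrics(benchmark_traj, abort_fraction=1.0)
        assert m.abort_time == pytest.approx(14.0, abs=1e-6)

    def test_abort_undefined_without_eggs(self):
        traj = B.simulate(P, B.ControlSchedule.constant(12.0, 16.0, 14.0))
        with pytest.raises(ValueError, match="no eggs"):
            B.cycle_metrics(traj)


@pytest.fixture(scope="module")
def surface():
    return B.response_surface(P, np.arange(20.0, 38.0, 1.0), [2.0, 6.0, 16.0])


class TestResponseSurface:

    def test_egg_maximum_location(self, surface):
        best = surface.loc[surface["m_e_14d"].idxmax()]
        assert best["u_T"] == 28.0
        assert best["u_L"] == 16.0

    def test_egg_mass_monotone_in_photoperiod(self, surface):
        for u_T, group in surface.groupby("u_T"):
            ordered = group.sort_values("u_L")["m_e_14d"].to_numpy()
            assert np.all(np.diff(ordered) >= -1e-9)

    def test_egg_mass_unimodal_in_temperature(self, surface):
        at16 = surface[surface["u_L"] == 16.0].sort_values("u_T")
        m = at16["m_e_14d"].to_numpy()
        peak = int(np.argmax(m))
        assert 27.0 <= at16["u_T"].iloc[peak] <= 30.0
        assert np.all(np.diff(m[: peak + 1]) > 0)
        assert np.all(np.diff(m[peak:]) < 0)

    def test_halving_time_decreasing_at_warm_temperatures(self, surface):
        # longevity peaks near 25 °C (mortality-curve vertex); above it the
        # halving time falls monotonically with temperature
        warm = surface[(surface["u_L"] == 2.0) & (surface["u_T"] >= 26.0)]
        h = warm.sort_values("u_T")["halving_time_d"].to_numpy()
        assert np.all(np.diff(h) < 0)


class TestMu0Sensitivity:
    def test_zero_delta_changes_nothing(self):
        s = B.mu0_sensitivity(P, 0.0)
        assert s["egg_mass_pct_change"] == pytest.approx(0.0, abs=1e-12)
        assert s["mu_zero_crossing_pct_change"] == pytest.approx(0.0, abs=1e-9)

    def test_better_fed_pupae_produce_more_eggs(self):
        s = B.mu0_sensitivity(P, 0.5)
        assert s["egg_mass_pct_change"] > 15.0

    def test_mu_crossing_scales_linearly_with_reserves(self):
        # linear reserve dynamics: crossing time |mu0| / (xi_mu k_mu)
        s = B.mu0_sensitivity(P, 0.5)
        assert s["mu_zero_crossing_pct_change"] == pytest.approx(50.0, rel=0.01)
        oracle = 0.1 / (1.0425 * 0.0183)
        assert s["mu_zero_crossing_base"] == pytest.approx(oracle, rel=0.01)
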