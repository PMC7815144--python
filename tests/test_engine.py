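"""Tests for the population engine: integration, demography, determinism."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from glycoevo._integrator import integrate_population, integrate_population_ncg
from glycoevo.engine import (
    Population,
    SimulationConfig,
    _kin_array,
    initialize_population,
    integrate_interval,
    lifecycle_update,
    presim_calibrate,
    run,
)
from glycoevo.environment import EnvironmentConfig, GlucoseSchedule, ScheduleRealization
from glycoevo.kinetics import Genotype
from glycoevo.physiology import REFERENCE_GENOTYPE


def single_cell_population(phys, state=(2.0, 1.0, 10.4), glc=2.0,
                           genotype=REFERENCE_GENOTYPE, vatp_e=5.0,
                           h=1.0, hmax=1.0, v=None):
    n = 1
    return Population(
        FBP=np.array([state[0]]), ATP=np.array([state[1]]),
        Pi=np.array([state[2]]),
        V=np.array([v if v is not None else phys.V_c]),
        H=np.array([h]),
        vmax_up=np.array([genotype.vmax_up]),
        vmax_lo=np.array([genotype.vmax_lo]),
        k_atp=np.array([genotype.k_atp]),
        k_p=np.array([genotype.k_p]),
        vatp_e=np.array([vatp_e]),
        H_max=np.array([hmax]),
        cell_id=np.arange(n, dtype=np.int64),
        type_id=np.zeros(n, dtype=np.int64),
        glucose=glc, t=0.0, next_id=n,
    )


@pytest.fixture(scope="module")
def ncg_const_env():
    return EnvironmentConfig(mode="ncg", D=5.0, d=1e-6,
                             schedule=GlucoseSchedule(kind="constant"))


class TestInitialization:
    def test_ranges_and_health(self, phys, cost):
        cfg = SimulationConfig(N0=5000, seed=0, t_ms=10, t_me=10, t_e=10)
        rng = np.random.default_rng(0)
        pop = initialize_population(cfg, REFERENCE_GENOTYPE, rng, phys, cost,
                                    glucose=2.0)
        assert pop.N == 5000
        assert pop.vmax_up.min() >= 1.0 and pop.vmax_up.max() <= 100.0
        assert pop.k_p.min() >= 0.03 and pop.k_p.max() <= 3.0
        np.testing.assert_array_equal(pop.H, pop.H_max)
        assert pop.H_max.min() >= 0.9 and pop.H_max.max() <= 1.1
        # mean initial volume ~ V_c (uniform-mean oracle)
        assert pop.V.mean() == pytest.approx(phys.V_c, rel=0.01)
        assert np.all(pop.FBP == 2.0) and np.all(pop.Pi == 10.4)


class TestIntegration:
    def test_fixed_point_stationary_both_kernels(
        self, kin, phys, balanced_fixed_point
    ):
        """A reference cell at its balanced steady state stays put under
        both the coupled and the per-cell stepper."""
        fp = balanced_fixed_point
        for mode in ("coupled", "ncg"):
            y0 = np.array([fp.FBP, fp.ATP, fp.Pi, phys.V_c, 1.0])
            one = np.ones(1)
            if mode == "coupled":
                y = np.concatenate([y0, [2.0]])
                integrate_population(
                    0.0, 200.0, y, (10 * one, 10 * one, 10 * one, 0.3 * one),
                    5.0 * one, one, _kin_array(kin),
                    phys.u_g, phys.u_d, 0.0, False, 1.0, 5.0,
                    np.array([0.0]), np.array([2.0]),
                    SimulationConfig().tolerances)
                end = y[:3]
            else:
                arrs = tuple(np.array([v]) for v in
                             (fp.FBP, fp.ATP, fp.Pi, phys.V_c, 1.0,
                              10.0, 10.0, 10.0, 0.3))
                integrate_population_ncg(
                    0.0, 200.0, arrs, 5.0 * one, one, _kin_array(kin),
                    phys.u_g, phys.u_d, 0.0, 5.0, 2.0,
                    np.array([0.0]), np.array([2.0]),
                    SimulationConfig().tolerances)
                end = np.array([arrs[0][0], arrs[1][0], arrs[2][0]])
            np.testing.assert_allclose(
                end, [fp.FBP, fp.ATP, fp.Pi], rtol=1e-3,
                err_msg=f"kernel mode {mode}")

    def test_kernel_matches_scipy_oracle(self, kin, phys):
        """Coupled stepper vs an independent scipy integration of the same
        single-cell system at constant glucose."""
        u_g, u_d = phys.u_g, phys.u_d

        def rhs(t, y):
            F, A, P = np.maximum(y[:3], 0)
            vu = 10 * 2.0 * A / ((0.1 + 2.0) * (0.1 + A * (1 + A / 3.0)))
            adp = max(5.0 - A, 0.0)
            vl = 10 * F * adp * P / ((1 + F) * (0.1 + adp) * (2 + P))
            va = 10 * A
            pv = 10 / (1 + ((P + 2 * F + A) / 250) ** 4)
            vp = 0.3 * (pv - P)
            vg = va - 5.0
            grow = u_g * vg if vg > 0 else 0.0
            return [vu - vl - F * grow, -2 * vu + 4 * vl - va - A * grow,
                    -2 * vl + va + vp - P * grow, grow * y[3], 0.0]

        ref = solve_ivp(rhs, (0, 60.0), [2.0, 1.0, 10.4, phys.V_c, 1.0],
                        rtol=1e-10, atol=1e-12).y[:, -1]
        one = np.ones(1)
        y = np.array([2.0, 1.0, 10.4, phys.V_c, 1.0, 2.0])
        integrate_population(
            0.0, 60.0, y, (10 * one, 10 * one, 10 * one, 0.3 * one),
            5.0 * one, one, _kin_array(kin), u_g, u_d, 0.0,
            False, 1.0, 5.0, np.array([0.0]), np.array([2.0]),
            SimulationConfig().tolerances)
        np.testing.assert_allclose(y[:3], ref[:3], rtol=2e-4, atol=1e-6)
        assert y[3] == pytest.approx(ref[3], rel=1e-5)

    def test_phosphate_conservation_without_transport_or_growth(
        self, kin, phys
    ):
        """With k_p ~ 0 and growth blocked, total cytosolic phosphate is a
        conserved quantity along the trajectory."""
        g = Genotype(10.0, 10.0, 10.0, 1e-12)
        pop = single_cell_population(phys, genotype=g, vatp_e=50.0, h=0.5,
                                     hmax=1.0)
        env = EnvironmentConfig(mode="ncg", D=5.0, d=1e-6,
                                schedule=GlucoseSchedule(kind="constant"))
        cfg = SimulationConfig(t_ms=0, t_me=0, t_e=50)
        sched = ScheduleRealization(env.schedule)
        ptot0 = pop.FBP[0] * 2 + pop.ATP[0] + pop.Pi[0]
        # one interval: concentrations stay positive, so no projection of
        # near-zero components perturbs the balance
        integrate_interval(pop, env, 5.0, kin, phys, sched, cfg)
        ptot1 = pop.FBP[0] * 2 + pop.ATP[0] + pop.Pi[0]
        assert ptot1 == pytest.approx(ptot0, rel=1e-8)

    def test_tolerance_refinement_convergence(self, kin, phys, ncg_const_env):
        """Halving tolerances moves the endpoint by less than ~10x the
        original tolerance band."""
        ends = []
        for scale in (1.0, 0.5):
            cfg = SimulationConfig(
                atol_c=1e-5 * scale, rtol_c=1e-5 * scale,
                t_ms=0, t_me=0, t_e=50)
            pop = single_cell_population(phys)
            sched = ScheduleRealization(ncg_const_env.schedule)
            for _ in range(10):
                integrate_interval(pop, ncg_const_env, 5.0, kin, phys, sched,
                                   cfg)
            ends.append(np.array([pop.FBP[0], pop.ATP[0], pop.Pi[0]]))
        assert np.max(np.abs(ends[0] - ends[1])) < 10 * (1e-5 + 1e-5 * 10.4)

    def test_membership_frozen_within_interval(self, kin, phys, cost,
                                               ncg_const_env):
        cfg = SimulationConfig(N0=50, t_ms=0, t_me=0, t_e=5)
        rng = np.random.default_rng(3)
        pop = initialize_population(cfg, REFERENCE_GENOTYPE, rng, phys, cost,
                                    glucose=2.0)
        sched = ScheduleRealization(ncg_const_env.schedule)
        n0 = pop.N
        integrate_interval(pop, ncg_const_env, 5.0, kin, phys, sched, cfg)
        assert pop.N == n0  # demography only at boundaries


class TestLifecycle:
    def test_division_conserves_volume_and_death_precedes_it(
        self, kin, phys, cost
    ):
        env = EnvironmentConfig(mode="ncg", D=5.0, d=1e-12,
                                schedule=GlucoseSchedule(kind="constant"))
        cfg = SimulationConfig(t_ms=0, t_me=0, t_e=5, mu=0.0)
        n = 3
        pop = Population(
            FBP=np.full(n, 2.0), ATP=np.full(n, 1.0), Pi=np.full(n, 10.4),
            V=np.array([2.2, 1.0, 0.8]) * phys.V_c,
            H=np.array([1.0, 0.0, 1.0]),   # second cell is dead
            vmax_up=np.full(n, 10.0), vmax_lo=np.full(n, 10.0),
            k_atp=np.full(n, 10.0), k_p=np.full(n, 0.3),
            vatp_e=np.full(n, 5.0), H_max=np.ones(n),
            cell_id=np.arange(n, dtype=np.int64),
            type_id=np.zeros(n, dtype=np.int64),
            glucose=2.0, t=5.0, next_id=n,
        )
        rng = np.random.default_rng(0)
        events = lifecycle_update(pop, env, cfg, phys, cost, rng,
                                  np.random.default_rng(1), mutation_on=False)
        assert events["deaths"] == 1
        assert events["births"] == 1
        assert pop.N == 3  # 3 - 1 dead + 1 new daughter
        # the dividing cell's volume was split exactly
        divided = pop.V[pop.cell_id != 2]  # exclude untouched small cell
        assert divided.sum() == pytest.approx(2.2 * phys.V_c + 0.8 * phys.V_c,
                                              rel=1e-12)

    def test_no_mutation_outside_window(self, phys, cost, kin):
        env = EnvironmentConfig(mode="ncg", D=5.0, d=1e-12,
                                schedule=GlucoseSchedule(kind="constant"))
        cfg = SimulationConfig(t_ms=1000, t_me=2000, t_e=3000, mu=1.0,
                               sigma=0.5)
        n = 1
        pop = Population(
            FBP=np.full(n, 2.0), ATP=np.full(n, 1.0), Pi=np.full(n, 10.4),
            V=np.array([2.0 * phys.V_c]), H=np.ones(n),
            vmax_up=np.full(n, 10.0), vmax_lo=np.full(n, 10.0),
            k_atp=np.full(n, 10.0), k_p=np.full(n, 0.3),
            vatp_e=np.full(n, 5.0), H_max=np.ones(n),
            cell_id=np.arange(n, dtype=np.int64),
            type_id=np.zeros(n, dtype=np.int64),
            glucose=2.0, t=5.0, next_id=n,
        )
        lifecycle_update(pop, env, cfg, phys, cost, np.random.default_rng(0),
                         np.random.default_rng(1), mutation_on=False)
        assert pop.N == 2
        np.testing.assert_array_equal(pop.vmax_up, [10.0, 10.0])
        np.testing.assert_array_equal(pop.k_p, [0.3, 0.3])


class TestRunProtocol:
    def test_zero_duration_returns_initial_state(self, ncg_const_env):
        cfg = SimulationConfig(N0=20, t_ms=0, t_me=0, t_e=0, seed=9)
        res = run(cfg, ncg_const_env)
        assert res.population.N == 20
        assert res.population.t == 0.0
        assert len(res.summary) == 0

    def test_determinism_same_seed(self):
        env = EnvironmentConfig(mode="ncg", D=5.0, d=1e-4,
                                schedule=GlucoseSchedule(kind="square_wave",
                                                         T_on=20.0))
        cfg = SimulationConfig(N0=400, N_star=100, N_tr=5, t_s=0, t_ms=100,
                               t_me=300, t_e=400, seed=11, track_start=300)
        a = run(cfg, env)
        b = run(cfg, env)
        assert a.status == b.status
        assert a.summary.equals(b.summary)
        np.testing.assert_array_equal(a.population.cell_id,
                                      b.population.cell_id)
        np.testing.assert_array_equal(a.population.ATP, b.population.ATP)
        for ta, tb in zip(a.tracks, b.tracks):
            assert ta.cell_id == tb.cell_id
            np.testing.assert_array_equal(ta.ATP, tb.ATP)

    def test_without_mutation_genotype_set_never_grows(self):
        env = EnvironmentConfig(mode="ncg", D=5.0, d=1e-4,
                                schedule=GlucoseSchedule(kind="constant"))
        cfg = SimulationConfig(N0=4000, N_star=100, N_tr=0, t_s=0, t_ms=0,
                               t_me=0, t_e=500, seed=2, mu=0.5,
                               track_start=500)
        res = run(cfg, env)
        assert res.population.N > 0
        initial = cfg.N0
        final_set = set(map(tuple, np.c_[res.population.vmax_up,
                                         res.population.vmax_lo,
                                         res.population.k_atp,
                                         res.population.k_p]))
        assert len(final_set) <= initial

    def test_calibration_rescaling(self, ncg_const_env):
        """NCG: d is scaled by N_p / N_star after the pre-simulation."""
        env = EnvironmentConfig(mode="ncg", D=5.0, d=5e-5,
                                schedule=GlucoseSchedule(kind="constant"))
        cfg = SimulationConfig(N0=2000, N_star=50, N_tr=0, t_s=0, t_ms=500,
                               t_me=600, t_e=700, seed=4)
        env2 = presim_calibrate(cfg, env)
        assert env2.mode == "ncg"
        assert env2.d != env.d and env2.d > 0
        # rerunning the pre-simulation by hand reproduces the scale factor
        from dataclasses import replace

        pre_cfg = replace(cfg, t_ms=0.0, t_me=0.0, t_e=500.0, N_tr=0)
        res = run(pre_cfg, env)
        n_rows = len(res.summary)
        n_p = res.summary["N"].iloc[-max(1, n_rows // 4):].mean()
        assert env2.d == pytest.approx(env.d * n_p / cfg.N_star, rel=1e-12)
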