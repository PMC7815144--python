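"""Tests for balancedness statistics, reproduction rate and competition."""

import math

import numpy as np
import pytest

from glycoevo.engine import TrackRecord
from glycoevo.environment import GlucoseSchedule, ScheduleRealization
from glycoevo.kinetics import Genotype
from glycoevo.metrics import (
    GLC_GRID,
    CompetitionConfig,
    balancedness_cov,
    balancedness_phase,
    detect_catastrophes,
    fixation_time_generations,
    fraction_balanced,
    genotypic_balancedness,
    is_balanced_trajectory,
    reproduction_rate,
    run_competition,
)
from glycoevo.physiology import REFERENCE_GENOTYPE, expression_cost


def square_track(n_cycles=5, T_on=10.0, atp_on=2.0, atp_off=1.0,
                 glc_on=2.0, glc_off=0.0, dt=1.0, genotype=None):
    """Synthetic track following a square-wave environment exactly."""
    T = 2 * T_on
    t = np.arange(1.0, n_cycles * T + 1.0, dt)
    # a sample falling exactly on a switch time belongs to the new phase
    phase_on = (t % T) < T_on
    glc = np.where(phase_on, glc_on, glc_off)
    atp = np.where(phase_on, atp_on, atp_off)
    n = t.size
    return TrackRecord(
        cell_id=0, time=t, FBP=np.full(n, 2.0), ATP=atp,
        Pi=np.full(n, 10.0), V=np.full(n, 3.35e-15), H=np.ones(n),
        Glc=glc, H_max=np.ones(n), genotype=genotype,
    )


@pytest.fixture
def square_sched():
    return ScheduleRealization(
        GlucoseSchedule(kind="square_wave", glc0_on=2.0, glc0_off=0.0,
                        T_on=10.0))


class TestPhenotypicBalancedness:
    def test_cov_of_in_phase_two_point_process(self, square_sched):
        """Glc in {2,0}, ATP in {2,1} in phase, equal dwell: cov ~ 0.5."""
        track = square_track(n_cycles=10)
        val = balancedness_cov(track, square_sched)
        assert val == pytest.approx(0.5, abs=0.01)

    def test_cov_zero_for_constant_glucose(self, square_sched):
        track = square_track(glc_on=2.0, glc_off=2.0)
        assert balancedness_cov(track, square_sched) == pytest.approx(0.0,
                                                                      abs=1e-12)

    def test_cov_requires_full_cycle(self, square_sched):
        track = square_track(n_cycles=1)
        track.time = track.time[:8]
        for f in ("FBP", "ATP", "Pi", "V", "H", "Glc", "H_max"):
            setattr(track, f, getattr(track, f)[:8])
        with pytest.raises(ValueError):
            balancedness_cov(track, square_sched)

    def test_phs_on_minus_off(self, square_sched):
        track = square_track(atp_on=2.0, atp_off=0.5)
        assert balancedness_phase(track, square_sched) == pytest.approx(1.5)
        flat = square_track(atp_on=1.3, atp_off=1.3)
        assert balancedness_phase(flat, square_sched) == pytest.approx(0.0)

    def test_signs_agree_on_synthetic_tracks(self, square_sched):
        balanced = square_track(atp_on=2.0, atp_off=1.0)
        imbalanced = square_track(atp_on=1.0, atp_off=2.0)
        assert balancedness_cov(balanced, square_sched) > 0
        assert balancedness_phase(balanced, square_sched) > 0
        assert balancedness_cov(imbalanced, square_sched) < 0
        assert balancedness_phase(imbalanced, square_sched) < 0

    def test_fraction_balanced_counting(self):
        assert fraction_balanced([0.3, 0.1, 1.0, -0.2]) == 0.75
        assert fraction_balanced([1.0, 2.0]) == 1.0
        assert fraction_balanced([-1.0]) == 0.0
        with pytest.raises(ValueError):
            fraction_balanced([])


class TestBalancedCriterion:
    def test_fixed_point_track_is_balanced(self, kin, phys,
                                           balanced_fixed_point):
        fp = balanced_fixed_point
        n = 300
        track = TrackRecord(
            cell_id=0, time=np.arange(1.0, n + 1.0),
            FBP=np.full(n, fp.FBP), ATP=np.full(n, fp.ATP),
            Pi=np.full(n, fp.Pi), V=np.full(n, phys.V_c),
            H=np.ones(n), Glc=np.full(n, 2.0), H_max=np.ones(n),
        )
        assert is_balanced_trajectory(track, REFERENCE_GENOTYPE, kin, phys,
                                      vatp_e=5.0)

    def test_fbp_accumulating_track_is_imbalanced(self, kin, phys):
        n = 300
        track = TrackRecord(
            cell_id=0, time=np.arange(1.0, n + 1.0),
            FBP=np.linspace(2.0, 200.0, n), ATP=np.full(n, 0.05),
            Pi=np.full(n, 0.4), V=np.full(n, 3.35e-15),
            H=np.ones(n), Glc=np.full(n, 2.0), H_max=np.ones(n),
        )
        assert not is_balanced_trajectory(track, REFERENCE_GENOTYPE, kin,
                                          phys, vatp_e=5.0)


class TestGenotypicBalancedness:
    def test_weak_upper_glycolysis_is_balanced_everywhere(self):
        """Nearly-zero UG flux cannot produce imbalance: B_g = 2.00 mM."""
        g = Genotype(0.01, 10.0, 10.0, 0.3)
        assert genotypic_balancedness(g, seed=0) == pytest.approx(2.00)

    def test_result_on_grid_and_reproducible(self, kin, phys, cost):
        g = Genotype(12.0, 6.0, 6.0, 0.5)
        v1 = genotypic_balancedness(g, seed=3, n_init=20)
        v2 = genotypic_balancedness(g, seed=3, n_init=20)
        assert v1 == v2
        assert v1 in np.append(GLC_GRID, 0.0)

    def test_monotone_in_upper_glycolysis_expression(self):
        """Raising vmax_up at fixed vmax_lo never increases B_g,1."""
        vals = [
            genotypic_balancedness(Genotype(vu, 10.0, 10.0, 0.3), seed=5,
                                   n_init=30)
            for vu in (6.0, 10.0, 14.0)
        ]
        assert vals[0] >= vals[1] >= vals[2]

    def test_mode2_requires_observed_state(self):
        with pytest.raises(ValueError):
            genotypic_balancedness(REFERENCE_GENOTYPE, mode=2)


class TestReproductionRate:
    def test_constant_growth_closed_form(self, phys, cost, square_sched):
        """ATPase flux 12.7 at full health: r = ln 2 / 90 per min."""
        track = square_track(atp_on=1.27, atp_off=1.27,
                             genotype=REFERENCE_GENOTYPE)
        r = reproduction_rate(track, square_sched)
        assert r == pytest.approx(math.log(2) / 90.0, rel=1e-6)

    def test_non_growing_cell(self, phys, square_sched):
        track = square_track(atp_on=0.3, atp_off=0.3,
                             genotype=REFERENCE_GENOTYPE)
        assert reproduction_rate(track, square_sched) == 0.0

    def test_bounded_by_max_growth_flux(self, phys, cost, square_sched):
        track = square_track(atp_on=2.0, atp_off=0.5,
                             genotype=REFERENCE_GENOTYPE)
        r = reproduction_rate(track, square_sched)
        v_max = phys.u_g * (10.0 * 2.0 - expression_cost(REFERENCE_GENOTYPE,
                                                         cost))
        assert 0.0 <= r <= v_max


def test_fixation_time_rule():
    assert fixation_time_generations(0.03) == pytest.approx(133.33, abs=0.01)
    with pytest.raises(ValueError):
        fixation_time_generations(0.0)


class TestCompetition:
    @pytest.mark.parametrize("fb0,expected", [(1.0, 1.0), (0.0, 0.0)])
    def test_pure_populations_stay_pure(self, table2, fb0, expected):
        from dataclasses import replace

        cc = CompetitionConfig(genotype_bc=table2["BC"],
                               genotype_ic=table2["IC"], f_b0=fb0,
                               N_total=200, duration=300.0, seed=1, N_tr=0)
        cc.env = replace(cc.env, V_ch=2e-10)
        fb, res = run_competition(cc)
        alive = fb.dropna(subset=["f_b"])
        assert (alive["f_b"] == expected).all()


def test_catastrophe_heuristic():
    import pandas as pd

    t = np.arange(5.0, 1000.0, 5.0)
    n = np.full(t.size, 1000.0)
    n[60:80] = 300.0   # collapse
    n[80:] = 900.0     # recovery
    summary = pd.DataFrame({"time": t, "N": n})
    events = detect_catastrophes(summary, cycle_minutes=50.0)
    assert len(events) >= 1
    assert events["N_min"].iloc[0] == 300.0
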