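"""Balancedness statistics, reproduction rates and competition experiments.

A cell's metabolic strategy in a fluctuating environment is summarised by
its *phenotypic balancedness*: balanced cells hold high ATP while glucose is
available, imbalanced ("greedy") cells hold ATP low while hoarding FBP and
release it as ATP during starvation.  Two statistics capture this:

* ``B_p,cov`` — the sample covariance of external glucose and intracellular
  ATP over an integral number of supply cycles (positive = balanced);
* ``B_p,phs`` — mean ATP during ON phases minus mean ATP during OFF phases.

*Genotypic balancedness* ``B_g`` measures the propensity of a genotype to
reach the balanced steady state: it is the largest glucose concentration on
the grid 2.00, 1.95, ..., 0.05 mM at which all 100 randomised metabolite
initialisations settle into balanced dynamics within a 300 min single-cell
simulation.  A trajectory counts as balanced when the steady-state flux
identity v_up = v_lo + [FBP] V'/V holds within 0.1 % relative error for more
than 10 % of the sampled time points.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from glycoevo._integrator import integrate_population
from glycoevo.engine import (
    Population,
    RunResult,
    SimulationConfig,
    TrackRecord,
    _cost_array,
    _kin_array,
    run,
)
from glycoevo.environment import EnvironmentConfig, GlucoseSchedule, ScheduleRealization
from glycoevo.kinetics import Genotype, KineticParameters
from glycoevo.physiology import (
    REFERENCE_GENOTYPE,
    CostModel,
    PhysiologyParameters,
    expression_cost,
    normalize_cost,
)

__all__ = [
    "BalancednessReport",
    "CompetitionConfig",
    "balancedness_cov",
    "balancedness_phase",
    "is_balanced_trajectory",
    "genotypic_balancedness",
    "reproduction_rate",
    "fraction_balanced",
    "run_competition",
    "fixation_time_generations",
    "detect_catastrophes",
    "GLC_GRID",
]

#: Glucose grid (mM) scanned by the genotypic-balancedness procedure.
GLC_GRID = np.round(np.arange(2.00, 0.049, -0.05), 2)

#: Mean initial metabolites (FBP, ATP, Pi in mM) for B_g randomisation.
BG_INITIAL_METABOLITES = (2.0, 1.0, 10.0)


@dataclass
class BalancednessReport:
    """Balancedness summary for one cell/track."""

    B_p_cov: float | None = None
    B_p_phs: float | None = None
    B_g: float | None = None
    cycles_used: int = 0


def _integral_cycle_window(
    track: TrackRecord, sched: ScheduleRealization
) -> tuple[np.ndarray, int]:
    """Boolean mask selecting the largest whole number of supply cycles
    inside the track, plus the cycle count."""
    t = track.time
    phase0, c0 = sched.phase_at(float(t[0]))
    first = c0 if (phase0 == "on" and np.isclose(t[0], sched.cycle_bounds(c0)[0])) \
        else c0 + 1
    _, c_last = sched.phase_at(float(t[-1]))
    # last fully contained cycle
    last = c_last if sched.cycle_bounds(c_last)[1] <= t[-1] + 1e-9 else c_last - 1
    if last < first:
        return np.zeros(t.size, dtype=bool), 0
    t_a = sched.cycle_bounds(first)[0]
    t_b = sched.cycle_bounds(last)[1]
    return (t > t_a + 1e-9) & (t <= t_b + 1e-9), last - first + 1


def balancedness_cov(track: TrackRecord, sched: ScheduleRealization) -> float:
    """Phenotypic balancedness B_p,cov = cov([Glc], [ATP]) (mM^2) over the
    largest integral number of cycles contained in the track."""
    mask, n_cycles = _integral_cycle_window(track, sched)
    if n_cycles < 1:
        raise ValueError("track does not span a full supply cycle")
    cov = np.cov(track.Glc[mask], track.ATP[mask], ddof=1)
    return float(cov[0, 1])


def _phase_labels(times: np.ndarray, sched: ScheduleRealization) -> np.ndarray:
    """True where a sample falls in an ON phase."""
    # pad both ends so switches landing exactly on a sample time are kept
    bp_t, bp_v = sched.breakpoints(float(times[0]) - 1e-9,
                                   float(times[-1]) + 1e-6)
    on_level = sched.schedule.glc0_on
    idx = np.searchsorted(bp_t, times, side="right") - 1
    return bp_v[idx] == on_level


def balancedness_phase(track: TrackRecord, sched: ScheduleRealization) -> float:
    """Phenotypic balancedness B_p,phs = mean ATP(ON) - mean ATP(OFF) (mM)."""
    on = _phase_labels(track.time, sched)
    if not on.any() or on.all():
        raise ValueError("track must contain both ON and OFF phase samples")
    return float(track.ATP[on].mean() - track.ATP[~on].mean())


def _track_fluxes(
    track: TrackRecord,
    g: Genotype,
    kin: KineticParameters,
    phys: PhysiologyParameters,
    vatp_e: float,
):
    """Vectorised v_up, v_lo and gated V'/V along a sampled track."""
    F = np.maximum(track.FBP, 0.0)
    A = np.maximum(track.ATP, 0.0)
    P = np.maximum(track.Pi, 0.0)
    glc = np.maximum(track.Glc, 0.0)
    adp = np.maximum(kin.a_tot - A, 0.0)
    v_up = g.vmax_up * glc * A / (
        (kin.KM_glc + glc) * (kin.KM_atp + A * (1.0 + A / kin.Ki_atp))
    )
    v_lo = g.vmax_lo * F * adp * P / (
        (kin.KM_fbp + F) * (kin.KM_adp + adp) * (kin.KM_p + P)
    )
    v_g = g.k_atp * A - (vatp_e + phys.vatp_m)
    h_max = track.H_max if track.H_max is not None else np.full_like(F, 1.0)
    at_full_health = track.H >= h_max - 1e-9
    grow = np.where((v_g > 0) & at_full_health, phys.u_g * v_g, 0.0)
    return v_up, v_lo, grow


def is_balanced_trajectory(
    track: TrackRecord,
    g: Genotype,
    kin: KineticParameters,
    phys: PhysiologyParameters,
    vatp_e: float,
    rel_tol: float = 1e-3,
    min_fraction: float = 0.1,
    atol_c: float = 1e-5,
) -> bool:
    """Balanced-state criterion for a constant-glucose single-cell track.

    True iff |v_up - (v_lo + FBP V'/V)| / v_up < ``rel_tol`` at more than
    ``min_fraction`` of the sampled time points.  Samples with v_up below
    the metabolite tolerance are judged on the absolute residual instead.
    """
    v_up, v_lo, grow = _track_fluxes(track, g, kin, phys, vatp_e)
    resid = np.abs(v_up - (v_lo + track.FBP * grow))
    tiny = v_up < atol_c
    ok = np.where(tiny, resid < atol_c, resid < rel_tol * np.maximum(v_up, atol_c))
    return bool(ok.mean() > min_fraction)


def _simulate_bg_ensemble(
    g: Genotype,
    glc: float,
    init_states: np.ndarray,
    kin: KineticParameters,
    phys: PhysiologyParameters,
    vatp_e: float,
    sim_minutes: float,
    dt_s: float,
    tolerances,
) -> list[TrackRecord]:
    """Integrate an ensemble of identical-genotype cells at constant glucose
    (no feedback on the chamber) and return their sampled tracks."""
    n = init_states.shape[0]
    y = np.concatenate([
        init_states[:, 0], init_states[:, 1], init_states[:, 2],
        np.full(n, phys.V_c), np.ones(n), [glc],
    ])
    sample_times = dt_s * np.arange(1, int(round(sim_minutes / dt_s)) + 1)
    ones = np.ones(n)
    _, _, samples = integrate_population(
        0.0, sim_minutes, y,
        (g.vmax_up * ones, g.vmax_lo * ones, g.k_atp * ones, g.k_p * ones),
        vatp_e * ones, ones,  # H_max = 1 for all ensemble members
        _kin_array(kin), phys.u_g, phys.u_d, phys.vatp_m,
        False, 1.0, 5.0,
        np.array([0.0]), np.array([glc]),
        tolerances,
        sample_times=sample_times,
        track_idx=np.arange(n, dtype=np.int64),
    )
    tracks = []
    for j in range(n):
        tracks.append(TrackRecord(
            cell_id=j, time=sample_times,
            FBP=samples[:, j, 0], ATP=samples[:, j, 1], Pi=samples[:, j, 2],
            V=samples[:, j, 3], H=samples[:, j, 4], Glc=samples[:, j, 5],
            H_max=np.ones_like(sample_times), genotype=g,
        ))
    return tracks


def genotypic_balancedness(
    g: Genotype,
    mode: int = 1,
    kin: KineticParameters | None = None,
    phys: PhysiologyParameters | None = None,
    cost: CostModel | None = None,
    observed_state: tuple[float, float, float] | None = None,
    seed: int = 0,
    n_init: int = 100,
    sim_minutes: float = 300.0,
    cv: float = 0.06,
) -> float:
    """Genotypic balancedness B_g (mM).

    Scans the glucose grid from high to low; at each concentration, ``n_init``
    single-cell trajectories are started from normally distributed metabolite
    concentrations (CV 6 %, truncated to valid ranges) around either the
    standard initial state (mode 1) or an observed evolved state (mode 2).
    Returns the largest grid concentration at which every trajectory is
    balanced, or 0.  Initial-state draws depend only on ``seed`` and the grid
    position, so the result is independent of scan order.
    """
    if mode not in (1, 2):
        raise ValueError("mode must be 1 or 2")
    if mode == 2 and observed_state is None:
        raise ValueError("mode 2 requires an observed metabolite state")
    kin = kin or KineticParameters()
    phys = phys or PhysiologyParameters()
    if cost is None:
        cost = normalize_cost(CostModel(), REFERENCE_GENOTYPE)
    vatp_e = expression_cost(g, cost)
    means = np.array(BG_INITIAL_METABOLITES if mode == 1 else observed_state)
    tolerances = SimulationConfig().tolerances
    root = np.random.SeedSequence(seed)
    children = root.spawn(len(GLC_GRID))
    for i, glc in enumerate(GLC_GRID):
        rng = np.random.default_rng(children[i])
        init = rng.normal(means, cv * means, size=(n_init, 3))
        init = np.clip(init, 0.0, None)
        init[:, 1] = np.minimum(init[:, 1], kin.a_tot)
        tracks = _simulate_bg_ensemble(
            g, float(glc), init, kin, phys, vatp_e, sim_minutes, 1.0, tolerances
        )
        if all(
            is_balanced_trajectory(tr, g, kin, phys, vatp_e) for tr in tracks
        ):
            return float(glc)
    return 0.0


def reproduction_rate(
    track: TrackRecord,
    sched: ScheduleRealization,
    kin: KineticParameters | None = None,
    phys: PhysiologyParameters | None = None,
    cost: CostModel | None = None,
) -> float:
    """Average reproduction rate r (1/min) of a tracked cell.

    The fractional volume growth rate V'/V is reconstructed from the sampled
    states via the gated growth law (so division discontinuities in V do not
    enter) and averaged over the largest integral number of supply cycles.
    """
    kin = kin or KineticParameters()
    phys = phys or PhysiologyParameters()
    if cost is None:
        cost = normalize_cost(CostModel(), REFERENCE_GENOTYPE)
    if track.genotype is None:
        raise ValueError("track must carry its genotype")
    vatp_e = expression_cost(track.genotype, cost)
    _, _, grow = _track_fluxes(track, track.genotype, kin, phys, vatp_e)
    if sched.schedule.kind == "constant":
        return float(grow.mean())
    mask, n_cycles = _integral_cycle_window(track, sched)
    if n_cycles < 1:
        raise ValueError("track does not span a full supply cycle")
    return float(grow[mask].mean())


def fraction_balanced(b_values) -> float:
    """Fraction of cells with positive phenotypic balancedness."""
    arr = np.asarray(list(b_values), dtype=float)
    if arr.size == 0:
        raise ValueError("empty balancedness set")
    return float((arr > 0).mean())


def fixation_time_generations(s: float) -> float:
    """Sweep time (generations) of a beneficial allele at frequency 0.5 with
    selective advantage ``s``: the classic 4/s rule.  At s = 0.03 this gives
    about 133 generations."""
    if s <= 0:
        raise ValueError("selective advantage must be positive")
    return 4.0 / s


@dataclass
class CompetitionConfig:
    """Two-genotype, mutation-free competition experiment."""

    genotype_bc: Genotype
    genotype_ic: Genotype
    f_b0: float = 0.5
    N_total: int = 12000
    duration: float = 30000.0
    seed: int = 0
    env: EnvironmentConfig = field(default_factory=lambda: EnvironmentConfig(
        mode="chemostat", V_ch=1e-8, D=4e-3,
        schedule=GlucoseSchedule(
            kind="pulse_train", glc0_on=300.0, glc0_off=0.01,
            T_on=1.0, T_off_mean=99.0, T_off_cv=0.05,
        ),
    ))
    dt_p: float = 5.0
    N_tr: int = 100
    track_start: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.f_b0 <= 1.0:
            raise ValueError("f_b0 must lie in [0, 1]")


def run_competition(
    cc: CompetitionConfig,
    kin: KineticParameters | None = None,
    phys: PhysiologyParameters | None = None,
    cost: CostModel | None = None,
) -> tuple[pd.DataFrame, RunResult]:
    """Simulate the joint dynamics of a balanced and an imbalanced genotype.

    Builds a mixed population with initial balanced fraction ``f_b0``
    (balanced cells carry type_id 1), runs the chemostat engine without
    mutation, and returns the f_b(t) trajectory alongside the full result.
    """
    kin = kin or KineticParameters()
    phys = phys or PhysiologyParameters()
    if cost is None:
        cost = normalize_cost(CostModel(), REFERENCE_GENOTYPE)
    cfg = SimulationConfig(
        N0=cc.N_total, N_star=cc.N_total, N_tr=cc.N_tr,
        t_s=0.0, t_ms=0.0, t_me=0.0, t_e=cc.duration,
        dt_p=cc.dt_p, mu=0.0, seed=cc.seed,
        track_start=cc.duration if cc.N_tr == 0 else cc.track_start,
    )
    rng = np.random.default_rng(np.random.SeedSequence(cc.seed).spawn(1)[0])
    n_bc = int(round(cc.f_b0 * cc.N_total))
    n = cc.N_total
    type_id = np.zeros(n, dtype=np.int64)
    type_id[:n_bc] = 1
    gen = np.empty((n, 4))
    gen[:n_bc] = cc.genotype_bc.as_tuple()
    gen[n_bc:] = cc.genotype_ic.as_tuple()
    h_max = rng.uniform(0.9, 1.1, size=n)
    from glycoevo.environment import initial_chamber_glucose
    pop = Population(
        FBP=np.full(n, 2.0), ATP=np.full(n, 1.0), Pi=np.full(n, 10.4),
        V=rng.uniform(0.5 * phys.V_c, 1.5 * phys.V_c, size=n),
        H=h_max.copy(),
        vmax_up=gen[:, 0].copy(), vmax_lo=gen[:, 1].copy(),
        k_atp=gen[:, 2].copy(), k_p=gen[:, 3].copy(),
        vatp_e=_cost_array(cost, gen[:, 0], gen[:, 1], gen[:, 2], gen[:, 3]),
        H_max=h_max,
        cell_id=np.arange(n, dtype=np.int64),
        type_id=type_id,
        glucose=initial_chamber_glucose(cc.env.schedule),
        t=0.0,
        next_id=n,
    )
    result = run(cfg, cc.env, kin=kin, phys=phys, cost=cost, pop=pop)
    fb = result.summary[["time", "N", "n_type1"]].copy()
    with np.errstate(invalid="ignore"):
        fb["f_b"] = fb["n_type1"] / fb["N"].replace(0, np.nan)
    return fb, result


def calibrate_competition_chamber(
    cc: CompetitionConfig,
    target_n: int,
    presim_duration: float = 2000.0,
    kin: KineticParameters | None = None,
    phys: PhysiologyParameters | None = None,
    cost: CostModel | None = None,
) -> CompetitionConfig:
    """Rescale the chamber volume so the mixed population settles near
    ``target_n`` (V_ch = V_ch,0 * N_target / N_presim)."""
    probe = replace(cc, duration=presim_duration, N_tr=0)
    fb, res = run_competition(probe, kin=kin, phys=phys, cost=cost)
    n_rows = len(fb)
    n_p = float(fb["N"].iloc[-max(1, n_rows // 4):].mean())
    if n_p <= 0:
        raise RuntimeError("competition pre-simulation went extinct")
    env = replace(cc.env, V_ch=cc.env.V_ch * target_n / n_p)
    return replace(cc, env=env)


def detect_catastrophes(
    summary: pd.DataFrame, cycle_minutes: float,
    drop_fraction: float = 0.5, recovery_fraction: float = 0.8,
) -> pd.DataFrame:
    """Simple summary heuristic for population catastrophes (reporting aid).

    Flags times where N drops by more than ``drop_fraction`` within one mean
    supply cycle and later recovers above ``recovery_fraction`` of the
    pre-drop size.  This is a descriptive convenience, not a statistic from
    the underlying model analysis.
    """
    t = summary["time"].to_numpy()
    n = summary["N"].to_numpy(dtype=float)
    events = []
    if len(t) < 3:
        return pd.DataFrame(columns=["t_drop", "N_before", "N_min", "t_recovered"])
    dt = t[1] - t[0]
    lag = max(1, int(round(cycle_minutes / dt)))
    for i in range(lag, len(t)):
        n_before = n[i - lag]
        if n_before > 0 and n[i] < (1 - drop_fraction) * n_before:
            rec = np.nonzero(n[i:] > recovery_fraction * n_before)[0]
            if rec.size:
                events.append((t[i], n_before, n[i:i + rec[0] + 1].min(),
                               t[i + rec[0]]))
    return pd.DataFrame(events, columns=["t_drop", "N_before", "N_min",
                                         "t_recovered"]).drop_duplicates(
        subset="t_recovered")
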