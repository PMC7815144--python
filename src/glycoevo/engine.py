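"""Population simulation engine.

The simulation alternates two phases on a fixed demographic interval
``dt_p``: (i) all cell states (metabolites, volume, health) and the chamber
glucose are integrated jointly as one coupled ODE system; (ii) demographic
events are applied at the interval boundary, in a fixed order — death
(H <= 0), division (V >= 2 V_c, with mutation during the mutation-on
segment), washout sampling, and tracked-set maintenance.  Population
membership never changes inside an integration interval.

A run is divided into three segments: a mutation-free burn-in [t_s, t_ms)
that establishes a viable population from broad standing variation, a
mutation-on segment [t_ms, t_me), and a final mutation-free segment
[t_me, t_e] in which only the fittest genotypes survive.  Before a full run,
:func:`presim_calibrate` rescales the chamber volume (chemostat) or the
crowding constant (NCG) so the equilibrium population size matches the
target ``N_star``.

Randomness is drawn from four named streams spawned from one root seed
(initialization, schedule, demography, mutation), so runs are reproducible
bit-for-bit from the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from glycoevo._integrator import integrate_population, integrate_population_ncg
from glycoevo.environment import EnvironmentConfig, ScheduleRealization
from glycoevo.kinetics import Genotype, KineticParameters
from glycoevo.physiology import (
    REFERENCE_GENOTYPE,
    CostModel,
    PhysiologyParameters,
    expression_cost,
    mutate_genotype,
    normalize_cost,
)

__all__ = [
    "SimulationConfig",
    "Population",
    "TrackRecord",
    "RunResult",
    "CalibrationError",
    "initialize_population",
    "integrate_interval",
    "lifecycle_update",
    "presim_calibrate",
    "run",
]

#: Initial cytosolic metabolite concentrations (mM) for new populations.
INITIAL_METABOLITES = (2.0, 1.0, 10.4)


class CalibrationError(RuntimeError):
    """Raised when the calibration pre-simulation goes extinct."""


@dataclass(frozen=True)
class SimulationConfig:
    """Protocol parameters of a population run.

    Times are minutes.  ``dt_p`` is the demographic interval within which
    population membership is frozen; ``dt_s`` the sampling interval for
    tracked cells.  ``init_genotype_span`` s sets the width of the initial
    uniform genotype draw U(P/s, s*P) around each reference parameter P.
    ``track_start`` bounds the memory of track recording: sampling of the
    tracked subpopulation begins at that time (default: from t_s).
    """

    N0: int = 10000
    N_star: int = 10000
    N_tr: int = 100
    t_s: float = 0.0
    t_ms: float = 10000.0
    t_me: float = 500000.0
    t_e: float = 800000.0
    dt_p: float = 5.0
    dt_s: float = 1.0
    mu: float = 1e-2
    sigma: float = 0.1
    seed: int = 0
    atol_c: float = 1e-5
    rtol_c: float = 1e-5
    atol_v: float = 0.01e-15
    rtol_v: float = 0.0
    atol_h: float = 1e-2
    rtol_h: float = 0.0
    init_genotype_span: float = 10.0
    track_start: float | None = None
    mutate_both_daughters: bool = True

    def __post_init__(self) -> None:
        if not (self.t_s <= self.t_ms <= self.t_me <= self.t_e):
            raise ValueError("need t_s <= t_ms <= t_me <= t_e")
        if self.dt_s > self.dt_p:
            raise ValueError("dt_s must not exceed dt_p")
        for name in ("atol_c", "rtol_c", "atol_v", "atol_h"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def tolerances(self) -> tuple[float, float, float, float, float, float]:
        return (self.atol_c, self.rtol_c, self.atol_v,
                self.rtol_v, self.atol_h, self.rtol_h)


@dataclass
class Population:
    """Array-of-struct population state (one entry per cell)."""

    FBP: np.ndarray
    ATP: np.ndarray
    Pi: np.ndarray
    V: np.ndarray
    H: np.ndarray
    vmax_up: np.ndarray
    vmax_lo: np.ndarray
    k_atp: np.ndarray
    k_p: np.ndarray
    vatp_e: np.ndarray
    H_max: np.ndarray
    cell_id: np.ndarray
    type_id: np.ndarray
    glucose: float
    t: float
    next_id: int
    births: int = 0
    deaths: int = 0
    washouts: int = 0
    h_step: np.ndarray | None = None  # per-cell warm-start step size (min)

    _ARRAYS = ("FBP", "ATP", "Pi", "V", "H", "vmax_up", "vmax_lo",
               "k_atp", "k_p", "vatp_e", "H_max", "cell_id", "type_id",
               "h_step")

    def __post_init__(self) -> None:
        if self.h_step is None:
            self.h_step = np.full(self.FBP.size, 1e-2)

    @property
    def N(self) -> int:
        return self.FBP.size

    def keep(self, idx: np.ndarray) -> None:
        """Restrict the population to the cells at positions ``idx``."""
        for name in self._ARRAYS:
            setattr(self, name, getattr(self, name)[idx])

    def pack_state(self) -> np.ndarray:
        return np.concatenate(
            [self.FBP, self.ATP, self.Pi, self.V, self.H, [self.glucose]]
        )

    def unpack_state(self, y: np.ndarray) -> None:
        n = self.N
        self.FBP = y[0:n].copy()
        self.ATP = y[n:2 * n].copy()
        self.Pi = y[2 * n:3 * n].copy()
        self.V = y[3 * n:4 * n].copy()
        self.H = y[4 * n:5 * n].copy()
        self.glucose = float(y[5 * n])

    def genotype_of(self, i: int) -> Genotype:
        return Genotype(float(self.vmax_up[i]), float(self.vmax_lo[i]),
                        float(self.k_atp[i]), float(self.k_p[i]))


@dataclass
class TrackRecord:
    """Sampled time series of one tracked cell (lineage continues through
    division for the daughter that inherits tracking)."""

    cell_id: int
    time: np.ndarray
    FBP: np.ndarray
    ATP: np.ndarray
    Pi: np.ndarray
    V: np.ndarray
    H: np.ndarray
    Glc: np.ndarray
    H_max: np.ndarray | None = None
    genotype: Genotype | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.time,
                "cell_id": self.cell_id,
                "FBP": self.FBP,
                "ATP": self.ATP,
                "Pi": self.Pi,
                "V": self.V,
                "H": self.H,
                "Glc": self.Glc,
            }
        )


@dataclass
class RunResult:
    population: Population
    tracks: list[TrackRecord]
    summary: pd.DataFrame
    status: str
    schedule: ScheduleRealization | None = None
    env: EnvironmentConfig | None = None


def _spawn_streams(seed: int) -> dict[str, np.random.Generator]:
    ss = np.random.SeedSequence(seed)
    names = ("init", "schedule", "demography", "mutation")
    children = ss.spawn(len(names))
    return {n: np.random.default_rng(c) for n, c in zip(names, children)}


def _cost_array(cost: CostModel, vmax_up, vmax_lo, k_atp, k_p) -> np.ndarray:
    """Vectorised expression cost for per-cell genotype arrays."""
    if not cost.normalized:
        raise ValueError("CostModel must be normalized")
    terms = (
        cost.w_up * np.asarray(vmax_up),
        cost.w_lo * np.asarray(vmax_lo),
        cost.w_atp * cost.c_u * np.asarray(k_atp),
        cost.w_p * cost.c_u * np.asarray(k_p),
    )
    if cost.variant == "power_sum":
        raw = sum(t**cost.n for t in terms)
    else:
        raw = sum(terms) ** cost.n
    return cost.k_e * raw


def _kin_array(k: KineticParameters) -> np.ndarray:
    return np.array([k.KM_glc, k.KM_atp, k.Ki_atp, k.a_tot, k.KM_fbp,
                     k.KM_adp, k.KM_p, k.Pi_vac_max, k.K_vac, k.m])


def initialize_population(
    cfg: SimulationConfig,
    reference: Genotype,
    rng: np.random.Generator,
    phys: PhysiologyParameters,
    cost: CostModel,
    glucose: float,
    t: float | None = None,
) -> Population:
    """Create N0 cells with genotypes drawn U(P/span, span*P) around the
    reference, volumes U(0.5, 1.5) V_c, fresh health, and the standard
    initial metabolite concentrations."""
    n = cfg.N0
    span = cfg.init_genotype_span
    ref = np.array(reference.as_tuple())
    draws = rng.uniform(ref / span, span * ref, size=(n, 4))
    h_max = rng.uniform(0.9, 1.1, size=n)
    v = rng.uniform(0.5 * phys.V_c, 1.5 * phys.V_c, size=n)
    f0, a0, p0 = INITIAL_METABOLITES
    return Population(
        FBP=np.full(n, f0),
        ATP=np.full(n, a0),
        Pi=np.full(n, p0),
        V=v,
        H=h_max.copy(),
        vmax_up=draws[:, 0].copy(),
        vmax_lo=draws[:, 1].copy(),
        k_atp=draws[:, 2].copy(),
        k_p=draws[:, 3].copy(),
        vatp_e=_cost_array(cost, draws[:, 0], draws[:, 1], draws[:, 2], draws[:, 3]),
        H_max=h_max,
        cell_id=np.arange(n, dtype=np.int64),
        type_id=np.zeros(n, dtype=np.int64),
        glucose=float(glucose),
        t=cfg.t_s if t is None else t,
        next_id=n,
    )


def integrate_interval(
    pop: Population,
    env: EnvironmentConfig,
    dt: float,
    kin: KineticParameters,
    phys: PhysiologyParameters,
    sched: ScheduleRealization,
    cfg: SimulationConfig,
    sample_times: np.ndarray | None = None,
    track_idx: np.ndarray | None = None,
    h0: float = 1e-2,
):
    """Advance all cells and the chamber glucose over one interval.

    Population membership is unchanged; returns (samples, h_last) where
    samples holds tracked-cell states at the requested times.
    """
    t0, t1 = pop.t, pop.t + dt
    bp_times, bp_values = sched.breakpoints(t0, t1)
    if env.mode == "ncg":
        # cells are independent of the chamber in the NCG limit: per-cell
        # adaptive stepping with analytic glucose
        glc_end, samples = integrate_population_ncg(
            t0, t1,
            (pop.FBP, pop.ATP, pop.Pi, pop.V, pop.H,
             pop.vmax_up, pop.vmax_lo, pop.k_atp, pop.k_p),
            pop.vatp_e, pop.H_max,
            _kin_array(kin), phys.u_g, phys.u_d, phys.vatp_m,
            env.D, pop.glucose, bp_times, bp_values,
            cfg.tolerances,
            sample_times=sample_times,
            track_idx=track_idx,
            h_cells=pop.h_step,
        )
        pop.glucose = glc_end
        h_last = h0
    else:
        y = pop.pack_state()
        _, h_last, samples = integrate_population(
            t0, t1, y,
            (pop.vmax_up, pop.vmax_lo, pop.k_atp, pop.k_p),
            pop.vatp_e, pop.H_max,
            _kin_array(kin), phys.u_g, phys.u_d, phys.vatp_m,
            True, env.V_ch, env.D,
            bp_times, bp_values,
            cfg.tolerances,
            sample_times=sample_times,
            track_idx=track_idx,
            h0=h0,
        )
        pop.unpack_state(y)
    # hard clip health to [0, H_max] at the interval boundary
    np.clip(pop.H, 0.0, pop.H_max, out=pop.H)
    pop.t = t1
    return samples, h_last


def lifecycle_update(
    pop: Population,
    env: EnvironmentConfig,
    cfg: SimulationConfig,
    phys: PhysiologyParameters,
    cost: CostModel,
    rng_demography: np.random.Generator,
    rng_mutation: np.random.Generator,
    mutation_on: bool,
    tracked_ids: set[int] | None = None,
) -> dict[str, int]:
    """Apply boundary demographic events in order: death, division, washout,
    tracked-set refresh.  Returns the event counts for this boundary."""
    events = {"deaths": 0, "births": 0, "washouts": 0}

    # 1. death
    dead = pop.H <= 0.0
    n_dead = int(dead.sum())
    if n_dead:
        if tracked_ids is not None:
            tracked_ids.difference_update(pop.cell_id[dead].tolist())
        pop.keep(np.nonzero(~dead)[0])
        pop.deaths += n_dead
        events["deaths"] = n_dead
    if pop.N == 0:
        return events

    # 2. division (+ mutation of both daughters while mutation is on)
    div_idx = np.nonzero(pop.V >= 2.0 * phys.V_c)[0]
    if div_idx.size:
        new_rows: dict[str, list] = {name: [] for name in Population._ARRAYS}
        for i in div_idx:
            v_random = rng_demography.uniform(0.5 * phys.V_c, 1.5 * phys.V_c)
            v_other = pop.V[i] - v_random
            if rng_demography.random() < 0.5:
                v_slot, v_new = v_random, v_other
            else:
                v_slot, v_new = v_other, v_random
            hm_slot = rng_demography.uniform(0.9, 1.1)
            hm_new = rng_demography.uniform(0.9, 1.1)
            parent_geno = pop.genotype_of(i)
            genos = [parent_geno, parent_geno]
            if mutation_on and cfg.mu > 0:
                genos = [
                    mutate_genotype(parent_geno, cfg.mu, cfg.sigma, rng_mutation)
                    for _ in range(2)
                ] if cfg.mutate_both_daughters else [
                    parent_geno,
                    mutate_genotype(parent_geno, cfg.mu, cfg.sigma, rng_mutation),
                ]
            # daughter in the parent slot
            pop.V[i] = v_slot
            pop.H[i] = hm_slot
            pop.H_max[i] = hm_slot
            if genos[0] is not parent_geno:
                pop.vmax_up[i], pop.vmax_lo[i], pop.k_atp[i], pop.k_p[i] = (
                    genos[0].as_tuple()
                )
                pop.vatp_e[i] = expression_cost(genos[0], cost)
            # second daughter appended
            g1 = genos[1]
            new_rows["FBP"].append(pop.FBP[i])
            new_rows["ATP"].append(pop.ATP[i])
            new_rows["Pi"].append(pop.Pi[i])
            new_rows["V"].append(v_new)
            new_rows["H"].append(hm_new)
            new_rows["H_max"].append(hm_new)
            new_rows["vmax_up"].append(g1.vmax_up)
            new_rows["vmax_lo"].append(g1.vmax_lo)
            new_rows["k_atp"].append(g1.k_atp)
            new_rows["k_p"].append(g1.k_p)
            new_rows["vatp_e"].append(
                pop.vatp_e[i] if g1 is parent_geno else expression_cost(g1, cost)
            )
            new_rows["h_step"].append(pop.h_step[i])
            new_id = pop.next_id
            pop.next_id += 1
            new_rows["cell_id"].append(new_id)
            new_rows["type_id"].append(pop.type_id[i])
            # a dividing tracked cell passes tracking to one uniform daughter
            if tracked_ids is not None and int(pop.cell_id[i]) in tracked_ids:
                if rng_demography.random() < 0.5:
                    tracked_ids.discard(int(pop.cell_id[i]))
                    tracked_ids.add(new_id)
        for name in Population._ARRAYS:
            arr = getattr(pop, name)
            setattr(
                pop, name,
                np.concatenate([arr, np.asarray(new_rows[name], dtype=arr.dtype)]),
            )
        pop.births += div_idx.size
        events["births"] = int(div_idx.size)

    # 3. washout
    from glycoevo.environment import removal_count

    n_out = removal_count(pop.N, env, cfg.dt_p, rng_demography)
    n_out = min(n_out, pop.N)
    if n_out:
        out = rng_demography.choice(pop.N, size=n_out, replace=False)
        if tracked_ids is not None:
            tracked_ids.difference_update(pop.cell_id[out].tolist())
        mask = np.ones(pop.N, dtype=bool)
        mask[out] = False
        pop.keep(np.nonzero(mask)[0])
        pop.washouts += n_out
        events["washouts"] = n_out

    # 4. tracked-set refresh: keep N_tr cells tracked, replacements uniform
    if tracked_ids is not None and pop.N > 0:
        want = min(cfg.N_tr, pop.N)
        if len(tracked_ids) > want:
            drop = rng_demography.choice(
                sorted(tracked_ids), size=len(tracked_ids) - want, replace=False
            )
            tracked_ids.difference_update(drop.tolist())
        elif len(tracked_ids) < want:
            candidates = np.setdiff1d(pop.cell_id, np.fromiter(
                tracked_ids, dtype=np.int64, count=len(tracked_ids)))
            n_add = min(want - len(tracked_ids), candidates.size)
            if n_add:
                add = rng_demography.choice(candidates, size=n_add, replace=False)
                tracked_ids.update(int(a) for a in add)
    return events


def run(
    cfg: SimulationConfig,
    env: EnvironmentConfig,
    kin: KineticParameters | None = None,
    phys: PhysiologyParameters | None = None,
    cost: CostModel | None = None,
    reference: Genotype = REFERENCE_GENOTYPE,
    pop: Population | None = None,
    progress: bool = False,
) -> RunResult:
    """Run the three-segment protocol from t_s to t_e.

    Mutation is active only for divisions at boundaries in [t_ms, t_me).
    Tracked cells are sampled every ``dt_s`` from ``track_start`` onwards.
    Returns the final population, the track records, and a per-interval
    summary table (time, N, glucose, mean genotype, event counts).
    """
    kin = kin or KineticParameters()
    phys = phys or PhysiologyParameters()
    if cost is None:
        cost = normalize_cost(CostModel(), reference)
    elif not cost.normalized:
        cost = normalize_cost(cost, reference)

    streams = _spawn_streams(cfg.seed)
    sched = ScheduleRealization(env.schedule, streams["schedule"])
    if pop is None:
        from glycoevo.environment import initial_chamber_glucose

        pop = initialize_population(
            cfg, reference, streams["init"], phys, cost,
            glucose=initial_chamber_glucose(env.schedule), t=cfg.t_s,
        )
    track_start = cfg.t_s if cfg.track_start is None else cfg.track_start

    tracked_ids: set[int] = set()
    buffers: dict[int, list[np.ndarray]] = {}
    time_buffers: dict[int, list[np.ndarray]] = {}
    geno_of_track: dict[int, Genotype] = {}

    summary_rows = []
    status = "ok"
    h_last = 1e-2
    n_steps = int(round((cfg.t_e - cfg.t_s) / cfg.dt_p))
    iterator = range(n_steps)
    if progress:
        from tqdm import tqdm

        iterator = tqdm(iterator)

    for step in iterator:
        t0 = cfg.t_s + step * cfg.dt_p
        t1 = t0 + cfg.dt_p
        tracking = t1 > track_start and cfg.N_tr > 0
        if tracking and not tracked_ids and pop.N > 0:
            want = min(cfg.N_tr, pop.N)
            pick = streams["demography"].choice(pop.cell_id, size=want, replace=False)
            tracked_ids.update(int(p) for p in pick)
        sample_times = None
        track_idx = None
        ordered_ids: list[int] = []
        if tracking and tracked_ids:
            n_s = int(round(cfg.dt_p / cfg.dt_s))
            sample_times = t0 + cfg.dt_s * np.arange(1, n_s + 1)
            id_to_pos = {int(cid): i for i, cid in enumerate(pop.cell_id)}
            ordered_ids = sorted(tracked_ids)
            track_idx = np.array([id_to_pos[c] for c in ordered_ids], dtype=np.int64)

        samples, h_last = integrate_interval(
            pop, env, cfg.dt_p, kin, phys, sched, cfg,
            sample_times=sample_times, track_idx=track_idx, h0=h_last,
        )
        if track_idx is not None and samples.size:
            hmax_now = pop.H_max[track_idx]
            for j, cid in enumerate(ordered_ids):
                chunk = np.empty((samples.shape[0], 7))
                chunk[:, :6] = samples[:, j, :]
                chunk[:, 6] = hmax_now[j]
                buffers.setdefault(cid, []).append(chunk)
                time_buffers.setdefault(cid, []).append(sample_times)
                geno_of_track[cid] = pop.genotype_of(int(track_idx[j]))

        mutation_on = cfg.t_ms <= t1 < cfg.t_me
        events = lifecycle_update(
            pop, env, cfg, phys, cost,
            streams["demography"], streams["mutation"], mutation_on,
            tracked_ids=tracked_ids if tracking else None,
        )
        summary_rows.append((
            t1, pop.N, pop.glucose,
            pop.vmax_up.mean() if pop.N else np.nan,
            pop.vmax_lo.mean() if pop.N else np.nan,
            pop.k_atp.mean() if pop.N else np.nan,
            pop.k_p.mean() if pop.N else np.nan,
            int((pop.type_id == 1).sum()),
            events["births"], events["deaths"], events["washouts"],
        ))
        if pop.N == 0:
            status = "extinct"
            break

    summary = pd.DataFrame(
        summary_rows,
        columns=["time", "N", "Glc", "mean_vmax_up", "mean_vmax_lo",
                 "mean_k_atp", "mean_k_p", "n_type1",
                 "births", "deaths", "washouts"],
    )
    tracks = []
    for cid, chunks in buffers.items():
        data = np.vstack(chunks)
        times = np.concatenate(time_buffers[cid])
        tracks.append(TrackRecord(
            cell_id=cid, time=times,
            FBP=data[:, 0], ATP=data[:, 1], Pi=data[:, 2],
            V=data[:, 3], H=data[:, 4], Glc=data[:, 5],
            H_max=data[:, 6],
            genotype=geno_of_track.get(cid),
        ))
    tracks.sort(key=lambda tr: tr.cell_id)
    return RunResult(population=pop, tracks=tracks, summary=summary,
                     status=status, schedule=sched, env=env)


def presim_calibrate(
    cfg: SimulationConfig,
    env: EnvironmentConfig,
    kin: KineticParameters | None = None,
    phys: PhysiologyParameters | None = None,
    cost: CostModel | None = None,
    reference: Genotype = REFERENCE_GENOTYPE,
) -> EnvironmentConfig:
    """Calibrate V_ch (chemostat) or d (NCG) with a mutation-free
    pre-simulation of the burn-in duration.

    The steady-state population size N_p is the mean of N over the final
    quarter of the pre-simulation; the provisional parameter is rescaled as
    V_ch = V_ch,0 * N_star / N_p or d = d_0 * N_p / N_star.
    """
    duration = cfg.t_ms - cfg.t_s
    if duration <= 0:
        raise ValueError("pre-simulation needs t_ms > t_s")
    pre_cfg = replace(
        cfg,
        t_ms=cfg.t_s, t_me=cfg.t_s,  # mutation off throughout
        t_e=cfg.t_s + duration,
        N_tr=0,
    )
    result = run(pre_cfg, env, kin=kin, phys=phys, cost=cost, reference=reference)
    if result.status == "extinct" or result.population.N == 0:
        raise CalibrationError("pre-simulation population went extinct")
    n_rows = len(result.summary)
    tail = result.summary["N"].iloc[-max(1, n_rows // 4):]
    n_p = float(tail.mean())
    if n_p <= 0:
        raise CalibrationError("pre-simulation steady-state size is zero")
    if env.mode == "chemostat":
        return replace(env, V_ch=env.V_ch * cfg.N_star / n_p)
    return replace(env, d=env.d * n_p / cfg.N_star)
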