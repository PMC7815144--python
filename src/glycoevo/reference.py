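"""Reference single-cell experiments anchoring the model calibration.

These functions exercise the pathway at single-cell scale: locating the
balanced fixed point of the reference genotype, measuring its volume
doubling time and ATPase flux at constant 2 mM glucose, the death time at
the reference imbalanced growth flux, and the quasi-steady ATPase flux of
the imbalanced regime before vacuolar phosphate depletion.
"""

from __future__ import annotations

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import fsolve

from glycoevo._integrator import integrate_population_ncg
from glycoevo.engine import SimulationConfig, _kin_array
from glycoevo.kinetics import (
    Genotype,
    KineticParameters,
    MetaboliteState,
    atpase_rate,
    metabolite_derivatives,
)
from glycoevo.physiology import (
    REFERENCE_GENOTYPE,
    PhysiologyParameters,
    health_rate,
)

__all__ = [
    "balanced_fixed_point",
    "simulate_single_cell",
    "doubling_time",
    "death_time",
    "balanced_atpase_flux",
    "imbalanced_atpase_plateau",
]


def balanced_fixed_point(
    kin: KineticParameters | None = None,
    phys: PhysiologyParameters | None = None,
    genotype: Genotype = REFERENCE_GENOTYPE,
    glc: float = 2.0,
    vatp_e: float = 5.0,
    x0=(2.0, 1.0, 10.4),
) -> MetaboliteState:
    """Root of the metabolite ODEs at constant glucose with self-consistent
    growth dilution (growth gated on a positive growth flux)."""
    kin = kin or KineticParameters()
    phys = phys or PhysiologyParameters()

    def residual(y):
        s = MetaboliteState(*np.maximum(y, 0.0))
        v_atp = atpase_rate(s, genotype)
        growth = max(phys.u_g * (v_atp - vatp_e - phys.vatp_m), 0.0)
        return metabolite_derivatives(s, glc, growth, genotype, kin)

    root, info, ier, _ = fsolve(residual, list(x0), full_output=True)
    if ier != 1 or np.max(np.abs(info["fvec"])) > 1e-9:
        raise RuntimeError("balanced fixed point root-find failed")
    return MetaboliteState(*root)


def simulate_single_cell(
    state0,
    glc: float,
    minutes: float,
    dt: float,
    kin: KineticParameters | None = None,
    phys: PhysiologyParameters | None = None,
    genotype: Genotype = REFERENCE_GENOTYPE,
    vatp_e: float = 5.0,
):
    """Integrate one cell at constant glucose (full growth/health coupling,
    starting at full health).  Returns (t, samples) with sample columns
    FBP, ATP, Pi, V, H, Glc."""
    kin = kin or KineticParameters()
    phys = phys or PhysiologyParameters()
    one = np.ones(1)
    arrs = (
        np.array([state0[0]]), np.array([state0[1]]), np.array([state0[2]]),
        np.array([phys.V_c]), np.array([1.0]),
        genotype.vmax_up * one, genotype.vmax_lo * one,
        genotype.k_atp * one, genotype.k_p * one,
    )
    sample_times = dt * np.arange(1, int(round(minutes / dt)) + 1)
    _, samples = integrate_population_ncg(
        0.0, minutes, arrs, vatp_e * one, one, _kin_array(kin),
        phys.u_g, phys.u_d, phys.vatp_m, 5.0, glc,
        np.array([0.0]), np.array([glc]), SimulationConfig().tolerances,
        sample_times=sample_times, track_idx=np.array([0]),
    )
    return sample_times, samples[:, 0, :]


def doubling_time(
    kin: KineticParameters | None = None,
    phys: PhysiologyParameters | None = None,
) -> float:
    """Time (min) for a reference cell at its balanced fixed point under
    constant 2 mM glucose to double its volume."""
    kin = kin or KineticParameters()
    phys = phys or PhysiologyParameters()
    fp = balanced_fixed_point(kin, phys)
    t, smp = simulate_single_cell((fp.FBP, fp.ATP, fp.Pi), 2.0, 150.0, 0.25,
                                  kin, phys)
    v = smp[:, 3]
    v0 = phys.V_c
    idx = int(np.argmax(v >= 2.0 * v0))
    if v[idx] < 2.0 * v0:
        raise RuntimeError("cell did not double within the horizon")
    t_hi, v_hi = t[idx], v[idx]
    t_lo, v_lo = t[idx - 1], v[idx - 1]
    return float(t_lo + (2.0 * v0 - v_lo) / (v_hi - v_lo) * (t_hi - t_lo))


def death_time(phys: PhysiologyParameters | None = None) -> float:
    """Time (min) for health to fall 1 -> 0 with the growth flux held at
    the reference imbalanced value."""
    phys = phys or PhysiologyParameters()
    v_atp_g = phys.vatp_ref_imbalanced - phys.vatp_e_ref - phys.vatp_m

    def rhs(t, y):
        return [health_rate(v_atp_g, y[0], 1.0, phys)]

    def hit_zero(t, y):
        return y[0]

    hit_zero.terminal = True
    hit_zero.direction = -1
    sol = solve_ivp(rhs, (0.0, 10.0 * phys.tau_d), [1.0], events=hit_zero,
                    rtol=1e-10, atol=1e-12)
    if not sol.t_events[0].size:
        raise RuntimeError("health never reached zero")
    return float(sol.t_events[0][0])


def balanced_atpase_flux(
    kin: KineticParameters | None = None,
    phys: PhysiologyParameters | None = None,
) -> float:
    """ATPase flux k_atp [ATP] (mM/min) at the balanced fixed point of the
    reference genotype at 2 mM glucose."""
    fp = balanced_fixed_point(kin, phys)
    return atpase_rate(fp, REFERENCE_GENOTYPE)


def imbalanced_atpase_plateau(
    kin: KineticParameters | None = None,
    phys: PhysiologyParameters | None = None,
    p_tot_max: float = 50.0,
) -> tuple[float, int]:
    """Quasi-steady ATPase flux of the imbalanced regime.

    Integrates the reference cell at 2 mM glucose from a phosphate-poor
    start (FBP 2, ATP 1, Pi 1 mM) into the FBP-accumulating regime and
    returns the median of k_atp [ATP] over samples where FBP is rising,
    P_tot < ``p_tot_max`` and the initial ATP transient has passed, plus
    the number of samples in that window."""
    kin = kin or KineticParameters()
    phys = phys or PhysiologyParameters()
    t, smp = simulate_single_cell((2.0, 1.0, 1.0), 2.0, 60.0, 0.1, kin, phys)
    fbp, atp, pi = smp[:, 0], smp[:, 1], smp[:, 2]
    p_tot = pi + 2 * fbp + atp
    rising = np.gradient(fbp, t) > 0
    sel = (p_tot < p_tot_max) & rising & (t >= 2.0)
    if not sel.any():
        raise RuntimeError("no plateau window found")
    flux = REFERENCE_GENOTYPE.k_atp * atp[sel]
    return float(np.median(flux)), int(sel.sum())
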