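"""Adaptive Dormand-Prince 5(4) integrator for the coupled population system.

The whole population plus the chamber glucose concentration is advanced as a
single ODE system with state layout

    y = [FBP_0..FBP_{N-1}, ATP_0.., Pi_0.., V_0.., H_0.., Glc]

Per-component error control uses separate (atol, rtol) pairs for metabolite
concentrations, cell volume and cell health.  After every accepted step, any
metabolite component c with -(atol_c + |c| rtol_c) < c < 0 is projected to
zero; if a more negative component remains, the step is rejected and retried
with half the step size.  Steps never cross supply-schedule switch times or
requested sample times, so the right-hand side is smooth within each step.

The stepper is compiled with numba and vectorised over cells; the scalar
rate functions in :mod:`glycoevo.kinetics` are the readable reference
implementation against which this kernel is cross-checked in the test suite.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["integrate_population", "STATUS_OK", "STATUS_STEP_UNDERFLOW"]

STATUS_OK = 0
STATUS_STEP_UNDERFLOW = 1

# Dormand-Prince 5(4) tableau.
_A21 = 1.0 / 5.0
_A31, _A32 = 3.0 / 40.0, 9.0 / 40.0
_A41, _A42, _A43 = 44.0 / 45.0, -56.0 / 15.0, 32.0 / 9.0
_A51, _A52, _A53, _A54 = (
    19372.0 / 6561.0,
    -25360.0 / 2187.0,
    64448.0 / 6561.0,
    -212.0 / 729.0,
)
_A61, _A62, _A63, _A64, _A65 = (
    9017.0 / 3168.0,
    -355.0 / 33.0,
    46732.0 / 5247.0,
    49.0 / 176.0,
    -5103.0 / 18656.0,
)
_B1, _B3, _B4, _B5, _B6 = (
    35.0 / 384.0,
    500.0 / 1113.0,
    125.0 / 192.0,
    -2187.0 / 6784.0,
    11.0 / 84.0,
)
# 5th-order minus embedded 4th-order weights (error estimate).
_E1, _E3, _E4, _E5, _E6, _E7 = (
    71.0 / 57600.0,
    -71.0 / 16695.0,
    71.0 / 1920.0,
    -17253.0 / 339200.0,
    22.0 / 525.0,
    -1.0 / 40.0,
)


@njit(cache=True, inline="always")
def _pvac(ptot, Pvmax, Kvac, m):
    x = ptot / Kvac
    if m == 4.0:
        x2 = x * x
        return Pvmax / (1.0 + x2 * x2)
    return Pvmax / (1.0 + x**m)


@njit(cache=True)
def _rhs(y, dy, N, vmax_up, vmax_lo, k_atp, k_p, vatp_e, h_max, kin,
         u_g, u_d, vatp_m, chemostat, V_ch, D, g0):
    """Coupled RHS; clamps transiently negative concentrations to zero
    before kinetic evaluation."""
    KMg, KMa, Kia, atot, KMf, KMadp, KMp, Pvmax, Kvac, m = (
        kin[0], kin[1], kin[2], kin[3], kin[4],
        kin[5], kin[6], kin[7], kin[8], kin[9],
    )
    glc = y[5 * N]
    if glc < 0.0:
        glc = 0.0
    uptake = 0.0
    for i in range(N):
        F = y[i]
        A = y[N + i]
        P = y[2 * N + i]
        V = y[3 * N + i]
        H = y[4 * N + i]
        if F < 0.0:
            F = 0.0
        if A < 0.0:
            A = 0.0
        if P < 0.0:
            P = 0.0
        adp = atot - A
        if adp < 0.0:
            adp = 0.0
        vu = vmax_up[i] * glc * A / (
            (KMg + glc) * (KMa + A * (1.0 + A / Kia))
        )
        vl = vmax_lo[i] * F * adp * P / (
            (KMf + F) * (KMadp + adp) * (KMp + P)
        )
        va = k_atp[i] * A
        ptot = P + 2.0 * F + A
        pvac = _pvac(ptot, Pvmax, Kvac, m)
        vp = k_p[i] * (pvac - P)
        vg = va - (vatp_e[i] + vatp_m)
        if vg > 0.0 and H >= h_max[i]:
            grow = u_g * vg
        else:
            grow = 0.0
        dy[i] = vu - vl - F * grow
        dy[N + i] = -2.0 * vu + 4.0 * vl - va - A * grow
        dy[2 * N + i] = -2.0 * vl + va + vp - P * grow
        dy[3 * N + i] = grow * V
        if vg <= 0.0:
            dy[4 * N + i] = -u_d * vg
        elif H < h_max[i]:
            dy[4 * N + i] = u_g * vg
        else:
            dy[4 * N + i] = 0.0
        uptake += vu * V
    d_glc = D * (g0 - glc)
    if chemostat:
        d_glc -= uptake / V_ch
    dy[5 * N] = d_glc


@njit(cache=True)
def _error_norm(err, y, ynew, N, atol_c, rtol_c, atol_v, rtol_v, atol_h, rtol_h):
    n = err.size
    acc = 0.0
    for i in range(n):
        if i < 3 * N or i == 5 * N:
            atol, rtol = atol_c, rtol_c
        elif i < 4 * N:
            atol, rtol = atol_v, rtol_v
        else:
            atol, rtol = atol_h, rtol_h
        ya = abs(y[i])
        yb = abs(ynew[i])
        sc = atol + rtol * (ya if ya > yb else yb)
        e = err[i] / sc
        acc += e * e
    return np.sqrt(acc / n)


@njit(cache=True)
def _dopri_interval(
    t0, t1, y,
    vmax_up, vmax_lo, k_atp, k_p, vatp_e, h_max,
    kin, u_g, u_d, vatp_m,
    chemostat, V_ch, D,
    bp_times, bp_values,
    atol_c, rtol_c, atol_v, rtol_v, atol_h, rtol_h,
    sample_times, track_idx, samples_out,
    h0,
):
    n = y.size
    N = (n - 1) // 5
    k1 = np.empty(n)
    k2 = np.empty(n)
    k3 = np.empty(n)
    k4 = np.empty(n)
    k5 = np.empty(n)
    k6 = np.empty(n)
    k7 = np.empty(n)
    ytmp = np.empty(n)
    ynew = np.empty(n)
    err = np.empty(n)

    n_bp = bp_times.size
    n_smp = sample_times.size
    sptr = 0
    bptr = 0
    # position breakpoint pointer at the segment containing t0
    while bptr + 1 < n_bp and bp_times[bptr + 1] <= t0 + 1e-12:
        bptr += 1

    t = t0
    h = h0
    if h <= 0.0:
        h = 1e-2
    h_min_floor = 1e-12
    eps_t = 1e-9
    n_accept = 0
    n_reject = 0

    _rhs(y, k1, N, vmax_up, vmax_lo, k_atp, k_p, vatp_e, h_max, kin,
         u_g, u_d, vatp_m, chemostat, V_ch, D, bp_values[bptr])

    while t < t1 - eps_t:
        # advance breakpoint pointer (supply is constant within a step)
        while bptr + 1 < n_bp and bp_times[bptr + 1] <= t + 1e-12:
            bptr += 1
            # supply changed at this boundary: refresh k1 (FSAL invalidated)
            _rhs(y, k1, N, vmax_up, vmax_lo, k_atp, k_p, vatp_e, h_max, kin,
                 u_g, u_d, vatp_m, chemostat, V_ch, D, bp_values[bptr])
        g0 = bp_values[bptr]
        # next hard stop: schedule switch, sample time, or interval end
        next_stop = t1
        if bptr + 1 < n_bp and bp_times[bptr + 1] < next_stop:
            next_stop = bp_times[bptr + 1]
        if sptr < n_smp and sample_times[sptr] < next_stop:
            next_stop = sample_times[sptr]
        h_use = h
        hit_stop = False
        if h_use >= next_stop - t - eps_t:
            h_use = next_stop - t
            hit_stop = True
        if h_use < h_min_floor:
            return STATUS_STEP_UNDERFLOW, h, -1, n_accept, n_reject

        # Dormand-Prince stages
        for i in range(n):
            ytmp[i] = y[i] + h_use * _A21 * k1[i]
        _rhs(ytmp, k2, N, vmax_up, vmax_lo, k_atp, k_p, vatp_e, h_max, kin,
             u_g, u_d, vatp_m, chemostat, V_ch, D, g0)
        for i in range(n):
            ytmp[i] = y[i] + h_use * (_A31 * k1[i] + _A32 * k2[i])
        _rhs(ytmp, k3, N, vmax_up, vmax_lo, k_atp, k_p, vatp_e, h_max, kin,
             u_g, u_d, vatp_m, chemostat, V_ch, D, g0)
        for i in range(n):
            ytmp[i] = y[i] + h_use * (_A41 * k1[i] + _A42 * k2[i] + _A43 * k3[i])
        _rhs(ytmp, k4, N, vmax_up, vmax_lo, k_atp, k_p, vatp_e, h_max, kin,
             u_g, u_d, vatp_m, chemostat, V_ch, D, g0)
        for i in range(n):
            ytmp[i] = y[i] + h_use * (
                _A51 * k1[i] + _A52 * k2[i] + _A53 * k3[i] + _A54 * k4[i]
            )
        _rhs(ytmp, k5, N, vmax_up, vmax_lo, k_atp, k_p, vatp_e, h_max, kin,
             u_g, u_d, vatp_m, chemostat, V_ch, D, g0)
        for i in range(n):
            ytmp[i] = y[i] + h_use * (
                _A61 * k1[i] + _A62 * k2[i] + _A63 * k3[i]
                + _A64 * k4[i] + _A65 * k5[i]
            )
        _rhs(ytmp, k6, N, vmax_up, vmax_lo, k_atp, k_p, vatp_e, h_max, kin,
             u_g, u_d, vatp_m, chemostat, V_ch, D, g0)
        for i in range(n):
            ynew[i] = y[i] + h_use * (
                _B1 * k1[i] + _B3 * k3[i] + _B4 * k4[i]
                + _B5 * k5[i] + _B6 * k6[i]
            )
        _rhs(ynew, k7, N, vmax_up, vmax_lo, k_atp, k_p, vatp_e, h_max, kin,
             u_g, u_d, vatp_m, chemostat, V_ch, D, g0)
        for i in range(n):
            err[i] = h_use * (
                _E1 * k1[i] + _E3 * k3[i] + _E4 * k4[i]
                + _E5 * k5[i] + _E6 * k6[i] + _E7 * k7[i]
            )
        enorm = _error_norm(err, y, ynew, N,
                            atol_c, rtol_c, atol_v, rtol_v, atol_h, rtol_h)

        if enorm > 1.0:
            n_reject += 1
            fac = 0.9 * enorm ** -0.2
            if fac < 0.2:
                fac = 0.2
            h = h_use * fac
            if h < h_min_floor:
                return STATUS_STEP_UNDERFLOW, h, -1, n_accept, n_reject
            continue

        # non-negativity projection on metabolite components + glucose
        reject_neg = False
        bad = -1
        projected = False
        for i in range(n):
            if i < 3 * N or i == 5 * N:
                c = ynew[i]
                if c < 0.0:
                    if c > -(atol_c + abs(c) * rtol_c):
                        ynew[i] = 0.0
                        projected = True
                    else:
                        reject_neg = True
                        bad = i
                        break
        if reject_neg:
            n_reject += 1
            h = h_use * 0.5
            if h < h_min_floor:
                return STATUS_STEP_UNDERFLOW, h, bad, n_accept, n_reject
            continue

        # accept
        t_new = next_stop if hit_stop else t + h_use
        for i in range(n):
            y[i] = ynew[i]
        if projected:
            _rhs(y, k1, N, vmax_up, vmax_lo, k_atp, k_p, vatp_e, h_max, kin,
                 u_g, u_d, vatp_m, chemostat, V_ch, D, g0)
        else:
            for i in range(n):
                k1[i] = k7[i]
        t = t_new
        # record sample if we landed on one
        if sptr < n_smp and abs(t - sample_times[sptr]) <= eps_t:
            for j in range(track_idx.size):
                ci = track_idx[j]
                samples_out[sptr, j, 0] = y[ci]
                samples_out[sptr, j, 1] = y[N + ci]
                samples_out[sptr, j, 2] = y[2 * N + ci]
                samples_out[sptr, j, 3] = y[3 * N + ci]
                samples_out[sptr, j, 4] = y[4 * N + ci]
                samples_out[sptr, j, 5] = y[5 * N]
            sptr += 1
        # grow/shrink step for next step
        if enorm == 0.0:
            fac = 5.0
        else:
            fac = 0.9 * enorm ** -0.2
            if fac > 5.0:
                fac = 5.0
            elif fac < 0.2:
                fac = 0.2
        h = h_use * fac
        n_accept += 1

    return STATUS_OK, h, -1, n_accept, n_reject


def integrate_population(
    t0: float,
    t1: float,
    y: np.ndarray,
    genotype_arrays: tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray],
    vatp_e: np.ndarray,
    h_max: np.ndarray,
    kin: np.ndarray,
    u_g: float,
    u_d: float,
    vatp_m: float,
    chemostat: bool,
    V_ch: float,
    D: float,
    bp_times: np.ndarray,
    bp_values: np.ndarray,
    tolerances: tuple[float, float, float, float, float, float],
    sample_times: np.ndarray | None = None,
    track_idx: np.ndarray | None = None,
    h0: float = 1e-2,
):
    """Advance the population state ``y`` from t0 to t1 in place.

    Returns ``(status, h_last, samples)`` where ``samples`` has shape
    (n_sample_times, n_tracked, 6) with columns FBP, ATP, Pi, V, H, Glc.
    Raises ``RuntimeError`` naming the offending cell on step-size underflow.
    """
    vmax_up, vmax_lo, k_atp, k_p = genotype_arrays
    atol_c, rtol_c, atol_v, rtol_v, atol_h, rtol_h = tolerances
    if sample_times is None:
        sample_times = np.empty(0)
    if track_idx is None:
        track_idx = np.empty(0, dtype=np.int64)
    samples = np.empty((sample_times.size, track_idx.size, 6))
    status, h_last, bad, n_accept, n_reject = _dopri_interval(
        float(t0), float(t1), y,
        np.ascontiguousarray(vmax_up, dtype=np.float64),
        np.ascontiguousarray(vmax_lo, dtype=np.float64),
        np.ascontiguousarray(k_atp, dtype=np.float64),
        np.ascontiguousarray(k_p, dtype=np.float64),
        np.ascontiguousarray(vatp_e, dtype=np.float64),
        np.ascontiguousarray(h_max, dtype=np.float64),
        np.ascontiguousarray(kin, dtype=np.float64),
        float(u_g), float(u_d), float(vatp_m),
        bool(chemostat), float(V_ch), float(D),
        np.ascontiguousarray(bp_times, dtype=np.float64),
        np.ascontiguousarray(bp_values, dtype=np.float64),
        float(atol_c), float(rtol_c), float(atol_v),
        float(rtol_v), float(atol_h), float(rtol_h),
        np.ascontiguousarray(sample_times, dtype=np.float64),
        np.ascontiguousarray(track_idx, dtype=np.int64),
        samples,
        float(h0),
    )
    if status == STATUS_STEP_UNDERFLOW:
        N = (y.size - 1) // 5
        cell = bad % N if 0 <= bad < 5 * N else -1
        raise RuntimeError(
            f"integration step size underflow at t in [{t0}, {t1}]"
            + (f" (cell index {cell})" if cell >= 0 else "")
        )
    return status, h_last, samples


@njit(cache=True, inline="always")
def _rhs_cell(F, A, P, V, H, glc,
              vmax_up, vmax_lo, k_atp, k_p, vatp_e, h_max,
              kin, u_g, u_d, vatp_m):
    """Single-cell RHS; returns (dF, dA, dP, dV, dH)."""
    KMg, KMa, Kia, atot, KMf, KMadp, KMp, Pvmax, Kvac, m = (
        kin[0], kin[1], kin[2], kin[3], kin[4],
        kin[5], kin[6], kin[7], kin[8], kin[9],
    )
    Fc = F if F > 0.0 else 0.0
    Ac = A if A > 0.0 else 0.0
    Pc = P if P > 0.0 else 0.0
    adp = atot - Ac
    if adp < 0.0:
        adp = 0.0
    vu = vmax_up * glc * Ac / ((KMg + glc) * (KMa + Ac * (1.0 + Ac / Kia)))
    vl = vmax_lo * Fc * adp * Pc / ((KMf + Fc) * (KMadp + adp) * (KMp + Pc))
    va = k_atp * Ac
    ptot = Pc + 2.0 * Fc + Ac
    pvac = _pvac(ptot, Pvmax, Kvac, m)
    vp = k_p * (pvac - Pc)
    vg = va - (vatp_e + vatp_m)
    if vg > 0.0 and H >= h_max:
        grow = u_g * vg
    else:
        grow = 0.0
    dF = vu - vl - Fc * grow
    dA = -2.0 * vu + 4.0 * vl - va - Ac * grow
    dP = -2.0 * vl + va + vp - Pc * grow
    dV = grow * V
    if vg <= 0.0:
        dH = -u_d * vg
    elif H < h_max:
        dH = u_g * vg
    else:
        dH = 0.0
    return dF, dA, dP, dV, dH


@njit(cache=True)
def _dopri_cells_ncg(
    t0, t1, F, A, P, V, H,
    vmax_up, vmax_lo, k_atp, k_p, vatp_e, h_max,
    kin, u_g, u_d, vatp_m,
    D, seg_t, seg_g0, seg_gi,
    atol_c, rtol_c, atol_v, rtol_v, atol_h, rtol_h,
    sample_times, track_pos, samples_out,
    h_cells,
):
    """Per-cell adaptive integration in the NCG limit.

    Cells do not feed back on the chamber, so each cell integrates its own
    5-dimensional system with an individually adapted step size; the chamber
    glucose follows the closed form G(t) = G0 + (G_k - G0) exp(-D (t - t_k))
    within each supply segment (seg_t are the segment start times, seg_g0
    the supply levels, seg_gi the glucose at each segment start).  The same
    non-negativity projection/rejection rule as the coupled stepper applies.
    """
    N = F.size
    n_seg = seg_t.size
    n_smp = sample_times.size
    h_min_floor = 1e-12
    eps_t = 1e-9
    y = np.empty(5)
    ytmp = np.empty(5)
    ynew = np.empty(5)
    err = np.empty(5)
    k1 = np.empty(5)
    k2 = np.empty(5)
    k3 = np.empty(5)
    k4 = np.empty(5)
    k5 = np.empty(5)
    k6 = np.empty(5)
    k7 = np.empty(5)

    for ci in range(N):
        y[0] = F[ci]
        y[1] = A[ci]
        y[2] = P[ci]
        y[3] = V[ci]
        y[4] = H[ci]
        h = h_cells[ci]
        if h <= 0.0:
            h = 1e-2
        t = t0
        sptr = 0
        seg = 0
        while seg + 1 < n_seg and seg_t[seg + 1] <= t + 1e-12:
            seg += 1
        tracked = track_pos[ci] >= 0
        glc = seg_g0[seg] + (seg_gi[seg] - seg_g0[seg]) * np.exp(-D * (t - seg_t[seg]))
        dF, dA, dP, dV, dH = _rhs_cell(
            y[0], y[1], y[2], y[3], y[4], glc,
            vmax_up[ci], vmax_lo[ci], k_atp[ci], k_p[ci], vatp_e[ci], h_max[ci],
            kin, u_g, u_d, vatp_m)
        k1[0], k1[1], k1[2], k1[3], k1[4] = dF, dA, dP, dV, dH

        while t < t1 - eps_t:
            while seg + 1 < n_seg and seg_t[seg + 1] <= t + 1e-12:
                seg += 1
                glc = seg_g0[seg] + (seg_gi[seg] - seg_g0[seg]) * np.exp(
                    -D * (t - seg_t[seg]))
                dF, dA, dP, dV, dH = _rhs_cell(
                    y[0], y[1], y[2], y[3], y[4], glc,
                    vmax_up[ci], vmax_lo[ci], k_atp[ci], k_p[ci],
                    vatp_e[ci], h_max[ci], kin, u_g, u_d, vatp_m)
                k1[0], k1[1], k1[2], k1[3], k1[4] = dF, dA, dP, dV, dH
            next_stop = t1
            if seg + 1 < n_seg and seg_t[seg + 1] < next_stop:
                next_stop = seg_t[seg + 1]
            if tracked:
                while sptr < n_smp and sample_times[sptr] <= t + eps_t:
                    sptr += 1
                if sptr < n_smp and sample_times[sptr] < next_stop:
                    next_stop = sample_times[sptr]
            h_use = h
            hit_stop = False
            if h_use >= next_stop - t - eps_t:
                h_use = next_stop - t
                hit_stop = True
            if h_use < h_min_floor:
                return STATUS_STEP_UNDERFLOW, ci

            # stages (glucose evaluated analytically at stage times)
            c_times = (0.2, 0.3, 0.8, 8.0 / 9.0, 1.0, 1.0)
            for i in range(5):
                ytmp[i] = y[i] + h_use * _A21 * k1[i]
            g_s = seg_g0[seg] + (seg_gi[seg] - seg_g0[seg]) * np.exp(
                -D * (t + c_times[0] * h_use - seg_t[seg]))
            dF, dA, dP, dV, dH = _rhs_cell(
                ytmp[0], ytmp[1], ytmp[2], ytmp[3], ytmp[4], g_s,
                vmax_up[ci], vmax_lo[ci], k_atp[ci], k_p[ci],
                vatp_e[ci], h_max[ci], kin, u_g, u_d, vatp_m)
            k2[0], k2[1], k2[2], k2[3], k2[4] = dF, dA, dP, dV, dH
            for i in range(5):
                ytmp[i] = y[i] + h_use * (_A31 * k1[i] + _A32 * k2[i])
            g_s = seg_g0[seg] + (seg_gi[seg] - seg_g0[seg]) * np.exp(
                -D * (t + c_times[1] * h_use - seg_t[seg]))
            dF, dA, dP, dV, dH = _rhs_cell(
                ytmp[0], ytmp[1], ytmp[2], ytmp[3], ytmp[4], g_s,
                vmax_up[ci], vmax_lo[ci], k_atp[ci], k_p[ci],
                vatp_e[ci], h_max[ci], kin, u_g, u_d, vatp_m)
            k3[0], k3[1], k3[2], k3[3], k3[4] = dF, dA, dP, dV, dH
            for i in range(5):
                ytmp[i] = y[i] + h_use * (_A41 * k1[i] + _A42 * k2[i]
                                          + _A43 * k3[i])
            g_s = seg_g0[seg] + (seg_gi[seg] - seg_g0[seg]) * np.exp(
                -D * (t + c_times[2] * h_use - seg_t[seg]))
            dF, dA, dP, dV, dH = _rhs_cell(
                ytmp[0], ytmp[1], ytmp[2], ytmp[3], ytmp[4], g_s,
                vmax_up[ci], vmax_lo[ci], k_atp[ci], k_p[ci],
                vatp_e[ci], h_max[ci], kin, u_g, u_d, vatp_m)
            k4[0], k4[1], k4[2], k4[3], k4[4] = dF, dA, dP, dV, dH
            for i in range(5):
                ytmp[i] = y[i] + h_use * (_A51 * k1[i] + _A52 * k2[i]
                                          + _A53 * k3[i] + _A54 * k4[i])
            g_s = seg_g0[seg] + (seg_gi[seg] - seg_g0[seg]) * np.exp(
                -D * (t + c_times[3] * h_use - seg_t[seg]))
            dF, dA, dP, dV, dH = _rhs_cell(
                ytmp[0], ytmp[1], ytmp[2], ytmp[3], ytmp[4], g_s,
                vmax_up[ci], vmax_lo[ci], k_atp[ci], k_p[ci],
                vatp_e[ci], h_max[ci], kin, u_g, u_d, vatp_m)
            k5[0], k5[1], k5[2], k5[3], k5[4] = dF, dA, dP, dV, dH
            for i in range(5):
                ytmp[i] = y[i] + h_use * (_A61 * k1[i] + _A62 * k2[i]
                                          + _A63 * k3[i] + _A64 * k4[i]
                                          + _A65 * k5[i])
            g_end = seg_g0[seg] + (seg_gi[seg] - seg_g0[seg]) * np.exp(
                -D * (t + h_use - seg_t[seg]))
            dF, dA, dP, dV, dH = _rhs_cell(
                ytmp[0], ytmp[1], ytmp[2], ytmp[3], ytmp[4], g_end,
                vmax_up[ci], vmax_lo[ci], k_atp[ci], k_p[ci],
                vatp_e[ci], h_max[ci], kin, u_g, u_d, vatp_m)
            k6[0], k6[1], k6[2], k6[3], k6[4] = dF, dA, dP, dV, dH
            for i in range(5):
                ynew[i] = y[i] + h_use * (_B1 * k1[i] + _B3 * k3[i]
                                          + _B4 * k4[i] + _B5 * k5[i]
                                          + _B6 * k6[i])
            dF, dA, dP, dV, dH = _rhs_cell(
                ynew[0], ynew[1], ynew[2], ynew[3], ynew[4], g_end,
                vmax_up[ci], vmax_lo[ci], k_atp[ci], k_p[ci],
                vatp_e[ci], h_max[ci], kin, u_g, u_d, vatp_m)
            k7[0], k7[1], k7[2], k7[3], k7[4] = dF, dA, dP, dV, dH
            for i in range(5):
                err[i] = h_use * (_E1 * k1[i] + _E3 * k3[i] + _E4 * k4[i]
                                  + _E5 * k5[i] + _E6 * k6[i] + _E7 * k7[i])
            acc = 0.0
            for i in range(5):
                if i < 3:
                    atol, rtol = atol_c, rtol_c
                elif i == 3:
                    atol, rtol = atol_v, rtol_v
                else:
                    atol, rtol = atol_h, rtol_h
                ya = abs(y[i])
                yb = abs(ynew[i])
                sc = atol + rtol * (ya if ya > yb else yb)
                e = err[i] / sc
                acc += e * e
            enorm = np.sqrt(acc / 5.0)

            if enorm > 1.0:
                fac = 0.9 * enorm ** -0.2
                if fac < 0.2:
                    fac = 0.2
                h = h_use * fac
                if h < h_min_floor:
                    return STATUS_STEP_UNDERFLOW, ci
                continue

            reject_neg = False
            projected = False
            for i in range(3):
                c = ynew[i]
                if c < 0.0:
                    if c > -(atol_c + abs(c) * rtol_c):
                        ynew[i] = 0.0
                        projected = True
                    else:
                        reject_neg = True
                        break
            if reject_neg:
                h = h_use * 0.5
                if h < h_min_floor:
                    return STATUS_STEP_UNDERFLOW, ci
                continue

            t_new = next_stop if hit_stop else t + h_use
            for i in range(5):
                y[i] = ynew[i]
            glc = seg_g0[seg] + (seg_gi[seg] - seg_g0[seg]) * np.exp(
                -D * (t_new - seg_t[seg]))
            if projected:
                dF, dA, dP, dV, dH = _rhs_cell(
                    y[0], y[1], y[2], y[3], y[4], glc,
                    vmax_up[ci], vmax_lo[ci], k_atp[ci], k_p[ci],
                    vatp_e[ci], h_max[ci], kin, u_g, u_d, vatp_m)
                k1[0], k1[1], k1[2], k1[3], k1[4] = dF, dA, dP, dV, dH
            else:
                for i in range(5):
                    k1[i] = k7[i]
            t = t_new
            if tracked and sptr < n_smp and abs(t - sample_times[sptr]) <= eps_t:
                j = track_pos[ci]
                samples_out[sptr, j, 0] = y[0]
                samples_out[sptr, j, 1] = y[1]
                samples_out[sptr, j, 2] = y[2]
                samples_out[sptr, j, 3] = y[3]
                samples_out[sptr, j, 4] = y[4]
                sptr += 1
            if enorm == 0.0:
                fac = 5.0
            else:
                fac = 0.9 * enorm ** -0.2
                if fac > 5.0:
                    fac = 5.0
                elif fac < 0.2:
                    fac = 0.2
            h = h_use * fac

        F[ci] = y[0]
        A[ci] = y[1]
        P[ci] = y[2]
        V[ci] = y[3]
        H[ci] = y[4]
        h_cells[ci] = h
    return STATUS_OK, -1


def integrate_population_ncg(
    t0: float,
    t1: float,
    pop_arrays,
    vatp_e: np.ndarray,
    h_max: np.ndarray,
    kin: np.ndarray,
    u_g: float,
    u_d: float,
    vatp_m: float,
    D: float,
    glc_start: float,
    bp_times: np.ndarray,
    bp_values: np.ndarray,
    tolerances,
    sample_times: np.ndarray | None = None,
    track_idx: np.ndarray | None = None,
    h_cells: np.ndarray | None = None,
):
    """Advance all cells over [t0, t1] in the NCG limit (per-cell stepping).

    ``pop_arrays`` is (F, A, P, V, H, vmax_up, vmax_lo, k_atp, k_p); state
    arrays are updated in place.  Returns (glc_end, samples) with samples of
    shape (n_samples, n_tracked, 6) including the analytic chamber glucose.
    """
    F, A, P, V, H, vmax_up, vmax_lo, k_atp, k_p = pop_arrays
    atol_c, rtol_c, atol_v, rtol_v, atol_h, rtol_h = tolerances
    if sample_times is None:
        sample_times = np.empty(0)
    if track_idx is None:
        track_idx = np.empty(0, dtype=np.int64)
    n = F.size
    # glucose at the start of each supply segment (closed-form recursion)
    n_seg = bp_times.size
    seg_gi = np.empty(n_seg)
    g = glc_start
    seg_gi[0] = g
    for s in range(1, n_seg):
        dur = bp_times[s] - bp_times[s - 1]
        g = bp_values[s - 1] + (g - bp_values[s - 1]) * np.exp(-D * dur)
        seg_gi[s] = g
    track_pos = np.full(n, -1, dtype=np.int64)
    for j, ci in enumerate(track_idx):
        track_pos[ci] = j
    samples = np.empty((sample_times.size, track_idx.size, 6))
    if h_cells is None:
        h_cells = np.full(n, 1e-2)
    status, bad = _dopri_cells_ncg(
        float(t0), float(t1), F, A, P, V, H,
        np.ascontiguousarray(vmax_up, dtype=np.float64),
        np.ascontiguousarray(vmax_lo, dtype=np.float64),
        np.ascontiguousarray(k_atp, dtype=np.float64),
        np.ascontiguousarray(k_p, dtype=np.float64),
        np.ascontiguousarray(vatp_e, dtype=np.float64),
        np.ascontiguousarray(h_max, dtype=np.float64),
        np.ascontiguousarray(kin, dtype=np.float64),
        float(u_g), float(u_d), float(vatp_m),
        float(D),
        np.ascontiguousarray(bp_times, dtype=np.float64),
        np.ascontiguousarray(bp_values, dtype=np.float64),
        seg_gi,
        float(atol_c), float(rtol_c), float(atol_v),
        float(rtol_v), float(atol_h), float(rtol_h),
        np.ascontiguousarray(sample_times, dtype=np.float64),
        track_pos, samples,
        h_cells,
    )
    if status == STATUS_STEP_UNDERFLOW:
        raise RuntimeError(
            f"integration step size underflow at t in [{t0}, {t1}]"
            f" (cell index {bad})"
        )
    # chamber glucose at sample times and at t1 (analytic)
    if sample_times.size:
        idx = np.searchsorted(bp_times, sample_times, side="right") - 1
        g_smp = bp_values[idx] + (seg_gi[idx] - bp_values[idx]) * np.exp(
            -D * (sample_times - bp_times[idx]))
        samples[:, :, 5] = g_smp[:, None]
    i_last = n_seg - 1
    glc_end = bp_values[i_last] + (seg_gi[i_last] - bp_values[i_last]) * np.exp(
        -D * (t1 - bp_times[i_last]))
    return float(glc_end), samples
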