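"""Compiled fast path for cycle simulation and Monte Carlo batches.

Hand-inlined right-hand side of the PAO model plus an adaptive Cash-Karp
Runge-Kutta(4,5) integrator that lands exactly on the uniform reporting
grid. The math mirrors :mod:`ebpr_gsa.model`'s reference formulation; the
test suite cross-checks the two to 1e-12.

Parameter, constant and state index layouts are fixed by
``model.PARAM_NAMES``, ``model._CONST_KEYS`` and ``model.STATE_NAMES``.
"""

from __future__ import annotations

import numpy as np
from numba import njit, prange

# status codes
OK = 0
STEP_FAILURE = 1
NOT_FINITE = 2

_MAX_STEPS = 2_000_000


@njit(cache=True, inline="always")
def _pos(v):
    return v if v > 0.0 else 0.0


@njit(cache=True)
def _aux(p, c):
    """Per-simulation precomputation: Arrhenius factors and pH yields."""
    aux = np.empty(13)
    dt = p[37] - c[25]
    ph_fac = 1.0 - c[26] * (p[38] - 7.0)
    if ph_fac < 0.05:
        ph_fac = 0.05
    aux[0] = p[21] ** dt * ph_fac  # tc_qVFA incl. kinetic pH factor
    aux[1] = p[22] ** dt          # tc_mATP_an
    aux[2] = p[23] ** dt          # tc_qPHA
    aux[3] = p[24] ** dt          # tc_qGly
    aux[4] = p[25] ** dt          # tc_qPP
    aux[5] = p[26] ** dt          # tc_mATP_ox
    ph = p[38]
    alpha = c[11] + c[12] * (ph - 7.0)
    aux[6] = alpha
    y_gly_hac = c[0]
    aux[7] = y_gly_hac
    aux[8] = 1.0 + y_gly_hac - c[3]             # y_pha_hac
    aux[9] = alpha - c[13] * y_gly_hac          # p_release_hac
    y_gly_hpr = c[1] + c[2] * (ph - 7.0)
    aux[10] = y_gly_hpr
    aux[11] = 1.0 + y_gly_hpr - c[4]            # y_pha_hpr
    aux[12] = alpha - c[13] * y_gly_hpr         # p_release_hpr
    return aux


@njit(cache=True)
def _rhs(y, p, c, aux, aerobic, gate, dy):
    for i in range(11):
        dy[i] = 0.0
    if aerobic:
        dy[0] = c[22] * (c[23] - y[0])
    x = y[4]
    if x <= 0.0:
        return
    phb = _pos(y[5])
    phv = _pos(y[6])
    phm = _pos(y[7])
    pha = phb + phv + phm
    f_pha = pha / x
    f_gly = _pos(y[8]) / x
    f_pp = _pos(y[9]) / x
    if pha > 0.0:
        sb = phb / pha
        sv = phv / pha
        sm = phm / pha
    else:
        sb = 0.0
        sv = 0.0
        sm = 0.0

    # VFA uptake (anaerobic, or aerobic when the gate is open)
    sat_gly = f_gly / (p[8] + f_gly)
    sat_pp = f_pp / (p[10] + f_pp)
    s_hac = _pos(y[1])
    s_hpr = _pos(y[2])
    r0 = p[12] * aux[0] * s_hac / (p[4] + s_hac) * sat_gly * sat_pp * x
    r1 = p[13] * aux[0] * s_hpr / (p[5] + s_hpr) * sat_gly * sat_pp * x
    mon_o2 = 0.0
    if aerobic:
        o2 = _pos(y[0])
        mon_o2 = o2 / (p[11] + o2)
        if gate:
            r0 *= mon_o2
            r1 *= mon_o2
        else:
            r0 = 0.0
            r1 = 0.0
    if r0 > 0.0:
        dy[1] -= r0
        dy[8] -= aux[7] * r0
        dy[5] += aux[8] * c[5] * r0
        dy[6] += aux[8] * c[6] * r0
        dy[7] += aux[8] * c[7] * r0
        dy[10] += c[3] * r0
        dy[9] -= aux[9] * r0
        dy[3] += aux[9] * r0
    if r1 > 0.0:
        dy[2] -= r1
        dy[8] -= aux[10] * r1
        dy[5] += aux[11] * c[8] * r1
        dy[6] += aux[11] * c[9] * r1
        dy[7] += aux[11] * c[10] * r1
        dy[10] += c[4] * r1
        dy[9] -= aux[12] * r1
        dy[3] += aux[12] * r1

    ksw = c[24]
    g_gly = f_gly / (f_gly + ksw)
    g_pp = f_pp / (f_pp + ksw)

    if not aerobic:
        # sequential maintenance: poly-P first, then glycogen -> PHB
        d = p[14] * aux[1] * x
        phi = (1.0 - g_pp) * g_gly
        dy[9] -= d * g_pp
        dy[3] += d * g_pp
        dy[8] -= d * phi / c[13]
        dy[5] += d * phi * c[14] / c[13]
        dy[10] += d * phi * (1.0 - c[14]) / c[13]
        return

    delta = p[2]
    atp_pha = c[15] * delta
    atp_gly = c[17] + c[18] * delta
    sat_pha = f_pha / (p[7] + f_pha)
    cap = p[15] * aux[2] * f_pha / (p[9] + f_pha) * mon_o2 * x
    r_gly = p[16] * aux[3] * sat_pha * mon_o2 * _pos(1.0 - f_gly / p[19]) * x
    s_po4 = _pos(y[3])
    r_pp = (p[17] * aux[4] * s_po4 / (p[6] + s_po4) * sat_pha * mon_o2
            * _pos(1.0 - f_pp / p[20]) * x)
    d = p[18] * aux[5] * x
    g1 = f_pha / (f_pha + ksw)
    phi2 = (1.0 - g1) * g_gly
    phi3 = (1.0 - g1) * (1.0 - g_gly) * g_pp

    c_ox_gly = c[20] / atp_pha
    c_pp = (c[21] + p[3]) / atp_pha
    d_gly = (1.0 + c_ox_gly) * r_gly
    d_pp = c_pp * r_pp
    d_m = g1 / atp_pha * d
    r_gr = _pos(cap - d_gly - d_pp - d_m)
    kw = sb * p[0] + (1.0 - sb) * p[1]
    y_x = 1.0 / (1.0 + kw / atp_pha)

    pha_cons = d_gly + d_pp + d_m + r_gr
    dy[5] -= pha_cons * sb
    dy[6] -= pha_cons * sv
    dy[7] -= pha_cons * sm
    m_gly = d * phi2 / atp_gly
    dy[8] += r_gly - m_gly
    dy[4] += y_x * r_gr
    ox_pha = c_ox_gly * r_gly + d_pp + d_m + (1.0 - y_x) * r_gr
    dy[10] += ox_pha + m_gly
    dy[0] -= c[16] * ox_pha + c[19] * m_gly
    dy[3] += phi3 * d - r_pp
    dy[9] += r_pp - phi3 * d


# Cash-Karp tableau
_B21 = 0.2
_B31, _B32 = 3.0 / 40.0, 9.0 / 40.0
_B41, _B42, _B43 = 0.3, -0.9, 1.2
_B51, _B52, _B53, _B54 = -11.0 / 54.0, 2.5, -70.0 / 27.0, 35.0 / 27.0
_B61, _B62, _B63, _B64, _B65 = (
    1631.0 / 55296.0, 175.0 / 512.0, 575.0 / 13824.0,
    44275.0 / 110592.0, 253.0 / 4096.0,
)
_C1, _C3, _C4, _C6 = 37.0 / 378.0, 250.0 / 621.0, 125.0 / 594.0, 512.0 / 1771.0
_D1 = _C1 - 2825.0 / 27648.0
_D3 = _C3 - 18575.0 / 48384.0
_D4 = _C4 - 13525.0 / 55296.0
_D5 = -277.0 / 14336.0
_D6 = _C6 - 0.25


@njit(cache=True)
def _advance(y, t0, t1, p, c, aux, aerobic, gate, rtol, atol, h_start):
    """Adaptive Cash-Karp steps from t0 to t1 in place; returns (h, steps)."""
    n = 11
    k1 = np.empty(n); k2 = np.empty(n); k3 = np.empty(n)
    k4 = np.empty(n); k5 = np.empty(n); k6 = np.empty(n)
    yt = np.empty(n)
    t = t0
    h = h_start
    steps = 0
    while t < t1 - 1e-14:
        if h > t1 - t:
            h = t1 - t
        steps += 1
        if steps > _MAX_STEPS:
            return -1.0, steps
        _rhs(y, p, c, aux, aerobic, gate, k1)
        for i in range(n):
            yt[i] = y[i] + h * _B21 * k1[i]
        _rhs(yt, p, c, aux, aerobic, gate, k2)
        for i in range(n):
            yt[i] = y[i] + h * (_B31 * k1[i] + _B32 * k2[i])
        _rhs(yt, p, c, aux, aerobic, gate, k3)
        for i in range(n):
            yt[i] = y[i] + h * (_B41 * k1[i] + _B42 * k2[i] + _B43 * k3[i])
        _rhs(yt, p, c, aux, aerobic, gate, k4)
        for i in range(n):
            yt[i] = y[i] + h * (_B51 * k1[i] + _B52 * k2[i] + _B53 * k3[i]
                                + _B54 * k4[i])
        _rhs(yt, p, c, aux, aerobic, gate, k5)
        for i in range(n):
            yt[i] = y[i] + h * (_B61 * k1[i] + _B62 * k2[i] + _B63 * k3[i]
                                + _B64 * k4[i] + _B65 * k5[i])
        _rhs(yt, p, c, aux, aerobic, gate, k6)

        err = 0.0
        ok = True
        for i in range(n):
            ynew = y[i] + h * (_C1 * k1[i] + _C3 * k3[i] + _C4 * k4[i]
                               + _C6 * k6[i])
            if not np.isfinite(ynew):
                ok = False
                break
            eloc = h * (_D1 * k1[i] + _D3 * k3[i] + _D4 * k4[i]
                        + _D5 * k5[i] + _D6 * k6[i])
            sc = atol + rtol * (abs(y[i]) if abs(y[i]) > abs(ynew) else abs(ynew))
            r = abs(eloc) / sc
            if r > err:
                err = r
            yt[i] = ynew
        if ok and err <= 1.0:
            t += h
            for i in range(n):
                y[i] = yt[i]
            fac = 5.0 if err == 0.0 else 0.9 * err ** -0.2
            if fac > 5.0:
                fac = 5.0
            h *= fac
        else:
            if not ok:
                h *= 0.1
            else:
                fac = 0.9 * err ** -0.25
                if fac < 0.1:
                    fac = 0.1
                h *= fac
            if h < 1e-12:
                return -1.0, steps
    return h, steps


@njit(cache=True)
def _initial_state(p):
    y0 = np.zeros(11)
    s_vfa = p[27]
    r = p[28]
    x = p[30]
    y0[1] = s_vfa * r
    y0[2] = s_vfa * (1.0 - r)
    y0[3] = s_vfa * p[29]
    y0[4] = x
    y0[5] = p[32] * x
    y0[6] = p[33] * x
    y0[7] = p[34] * x
    y0[8] = p[35] * x
    y0[9] = p[36] * x
    return y0


@njit(cache=True)
def _integrate(p, c, y0, n_grid, rtol, atol, out):
    """Fill ``out`` (n_grid x 11) with the raw (unclamped) trajectory."""
    aux = _aux(p, c)
    mid = (n_grid - 1) // 2
    dt = 5.0 / (n_grid - 1)
    y = y0.copy()
    for i in range(11):
        out[0, i] = y[i]
    h = 1e-3
    for j in range(1, mid + 1):
        h, _ = _advance(y, (j - 1) * dt, j * dt, p, c, aux, False, False,
                        rtol, atol, h)
        if h < 0.0:
            return STEP_FAILURE
        for i in range(11):
            out[j, i] = y[i]
    gate = not (y[1] + y[2] > 1e-6)
    h = 1e-3
    for j in range(mid + 1, n_grid):
        h, _ = _advance(y, (j - 1) * dt, j * dt, p, c, aux, True, gate,
                        rtol, atol, h)
        if h < 0.0:
            return STEP_FAILURE
        for i in range(11):
            out[j, i] = y[i]
    for j in range(n_grid):
        for i in range(11):
            if not np.isfinite(out[j, i]):
                return NOT_FINITE
    return OK


def integrate_cycle_fast(p, c, y0, n_grid, rtol, atol):
    """Single-cycle entry point; returns (trajectory, status)."""
    out = np.empty((n_grid, 11))
    status = _integrate(
        np.asarray(p, dtype=np.float64), np.asarray(c, dtype=np.float64),
        np.asarray(y0, dtype=np.float64), n_grid, rtol, atol, out
    )
    return out, status


@njit(cache=True, parallel=True)
def batch_trajectories(P, c, n_grid, rtol, atol):
    """All-row trajectories (N x T x 10, clamped) plus per-row status."""
    n = P.shape[0]
    traj = np.full((n, n_grid, 10), np.nan)
    status = np.zeros(n, dtype=np.int64)
    for i in prange(n):
        out = np.empty((n_grid, 11))
        y0 = _initial_state(P[i])
        st = _integrate(P[i], c, y0, n_grid, rtol, atol, out)
        status[i] = st
        if st == OK:
            for j in range(n_grid):
                for k in range(10):
                    traj[i, j, k] = _pos(out[j, k])
    return traj, status


@njit(cache=True, parallel=True)
def batch_cycle_means(P, c, n_grid, rtol, atol):
    """Trapezoidal cycle means (N x 10, clamped trajectories) per row."""
    n = P.shape[0]
    means = np.full((n, 10), np.nan)
    status = np.zeros(n, dtype=np.int64)
    for i in prange(n):
        out = np.empty((n_grid, 11))
        y0 = _initial_state(P[i])
        st = _integrate(P[i], c, y0, n_grid, rtol, atol, out)
        status[i] = st
        if st == OK:
            for k in range(10):
                acc = 0.5 * (_pos(out[0, k]) + _pos(out[n_grid - 1, k]))
                for j in range(1, n_grid - 1):
                    acc += _pos(out[j, k])
                means[i, k] = acc / (n_grid - 1)
    return means, status
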