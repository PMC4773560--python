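"""Compiled numerical core: ODE right-hand side and adaptive RK4 stepping.

Everything here works on flat float64 vectors whose layout is fixed by
:mod:`adrenosim.species` (state) and :mod:`adrenosim.parameters` (kinetic
vector).  The index tables below are baked in at import time; they are
derived from the declarative reaction table so the two cannot drift apart.

The integrator is the classic fourth-order Runge-Kutta scheme with a
rate-controlled variable step: dt = clamp(c / max|rate|, dt_min, dt_max),
where max|rate| is the largest absolute flux or reaction rate (nmol/L/h)
seen at the start of the step.  Segments always land exactly on requested
record times by shortening the final step.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .parameters import PARAM_INDEX
from .species import (
    ENZYMES,
    N_POOLS,
    N_STATE,
    N_STEROIDS,
    POOL_INDEX,
    REACTIONS,
    STEROID_INDEX,
    cell_index,
)

# ---------------------------------------------------------------------------
# Index tables (compile-time constants for the jitted functions)
# ---------------------------------------------------------------------------

I_CHOL = POOL_INDEX["CHOL"]
I_CHOS = POOL_INDEX["CHOS"]
I_CHOC = POOL_INDEX["CHOC"]
I_CHOM = POOL_INDEX["CHOM"]
I_CHON = POOL_INDEX["CHON"]
I_CHOR = POOL_INDEX["CHOR"]
I_OXY = POOL_INDEX["OXY"]

P_KCT = PARAM_INDEX["k_CholesterolTransport"]
P_KCEH = PARAM_INDEX["k_CEH"]
P_KF_MTR = PARAM_INDEX["kf_MTR"]
P_KB_MTR = PARAM_INDEX["kb_MTR"]
P_KF_ACC = PARAM_INDEX["kf_acc"]
P_KB_ACC = PARAM_INDEX["kb_acc"]
P_KF_LOC = PARAM_INDEX["kf_loc"]
P_KB_LOC = PARAM_INDEX["kb_loc"]
P_KOXY = PARAM_INDEX["k_OxysterolSynthesis"]
P_K11B2 = PARAM_INDEX["k_CYP11B2"]

CELL0 = N_POOLS
MED0 = N_POOLS + N_STEROIDS

I_CORTICO_CELL = cell_index("CORTICO")
I_ALDO_CELL = cell_index("ALDO")
A_CYP11B2 = ENZYMES.index("CYP11B2")


def _build_competing_tables():
    """Flatten the competing-substrate reactions into per-enzyme groups."""
    sub, prod, km, vmax, gstart, genz = [], [], [], [], [0], []
    for enzyme in ENZYMES:
        rxns = sorted((r for r in REACTIONS
                       if r.enzyme == enzyme and r.law == "competing"),
                      key=lambda r: r.letter)
        if not rxns:
            continue
        genz.append(ENZYMES.index(enzyme))
        for r in rxns:
            if r.substrate in POOL_INDEX:
                sub.append(POOL_INDEX[r.substrate])
            else:
                sub.append(cell_index(r.substrate))
            prod.append(cell_index(r.product))
            letter = "" if len(rxns) == 1 and enzyme == "CYP11A1" else r.letter
            km.append(PARAM_INDEX[f"Km{letter}_{enzyme}"])
            vmax.append(PARAM_INDEX[f"Vmax{letter}_{enzyme}"])
        gstart.append(len(sub))
    return (np.array(sub, dtype=np.int64), np.array(prod, dtype=np.int64),
            np.array(km, dtype=np.int64), np.array(vmax, dtype=np.int64),
            np.array(gstart, dtype=np.int64), np.array(genz, dtype=np.int64))


_RXN_SUB, _RXN_PROD, _RXN_KM, _RXN_VMAX, _GSTART, _GENZ = _build_competing_tables()
_N_GROUPS = len(_GENZ)

_KDIFF = np.array([PARAM_INDEX[f"kdiff_{s}"] for s in STEROID_INDEX],
                  dtype=np.int64)


# ---------------------------------------------------------------------------
# Right-hand side
# ---------------------------------------------------------------------------


@njit(cache=True)
def rhs(t, y, p, act, geom, dilution, dy):
    """Fill ``dy`` with d(state)/dt; return max absolute flux magnitude.

    ``y``/``dy`` are length-35 state vectors (nmol/L), ``p`` the packed
    kinetic vector, ``act`` the 9 enzyme-activity multipliers, ``geom`` the
    5-vector (N0, gN, v0, gv, Vm).
    """
    for i in range(N_STATE):
        dy[i] = 0.0
    n0, g_n, v0, g_v, vm = geom[0], geom[1], geom[2], geom[3], geom[4]
    vc = n0 * v0 * np.exp((g_n + g_v) * t)  # mL, total intracellular
    maxrate = 0.0

    # medium cholesterol uptake: CHOL (medium) -> CHOC (cell)
    chol = y[I_CHOL] if y[I_CHOL] > 0.0 else 0.0
    r_up = p[P_KCT] * chol                 # nmol/L/h, medium basis
    r_up_cell = r_up * vm / vc             # nmol/L/h, cell basis
    dy[I_CHOL] -= r_up
    dy[I_CHOC] += r_up_cell
    if r_up_cell > maxrate:
        maxrate = r_up_cell

    choc = y[I_CHOC] if y[I_CHOC] > 0.0 else 0.0
    chos = y[I_CHOS] if y[I_CHOS] > 0.0 else 0.0
    chom = y[I_CHOM] if y[I_CHOM] > 0.0 else 0.0
    chor = y[I_CHOR] if y[I_CHOR] > 0.0 else 0.0
    chon = y[I_CHON] if y[I_CHON] > 0.0 else 0.0

    # ester storage CHOC <-> CHOS, hydrolysis CHOS -> CHOC
    r = p[P_KF_ACC] * choc
    dy[I_CHOC] -= r
    dy[I_CHOS] += r
    if r > maxrate:
        maxrate = r
    r = (p[P_KB_ACC] + p[P_KCEH]) * chos
    dy[I_CHOS] -= r
    dy[I_CHOC] += r
    if r > maxrate:
        maxrate = r

    # cytosol <-> mitochondria, then partition toward the remote pool
    r = p[P_KF_MTR] * choc
    dy[I_CHOC] -= r
    dy[I_CHOM] += r
    if r > maxrate:
        maxrate = r
    r = p[P_KB_MTR] * chom
    dy[I_CHOM] -= r
    dy[I_CHOC] += r
    if r > maxrate:
        maxrate = r
    r = p[P_KF_MTR] * chom
    dy[I_CHOM] -= r
    dy[I_CHOR] += r
    if r > maxrate:
        maxrate = r
    r = p[P_KB_MTR] * chor
    dy[I_CHOR] -= r
    dy[I_CHOM] += r
    if r > maxrate:
        maxrate = r

    # StAR-mediated localization CHOR <-> CHON
    r = p[P_KF_LOC] * chor
    dy[I_CHOR] -= r
    dy[I_CHON] += r
    if r > maxrate:
        maxrate = r
    r = p[P_KB_LOC] * chon
    dy[I_CHON] -= r
    dy[I_CHOR] += r
    if r > maxrate:
        maxrate = r

    # oxysterol bypass CHOC -> OXY (irreversible sink)
    r = p[P_KOXY] * choc
    dy[I_CHOC] -= r
    dy[I_OXY] += r
    if r > maxrate:
        maxrate = r

    # competing-substrate enzymatic reactions
    for g in range(_N_GROUPS):
        a = act[_GENZ[g]]
        start, stop = _GSTART[g], _GSTART[g + 1]
        denom = 1.0
        for k in range(start, stop):
            s = y[_RXN_SUB[k]]
            if s > 0.0:
                denom += s / p[_RXN_KM[k]]
        for k in range(start, stop):
            s = y[_RXN_SUB[k]]
            if s <= 0.0:
                continue
            v = a * p[_RXN_VMAX[k]] * (s / p[_RXN_KM[k]]) / denom
            dy[_RXN_SUB[k]] -= v
            dy[_RXN_PROD[k]] += v
            if v > maxrate:
                maxrate = v

    # CYP11B2: CORTICO -> ALDO, first-order
    s = y[I_CORTICO_CELL]
    if s > 0.0:
        v = act[A_CYP11B2] * p[P_K11B2] * s
        dy[I_CORTICO_CELL] -= v
        dy[I_ALDO_CELL] += v
        if v > maxrate:
            maxrate = v

    # passive diffusion of each steroid (clearance kdiff, mL/h)
    for i in range(N_STEROIDS):
        ic = CELL0 + i
        im = MED0 + i
        j = p[_KDIFF[i]] * (y[ic] - y[im])  # nmol/L * mL/h
        rc = j / vc
        rm = j / vm
        dy[ic] -= rc
        dy[im] += rm
        arc = abs(rc)
        if arc > maxrate:
            maxrate = arc

    # dilution of intracellular concentrations by volume growth
    if dilution:
        g_tot = g_n + g_v
        for i in range(1, N_POOLS):  # every pool except medium CHOL
            dy[i] -= g_tot * y[i]
        for i in range(CELL0, MED0):
            dy[i] -= g_tot * y[i]

    return maxrate


# ---------------------------------------------------------------------------
# RK4 stepping
# ---------------------------------------------------------------------------


@njit(cache=True)
def advance(y, p, act, geom, dilution, t0, t1, c, dt_min, dt_max, fixed_dt):
    """Integrate ``y`` in place from t0 to t1.

    ``fixed_dt <= 0`` selects the adaptive rate-controlled step.  Returns
    ``(n_steps, dt_smallest, dt_largest, ok, t_bad)``; ``ok`` is False when a
    non-finite state was produced, at time ``t_bad``.
    """
    n = y.shape[0]
    k1 = np.empty(n)
    k2 = np.empty(n)
    k3 = np.empty(n)
    k4 = np.empty(n)
    ytmp = np.empty(n)
    t = t0
    n_steps = 0
    dt_lo = 1e300
    dt_hi = 0.0
    while t < t1 - 1e-12:
        maxrate = rhs(t, y, p, act, geom, dilution, k1)
        if fixed_dt > 0.0:
            dt = fixed_dt
        elif maxrate <= 0.0:
            dt = dt_max
        else:
            dt = c / maxrate
            if dt < dt_min:
                dt = dt_min
            elif dt > dt_max:
                dt = dt_max
        if t + dt > t1:
            dt = t1 - t
        half = 0.5 * dt
        for i in range(n):
            ytmp[i] = y[i] + half * k1[i]
        rhs(t + half, ytmp, p, act, geom, dilution, k2)
        for i in range(n):
            ytmp[i] = y[i] + half * k2[i]
        rhs(t + half, ytmp, p, act, geom, dilution, k3)
        for i in range(n):
            ytmp[i] = y[i] + dt * k3[i]
        rhs(t + dt, ytmp, p, act, geom, dilution, k4)
        sixth = dt / 6.0
        ok = True
        for i in range(n):
            y[i] += sixth * (k1[i] + 2.0 * k2[i] + 2.0 * k3[i] + k4[i])
            if not np.isfinite(y[i]):
                ok = False
        t += dt
        n_steps += 1
        if dt < dt_lo:
            dt_lo = dt
        if dt > dt_hi:
            dt_hi = dt
        if not ok:
            return n_steps, dt_lo, dt_hi, False, t
    return n_steps, dt_lo, dt_hi, True, t1


@njit(cache=True)
def integrate_record(y0, p, act, geom, dilution, times, c, dt_min, dt_max,
                     fixed_dt):
    """Integrate from times[0], recording the state at every entry of times.

    Returns ``(Y, seg_steps, seg_dt_min, seg_dt_max, ok, t_bad)`` where
    ``Y[j]`` is the state at ``times[j]`` and the ``seg_*`` arrays summarize
    the steps taken inside each inter-record segment.
    """
    n_rec = times.shape[0]
    n = y0.shape[0]
    Y = np.empty((n_rec, n))
    seg_steps = np.zeros(n_rec - 1, dtype=np.int64)
    seg_dt_min = np.zeros(n_rec - 1)
    seg_dt_max = np.zeros(n_rec - 1)
    y = y0.copy()
    Y[0] = y
    for j in range(n_rec - 1):
        ns, lo, hi, ok, t_bad = advance(y, p, act, geom, dilution,
                                        times[j], times[j + 1],
                                        c, dt_min, dt_max, fixed_dt)
        seg_steps[j] = ns
        seg_dt_min[j] = lo
        seg_dt_max[j] = hi
        Y[j + 1] = y
        if not ok:
            return Y, seg_steps, seg_dt_min, seg_dt_max, False, t_bad
    return Y, seg_steps, seg_dt_min, seg_dt_max, True, times[n_rec - 1]


@njit(cache=True)
def final_states_ensemble(Y0, P, ACT, geom, dilution, t1, c, dt_min, dt_max):
    """72-h style batch run: integrate every ensemble member to ``t1``.

    ``Y0`` is (m, n_state); ``P`` (m, n_params) and ``ACT`` (m, 9) give each
    member its own parameters and activities.  Returns the final states and a
    per-member success flag.
    """
    m = Y0.shape[0]
    out = np.empty_like(Y0)
    ok = np.zeros(m, dtype=np.bool_)
    for j in range(m):
        y = Y0[j].copy()
        _, _, _, good, _ = advance(y, P[j], ACT[j], geom, dilution,
                                   0.0, t1, c, dt_min, dt_max, -1.0)
        out[j] = y
        ok[j] = good
    return out, ok
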