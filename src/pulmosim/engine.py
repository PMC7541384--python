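"""Compiled integration kernel.

The circuit ODE is integrated with classical fixed-step 4th-order
Runge-Kutta at the configured step (default 0.0005 s).  Ideal-diode valves
are resolved inside every derivative evaluation from the instantaneous
pressure difference — no event detection; at this step size the switching
error is far below the waveform tolerances of interest.

Domain guards (over-filled systemic vein, saturating-log vessel at its
volume limit) abort the run with a status code identifying the offending
node; the driver attaches the node name and time.

A pure-Python mirror of the derivative computation lives in
:mod:`pulmosim.network` and is held against this kernel in the test-suite.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .topology import (
    LAW_CHAMBER, LAW_LINEAR, LAW_SV, LAW_VC, LAW_SAP, LAW_LOG,
    RLAW_CONST, RLAW_VC, RLAW_SAP, MAXACT,
)

__all__ = ["kernel_pressures", "kernel_deriv", "rk4_run"]

LOG10 = np.log(10.0)
LOG_GUARD = 0.999  # keep in sync with vasculature.LOG_LAW_GUARD


@njit(cache=True)
def kernel_pressures(V, phase, law, nodep, actA, actB, actC, actn, P):
    """Fill P with per-node pressures; return 0 or (node index + 1) on a
    domain violation."""
    nn = V.shape[0]
    for i in range(nn):
        c = law[i]
        if c == LAW_CHAMBER:
            e = nodep[i, 7]  # additive baseline
            o = i * MAXACT
            if nodep[i, 5] == 0.0:  # ventricular form
                b = nodep[i, 6]
                for k in range(actn[i]):
                    x = (b * phase - actC[o + k]) / actB[o + k]
                    e += actA[o + k] * np.exp(-x * x)
            else:  # atrial form
                for k in range(actn[i]):
                    x = (phase - actC[o + k]) / actB[o + k]
                    e += actA[o + k] * np.exp(-0.5 * x * x)
            if e < 0.0:
                e = 0.0
            Pes = nodep[i, 0] * (V[i] - nodep[i, 4])
            Ped = nodep[i, 1] * abs(np.exp(nodep[i, 2] * (V[i] - nodep[i, 3])) - 1.0)
            P[i] = e * Pes + (1.0 - e) * Ped
        elif c == LAW_LINEAR:
            P[i] = V[i] / nodep[i, 0]
        elif c == LAW_SV:
            if V[i] <= 0.0:
                return i + 1
            arg = nodep[i, 1] / V[i] - 0.99
            if arg <= 0.0:
                return i + 1
            P[i] = -nodep[i, 0] * np.log(arg) / LOG10
        elif c == LAW_VC:
            if V[i] <= 0.0:
                return i + 1
            if V[i] >= nodep[i, 4]:
                P[i] = nodep[i, 0] + nodep[i, 1] * (V[i] - nodep[i, 4])
            else:
                P[i] = nodep[i, 2] + nodep[i, 3] * np.exp(V[i] / nodep[i, 5])
        elif c == LAW_SAP:
            x = V[i] - nodep[i, 5]
            if x < 0.0:
                return i + 1
            Pa = nodep[i, 0] * np.log(x / nodep[i, 1] + 1.0) / LOG10
            Pp = nodep[i, 2] * np.exp(nodep[i, 4] * x) + nodep[i, 3] * x * x
            F = nodep[i, 6]
            P[i] = F * Pa + (1.0 - F) * Pp
        else:  # LAW_LOG
            if V[i] >= LOG_GUARD * nodep[i, 1] or V[i] < 0.0:
                return i + 1
            P[i] = -nodep[i, 0] * np.log(1.0 - V[i] / nodep[i, 1])
    return 0


@njit(cache=True)
def kernel_deriv(y, t, T,
                 law, nodep, actA, actB, actC, actn,
                 efrom, eto, evalve, erlaw, erp, eL, eqidx,
                 dy, P, Q):
    """One derivative evaluation: fills dy, P (node pressures) and Q (edge
    flows).  Returns 0, or (node index + 1) on a pressure-law domain error."""
    nn = law.shape[0]
    ne = efrom.shape[0]
    phase = t % T
    st = kernel_pressures(y[:nn], phase, law, nodep, actA, actB, actC, actn, P)
    if st != 0:
        return st
    for i in range(y.shape[0]):
        dy[i] = 0.0
    for e in range(ne):
        u = efrom[e]
        v = eto[e]
        if eqidx[e] >= 0:  # inductive edge: flow is a state
            q = y[nn + eqidx[e]]
            dy[nn + eqidx[e]] = (P[u] - P[v] - erp[e, 0] * q) / eL[e]
        else:
            rl = erlaw[e]
            if rl == RLAW_CONST:
                R = erp[e, 0]
            elif rl == RLAW_VC:
                R = erp[e, 0] * erp[e, 1] / y[u] + erp[e, 2]
            else:  # RLAW_SAP
                ratio = erp[e, 1] / y[u]
                R = erp[e, 0] * (np.exp(4.0 * erp[e, 2]) + ratio * ratio) + erp[e, 3]
            q = (P[u] - P[v]) / R
            if evalve[e] and q < 0.0:
                q = 0.0
        Q[e] = q
        dy[u] -= q
        dy[v] += q
    return 0


@njit(cache=True)
def rk4_run(y, t0, nsteps, dt, T,
            law, nodep, actA, actB, actC, actn,
            efrom, eto, evalve, erlaw, erp, eL, eqidx,
            rec_every, step0, rect, recP, recV, recQ, rc,
            stat_sum, stat_min, stat_max, qint):
    """Advance ``y`` in place by ``nsteps`` RK4 steps from ``t0``.

    Samples (t, P, V, Q) every ``rec_every``-th global step (``step0`` is the
    global index of the first step here) into the rec* buffers starting at
    row ``rc``; accumulates per-node pressure sum/min/max and per-edge flow
    integrals for the cycle.  Returns (status, next record row, t reached).
    """
    nn = law.shape[0]
    ns = y.shape[0]
    dy = np.empty(ns)
    P = np.empty(nn)
    Q = np.empty(efrom.shape[0])
    k1 = np.empty(ns)
    k2 = np.empty(ns)
    k3 = np.empty(ns)
    k4 = np.empty(ns)
    yt = np.empty(ns)

    for s in range(nsteps):
        t = t0 + s * dt
        st = kernel_deriv(y, t, T, law, nodep, actA, actB, actC, actn,
                          efrom, eto, evalve, erlaw, erp, eL, eqidx, k1, P, Q)
        if st != 0:
            return st, rc, t
        if (step0 + s) % rec_every == 0:
            rect[rc] = t
            for i in range(nn):
                recP[rc, i] = P[i]
                recV[rc, i] = y[i]
            for e in range(Q.shape[0]):
                recQ[rc, e] = Q[e]
            rc += 1
        for i in range(nn):
            stat_sum[i] += P[i]
            if P[i] < stat_min[i]:
                stat_min[i] = P[i]
            if P[i] > stat_max[i]:
                stat_max[i] = P[i]
        for e in range(Q.shape[0]):
            qint[e] += Q[e] * dt

        for i in range(ns):
            yt[i] = y[i] + 0.5 * dt * k1[i]
        st = kernel_deriv(yt, t + 0.5 * dt, T, law, nodep, actA, actB, actC, actn,
                          efrom, eto, evalve, erlaw, erp, eL, eqidx, k2, P, Q)
        if st != 0:
            return st, rc, t
        for i in range(ns):
            yt[i] = y[i] + 0.5 * dt * k2[i]
        st = kernel_deriv(yt, t + 0.5 * dt, T, law, nodep, actA, actB, actC, actn,
                          efrom, eto, evalve, erlaw, erp, eL, eqidx, k3, P, Q)
        if st != 0:
            return st, rc, t
        for i in range(ns):
            yt[i] = y[i] + dt * k3[i]
        st = kernel_deriv(yt, t + dt, T, law, nodep, actA, actB, actC, actn,
                          efrom, eto, evalve, erlaw, erp, eL, eqidx, k4, P, Q)
        if st != 0:
            return st, rc, t
        for i in range(ns):
            y[i] += dt * (k1[i] + 2.0 * k2[i] + 2.0 * k3[i] + k4[i]) / 6.0
        if not np.isfinite(y[0]):
            return -1, rc, t
    return 0, rc, t0 + nsteps * dt
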