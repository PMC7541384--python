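"""Closed-loop network integration driver.

The driver advances the circuit cycle by cycle: disease schedules are
applied exactly once per completed cardiac cycle (time-varying parameters
are frozen within a cycle), then the compiled RK4 kernel integrates the
cycle at the fixed step.  Per-cycle pressure statistics feed back into the
schedules (mean pulmonary pressures, mPAP breakpoint detection).

:func:`derivatives` is a deliberately independent pure-Python evaluation of
the same right-hand side, built from the scalar laws in
:mod:`pulmosim.chambers` and :mod:`pulmosim.vasculature`; the tests hold the
compiled kernel against it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from . import engine, vasculature
from .parameters import ScenarioSpec, cycle_phase
from .topology import (
    CompiledModel, MAXACT,
    LAW_CHAMBER, LAW_LINEAR, LAW_SV, LAW_VC, LAW_SAP, LAW_LOG,
    RLAW_CONST, RLAW_VC, RLAW_SAP,
)

__all__ = [
    "IntegrationError",
    "Trajectory",
    "valve_flow",
    "derivatives",
    "integrate",
    "steady_cycle",
]


class IntegrationError(RuntimeError):
    """Integration failure, reporting the simulation time and, when known,
    the circuit node whose pressure law left its domain."""

    def __init__(self, message: str, t: float | None = None, node: str | None = None):
        self.t = t
        self.node = node
        super().__init__(message)


def valve_flow(delta_P: float, R: float) -> float:
    """Flow [ml/s] through an ideal diode in series with a resistance:
    delta_P/R when forward-biased, zero otherwise."""
    if R <= 0.0:
        raise ValueError(f"valve resistance R={R!r} must be > 0")
    return delta_P / R if delta_P > 0.0 else 0.0


# ---------------------------------------------------------------------------
# pure-Python reference right-hand side
# ---------------------------------------------------------------------------

def _node_pressure_py(model: CompiledModel, i: int, V: float, phase: float) -> float:
    from . import chambers

    law = int(model.law[i])
    p = model.nodep[i]
    if law == LAW_CHAMBER:
        sl = model.act_slice(i)
        comps = list(zip(model.actA[sl], model.actB[sl], model.actC[sl]))
        form = chambers.VENTRICULAR if p[5] == 0.0 else chambers.ATRIAL
        e = chambers.activation_sum(phase, comps, form, time_scale=p[6], linear_term=p[7])
        Pes = p[0] * (V - p[4])
        Ped = p[1] * abs(math.exp(p[2] * (V - p[3])) - 1.0)
        return e * Pes + (1.0 - e) * Ped
    if law == LAW_LINEAR:
        return vasculature.linear_pressure(V, p[0])
    if law == LAW_SV:
        return vasculature.systemic_vein_pressure(V, p[0], p[1])
    if law == LAW_VC:
        return vasculature.vena_cava_pressure(V, p[0], p[1], p[2], p[3], p[4], p[5])
    if law == LAW_SAP:
        return vasculature.sap_pressure(V, p[6], p[0], p[1], p[2], p[3], p[4], p[5])
    if law == LAW_LOG:
        return vasculature.log_vessel_pressure(V, p[0], p[1])
    raise ValueError(f"unknown law code {law}")


def node_pressures(model: CompiledModel, y: np.ndarray, t: float) -> np.ndarray:
    """Per-node pressures at state ``y`` and time ``t`` (pure Python)."""
    phase = cycle_phase(t, model.T)
    P = np.empty(model.n_nodes)
    for i in range(model.n_nodes):
        try:
            P[i] = _node_pressure_py(model, i, float(y[i]), phase)
        except ValueError as err:
            raise IntegrationError(
                f"pressure law of node {model.node_names[i]!r} failed at t={t:.4f}: {err}",
                t=t, node=model.node_names[i],
            ) from err
    return P


def _edge_resistance_py(model: CompiledModel, e: int, y: np.ndarray) -> float:
    rl = int(model.erlaw[e])
    p = model.erp[e]
    if rl == RLAW_CONST:
        return float(p[0])
    Vu = float(y[model.efrom[e]])
    if rl == RLAW_VC:
        return vasculature.vena_cava_resistance(Vu, p[0], p[1], p[2])
    return vasculature.sap_resistance(Vu, p[2], p[0], p[1]) + p[3]


def derivatives(model: CompiledModel, y: np.ndarray, t: float) -> np.ndarray:
    """State derivative at (y, t): dV/dt per compartment from the edge-flow
    balance, dQ/dt per inductive edge.  The analytic sum of all volume
    derivatives is zero — the circuit is a closed loop."""
    nn = model.n_nodes
    P = node_pressures(model, y, t)
    dy = np.zeros_like(y)
    for e in range(model.n_edges):
        u, v = int(model.efrom[e]), int(model.eto[e])
        if model.eqidx[e] >= 0:
            q = float(y[nn + model.eqidx[e]])
            dy[nn + model.eqidx[e]] = (P[u] - P[v] - model.erp[e, 0] * q) / model.eL[e]
        else:
            R = _edge_resistance_py(model, e, y)
            dp = P[u] - P[v]
            q = valve_flow(dp, R) if model.evalve[e] else dp / R
        dy[u] -= q
        dy[v] += q
    return dy


def edge_flows(model: CompiledModel, y: np.ndarray, t: float) -> np.ndarray:
    """Instantaneous per-edge flows [ml/s] (pure Python)."""
    nn = model.n_nodes
    P = node_pressures(model, y, t)
    Q = np.empty(model.n_edges)
    for e in range(model.n_edges):
        if model.eqidx[e] >= 0:
            Q[e] = y[nn + model.eqidx[e]]
        else:
            u, v = int(model.efrom[e]), int(model.eto[e])
            dp = P[u] - P[v]
            R = _edge_resistance_py(model, e, y)
            Q[e] = valve_flow(dp, R) if model.evalve[e] else dp / R
    return Q


# ---------------------------------------------------------------------------
# trajectory container
# ---------------------------------------------------------------------------

@dataclass
class Trajectory:
    """Time-indexed record of a run: sampled pressures/volumes/flows plus
    per-cycle statistics and the scenario-parameter snapshots."""

    t: np.ndarray                 # (ns,)
    P: np.ndarray                 # (ns, nn) mmHg
    V: np.ndarray                 # (ns, nn) ml
    Q: np.ndarray                 # (ns, ne) ml/s
    node_names: list[str]
    edge_names: list[str]
    T: float
    dt: float
    total_volume: float
    cycle_start: np.ndarray       # (nc,) start time of each completed cycle
    cycle_mean_P: np.ndarray      # (nc, nn)
    cycle_min_P: np.ndarray       # (nc, nn)
    cycle_max_P: np.ndarray       # (nc, nn)
    cycle_flow_int: np.ndarray    # (nc, ne) ml per cycle
    snapshots: list[dict] = field(default_factory=list)

    @property
    def n_cycles(self) -> int:
        return len(self.cycle_start)

    def node(self, name: str) -> int:
        return self.node_names.index(name)

    def edge(self, name: str) -> int:
        return self.edge_names.index(name)

    def pressure(self, name: str) -> np.ndarray:
        return self.P[:, self.node(name)]

    def volume(self, name: str) -> np.ndarray:
        return self.V[:, self.node(name)]

    def flow(self, name: str) -> np.ndarray:
        return self.Q[:, self.edge(name)]

    def total_volume_series(self) -> np.ndarray:
        return self.V.sum(axis=1)

    def volume_drift(self) -> float:
        """Maximum absolute deviation of the volume sum from the configured
        total [ml] over all samples."""
        return float(np.abs(self.total_volume_series() - self.total_volume).max())

    def cycle_samples(self, cycle: int) -> slice:
        """Sample-index slice covering one completed cycle."""
        t0 = self.cycle_start[cycle]
        t1 = t0 + self.T
        i0 = int(np.searchsorted(self.t, t0 - 1e-12))
        i1 = int(np.searchsorted(self.t, t1 - 1e-12))
        return slice(i0, i1)

    def to_frame(self) -> pd.DataFrame:
        """Tidy per-node series: time_s, node, pressure_mmHg, volume_ml."""
        ns, nn = self.P.shape
        return pd.DataFrame({
            "time_s": np.repeat(self.t, nn),
            "node": np.tile(np.array(self.node_names, dtype=object), ns),
            "pressure_mmHg": self.P.ravel(),
            "volume_ml": self.V.ravel(),
        })

    def flows_frame(self) -> pd.DataFrame:
        ns, ne = self.Q.shape
        return pd.DataFrame({
            "time_s": np.repeat(self.t, ne),
            "edge": np.tile(np.array(self.edge_names, dtype=object), ns),
            "flow_ml_s": self.Q.ravel(),
        })

    def snapshots_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.snapshots)


# ---------------------------------------------------------------------------
# integration drivers
# ---------------------------------------------------------------------------

def _integrate_python(model, n_steps, dt, record_every):
    """Small-problem reference integrator (same RK4 scheme, pure Python)."""
    y = model.y0.copy()
    rec_t, rec_y = [], []
    for s in range(n_steps):
        t = s * dt
        if s % record_every == 0:
            rec_t.append(t)
            rec_y.append(y.copy())
        k1 = derivatives(model, y, t)
        k2 = derivatives(model, y + 0.5 * dt * k1, t + 0.5 * dt)
        k3 = derivatives(model, y + 0.5 * dt * k2, t + 0.5 * dt)
        k4 = derivatives(model, y + dt * k3, t + dt)
        y = y + dt * (k1 + 2 * k2 + 2 * k3 + k4) / 6.0
    rec_t.append(n_steps * dt)
    rec_y.append(y.copy())
    return np.array(rec_t), np.array(rec_y)


def integrate(
    model: CompiledModel,
    spec: ScenarioSpec | None = None,
    schedule: Callable[[CompiledModel, float, int, dict | None], dict] | None = None,
    duration: float | None = None,
    dt: float | None = None,
    record_every: int = 10,
) -> Trajectory:
    """Integrate the circuit over ``duration`` seconds at fixed step ``dt``.

    ``schedule(model, t_boundary, cycle_index, last_cycle_stats)`` is invoked
    exactly once per cardiac-cycle boundary (including t = 0) and may mutate
    the model's constant arrays in place; the snapshot dict it returns is
    recorded.  ``last_cycle_stats`` carries the previous completed cycle's
    per-node pressure mean/min/max (None before the first cycle completes).
    Recording keeps every ``record_every``-th step (sampling interval
    dt * record_every; 2 ms at the default 0.0005 s step).
    """
    if spec is not None:
        duration = duration if duration is not None else spec.duration
        dt = dt if dt is not None else spec.dt
    if duration is None or dt is None or dt <= 0 or duration <= 0:
        raise ValueError("positive duration and dt required")

    T = model.T
    n_total = int(round(duration / dt))
    n_rec = n_total // record_every + 2
    nn, ne = model.n_nodes, model.n_edges

    rect = np.empty(n_rec)
    recP = np.empty((n_rec, nn))
    recV = np.empty((n_rec, nn))
    recQ = np.empty((n_rec, ne))

    y = model.y0.copy()
    rc = 0
    step = 0
    cyc = 0
    cycle_start, means, mins, maxs, qints = [], [], [], [], []
    snapshots: list[dict] = []
    last_stats: dict | None = None

    while step < n_total:
        t0 = step * dt
        next_boundary = int(round((cyc + 1) * T / dt))
        nsteps = min(next_boundary, n_total) - step
        full_cycle = next_boundary <= n_total

        if schedule is not None:
            snap = schedule(model, t0, cyc, last_stats)
            # one snapshot per *completed* cycle; a trailing partial cycle
            # still gets its parameter update but no snapshot row
            if snap and full_cycle:
                snapshots.append({"cycle": cyc, "t": t0, **snap})

        stat_sum = np.zeros(nn)
        stat_min = np.full(nn, np.inf)
        stat_max = np.full(nn, -np.inf)
        qint = np.zeros(ne)
        status, rc, t_end = engine.rk4_run(
            y, t0, nsteps, dt, T,
            model.law, model.nodep, model.actA, model.actB, model.actC, model.actn,
            model.efrom, model.eto, model.evalve, model.erlaw, model.erp,
            model.eL, model.eqidx,
            record_every, step, rect, recP, recV, recQ, rc,
            stat_sum, stat_min, stat_max, qint,
        )
        if status > 0:
            node = model.node_names[status - 1]
            raise IntegrationError(
                f"pressure law of node {node!r} left its domain at t={t_end:.4f} s",
                t=t_end, node=node,
            )
        if status < 0 or not np.all(np.isfinite(y)):
            raise IntegrationError(f"non-finite state at t={t_end:.4f} s", t=t_end)

        if full_cycle:
            cycle_start.append(t0)
            means.append(stat_sum / nsteps)
            mins.append(stat_min)
            maxs.append(stat_max)
            qints.append(qint)
            last_stats = {"mean": means[-1], "min": mins[-1], "max": maxs[-1]}
        step += nsteps
        cyc += 1

    # final state sample
    t_final = n_total * dt
    P_final = node_pressures(model, y, t_final)
    Q_final = edge_flows(model, y, t_final)
    rect[rc], recP[rc], recV[rc], recQ[rc] = t_final, P_final, y[:nn], Q_final
    rc += 1

    return Trajectory(
        t=rect[:rc].copy(), P=recP[:rc].copy(), V=recV[:rc].copy(), Q=recQ[:rc].copy(),
        node_names=list(model.node_names), edge_names=list(model.edge_names),
        T=T, dt=dt, total_volume=model.total_volume,
        cycle_start=np.array(cycle_start),
        cycle_mean_P=np.array(means) if means else np.zeros((0, nn)),
        cycle_min_P=np.array(mins) if mins else np.zeros((0, nn)),
        cycle_max_P=np.array(maxs) if maxs else np.zeros((0, nn)),
        cycle_flow_int=np.array(qints) if qints else np.zeros((0, ne)),
        snapshots=snapshots,
    )


def steady_cycle(trajectory: Trajectory, tolerance: float = 1e-3) -> int:
    """First cycle index after which the per-cycle systolic and diastolic
    pressures change by less than ``tolerance`` (relative) between
    consecutive cycles.  Raises on non-convergence."""
    nc = trajectory.n_cycles
    if nc < 3:
        raise ValueError(f"need >= 3 completed cycles, got {nc}")
    span = np.maximum(np.abs(trajectory.cycle_max_P).max(axis=0), 1.0)
    for c in range(1, nc):
        dmax = np.abs(trajectory.cycle_max_P[c] - trajectory.cycle_max_P[c - 1]) / span
        dmin = np.abs(trajectory.cycle_min_P[c] - trajectory.cycle_min_P[c - 1]) / span
        if max(dmax.max(), dmin.max()) < tolerance:
            return c
    raise IntegrationError(
        f"no steady cycle reached within {nc} cycles at tolerance {tolerance}"
    )
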