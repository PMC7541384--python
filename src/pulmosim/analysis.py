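"""Hemodynamic read-outs: per-cycle pressure summaries, chamber volumes and
derived indices (stroke volume, ejection fraction, cardiac output, mPAP),
pressure-volume loops, and CSV export.

Systolic and diastolic pressures are the per-cycle extrema of the sampled
pressure trace (not valve-timing gated); the mean is the time average over
the cycle.  mPAP is computed from the extrema of the mean of the two
proximal pulmonary artery pressures via mPAP = sPAP/3 + 2*dPAP/3.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .network import Trajectory
from .parameters import mean_pap

__all__ = ["CycleSummary", "summarize_cycles", "summary_frame", "pv_loop",
           "loop_is_simple", "write_outputs"]

CHAMBERS = ("lv", "la", "rv", "ra")


@dataclass
class CycleSummary:
    """Headline hemodynamics of one completed cardiac cycle."""

    cycle: int
    t_start: float
    systolic: dict[str, float]    # per-node max pressure [mmHg]
    diastolic: dict[str, float]   # per-node min pressure [mmHg]
    mean: dict[str, float]        # per-node time-average pressure [mmHg]
    edv: dict[str, float]         # per-chamber max volume [ml]
    esv: dict[str, float]         # per-chamber min volume [ml]
    sv: dict[str, float]          # per-chamber stroke volume [ml]
    ef: dict[str, float]          # per-chamber ejection fraction
    cardiac_output: float         # ml/min, LV stroke volume x heart rate
    mpap: float                   # mmHg
    shunt_volume: float = 0.0     # ml shunted per cycle (VSD runs)


def summarize_cycles(trajectory: Trajectory, T: float | None = None) -> list[CycleSummary]:
    """Per-cycle hemodynamic summaries from a sampled trajectory.

    An incomplete final cycle is dropped (with a warning).  Heart rate is
    60/T, so cardiac output is SV_lv * 60/T [ml/min].
    """
    T = T or trajectory.T
    t_end = trajectory.t[-1]
    n_complete = int(np.floor((t_end + 1e-9) / T))
    if n_complete < trajectory.n_cycles:
        warnings.warn(f"dropping {trajectory.n_cycles - n_complete} incomplete cycle(s)")
    n_complete = min(n_complete, trajectory.n_cycles)
    if n_complete < 1:
        raise ValueError("trajectory spans less than one full cycle")

    hr = 60.0 / T
    names = trajectory.node_names
    chambers = [c for c in CHAMBERS if c in names]
    il = names.index("lpap") if "lpap" in names else None
    ir = names.index("rpap") if "rpap" in names else None
    shunt_idx = trajectory.edge_names.index("shunt") if "shunt" in trajectory.edge_names else None

    out = []
    for c in range(n_complete):
        sl = trajectory.cycle_samples(c)
        P = trajectory.P[sl]
        V = trajectory.V[sl]
        sys_p = {n: float(P[:, i].max()) for i, n in enumerate(names)}
        dia_p = {n: float(P[:, i].min()) for i, n in enumerate(names)}
        mean_p = {n: float(P[:, i].mean()) for i, n in enumerate(names)}
        edv = {n: float(V[:, names.index(n)].max()) for n in chambers}
        esv = {n: float(V[:, names.index(n)].min()) for n in chambers}
        sv = {n: edv[n] - esv[n] for n in chambers}
        ef = {n: sv[n] / edv[n] if edv[n] > 0 else 0.0 for n in chambers}
        if il is not None and ir is not None:
            pa = 0.5 * (P[:, il] + P[:, ir])
            mpap = mean_pap(float(pa.max()), float(pa.min()))
        else:
            mpap = float("nan")
        shunt = (float(trajectory.cycle_flow_int[c, shunt_idx])
                 if shunt_idx is not None and c < len(trajectory.cycle_flow_int) else 0.0)
        out.append(CycleSummary(
            cycle=c, t_start=float(c * T),
            systolic=sys_p, diastolic=dia_p, mean=mean_p,
            edv=edv, esv=esv, sv=sv, ef=ef,
            cardiac_output=sv.get("lv", 0.0) * hr,
            mpap=mpap, shunt_volume=shunt,
        ))
    return out


def summary_frame(summaries: list[CycleSummary],
                  nodes: tuple[str, ...] = ("lv", "la", "rv", "ra", "aop", "lpap", "lpad", "lpv")) -> pd.DataFrame:
    """Flatten summaries into a tidy per-cycle table."""
    rows = []
    for s in summaries:
        row: dict = {"cycle": s.cycle, "t_start": s.t_start,
                     "cardiac_output_ml_min": s.cardiac_output, "mPAP_mmHg": s.mpap,
                     "shunt_ml_per_cycle": s.shunt_volume}
        for n in nodes:
            if n in s.systolic:
                row[f"{n}_sys_mmHg"] = s.systolic[n]
                row[f"{n}_dia_mmHg"] = s.diastolic[n]
                row[f"{n}_mean_mmHg"] = s.mean[n]
        for c in s.edv:
            row[f"{c}_EDV_ml"] = s.edv[c]
            row[f"{c}_ESV_ml"] = s.esv[c]
            row[f"{c}_SV_ml"] = s.sv[c]
            row[f"{c}_EF"] = s.ef[c]
        rows.append(row)
    return pd.DataFrame(rows)


def pv_loop(trajectory: Trajectory, chamber: str, cycle: int,
            closure_tol: float = 0.01) -> tuple[np.ndarray, np.ndarray]:
    """Ordered (V, P) path of one chamber over one completed cycle.

    In a periodic steady state the path closes; a closure gap larger than
    ``closure_tol`` of the volume range raises a warning (the loop is still
    returned — transient cycles are legitimately open).
    """
    if cycle >= trajectory.n_cycles or cycle < 0:
        raise ValueError(f"cycle {cycle} not contained in trajectory "
                         f"({trajectory.n_cycles} completed cycles)")
    sl = trajectory.cycle_samples(cycle)
    i = trajectory.node(chamber)
    V = trajectory.V[sl, i]
    P = trajectory.P[sl, i]
    if len(V) < 2:
        raise ValueError("cycle contains a single sample; cannot form a loop")
    vrange = float(V.max() - V.min())
    gap = float(abs(V[-1] - V[0]))
    if vrange > 0 and gap > closure_tol * vrange:
        warnings.warn(f"open P-V path: closure gap {gap:.3g} ml exceeds "
                      f"{closure_tol:.0%} of the {vrange:.3g} ml volume range")
    return V, P


def loop_is_simple(V: np.ndarray, P: np.ndarray, n_points: int = 150) -> bool:
    """True when the P-V path is a simple (non-self-intersecting) closed
    curve; a figure-eight ("two-loop") atrial path returns False."""
    from shapely.geometry import LineString

    idx = np.linspace(0, len(V) - 1, min(n_points, len(V))).astype(int)
    v, p = V[idx], P[idx]
    # normalize scales so the intersection test is geometry-agnostic
    v = (v - v.min()) / max(np.ptp(v), 1e-12)
    p = (p - p.min()) / max(np.ptp(p), 1e-12)
    ring = np.column_stack([v, p])
    return LineString(np.vstack([ring, ring[:1]])).is_simple


def write_outputs(trajectory: Trajectory, outdir: str | Path,
                  summaries: list[CycleSummary] | None = None) -> dict[str, Path]:
    """Write trajectory, flow, per-cycle summary and parameter-snapshot CSVs.

    Re-running the same configuration byte-reproduces every file (the model
    has no stochastic component).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "trajectory": outdir / "trajectory.csv",
        "flows": outdir / "flows.csv",
        "cycles": outdir / "cycles.csv",
        "snapshots": outdir / "parameter_snapshots.csv",
    }
    trajectory.to_frame().to_csv(paths["trajectory"], index=False)
    trajectory.flows_frame().to_csv(paths["flows"], index=False)
    if summaries is None:
        summaries = summarize_cycles(trajectory)
    summary_frame(summaries).to_csv(paths["cycles"], index=False)
    trajectory.snapshots_frame().to_csv(paths["snapshots"], index=False)
    return paths
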