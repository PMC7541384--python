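"""Disease-progression schedules.

Each scenario is a per-cycle parameter schedule that morphs the normal
circulation into one pulmonary-hypertension etiology.  Disease time t is
identified with simulation time in seconds (the clinical course of months
to years is compressed onto the 700 s run, so every rate coefficient is
per second of simulation time).  Scheduled parameters are frozen within a
cardiac cycle and updated only at cycle boundaries.

Scenarios
---------
dpas  Distal pulmonary artery stenosis: Poiseuille radius shrinkage raises
      the distal arterial resistances, the RC-time decay shrinks their
      compliances, the proximal pulmonary arteries switch to the saturating
      log P-V law, and the right ventricle compensates through a piecewise-
      linear elastance ramp that slows once mPAP crosses 50 mmHg.
lvdd  Left-ventricular diastolic dysfunction: the LV end-diastolic envelope
      stiffens (M_lv, lambda_lv ramps), all six pulmonary compartments turn
      into saturating-log vessels with growing stiffness K(t), pulmonary
      resistances follow the RC-time / pressure-coupled compliance law, the
      left atrium stiffens and acquires a ten-Gaussian activation.
vsd   Ventricular septal defect: an interventricular resistive shunt whose
      resistance collapses as the defect widens, plus pulmonary remodelling
      and a three-Gaussian left-atrial activation with a growing second peak.
ms    Mitral stenosis: the mitral resistance ramps up, the left atrium
      compensates (elastance ramps, three-Gaussian activation with a rising
      baseline term), plus the same class of pulmonary remodelling.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

from . import vasculature
from .chambers import contractility_scale
from .parameters import ParameterSet, mean_pap
from .topology import CompiledModel, LAW_LINEAR, LAW_LOG

__all__ = ["ScheduleState", "Schedule", "make_schedule",
           "DpasSchedule", "LvddSchedule", "VsdSchedule", "MsSchedule"]

_PULMONARY_SIDES = ("r", "l")
#: inflow edge carrying each pulmonary compartment's resistance
#: (inlet-resistance Windkessel convention; the proximal arteries' inlet
#: resistance is in series with the pulmonary valve)
_PULM_EDGES = {
    "rpap": "rv->rpap", "lpap": "rv->lpap",
    "rpad": "rpap->rpad", "lpad": "lpap->lpad",
    "rpv": "rpad->rpv", "lpv": "lpad->lpv",
}
_PULM_CLASS = {"rpap": "p", "lpap": "p", "rpad": "d", "lpad": "d", "rpv": "v", "lpv": "v"}


@dataclass
class ScheduleState:
    """Mutable progression state: the mPAP breakpoint time (distal-stenosis
    case; immutable once set) and the last cycle's cached pressure means."""

    t_c: float | None = None
    last_mpap: float | None = None
    last_mean: dict[str, float] = field(default_factory=dict)


class Schedule:
    """Identity schedule (normal scenario); base class for the disease cases.

    Invoked at every cycle boundary as ``schedule(model, t, cycle, stats)``
    where ``stats`` holds the previous completed cycle's per-node pressure
    mean/min/max arrays.
    """

    scenario = "normal"

    def __init__(self, params: ParameterSet, model: CompiledModel):
        self.params = params
        self.coeff: dict[str, Any] = dict(params.scenarios.get(self.scenario, {}))
        self.state = ScheduleState()
        self.model = model
        self._a = contractility_scale(params.frequencies["F_con"], params.contractility)
        self._normal = {
            "E_es_rv": params.chambers["rv"]["E_es"],
            "E_es_la": params.chambers["la"]["E_es"],
            "M_la": params.chambers["la"]["M_0"],
            "lambda_la": params.chambers["la"]["lambda_"],
            "M_lv": params.chambers["lv"]["M_0"],
            "lambda_lv": params.chambers["lv"]["lambda_"],
        }

    # -- helpers -------------------------------------------------------------
    def _ingest(self, model: CompiledModel, stats: dict | None) -> None:
        if stats is None:
            return
        mean = stats["mean"]
        self.state.last_mean = {n: float(mean[i]) for i, n in enumerate(model.node_names)}
        il, ir = model.node_index["lpap"], model.node_index["rpap"]
        spap = 0.5 * (stats["max"][il] + stats["max"][ir])
        dpap = 0.5 * (stats["min"][il] + stats["min"][ir])
        self.state.last_mpap = mean_pap(spap, dpap)

    def _switch_to_log(self, model: CompiledModel, node: str, K0: float, Vm: float) -> None:
        i = model.node_index[node]
        model.law[i] = LAW_LOG
        model.nodep[i, :] = 0.0
        model.nodep[i, 0] = K0
        model.nodep[i, 1] = Vm

    def _set_rv_elastance(self, model: CompiledModel, E_rv: float) -> None:
        model.nodep[model.node_index["rv"], 0] = self._a * E_rv

    def _pulmonary_R_update(self, model: CompiledModel, t: float, prefix: str) -> dict:
        """Pressure-coupled pulmonary resistance law shared by the left-heart
        and shunt cases: R_x = tau_x(t) / (g_c * exp(-h_c * P_m_x)) with the
        previous cycle's mean compartment pressure P_m_x.  Resistances keep
        their normal values until a first cycle of pressure statistics
        exists."""
        c = self.coeff
        out = {}
        if not self.state.last_mean:
            return out
        for node, edge in _PULM_EDGES.items():
            klass = _PULM_CLASS[node]
            g = c[f"g_c{klass}{prefix}"]
            h = c[f"h_c{klass}{prefix}"]
            tau0 = c[f"tau_{node}_0"]
            sigma = c[f"sigma_{node}"]
            tau = vasculature.rc_time(t, tau0, sigma)
            P_m = self.state.last_mean[node]
            C = vasculature.compliance_from_mpap(P_m, g, h)
            R = vasculature.resistance_from_rc(tau, C)
            model.set_edge_R(edge, R)
            out[f"R_{node}"] = R
        return out

    def _pulmonary_K_update(self, model: CompiledModel, t: float,
                            k_p: float, k_d: float, k_v: float) -> dict:
        """Grow the saturating-log stiffness constants K(t) linearly, clamped
        to the published admissible intervals."""
        c = self.coeff
        rates = {"p": k_p, "d": k_d, "v": k_v}
        lo_hi = {"p": c.get("K_pap_range", (19.0, 56.0)),
                 "d": c.get("K_pad_range", (14.0, 49.0)),
                 "v": c.get("K_pv_range", (4.0, 37.0))}
        out = {}
        for node in _PULM_EDGES:
            klass = _PULM_CLASS[node]
            K0 = c[f"K_{node}_0"]
            lo, hi = lo_hi[klass]
            K = float(np.clip(K0 + rates[klass] * t, lo, hi))
            model.nodep[model.node_index[node], 0] = K
            out[f"K_{node}"] = K
        return out

    # -- the per-cycle event -------------------------------------------------
    def __call__(self, model: CompiledModel, t: float, cycle: int,
                 stats: dict | None = None) -> dict:
        self._ingest(model, stats)
        return self.update(model, t, cycle)

    def update(self, model: CompiledModel, t: float, cycle: int) -> dict:
        return {}


class DpasSchedule(Schedule):
    scenario = "dpas"

    def update(self, model: CompiledModel, t: float, cycle: int) -> dict:
        c = self.coeff
        if cycle == 0:
            for side in _PULMONARY_SIDES:
                self._switch_to_log(model, f"{side}pap",
                                    c[f"K_{side}pap_0"], c[f"V_m_{side}pap"])
        r0, g_r = c["r_0"], c["g_r"]
        tau0, sigma = c["tau_0"], c["sigma"]
        snap = {}
        for side in _PULMONARY_SIDES:
            R0 = c[f"R_{side}pad_0"]
            R = vasculature.stenosed_resistance(t, R0, r0, g_r)
            C = vasculature.stenosed_compliance(t, R0, tau0, sigma, r0, g_r)
            model.set_edge_R(_PULM_EDGES[f"{side}pad"], R)
            i = model.node_index[f"{side}pad"]
            model.law[i] = LAW_LINEAR
            model.nodep[i, 0] = C
            snap[f"R_{side}pad"] = R
            snap[f"C_{side}pad"] = C

        bp = c.get("mpap_breakpoint", 50.0)
        if (self.state.t_c is None and self.state.last_mpap is not None
                and self.state.last_mpap >= bp):
            self.state.t_c = t
        E0, k1, k2 = c["E_es_rv_0"], c["k_1"], c["k_2"]
        if self.state.t_c is None:
            E_rv = E0 + k1 * t
        else:
            E_rv = E0 + k1 * self.state.t_c + k2 * (t - self.state.t_c)
        self._set_rv_elastance(model, E_rv)
        snap.update(E_es_rv=E_rv, mpap=self.state.last_mpap, t_c=self.state.t_c)
        return snap


class LvddSchedule(Schedule):
    scenario = "lvdd"

    def update(self, model: CompiledModel, t: float, cycle: int) -> dict:
        c = self.coeff
        n = self._normal
        if cycle == 0:
            for node in _PULM_EDGES:
                self._switch_to_log(model, node, c[f"K_{node}_0"], c[f"V_m_{node}"])

        ilv = model.node_index["lv"]
        M_lv = n["M_lv"] + c["k_3"] * t
        lam_lv = n["lambda_lv"] + c["k_4"] * t
        model.nodep[ilv, 1] = M_lv
        model.nodep[ilv, 2] = lam_lv

        snap = {"M_lv": M_lv, "lambda_lv": lam_lv}
        snap.update(self._pulmonary_K_update(model, t, c["k_5"], c["k_6"], c["k_7"]))
        snap.update(self._pulmonary_R_update(model, t, "l"))

        E_rv = c.get("E_es_rv_0", n["E_es_rv"]) + c["k_8"] * t
        self._set_rv_elastance(model, E_rv)

        ila = model.node_index["la"]
        E_la = n["E_es_la"] + c["k_9"] * t
        M_la = n["M_la"] + c["k_10"] * t
        lam_la = n["lambda_la"] + c["k_11"] * t
        model.nodep[ila, 0] = E_la
        model.nodep[ila, 1] = M_la
        model.nodep[ila, 2] = lam_la

        a0 = np.asarray(c["a_0"], dtype=float)
        ka = np.asarray(c["k_a"], dtype=float)
        amps = np.maximum(a0 + ka * t, 0.0)
        model.set_activation("la", amps, c["b"], c["c"])

        snap.update(E_es_rv=E_rv, E_es_la=E_la, M_la=M_la, lambda_la=lam_la,
                    a_3=float(amps[2]))
        return snap


class VsdSchedule(Schedule):
    scenario = "vsd"

    def update(self, model: CompiledModel, t: float, cycle: int) -> dict:
        c = self.coeff
        n = self._normal
        if cycle == 0:
            for node in _PULM_EDGES:
                self._switch_to_log(model, node, c[f"K_{node}_0"], c[f"V_m_{node}"])

        R_ltor = c["R_ltor_0"] / (1.0 + c["k_r"] * t) ** 2
        model.set_edge_R("shunt", R_ltor)

        snap = {"R_ltor": R_ltor}
        snap.update(self._pulmonary_K_update(model, t, c["k_vsd_p"], c["k_vsd_d"], c["k_vsd_v"]))
        snap.update(self._pulmonary_R_update(model, t, "v"))

        E_rv = c.get("E_es_rv_0", n["E_es_rv"]) + c["k_rv_v"] * t
        self._set_rv_elastance(model, E_rv)
        E_la = n["E_es_la"] + c["k_la_v"] * t
        model.nodep[model.node_index["la"], 0] = E_la

        a0 = np.asarray(c["alpha_0"], dtype=float)
        amps = np.maximum(a0 + np.array([0.0, c["k_alpha2"], c["k_alpha3"]]) * t, 0.0)
        model.set_activation("la", amps, c["beta"], c["omega"])

        snap.update(E_es_rv=E_rv, E_es_la=E_la,
                    alpha_2=float(amps[1]), alpha_3=float(amps[2]))
        return snap


class MsSchedule(Schedule):
    scenario = "ms"

    def update(self, model: CompiledModel, t: float, cycle: int) -> dict:
        c = self.coeff
        n = self._normal
        if cycle == 0:
            for node in _PULM_EDGES:
                self._switch_to_log(model, node, c[f"K_{node}_0"], c[f"V_m_{node}"])

        R_m = c["R_m_0"] + c["k_12"] * t
        model.set_edge_R("la->lv", R_m)

        snap = {"R_m": R_m}
        snap.update(self._pulmonary_K_update(model, t, c["k_ms_p"], c["k_ms_d"], c["k_ms_v"]))
        snap.update(self._pulmonary_R_update(model, t, "m"))

        E_rv = c.get("E_es_rv_0", n["E_es_rv"]) + c["k_rv_m"] * t
        self._set_rv_elastance(model, E_rv)

        ila = model.node_index["la"]
        E_la = n["E_es_la"] + c["k_13"] * t
        M_la = n["M_la"] + c["k_14"] * t
        lam_la = n["lambda_la"] + c["k_15"] * t
        model.nodep[ila, 0] = E_la
        model.nodep[ila, 1] = M_la
        model.nodep[ila, 2] = lam_la

        X0 = np.asarray(c["X_0"], dtype=float)
        rates = np.array([-c["k_x1"], c["k_x2"], c["k_x3"]])
        amps = np.maximum(X0 + rates * t, 0.0)
        model.set_activation("la", amps, c["Y"], c["Z"])
        # rising baseline of the activation (constant within a cycle)
        model.nodep[ila, 7] = c["k_x1"] * t

        snap.update(E_es_rv=E_rv, E_es_la=E_la, M_la=M_la, lambda_la=lam_la,
                    X_1=float(amps[0]), X_2=float(amps[1]), X_3=float(amps[2]),
                    baseline=c["k_x1"] * t)
        return snap


_SCHEDULES = {cls.scenario: cls for cls in (Schedule, DpasSchedule, LvddSchedule,
                                            VsdSchedule, MsSchedule)}


def make_schedule(scenario: str, params: ParameterSet, model: CompiledModel) -> Schedule:
    """Instantiate the schedule for a scenario id (identity for 'normal')."""
    try:
        cls = _SCHEDULES[scenario]
    except KeyError:
        raise ValueError(f"unknown scenario {scenario!r}; expected one of {sorted(_SCHEDULES)}")
    return cls(params, model)
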