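"""Circuit assembly: from a validated :class:`ParameterSet` to the flat
array representation the integration engine consumes.

The state vector is ``[volumes of all capacitive compartments, flows of all
inductive edges]``.  Node order follows the configuration file (chambers
first, then vessels); edge order follows the configured edge list.  Both
orderings are fixed at build time so trajectories are bit-reproducible.

The wiring of the peripheral systemic branches (head/arm/limb arteries and
their veins) is recoverable from the published circuit figure only in part;
the assumed wiring lives entirely in the shipped configuration's edge list
and can be rewired there without touching the solver.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .chambers import time_scale
from .parameters import ParameterSet

__all__ = ["CompiledModel", "build_model", "LAW_CODES", "RLAW_CODES", "MAXACT"]

# node pressure-law codes
LAW_CHAMBER = 0
LAW_LINEAR = 1
LAW_SV = 2
LAW_VC = 3
LAW_SAP = 4
LAW_LOG = 5

LAW_CODES = {
    "chamber": LAW_CHAMBER,
    "linear": LAW_LINEAR,
    "sv_log10": LAW_SV,
    "vc_piecewise": LAW_VC,
    "sap_blend": LAW_SAP,
    "log_saturating": LAW_LOG,
}

# edge resistance-law codes
RLAW_CONST = 0
RLAW_VC = 1
RLAW_SAP = 2

RLAW_CODES = {"constant": RLAW_CONST, "vc_volume": RLAW_VC, "sap_volume": RLAW_SAP}

#: activation-component capacity reserved per chamber (the largest published
#: disease schedule uses ten Gaussians)
MAXACT = 10

NODEP_WIDTH = 8
ERP_WIDTH = 4


@dataclass
class CompiledModel:
    """Flat-array circuit ready for integration.

    Mutable by design: the per-cycle disease schedules rewrite entries of
    ``nodep`` / ``erp`` / activation buffers between cardiac cycles.
    """

    node_names: list[str]
    edge_names: list[str]
    law: np.ndarray          # (nn,) int32 pressure-law code per node
    nodep: np.ndarray        # (nn, 8) float64 law constants per node
    actA: np.ndarray         # (nn*MAXACT,) activation amplitudes
    actB: np.ndarray         # (nn*MAXACT,) activation widths [s]
    actC: np.ndarray         # (nn*MAXACT,) activation centers [s]
    actn: np.ndarray         # (nn,) int32 active component count
    efrom: np.ndarray        # (ne,) int32 upstream node
    eto: np.ndarray          # (ne,) int32 downstream node
    evalve: np.ndarray       # (ne,) bool ideal diode in series
    erlaw: np.ndarray        # (ne,) int32 resistance-law code
    erp: np.ndarray          # (ne, 4) float64 resistance constants
    eL: np.ndarray           # (ne,) float64 inertance (0 => resistive edge)
    eqidx: np.ndarray        # (ne,) int32 index into flow states, -1 if none
    y0: np.ndarray           # initial state [V..., q...]
    T: float
    total_volume: float
    node_index: dict[str, int] = field(default_factory=dict)
    edge_index: dict[str, int] = field(default_factory=dict)

    @property
    def n_nodes(self) -> int:
        return len(self.node_names)

    @property
    def n_edges(self) -> int:
        return len(self.edge_names)

    @property
    def n_flows(self) -> int:
        return int((self.eqidx >= 0).sum())

    def act_slice(self, node: str | int) -> slice:
        i = node if isinstance(node, int) else self.node_index[node]
        return slice(i * MAXACT, i * MAXACT + int(self.actn[i]))

    def set_activation(self, node: str | int, A, B, C) -> None:
        """Replace a chamber's activation component table."""
        i = node if isinstance(node, int) else self.node_index[node]
        A, B, C = (np.asarray(x, dtype=float) for x in (A, B, C))
        if len(A) > MAXACT:
            raise ValueError(f"at most {MAXACT} activation components supported")
        o = i * MAXACT
        self.actA[o : o + len(A)] = A
        self.actB[o : o + len(A)] = B
        self.actC[o : o + len(A)] = C
        self.actn[i] = len(A)

    def set_edge_R(self, name: str, R: float) -> None:
        e = self.edge_index[name]
        self.erlaw[e] = RLAW_CONST
        self.erp[e, 0] = R

    def copy(self) -> "CompiledModel":
        return CompiledModel(
            node_names=list(self.node_names),
            edge_names=list(self.edge_names),
            law=self.law.copy(), nodep=self.nodep.copy(),
            actA=self.actA.copy(), actB=self.actB.copy(), actC=self.actC.copy(),
            actn=self.actn.copy(),
            efrom=self.efrom.copy(), eto=self.eto.copy(), evalve=self.evalve.copy(),
            erlaw=self.erlaw.copy(), erp=self.erp.copy(), eL=self.eL.copy(),
            eqidx=self.eqidx.copy(), y0=self.y0.copy(),
            T=self.T, total_volume=self.total_volume,
            node_index=dict(self.node_index), edge_index=dict(self.edge_index),
        )


def _chamber_row(name: str, blk: dict[str, Any], params: ParameterSet) -> tuple[np.ndarray, list]:
    from .chambers import contractility_scale  # local import to avoid cycle at module load

    row = np.zeros(NODEP_WIDTH)
    form = blk.get("form", "ventricular" if name in ("lv", "rv") else "atrial")
    F_con = params.frequencies["F_con"]
    a = contractility_scale(F_con, params.contractility) if form == "ventricular" else 1.0
    row[0] = a * blk["E_es"]
    row[1] = blk["M_0"]
    row[2] = blk["lambda_"]
    row[3] = blk["V_0"]
    row[4] = blk["V_d"]
    row[5] = 0.0 if form == "ventricular" else 1.0
    row[6] = time_scale(F_con, params.contractility) if form == "ventricular" else 1.0
    row[7] = 0.0  # additive activation baseline (mitral-stenosis schedule)
    return row, [tuple(c) for c in blk["activation"]]


def _vessel_row(name: str, blk: dict[str, Any]) -> tuple[int, np.ndarray]:
    law = blk.get("law", "linear")
    row = np.zeros(NODEP_WIDTH)
    if law == "linear":
        row[0] = blk["C"]
    elif law == "sv_log10":
        row[0] = blk.get("K_v", 40.0)
        row[1] = blk.get("V_max", 3500.0)
    elif law == "vc_piecewise":
        row[:6] = [
            blk.get("N_1", 0.0), blk.get("K_1", 0.15), blk.get("N_2", -5.0),
            blk.get("K_2", 0.4), blk.get("V_vc_0", 130.0), blk.get("V_vc_min", 50.0),
        ]
    elif law == "sap_blend":
        row[:6] = [
            blk.get("K_c", 1000.0), blk.get("N_0", 50.0), blk.get("K_p1", 0.03),
            blk.get("K_p2", 0.2), blk.get("tau_aop", 0.1), blk.get("V_min", 210.0),
        ]
        row[6] = blk["F_vaso"]
    elif law == "log_saturating":
        row[0] = blk["K"]
        row[1] = blk["V_m"]
    else:
        raise ValueError(f"vessels.{name}: unknown law {law!r}")
    return LAW_CODES[law], row


def build_model(params: ParameterSet, scenario: str = "normal") -> CompiledModel:
    """Compile a parameter set into the flat circuit representation.

    ``scenario='vsd'`` adds the interventricular shunt branch (a plain
    resistor between the two ventricles) at its initial, near-blocking
    resistance; every other scenario uses the normal topology and morphs
    constants per cycle through its schedule.
    """
    node_names = params.node_names
    node_index = {n: i for i, n in enumerate(node_names)}
    nn = len(node_names)

    law = np.zeros(nn, dtype=np.int32)
    nodep = np.zeros((nn, NODEP_WIDTH))
    actA = np.zeros(nn * MAXACT)
    actB = np.ones(nn * MAXACT)
    actC = np.zeros(nn * MAXACT)
    actn = np.zeros(nn, dtype=np.int32)

    F_vaso = params.frequencies["F_vaso"]
    for name, blk in params.chambers.items():
        i = node_index[name]
        law[i] = LAW_CHAMBER
        row, comps = _chamber_row(name, blk, params)
        nodep[i] = row
        o = i * MAXACT
        for k, (A, B, C) in enumerate(comps):
            actA[o + k], actB[o + k], actC[o + k] = A, B, C
        actn[i] = len(comps)
    for name, blk in params.vessels.items():
        i = node_index[name]
        if blk.get("law") == "sap_blend":
            blk = {**blk, "F_vaso": F_vaso}
        law[i], nodep[i] = _vessel_row(name, blk)

    edges = [dict(e) for e in params.edges]
    if scenario == "vsd":
        R0 = float(params.scenarios.get("vsd", {}).get("R_ltor_0", 100.0))
        edges.append({"from": "lv", "to": "rv", "R": R0, "name": "shunt"})

    ne = len(edges)
    efrom = np.zeros(ne, dtype=np.int32)
    eto = np.zeros(ne, dtype=np.int32)
    evalve = np.zeros(ne, dtype=bool)
    erlaw = np.zeros(ne, dtype=np.int32)
    erp = np.zeros((ne, ERP_WIDTH))
    eL = np.zeros(ne)
    eqidx = np.full(ne, -1, dtype=np.int32)
    edge_names = []
    nq = 0
    for j, e in enumerate(edges):
        efrom[j] = node_index[e["from"]]
        eto[j] = node_index[e["to"]]
        edge_names.append(e.get("name", f"{e['from']}->{e['to']}"))
        evalve[j] = bool(e.get("valve", False))
        rlaw = e.get("R_law", "constant")
        erlaw[j] = RLAW_CODES[rlaw]
        if rlaw == "constant":
            erp[j, 0] = e["R"]
        elif rlaw == "vc_volume":
            erp[j, :3] = [e.get("K_R", 0.001), e.get("V_max", 350.0), e.get("R_0", 0.025)]
        elif rlaw == "sap_volume":
            erp[j, :4] = [e.get("K_r", 0.04), e.get("V_max", 250.0), F_vaso, e.get("R_extra", 0.0)]
        L = float(e.get("L", 0.0))
        if L > 0.0:
            if evalve[j]:
                raise ValueError(f"edge {edge_names[-1]}: valve edges must be resistive")
            eL[j] = L
            eqidx[j] = nq
            nq += 1

    y0 = np.zeros(nn + nq)
    vols = params.initial_volumes()
    for name, i in node_index.items():
        y0[i] = vols[name]
    for j, e in enumerate(edges):
        if eqidx[j] >= 0:
            y0[nn + eqidx[j]] = float(e.get("Q_init", 0.0))

    return CompiledModel(
        node_names=node_names, edge_names=edge_names,
        law=law, nodep=nodep, actA=actA, actB=actB, actC=actC, actn=actn,
        efrom=efrom, eto=eto, evalve=evalve, erlaw=erlaw, erp=erp, eL=eL,
        eqidx=eqidx, y0=y0, T=params.cycle_duration,
        total_volume=params.total_blood_volume,
        node_index=node_index,
        edge_index={n: j for j, n in enumerate(edge_names)},
    )
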