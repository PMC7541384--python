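"""Time-varying elastance models for the four heart chambers.

Each chamber blends an end-systolic pressure-volume relation (ESPVR, linear
with slope a*E_es) and an end-diastolic relation (EDPVR, exponential) through
a periodic activation function e(t) in [0, 1] built from a sum of Gaussians:

    P(V, t) = e(t) * P_ES(V) + (1 - e(t)) * P_ED(V)

Ventricles use the form exp[-((b*phase - C_i)/B_i)^2] where the time-scale
factor b(F_con) shortens systole with rising sympathetic tone; atria use
exp[-0.5*((phase - C_i)/B_i)^2] with unit time scale.  The two exponent
conventions differ deliberately: each is implemented exactly as published
(the ventricular form lacks the 0.5 factor).  The disease schedules reuse
this machinery with longer component lists and an optional additive
baseline term (mitral-stenosis left atrium).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .parameters import ContractilityConstants

__all__ = [
    "ActivationComponent",
    "ChamberParams",
    "VENTRICULAR",
    "ATRIAL",
    "activation_sum",
    "contractility_scale",
    "time_scale",
    "espvr_pressure",
    "edpvr_pressure",
    "chamber_pressure",
]

#: activation form tags
VENTRICULAR = "ventricular"
ATRIAL = "atrial"


@dataclass(frozen=True)
class ActivationComponent:
    """One Gaussian component of an activation function: amplitude A
    (dimensionless, may be time-scheduled by the disease models), width B [s],
    center C [s]."""

    A: float
    B: float
    C: float

    def __post_init__(self):
        if self.B <= 0:
            raise ValueError(f"activation width B={self.B!r} must be > 0")


@dataclass
class ChamberParams:
    """Elastance-law constants for one chamber.

    E_es [mmHg/ml] end-systolic elastance; M_0 [mmHg] and lambda_ [1/ml]
    shape the EDPVR exponential; V_0 [ml] its volume intercept; V_d [ml]
    the ESPVR volume intercept.  ``form`` selects the activation convention.
    """

    name: str
    E_es: float
    M_0: float
    lambda_: float
    V_0: float
    V_d: float
    activation: list[ActivationComponent] = field(default_factory=list)
    form: str = VENTRICULAR

    def __post_init__(self):
        if self.E_es <= 0:
            raise ValueError(f"E_es={self.E_es!r} must be > 0")
        if self.lambda_ <= 0:
            raise ValueError(f"lambda={self.lambda_!r} must be > 0")
        if self.M_0 < 0 or self.V_0 < 0 or self.V_d < 0:
            raise ValueError("M_0, V_0, V_d must be >= 0")
        if self.form not in (VENTRICULAR, ATRIAL):
            raise ValueError(f"unknown activation form {self.form!r}")

    @property
    def is_ventricle(self) -> bool:
        return self.form == VENTRICULAR


def contractility_scale(F_con: float, constants: ContractilityConstants | None = None) -> float:
    """Contractility factor a(F_con) = a_min + K_a * F_con multiplying the
    ventricular ESPVR slope (atria use a = 1)."""
    c = constants or ContractilityConstants()
    if not 0.0 <= F_con <= 1.0:
        raise ValueError(f"F_con={F_con!r} outside [0, 1]")
    return c.a_min + c.K_a * F_con


def time_scale(F_con: float, constants: ContractilityConstants | None = None) -> float:
    """Systole time-scale factor b(F_con) = b_min + K_b * F_con applied inside
    the ventricular activation exponent."""
    c = constants or ContractilityConstants()
    if not 0.0 <= F_con <= 1.0:
        raise ValueError(f"F_con={F_con!r} outside [0, 1]")
    return c.b_min + c.K_b * F_con


def activation_sum(
    phase: float,
    components: Iterable[ActivationComponent] | Sequence[tuple[float, float, float]],
    form: str = VENTRICULAR,
    time_scale: float = 1.0,
    linear_term: float = 0.0,
) -> float:
    """Evaluate a Gaussian-sum activation at a cardiac phase [s].

    Ventricular form: sum A_i * exp(-((time_scale*phase - C_i)/B_i)^2);
    atrial form:      sum A_i * exp(-0.5*((phase - C_i)/B_i)^2) + linear_term.

    Components whose centers sit at the period boundary are evaluated
    without a periodic image (tails into the next cycle are neglected).
    Negative totals (possible under long extrapolation of scheduled
    amplitudes) are clamped to zero: activation is a physical fraction.
    """
    if time_scale <= 0:
        raise ValueError(f"time_scale={time_scale!r} must be > 0")
    total = 0.0
    for comp in components:
        if isinstance(comp, ActivationComponent):
            A, B, C = comp.A, comp.B, comp.C
        else:
            A, B, C = comp
        if form == VENTRICULAR:
            x = (time_scale * phase - C) / B
            total += A * math.exp(-x * x)
        else:
            x = (phase - C) / B
            total += A * math.exp(-0.5 * x * x)
    total += linear_term
    return max(total, 0.0)


def espvr_pressure(V: float, params: ChamberParams, a: float = 1.0) -> float:
    """End-systolic pressure [mmHg]: a * E_es * (V - V_d); the chamber's
    fully-activated (linear) P-V envelope."""
    return a * params.E_es * (V - params.V_d)


def edpvr_pressure(V: float, params: ChamberParams) -> float:
    """End-diastolic pressure [mmHg]: M_0 * |exp(lambda*(V - V_0)) - 1|; the
    passive filling envelope, zero at V = V_0."""
    return params.M_0 * abs(math.exp(params.lambda_ * (V - params.V_0)) - 1.0)


def chamber_pressure(
    V: float,
    phase: float,
    params: ChamberParams,
    F_con: float = 0.5,
    constants: ContractilityConstants | None = None,
    linear_term: float = 0.0,
) -> float:
    """Instantaneous chamber pressure [mmHg] at a given volume and phase:
    the activation-weighted blend of the ESPVR and EDPVR envelopes."""
    if params.is_ventricle:
        a = contractility_scale(F_con, constants)
        b = time_scale(F_con, constants)
        e = activation_sum(phase, params.activation, VENTRICULAR, time_scale=b)
    else:
        a = 1.0
        e = activation_sum(phase, params.activation, ATRIAL, linear_term=linear_term)
    return e * espvr_pressure(V, params, a) + (1.0 - e) * edpvr_pressure(V, params)
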