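"""Vessel pressure-volume and resistance laws.

Four families of compartments appear in the circuit:

* linear Windkessel segments, P = V/C;
* the large systemic reservoirs with published nonlinear laws — systemic
  veins (log10 stiffening), vena cava (piecewise exponential/linear with a
  volume-dependent resistance) and the proximal systemic artery (a blend of
  a fully vasoconstricted and a passive P-V branch, weighted by sympathetic
  tone F_vaso);
* saturating logarithmic vessels, P = -K ln(1 - V/V_m), used for the
  pulmonary compartments once hypertension remodels them (pressure diverges
  as volume approaches the anatomical maximum V_m);
* the distal-stenosis machinery: a Poiseuille radius shrinking over disease
  time, with resistance scaling as r^-4 and compliance tied to resistance
  through a decaying RC-time.

All functions are scalar closed forms; the network engine re-implements
them in compiled code, and the test-suite checks the two routes against
each other digit-for-digit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any

__all__ = [
    "VesselParams",
    "systemic_vein_pressure",
    "vena_cava_pressure",
    "vena_cava_resistance",
    "sap_pressure",
    "sap_resistance",
    "linear_pressure",
    "log_vessel_pressure",
    "stenosis_radius",
    "stenosed_resistance",
    "rc_time",
    "stenosed_compliance",
    "stenosed_pressure",
    "compliance_from_mpap",
    "resistance_from_rc",
]

#: fraction of V_m beyond which the integration guards declare a
#: physiological-limit error instead of returning a near-infinite pressure
LOG_LAW_GUARD = 0.999


@dataclass
class VesselParams:
    """Law tag plus the constants it needs (law-specific keys in ``constants``)."""

    name: str
    law: str = "linear"
    constants: dict[str, Any] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# systemic reservoirs
# ---------------------------------------------------------------------------

def systemic_vein_pressure(V: float, K_v: float = 40.0, V_sv_max: float = 3500.0) -> float:
    """Systemic-vein pressure [mmHg]: -K_v*log10(V_sv_max/V - 0.99).

    The veins stiffen as they fill; the law crosses zero at V = V_sv_max/1.99
    and diverges as V approaches V_sv_max/0.99 (over-filled vein -> domain
    error)."""
    arg = V_sv_max / V - 0.99
    if arg <= 0.0:
        raise ValueError(f"systemic vein over-filled: V={V!r} ml (log10 argument {arg!r} <= 0)")
    return -K_v * math.log10(arg)


def vena_cava_pressure(
    V: float,
    N_1: float = 0.0,
    K_1: float = 0.15,
    N_2: float = -5.0,
    K_2: float = 0.4,
    V_vc_0: float = 130.0,
    V_vc_min: float = 50.0,
) -> float:
    """Vena-cava pressure [mmHg]: linear branch above the unstressed volume
    V_vc_0 (boundary assigned to the upper branch), exponential collapse
    branch below it."""
    if V <= 0.0:
        raise ValueError(f"vena cava volume V={V!r} must be > 0")
    if V >= V_vc_0:
        return N_1 + K_1 * (V - V_vc_0)
    return N_2 + K_2 * math.exp(V / V_vc_min)


def vena_cava_resistance(
    V: float, K_R: float = 0.001, V_vc_max: float = 350.0, R_0: float = 0.025
) -> float:
    """Vena-cava outflow resistance [mmHg*s/ml]: K_R*V_vc_max/V + R_0,
    decreasing as the vessel distends."""
    if V <= 0.0:
        raise ValueError(f"vena cava volume V={V!r} must be > 0")
    return K_R * V_vc_max / V + R_0


def sap_pressure(
    V: float,
    F_vaso: float,
    K_c: float = 1000.0,
    N_0: float = 50.0,
    K_p1: float = 0.03,
    K_p2: float = 0.2,
    tau_aop: float = 0.1,
    V_sap_min: float = 210.0,
) -> float:
    """Proximal systemic artery pressure [mmHg]: sympathetic blend
    F_vaso * active + (1 - F_vaso) * passive of a fully vasoconstricted
    log10 branch and a passive exponential+quadratic branch."""
    if not 0.0 <= F_vaso <= 1.0:
        raise ValueError(f"F_vaso={F_vaso!r} outside [0, 1]")
    x = V - V_sap_min
    if x < 0.0:
        raise ValueError(f"proximal systemic artery under-filled: V={V!r} < V_sap_min={V_sap_min!r}")
    active = K_c * math.log10(x / N_0 + 1.0)
    passive = K_p1 * math.exp(tau_aop * x) + K_p2 * x * x
    return F_vaso * active + (1.0 - F_vaso) * passive


def sap_resistance(
    V: float, F_vaso: float, K_r: float = 0.04, V_sap_max: float = 250.0
) -> float:
    """Proximal systemic artery resistance [mmHg*s/ml]:
    K_r * (exp(4*F_vaso) + (V_sap_max/V)^2)."""
    if V <= 0.0:
        raise ValueError(f"V={V!r} must be > 0")
    return K_r * (math.exp(4.0 * F_vaso) + (V_sap_max / V) ** 2)


# ---------------------------------------------------------------------------
# linear and saturating-log compartments
# ---------------------------------------------------------------------------

def linear_pressure(V: float, C: float) -> float:
    """Linear Windkessel pressure [mmHg]: P = V/C."""
    if C <= 0.0:
        raise ValueError(f"compliance C={C!r} must be > 0")
    return V / C


def log_vessel_pressure(V: float, K: float, V_m: float) -> float:
    """Saturating vessel pressure [mmHg]: P = -K ln(1 - V/V_m); convex,
    zero at V = 0, diverging at the maximum volume V_m."""
    if not V < LOG_LAW_GUARD * V_m:
        raise ValueError(
            f"vessel at physiological volume limit: V={V!r} >= {LOG_LAW_GUARD}*V_m={LOG_LAW_GUARD * V_m!r}"
        )
    return -K * math.log(1.0 - V / V_m)


# ---------------------------------------------------------------------------
# distal stenosis machinery (shared with the pathology schedules)
# ---------------------------------------------------------------------------

def stenosis_radius(t: float, r_0: float = 1.0, g_r: float = 0.018) -> float:
    """Dimensionless lumen radius of a progressively stenosed distal
    pulmonary artery: r(t) = r_0 * (1 + g_r*t)^(-1/4)."""
    return r_0 * (1.0 + g_r * t) ** -0.25


def stenosed_resistance(t: float, R_0: float, r_0: float = 1.0, g_r: float = 0.018) -> float:
    """Resistance [mmHg*s/ml] of the stenosed artery: Poiseuille scaling
    (1/r)^4 * R_0 = (1 + g_r*t) * R_0 for r_0 = 1."""
    r = stenosis_radius(t, r_0, g_r)
    return (1.0 / r) ** 4 * R_0


def rc_time(t: float, tau_0: float, sigma: float) -> float:
    """RC-time [s] of a vascular bed, decaying with disease time:
    tau(t) = tau_0 * exp(-sigma*t)."""
    return tau_0 * math.exp(-sigma * t)


def stenosed_compliance(
    t: float, R_0: float, tau_0: float = 0.54, sigma: float = 0.0008,
    r_0: float = 1.0, g_r: float = 0.018,
) -> float:
    """Compliance [ml/mmHg] of the stenosed artery: C(t) = tau(t)*r(t)^4/R_0,
    so that R(t)*C(t) = tau(t) holds identically."""
    r = stenosis_radius(t, r_0, g_r)
    return rc_time(t, tau_0, sigma) * r**4 / R_0


def stenosed_pressure(
    V: float, t: float, R_0: float, tau_0: float = 0.54, sigma: float = 0.0008,
    r_0: float = 1.0, g_r: float = 0.018,
) -> float:
    """P-V law of the stenosed artery implied by the time-varying compliance:
    P = V * R_0 / (tau(t) * r(t)^4)."""
    r = stenosis_radius(t, r_0, g_r)
    return V * R_0 / (rc_time(t, tau_0, sigma) * r**4)


# ---------------------------------------------------------------------------
# pressure-coupled compliance (left-heart-disease pulmonary remodelling)
# ---------------------------------------------------------------------------

def compliance_from_mpap(P_m: float, g_c: float, h_c: float) -> float:
    """Pulmonary compliance [ml/mmHg] decaying exponentially with the
    compartment's mean pressure: C = g_c * exp(-h_c * P_m)."""
    return g_c * math.exp(-h_c * P_m)


def resistance_from_rc(tau_t: float, C: float) -> float:
    """Resistance [mmHg*s/ml] recovered from the RC-time: R = tau(t)/C."""
    if C <= 0.0:
        raise ValueError(f"compliance C={C!r} must be > 0")
    return tau_t / C
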