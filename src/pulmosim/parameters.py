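"""Parameter registry, configuration I/O and the shared cardiac clock.

Units are fixed throughout the package: pressures in mmHg, volumes in ml,
time in s.  Hence resistances are mmHg*s/ml, compliances ml/mmHg and
inertances mmHg*s^2/ml.  Every key in the configuration file is named after
the symbol it carries in the cardiovascular-modelling literature
(``E_es_lv``, ``K_rpap_0``, ``tau_rpad_0``, ...).

The shipped default configuration (``data/normal.yaml``) is a *calibrated*
fixture: the per-compartment circuit constants were tuned so that the normal
closed-loop run reproduces textbook systemic and pulmonary hemodynamics
(see ``docs/methods.md`` for the calibration procedure).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Any, Mapping

import yaml

__all__ = [
    "ConfigError",
    "HeartRateConstants",
    "ContractilityConstants",
    "ScenarioSpec",
    "ParameterSet",
    "heart_rate",
    "cycle_phase",
    "mean_pap",
    "load_config",
    "write_config",
    "default_config_path",
]

SCENARIOS = ("normal", "dpas", "lvdd", "vsd", "ms")

#: Default total blood volume of the closed circuit [ml].
TOTAL_BLOOD_VOLUME_DEFAULT = 4711.0


class ConfigError(ValueError):
    """Raised when a configuration fails validation; lists offending keys."""

    def __init__(self, problems: list[str]):
        self.problems = list(problems)
        super().__init__("invalid configuration:\n  - " + "\n  - ".join(self.problems))


# ---------------------------------------------------------------------------
# closed-form laws owned by this module
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HeartRateConstants:
    """Constants of the sympathetic/vagal heart-rate response surface [bpm scale]."""

    h1: float = 35.0
    h2: float = 140.0
    h3: float = 40.0
    h4: float = 32.0
    h5: float = 10.0
    h6: float = 20.0


@dataclass(frozen=True)
class ContractilityConstants:
    """Constants mapping sympathetic tone F_con to the contractility factor a
    and the systole time-scale factor b (dimensionless)."""

    a_min: float = -2.0
    b_min: float = 0.7
    K_a: float = 7.0
    K_b: float = 0.5


def heart_rate(F_Hrs: float, F_Hrv: float, constants: HeartRateConstants | None = None) -> float:
    """Heart rate [bpm] as a quadratic response to normalized sympathetic
    (``F_Hrs``) and vagal (``F_Hrv``) discharge frequencies.

    Hr = h1 + h2*Fs - h3*Fs^2 - h4*Fv + h5*Fv^2 - h6*Fv*Fs
    """
    c = constants or HeartRateConstants()
    for name, f in (("F_Hrs", F_Hrs), ("F_Hrv", F_Hrv)):
        if not 0.0 <= f <= 1.0:
            raise ValueError(f"{name}={f!r} outside the normalized range [0, 1]")
    return (
        c.h1
        + c.h2 * F_Hrs
        - c.h3 * F_Hrs**2
        - c.h4 * F_Hrv
        + c.h5 * F_Hrv**2
        - c.h6 * F_Hrv * F_Hrs
    )


def cycle_phase(t: float, T: float) -> float:
    """Phase of the cardiac clock: remainder of ``t`` after division by the
    cycle duration ``T``; always in [0, T)."""
    if T <= 0.0:
        raise ValueError(f"cycle duration T={T!r} must be positive")
    phase = math.fmod(t, T)
    if phase < 0.0:
        phase += T
    # fmod(x, T) may round to T for x marginally below an integer multiple
    return 0.0 if phase >= T else phase


def mean_pap(sPAP: float, dPAP: float) -> float:
    """Mean pulmonary artery pressure from systolic/diastolic extrema [mmHg]:
    mPAP = sPAP/3 + 2*dPAP/3."""
    if sPAP < dPAP:
        raise ValueError(f"sPAP={sPAP!r} < dPAP={dPAP!r}")
    return sPAP / 3.0 + 2.0 * dPAP / 3.0


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------

@dataclass
class ScenarioSpec:
    """A disease scenario: which progression schedule runs, for how long,
    and the coefficient block it reads (mirrors the published tables
    key-for-key, e.g. ``k_1``, ``g_r``, ``tau_0`` for distal stenosis)."""

    scenario: str = "normal"
    duration: float = 700.0
    dt: float = 0.0005
    coefficients: dict[str, Any] = field(default_factory=dict)

    def validate(self) -> list[str]:
        problems = []
        if self.scenario not in SCENARIOS:
            problems.append(f"scenario={self.scenario!r} not one of {SCENARIOS}")
        if not self.dt > 0.0:
            problems.append(f"dt={self.dt!r} must be > 0")
        if not self.duration > 0.0:
            problems.append(f"duration={self.duration!r} must be > 0")
        for key, val in self.coefficients.items():
            if isinstance(val, (int, float)) and not math.isfinite(val):
                problems.append(f"scenario coefficient {key}={val!r} not finite")
        return problems


@dataclass
class ParameterSet:
    """The full constant registry of the circulation model.

    ``chambers`` maps chamber name (lv/la/rv/ra) to its elastance-law
    constants and activation table; ``vessels`` maps compartment name to its
    P-V law block; ``edges`` is the ordered connection list of the circuit
    (each entry: from/to node, resistance law, optional inertance, optional
    valve tag); ``scenarios`` holds one coefficient block per disease case.
    """

    heart_rate_constants: HeartRateConstants = field(default_factory=HeartRateConstants)
    contractility: ContractilityConstants = field(default_factory=ContractilityConstants)
    frequencies: dict[str, float] = field(
        default_factory=lambda: {"F_con": 0.5, "F_Hrs": 0.5, "F_vaso": 0.5, "F_Hrv": 0.5}
    )
    total_blood_volume: float = TOTAL_BLOOD_VOLUME_DEFAULT
    T: float | None = None
    chambers: dict[str, dict[str, Any]] = field(default_factory=dict)
    vessels: dict[str, dict[str, Any]] = field(default_factory=dict)
    edges: list[dict[str, Any]] = field(default_factory=list)
    scenarios: dict[str, dict[str, Any]] = field(default_factory=dict)

    # -- derived quantities -------------------------------------------------
    @property
    def cycle_duration(self) -> float:
        """Cardiac cycle duration T [s]; taken from the config when present,
        otherwise derived once from the heart-rate law at the configured
        frequencies and held constant for the whole run."""
        if self.T is not None:
            return float(self.T)
        hr = heart_rate(
            self.frequencies["F_Hrs"], self.frequencies["F_Hrv"], self.heart_rate_constants
        )
        return 60.0 / hr

    @property
    def node_names(self) -> list[str]:
        return list(self.chambers) + list(self.vessels)

    def initial_volumes(self) -> dict[str, float]:
        out = {}
        for name, blk in list(self.chambers.items()) + list(self.vessels.items()):
            out[name] = float(blk["V_init"])
        return out

    # -- validation ---------------------------------------------------------
    def validate(self) -> list[str]:
        problems: list[str] = []
        for key, f in self.frequencies.items():
            if not 0.0 <= f <= 1.0:
                problems.append(f"frequencies.{key}={f!r} outside [0, 1]")
        if self.total_blood_volume <= 0:
            problems.append(f"total_blood_volume={self.total_blood_volume!r} must be > 0")
        if self.T is not None and self.T <= 0:
            problems.append(f"T={self.T!r} must be > 0")

        for name, blk in self.chambers.items():
            for key in ("E_es", "lambda_"):
                if blk.get(key, 0.0) <= 0:
                    problems.append(f"chambers.{name}.{key}={blk.get(key)!r} must be > 0")
            for key in ("M_0", "V_0", "V_d"):
                if blk.get(key, 0.0) < 0:
                    problems.append(f"chambers.{name}.{key}={blk.get(key)!r} must be >= 0")
            for i, comp in enumerate(blk.get("activation", [])):
                if comp[1] <= 0:
                    problems.append(f"chambers.{name}.activation[{i}] width B={comp[1]!r} must be > 0")

        for name, blk in self.vessels.items():
            law = blk.get("law", "linear")
            if law == "linear" and blk.get("C", 0.0) <= 0:
                problems.append(f"vessels.{name}.C={blk.get('C')!r} must be > 0")
            if law == "log_saturating" and blk.get("V_m", 0.0) <= 0:
                problems.append(f"vessels.{name}.V_m={blk.get('V_m')!r} must be > 0")
            if law == "sv_log10":
                if blk.get("V_max", 0.0) <= 0:
                    problems.append(f"vessels.{name}.V_max={blk.get('V_max')!r} must be > 0")

        node_names = set(self.node_names)
        for i, e in enumerate(self.edges):
            tag = f"edges[{i}] ({e.get('from')}->{e.get('to')})"
            for end in ("from", "to"):
                if e.get(end) not in node_names:
                    problems.append(f"{tag}: unknown node {e.get(end)!r}")
            rlaw = e.get("R_law", "constant")
            if rlaw == "constant" and e.get("R", 0.0) <= 0:
                problems.append(f"{tag}: R={e.get('R')!r} must be > 0")
            if e.get("L", 0.0) < 0:
                problems.append(f"{tag}: L={e.get('L')!r} must be >= 0")

        if self.chambers or self.vessels:
            vsum = sum(self.initial_volumes().values())
            if not math.isclose(vsum, self.total_blood_volume, rel_tol=1e-9, abs_tol=1e-6):
                problems.append(
                    "sum of initial volumes "
                    f"{vsum!r} != total_blood_volume {self.total_blood_volume!r}"
                )
        return problems


# ---------------------------------------------------------------------------
# configuration I/O
# ---------------------------------------------------------------------------

def default_config_path() -> Path:
    """Path of the shipped calibrated normal-circulation fixture."""
    return Path(str(resources.files("pulmosim").joinpath("data/normal.yaml")))


def _params_from_mapping(doc: Mapping[str, Any]) -> tuple[ParameterSet, ScenarioSpec]:
    sim = dict(doc.get("simulation", {}))
    params = ParameterSet(
        heart_rate_constants=HeartRateConstants(**doc.get("heart_rate", {})),
        contractility=ContractilityConstants(**doc.get("contractility", {})),
        frequencies={**ParameterSet().frequencies, **doc.get("frequencies", {})},
        total_blood_volume=float(sim.get("total_blood_volume", TOTAL_BLOOD_VOLUME_DEFAULT)),
        T=sim.get("T"),
        chambers={k: dict(v) for k, v in doc.get("chambers", {}).items()},
        vessels={k: dict(v) for k, v in doc.get("vessels", {}).items()},
        edges=[dict(e) for e in doc.get("edges", [])],
        scenarios={k: dict(v) for k, v in doc.get("scenarios", {}).items()},
    )
    spec = ScenarioSpec(
        scenario=str(sim.get("scenario", "normal")),
        duration=float(sim.get("duration", 700.0)),
        dt=float(sim.get("dt", 0.0005)),
    )
    spec.coefficients = dict(params.scenarios.get(spec.scenario, {}))
    problems = params.validate() + spec.validate()
    if problems:
        raise ConfigError(problems)
    return params, spec


def load_config(path: str | Path | None = None) -> tuple[ParameterSet, ScenarioSpec]:
    """Load and validate a model configuration.

    With ``path=None`` the shipped calibrated fixture is loaded.  Raises
    :class:`ConfigError` listing every offending key when validation fails.
    """
    p = Path(path) if path is not None else default_config_path()
    with open(p) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, Mapping):
        raise ConfigError([f"{p}: top level must be a mapping"])
    return _params_from_mapping(doc)


def write_config(params: ParameterSet, spec: ScenarioSpec, path: str | Path) -> None:
    """Write a configuration document that :func:`load_config` reads back
    with bit-identical numeric values."""
    doc: dict[str, Any] = {
        "simulation": {
            "scenario": spec.scenario,
            "duration": spec.duration,
            "dt": spec.dt,
            "total_blood_volume": params.total_blood_volume,
        },
        "heart_rate": vars(params.heart_rate_constants).copy(),
        "contractility": vars(params.contractility).copy(),
        "frequencies": dict(params.frequencies),
        "chambers": {k: dict(v) for k, v in params.chambers.items()},
        "vessels": {k: dict(v) for k, v in params.vessels.items()},
        "edges": [dict(e) for e in params.edges],
        "scenarios": {k: dict(v) for k, v in params.scenarios.items()},
    }
    if params.T is not None:
        doc["simulation"]["T"] = params.T
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False, default_flow_style=None)
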