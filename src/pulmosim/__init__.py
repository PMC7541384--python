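"""pulmosim — lumped-parameter closed-loop circulation simulator.

An electrical-analog (0D) model of the human systemic and pulmonary
circulation: four time-varying-elastance heart chambers, Windkessel and
nonlinear vessel compartments, ideal-diode valves, and per-cycle disease
schedules that grow four pulmonary-hypertension etiologies (distal
pulmonary artery stenosis, left-ventricular diastolic dysfunction,
ventricular septal defect, mitral stenosis) out of the normal state.
"""

from __future__ import annotations

from .parameters import (
    ParameterSet, ScenarioSpec, ConfigError,
    heart_rate, cycle_phase, mean_pap, load_config, write_config,
    default_config_path,
)
from .topology import CompiledModel, build_model
from .network import Trajectory, IntegrationError, integrate, steady_cycle, valve_flow
from .pathologies import make_schedule, Schedule, ScheduleState
from .analysis import CycleSummary, summarize_cycles, pv_loop

__version__ = "0.1.0"

__all__ = [
    "ParameterSet", "ScenarioSpec", "ConfigError", "CompiledModel", "Trajectory",
    "IntegrationError", "CycleSummary", "Schedule", "ScheduleState",
    "heart_rate", "cycle_phase", "mean_pap", "load_config", "write_config",
    "default_config_path", "build_model", "integrate", "steady_cycle",
    "valve_flow", "make_schedule", "summarize_cycles", "pv_loop", "run_scenario",
]


def run_scenario(
    scenario: str = "normal",
    duration: float | None = None,
    dt: float | None = None,
    config=None,
    record_every: int = 10,
):
    """End-to-end convenience: load config, build the circuit for a scenario,
    attach its schedule and integrate.  Returns the :class:`Trajectory`."""
    params, spec = load_config(config)
    spec.scenario = scenario
    spec.coefficients = dict(params.scenarios.get(scenario, {}))
    if duration is not None:
        spec.duration = duration
    if dt is not None:
        spec.dt = dt
    model = build_model(params, scenario)
    schedule = make_schedule(scenario, params, model)
    return integrate(model, spec, schedule=schedule, record_every=record_every)
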