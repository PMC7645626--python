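"""Canonical parameter sets, parameter sweeps and configuration comparison.

The base case is the published contactor: 9950 polypropylene-like fibers
(r1 = 1.1e-4 m, r2 = 1.5e-4 m) in a 0.0315 m module, 0.15 m long, porosity
0.40, tortuosity 2.2, with ibuprofen (IP) and 4-isobutylacetophenone (4-IBAP)
partitioning from water into octanol; both streams at 50 L/min for the whole
module.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import pandas as pd

from .geometry_hydro import (
    ContactorGeometry,
    FlowConfiguration,
    FlowSpec,
    LITERS_PER_MINUTE,
)
from .postprocess import SeparationSummary, mass_balance_residual, mixing_cup, separation_percent
from .solver import Resolution, SolverError, solve_steady
from .transport_model import MembraneSpec, SoluteSpec, TransportProblem, build_problem

__all__ = [
    "SOLUTES",
    "BASE_GEOMETRY",
    "BASE_MEMBRANE",
    "BASE_FLOW_LMIN",
    "ScenarioCase",
    "SweepResult",
    "SweepError",
    "table1_case",
    "solve_case",
    "sweep",
    "compare_configurations",
]

#: canonical solute definitions (diffusivities m^2/s, inlet g/mL)
SOLUTES: Dict[str, SoluteSpec] = {
    "IP": SoluteSpec(name="IP", D_aq=7.17e-10, D_org=1.47e-10, m=31.62, C0=1e-4),
    "4-IBAP": SoluteSpec(name="4-IBAP", D_aq=7.53e-10, D_org=1.56e-10, m=37.15, C0=1e-4),
}

BASE_GEOMETRY = dict(r1=1.1e-4, r2=1.5e-4, L=0.15, n=9950, R_module=0.0315)
BASE_MEMBRANE = dict(porosity=0.40, tortuosity=2.2)
BASE_FLOW_LMIN = dict(Q_aq=50.0, Q_org=50.0)

#: parameters accepted as overrides; values in the units noted
_OVERRIDABLE = {
    "Q_aq": "L/min (whole module)",
    "Q_org": "L/min (whole module)",
    "porosity": "fraction",
    "tortuosity": "dimensionless",
    "n_fibers": "count",
    "C0": "g/mL",
}


@dataclass(frozen=True)
class ScenarioCase:
    """A fully specified run: label, solute, configuration, overrides, problem."""

    label: str
    solute: str
    configuration: FlowConfiguration
    overrides: Dict[str, float]
    problem: TransportProblem

    def __post_init__(self) -> None:
        unknown = set(self.overrides) - set(_OVERRIDABLE)
        if unknown:
            raise ValueError(
                f"unknown override(s) {sorted(unknown)}; "
                f"valid: {sorted(_OVERRIDABLE)}"
            )


def _as_configuration(configuration) -> FlowConfiguration:
    if isinstance(configuration, FlowConfiguration):
        return configuration
    return FlowConfiguration(str(configuration).lower())


def table1_case(
    solute: str,
    configuration=FlowConfiguration.FEED_IN_TUBE,
    **overrides: float,
) -> ScenarioCase:
    """Build the base-case problem for one solute and flow configuration.

    Keyword overrides (``Q_aq``/``Q_org`` in L/min, ``porosity``,
    ``tortuosity``, ``n_fibers``, ``C0``) perturb single parameters for the
    sweep studies; the free-surface radius is recomputed whenever the fiber
    count changes.
    """
    if solute not in SOLUTES:
        raise KeyError(f"unknown solute {solute!r}; expected one of {sorted(SOLUTES)}")
    configuration = _as_configuration(configuration)
    spec = SOLUTES[solute]
    if "C0" in overrides:
        spec = spec.with_inlet(float(overrides["C0"]))
    geom_kwargs = dict(BASE_GEOMETRY)
    if "n_fibers" in overrides:
        geom_kwargs["n"] = int(overrides["n_fibers"])
    geom = ContactorGeometry(**geom_kwargs)
    mem_kwargs = dict(BASE_MEMBRANE)
    if "porosity" in overrides:
        mem_kwargs["porosity"] = float(overrides["porosity"])
    if "tortuosity" in overrides:
        mem_kwargs["tortuosity"] = float(overrides["tortuosity"])
    membrane = MembraneSpec(**mem_kwargs)
    flows = FlowSpec(
        Q_aq_total=float(overrides.get("Q_aq", BASE_FLOW_LMIN["Q_aq"])) * LITERS_PER_MINUTE,
        Q_org_total=float(overrides.get("Q_org", BASE_FLOW_LMIN["Q_org"])) * LITERS_PER_MINUTE,
        configuration=configuration,
    )
    problem = build_problem(geom, spec, membrane, flows)
    label = f"{solute}/{configuration.value}"
    if overrides:
        label += "/" + ",".join(f"{k}={v}" for k, v in sorted(overrides.items()))
    return ScenarioCase(
        label=label,
        solute=solute,
        configuration=configuration,
        overrides=dict(overrides),
        problem=problem,
    )


def solve_case(case: ScenarioCase, resolution: Optional[Resolution] = None) -> SeparationSummary:
    """Solve one scenario and summarize it."""
    fld = solve_steady(case.problem, resolution=resolution)
    c_out = mixing_cup(fld, case.problem, "feed")
    C0 = case.problem.solute.C0
    return SeparationSummary(
        solute=case.solute,
        configuration=case.configuration.value,
        inlet_concentration=C0,
        outlet_concentration=c_out,
        separation_percent=separation_percent(C0, c_out),
        mass_balance_residual=mass_balance_residual(fld, case.problem),
    )


@dataclass
class SweepResult:
    """Tabulated outcome of a one-parameter sweep for one solute/configuration."""

    parameter: str
    unit: str
    solute: str
    configuration: str
    values: List[float]
    outlet_concentrations: List[float]
    separation_percents: List[float]

    def __post_init__(self) -> None:
        diffs = [b - a for a, b in zip(self.values, self.values[1:])]
        if diffs and not (all(d > 0 for d in diffs) or all(d < 0 for d in diffs)):
            raise ValueError("sweep values must be strictly monotone")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                self.parameter: self.values,
                "outlet_concentration": self.outlet_concentrations,
                "separation_percent": self.separation_percents,
                "solute": self.solute,
                "configuration": self.configuration,
            }
        )


class SweepError(RuntimeError):
    """A sweep member failed to converge; carries the completed rows."""

    def __init__(self, message: str, partial: SweepResult):
        super().__init__(message)
        self.partial = partial


def sweep(
    base: ScenarioCase,
    parameter: str,
    values: Sequence[float],
    resolution: Optional[Resolution] = None,
) -> SweepResult:
    """Re-solve the base case across a range of one parameter.

    ``parameter`` is one of ``Q_aq`` (L/min), ``porosity`` or ``n_fibers``.
    Geometry is rebuilt when the fiber count changes (the free-surface radius
    depends on it).
    """
    if parameter not in ("Q_aq", "porosity", "n_fibers"):
        raise ValueError(f"unsupported sweep parameter {parameter!r}")
    diffs = [b - a for a, b in zip(values, values[1:])]
    if diffs and not (all(d > 0 for d in diffs) or all(d < 0 for d in diffs)):
        raise ValueError("sweep values must be strictly monotone")
    result = SweepResult(
        parameter=parameter,
        unit=_OVERRIDABLE[parameter],
        solute=base.solute,
        configuration=base.configuration.value,
        values=[],
        outlet_concentrations=[],
        separation_percents=[],
    )
    for v in values:
        overrides = dict(base.overrides)
        overrides[parameter] = v
        case = table1_case(base.solute, base.configuration, **overrides)
        try:
            summary = solve_case(case, resolution=resolution)
        except SolverError as exc:
            raise SweepError(
                f"sweep aborted at {parameter}={v}: {exc}", result
            ) from exc
        result.values.append(float(v))
        result.outlet_concentrations.append(summary.outlet_concentration)
        result.separation_percents.append(summary.separation_percent)
    return result


def compare_configurations(
    solute: str,
    overrides: Optional[Dict[str, float]] = None,
    resolution: Optional[Resolution] = None,
) -> Dict[str, object]:
    """Run both flow configurations at identical conditions.

    Returns the two separation percentages and which configuration removes
    more solute.
    """
    overrides = overrides or {}
    out: Dict[str, object] = {"solute": solute}
    seps = {}
    for conf in FlowConfiguration:
        case = table1_case(solute, conf, **overrides)
        summary = solve_case(case, resolution=resolution)
        seps[conf.value] = summary.separation_percent
        out[conf.value] = summary.to_dict()
    diff = seps[FlowConfiguration.FEED_IN_SHELL.value] - seps[FlowConfiguration.FEED_IN_TUBE.value]
    out["separation_difference_shell_minus_tube"] = diff
    out["better_configuration"] = (
        FlowConfiguration.FEED_IN_SHELL.value if diff > 0 else FlowConfiguration.FEED_IN_TUBE.value
    )
    return out
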