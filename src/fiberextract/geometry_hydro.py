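"""Single-fiber cell geometry and analytic laminar velocity profiles.

A bundle of ``n`` hollow fibers inside a cylindrical module is reduced to a
single representative fiber surrounded by a concentric fluid envelope whose
outer radius ``r3`` carries a zero-shear ("free surface") condition.  All
hydrodynamics are analytic fully developed laminar profiles: a Poiseuille
profile in the fiber lumen and the annular free-surface profile in the shell
envelope.  Fluid properties enter only through Reynolds-number diagnostics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Tuple

import numpy as np

__all__ = [
    "FlowConfiguration",
    "FlowArrangement",
    "ContactorGeometry",
    "FlowSpec",
    "FluidProperties",
    "WATER",
    "OCTANOL",
    "packing_fraction",
    "happel_shell_radius",
    "mean_velocities",
    "tube_velocity",
    "shell_velocity",
    "shell_profile_normalization",
    "reynolds_number",
    "LITERS_PER_MINUTE",
]

#: conversion factor: volumetric flow in L/min -> m^3/s
LITERS_PER_MINUTE = 1e-3 / 60.0


class FlowConfiguration(Enum):
    """Which side carries the aqueous feed."""

    FEED_IN_TUBE = "feed_in_tube"
    FEED_IN_SHELL = "feed_in_shell"


class FlowArrangement(Enum):
    """Relative axial direction of the two streams (only counter-current is modeled)."""

    COUNTER_CURRENT = "counter_current"


def packing_fraction(n: int, r2: float, R_module: float) -> float:
    """Fraction of the module cross-section occupied by fibers, ``n*r2**2 / R**2``.

    Parameters
    ----------
    n:
        Number of fibers (``>= 0``).
    r2:
        Fiber outer radius [m].
    R_module:
        Module radius [m].

    Returns
    -------
    float
        The solid fraction in ``[0, 1]``.

    Raises
    ------
    ValueError
        If radii are non-positive or the fibers do not fit in the module.
    """
    if r2 <= 0.0 or R_module <= 0.0:
        raise ValueError(f"radii must be positive, got r2={r2}, R_module={R_module}")
    if n < 0:
        raise ValueError(f"fiber count must be non-negative, got {n}")
    frac = n * r2**2 / R_module**2
    if frac > 1.0:
        raise ValueError(
            f"{n} fibers of radius {r2} m do not fit in a module of radius "
            f"{R_module} m (packing fraction {frac:.3f} > 1)"
        )
    return frac


def happel_shell_radius(r2: float, n: int, R_module: float) -> float:
    """Free-surface envelope radius ``r3 = r2 * (1/phi)**0.5`` with ``phi = n r2^2/R^2``.

    Each fiber is assigned an identical annular fluid envelope sized so that
    the ``n`` envelopes tile the module cross-section; the envelope boundary
    is shear-free.

    Raises
    ------
    ValueError
        If the packing fraction is 0 (envelope unbounded) or >= 1.
    """
    frac = packing_fraction(n, r2, R_module)
    if frac == 0.0:
        raise ValueError("zero packing fraction: free-surface radius is unbounded")
    if frac >= 1.0:
        raise ValueError(f"packing fraction {frac} leaves no shell-side volume")
    return r2 * math.sqrt(1.0 / frac)


@dataclass(frozen=True)
class ContactorGeometry:
    """Dimensions of the fiber bundle and of the representative Happel cell.

    ``r3`` is derived from ``(r2, n, R_module)`` when not given explicitly; if
    given it must agree with :func:`happel_shell_radius` to round-off.
    """

    r1: float
    r2: float
    L: float
    n: int
    R_module: float
    r3: float = field(default=0.0)

    def __post_init__(self) -> None:
        if not 0.0 < self.r1 < self.r2:
            raise ValueError(f"need 0 < r1 < r2, got r1={self.r1}, r2={self.r2}")
        if self.L <= 0.0:
            raise ValueError(f"fiber length must be positive, got {self.L}")
        if self.n < 1:
            raise ValueError(f"need at least one fiber, got n={self.n}")
        r3 = happel_shell_radius(self.r2, self.n, self.R_module)
        if self.r3 == 0.0:
            object.__setattr__(self, "r3", r3)
        elif not math.isclose(self.r3, r3, rel_tol=1e-9):
            raise ValueError(
                f"inconsistent r3: given {self.r3}, derived {r3} from (r2, n, R)"
            )

    @property
    def tube_area(self) -> float:
        """Lumen cross-section of one fiber [m^2]."""
        return math.pi * self.r1**2

    @property
    def shell_area(self) -> float:
        """Annular shell cross-section of one Happel cell [m^2]."""
        return math.pi * (self.r3**2 - self.r2**2)

    def with_fiber_count(self, n: int) -> "ContactorGeometry":
        """Same module, different fiber count (``r3`` is recomputed)."""
        return ContactorGeometry(r1=self.r1, r2=self.r2, L=self.L, n=n, R_module=self.R_module)


@dataclass(frozen=True)
class FlowSpec:
    """Whole-module volumetric flow rates and flow configuration.

    Flows are totals for the module; each of the ``n`` identical Happel cells
    carries ``1/n`` of each stream.
    """

    Q_aq_total: float
    Q_org_total: float
    configuration: FlowConfiguration = FlowConfiguration.FEED_IN_TUBE
    arrangement: FlowArrangement = FlowArrangement.COUNTER_CURRENT

    def __post_init__(self) -> None:
        if self.Q_aq_total <= 0.0 or self.Q_org_total <= 0.0:
            raise ValueError(
                f"flow rates must be positive, got Q_aq={self.Q_aq_total}, "
                f"Q_org={self.Q_org_total}"
            )
        if self.arrangement is not FlowArrangement.COUNTER_CURRENT:
            raise ValueError("only counter-current operation is modeled")

    @property
    def Q_tube_total(self) -> float:
        if self.configuration is FlowConfiguration.FEED_IN_TUBE:
            return self.Q_aq_total
        return self.Q_org_total

    @property
    def Q_shell_total(self) -> float:
        if self.configuration is FlowConfiguration.FEED_IN_TUBE:
            return self.Q_org_total
        return self.Q_aq_total


@dataclass(frozen=True)
class FluidProperties:
    """Density/viscosity pair, used only for Reynolds-number diagnostics."""

    density: float
    viscosity: float

    def __post_init__(self) -> None:
        if self.density <= 0.0 or self.viscosity <= 0.0:
            raise ValueError("density and viscosity must be positive")


#: reference values at ~25 C; overridable, diagnostics only
WATER = FluidProperties(density=997.0, viscosity=8.9e-4)
OCTANOL = FluidProperties(density=824.0, viscosity=7.29e-3)


def mean_velocities(flows: FlowSpec, geom: ContactorGeometry) -> Tuple[float, float]:
    """Per-fiber mean axial speeds ``(tube, shell)`` in m/s.

    The module flow of each stream is split equally among the ``n`` cells and
    divided by the respective cross-section.  Which stream flows where follows
    ``flows.configuration``.
    """
    if geom.n < 1:
        raise ValueError("zero fiber count")
    v_tube = (flows.Q_tube_total / geom.n) / geom.tube_area
    v_shell = (flows.Q_shell_total / geom.n) / geom.shell_area
    return v_tube, v_shell


def tube_velocity(r, v_mean: float, r1: float):
    """Poiseuille profile ``2*v_mean*(1-(r/r1)^2)`` on ``0 <= r <= r1``."""
    r = np.asarray(r, dtype=float)
    if np.any(r < 0.0) or np.any(r > r1 * (1.0 + 1e-12)):
        raise ValueError(f"radius outside [0, {r1}]")
    out = 2.0 * v_mean * (1.0 - (r / r1) ** 2)
    return out if out.ndim else float(out)


def shell_profile_normalization(r2: float, r3: float) -> float:
    """Area-weighted mean of the un-normalized shell shape function.

    Shape: ``s(r) = (r2^2 - r^2) + 2 r3^2 ln(r/r2)``, the fully developed
    annular Stokes solution with no slip at ``r2`` and zero shear at ``r3``.
    """
    if r3 <= r2:
        raise ValueError(f"need r3 > r2, got r2={r2}, r3={r3}")
    dA = r3**2 - r2**2
    i1 = r2**2 * dA / 2.0 - (r3**4 - r2**4) / 4.0
    i2 = 2.0 * r3**2 * (r3**2 / 2.0 * math.log(r3 / r2) - dA / 4.0)
    return 2.0 * (i1 + i2) / dA


def shell_velocity(r, v_mean: float, r2: float, r3: float):
    """Annular free-surface profile on ``r2 <= r <= r3``.

    No slip at the fiber wall ``r2``, zero shear at the envelope ``r3``,
    normalized so the area-weighted average equals ``v_mean``.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r < r2 * (1.0 - 1e-12)) or np.any(r > r3 * (1.0 + 1e-12)):
        raise ValueError(f"radius outside [{r2}, {r3}]")
    norm = shell_profile_normalization(r2, r3)
    shape = (r2**2 - r**2) + 2.0 * r3**2 * np.log(r / r2)
    out = v_mean * shape / norm
    return out if out.ndim else float(out)


def reynolds_number(fluid: FluidProperties, speed: float, hydraulic_diameter: float) -> float:
    """``Re = rho * v * d_h / mu`` — laminar-regime sanity check."""
    return fluid.density * abs(speed) * hydraulic_diameter / fluid.viscosity
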