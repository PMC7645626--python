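"""Solute specifications, boundary conditions and problem assembly.

The continuum model is the steady axisymmetric convection-diffusion equation
``div(C v) = div(D grad C)`` posed on up to three concentric annular layers
(tube lumen, porous membrane wall, shell envelope) coupled through interface
conditions.  The aqueous/organic interface carries an equilibrium partition
jump ``C_org = m * C_aq`` together with continuity of diffusive flux; the
other interface carries plain concentration continuity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Tuple

from .geometry_hydro import (
    ContactorGeometry,
    FlowArrangement,
    FlowConfiguration,
    FlowSpec,
    mean_velocities,
    shell_velocity,
    tube_velocity,
)

__all__ = [
    "SoluteSpec",
    "MembraneSpec",
    "BoundaryCondition",
    "InterfaceCondition",
    "DomainLayer",
    "BoundaryConditionSet",
    "TransportProblem",
    "effective_membrane_diffusivity",
    "build_problem",
]


@dataclass(frozen=True)
class SoluteSpec:
    """Transport properties of one solute.

    ``m`` is the equilibrium partition coefficient ``C_org / C_aq``; ``C0``
    the feed inlet concentration in g/mL.
    """

    name: str
    D_aq: float
    D_org: float
    m: float
    C0: float

    def __post_init__(self) -> None:
        if min(self.D_aq, self.D_org, self.m, self.C0) <= 0.0:
            raise ValueError(f"solute {self.name!r}: all transport properties must be positive")

    def with_inlet(self, C0: float) -> "SoluteSpec":
        return SoluteSpec(self.name, self.D_aq, self.D_org, self.m, C0)


@dataclass(frozen=True)
class MembraneSpec:
    """Porous wall description: porosity and tortuosity factor."""

    porosity: float
    tortuosity: float

    def __post_init__(self) -> None:
        if not 0.0 < self.porosity <= 1.0:
            raise ValueError(f"porosity must be in (0, 1], got {self.porosity}")
        if self.tortuosity < 1.0:
            raise ValueError(f"tortuosity must be >= 1, got {self.tortuosity}")


def effective_membrane_diffusivity(D_org: float, membrane: MembraneSpec) -> float:
    """Porous-medium corrected diffusivity ``D_org * porosity / tortuosity``.

    The pores are organic-filled, so the organic-phase diffusivity is the one
    corrected.
    """
    return D_org * membrane.porosity / membrane.tortuosity


@dataclass(frozen=True)
class BoundaryCondition:
    """One of: dirichlet (fixed concentration), outflow (zero diffusive flux),
    insulation (zero total flux), symmetry (axis)."""

    kind: str
    value: float = 0.0

    _KINDS = ("dirichlet", "outflow", "insulation", "symmetry")

    def __post_init__(self) -> None:
        if self.kind not in self._KINDS:
            raise ValueError(f"unknown boundary condition kind {self.kind!r}")


@dataclass(frozen=True)
class InterfaceCondition:
    """Radial interface between adjacent layers.

    ``jump`` is the equilibrium ratio (outer-side concentration)/(inner-side
    concentration) at the interface; 1.0 means plain continuity.  Diffusive
    flux is continuous in all cases.
    """

    jump: float = 1.0

    def __post_init__(self) -> None:
        if self.jump <= 0.0:
            raise ValueError(f"interface jump factor must be positive, got {self.jump}")

    @property
    def is_partition(self) -> bool:
        return not math.isclose(self.jump, 1.0)


@dataclass(frozen=True)
class DomainLayer:
    """One annular layer of the problem: geometry slice, diffusivity, signed
    axial velocity profile (``None`` for a stagnant layer) and its outer
    boundary conditions.

    ``grading`` names the radial side(s) requiring a refined mesh:
    one of ``{"none", "lo", "hi", "both"}``.
    """

    name: str
    r_lo: float
    r_hi: float
    diffusivity: float
    velocity: Optional[Callable] = None
    bc_z0: BoundaryCondition = BoundaryCondition("insulation")
    bc_zL: BoundaryCondition = BoundaryCondition("insulation")
    bc_r_lo: BoundaryCondition = BoundaryCondition("insulation")
    bc_r_hi: BoundaryCondition = BoundaryCondition("insulation")
    grading: str = "none"

    def __post_init__(self) -> None:
        if self.r_lo < 0.0 or self.r_hi <= self.r_lo:
            raise ValueError(f"layer {self.name!r}: need 0 <= r_lo < r_hi")
        if self.diffusivity < 0.0:
            raise ValueError(f"layer {self.name!r}: negative diffusivity")
        if self.grading not in ("none", "lo", "hi", "both"):
            raise ValueError(f"layer {self.name!r}: unknown grading {self.grading!r}")

    @property
    def stagnant(self) -> bool:
        return self.velocity is None


@dataclass(frozen=True)
class BoundaryConditionSet:
    """Complete boundary/interface condition bookkeeping for a layered problem."""

    layers: Tuple[DomainLayer, ...]
    interfaces: Tuple[InterfaceCondition, ...]

    def __post_init__(self) -> None:
        if len(self.interfaces) != len(self.layers) - 1:
            raise ValueError("need exactly one interface condition between adjacent layers")
        for a, b in zip(self.layers, self.layers[1:]):
            if not math.isclose(a.r_hi, b.r_lo, rel_tol=1e-12):
                raise ValueError(f"layers {a.name!r}/{b.name!r} do not abut")
        n_jump = sum(1 for ic in self.interfaces if ic.is_partition)
        if self.interfaces and n_jump > 1:
            raise ValueError("at most one interface may carry the partition jump")


@dataclass(frozen=True)
class TransportProblem:
    """Fully assembled steady transport problem over one or more layers.

    ``feed_index``/``solvent_index`` identify which layers carry the feed and
    the solvent stream (``None`` if absent, e.g. in verification subproblems).
    By construction the feed always enters at ``z = 0`` flowing in ``+z`` and
    the solvent at ``z = L`` flowing in ``-z`` (counter-current).
    """

    layers: Tuple[DomainLayer, ...]
    L: float
    interfaces: Tuple[InterfaceCondition, ...] = ()
    feed_index: Optional[int] = None
    solvent_index: Optional[int] = None
    geometry: Optional[ContactorGeometry] = None
    solute: Optional[SoluteSpec] = None
    membrane: Optional[MembraneSpec] = None
    flows: Optional[FlowSpec] = None

    def __post_init__(self) -> None:
        if self.L <= 0.0:
            raise ValueError("axial length must be positive")
        # validates layer tiling and the single-jump rule
        BoundaryConditionSet(self.layers, self.interfaces)

    @property
    def boundary_conditions(self) -> BoundaryConditionSet:
        return BoundaryConditionSet(self.layers, self.interfaces)

    @property
    def configuration(self) -> Optional[FlowConfiguration]:
        return self.flows.configuration if self.flows is not None else None

    @property
    def feed_layer(self) -> DomainLayer:
        if self.feed_index is None:
            raise ValueError("problem has no feed stream")
        return self.layers[self.feed_index]

    @property
    def solvent_layer(self) -> DomainLayer:
        if self.solvent_index is None:
            raise ValueError("problem has no solvent stream")
        return self.layers[self.solvent_index]

    def layer_index(self, name: str) -> int:
        for i, layer in enumerate(self.layers):
            if layer.name == name:
                return i
        raise KeyError(f"no layer named {name!r}")

    def with_inlet(self, C0: float) -> "TransportProblem":
        """Same problem with the feed inlet concentration rescaled."""
        if self.feed_index is None:
            raise ValueError("problem has no feed stream")
        layers = list(self.layers)
        feed = layers[self.feed_index]
        bc_z0 = feed.bc_z0
        if bc_z0.kind != "dirichlet":
            raise ValueError("feed inlet is not a fixed-concentration boundary")
        layers[self.feed_index] = DomainLayer(
            name=feed.name, r_lo=feed.r_lo, r_hi=feed.r_hi,
            diffusivity=feed.diffusivity, velocity=feed.velocity,
            bc_z0=BoundaryCondition("dirichlet", C0), bc_zL=feed.bc_zL,
            bc_r_lo=feed.bc_r_lo, bc_r_hi=feed.bc_r_hi, grading=feed.grading,
        )
        solute = self.solute.with_inlet(C0) if self.solute is not None else None
        return TransportProblem(
            layers=tuple(layers), L=self.L, interfaces=self.interfaces,
            feed_index=self.feed_index, solvent_index=self.solvent_index,
            geometry=self.geometry, solute=solute, membrane=self.membrane,
            flows=self.flows,
        )


def build_problem(
    geom: ContactorGeometry,
    solute: SoluteSpec,
    membrane: MembraneSpec,
    flows: FlowSpec,
) -> TransportProblem:
    """Assemble the three-layer counter-current extraction problem.

    Feed enters its layer at ``z = 0`` with concentration ``C0`` and flows in
    ``+z``; solvent enters the opposite layer at ``z = L`` with concentration
    0 and flows in ``-z``.  The partition jump sits at the aqueous/organic
    interface (``r1`` for feed-in-tube, ``r2`` for feed-in-shell); the other
    interface is plain continuity.  The membrane wall is stagnant with the
    porosity/tortuosity-corrected organic diffusivity.
    """
    if flows.arrangement is not FlowArrangement.COUNTER_CURRENT:
        raise ValueError("only counter-current operation is modeled")
    v_tube, v_shell = mean_velocities(flows, geom)
    D_eff = effective_membrane_diffusivity(solute.D_org, membrane)
    r1, r2, r3 = geom.r1, geom.r2, geom.r3
    feed_in_tube = flows.configuration is FlowConfiguration.FEED_IN_TUBE

    tube_sign = +1.0 if feed_in_tube else -1.0
    shell_sign = -tube_sign

    def v_t(r, _s=tube_sign, _v=v_tube, _r1=r1):
        return _s * tube_velocity(r, _v, _r1)

    def v_s(r, _s=shell_sign, _v=v_shell, _r2=r2, _r3=r3):
        return _s * shell_velocity(r, _v, _r2, _r3)

    inlet = BoundaryCondition("dirichlet", solute.C0)
    solvent_in = BoundaryCondition("dirichlet", 0.0)
    outflow = BoundaryCondition("outflow")
    insul = BoundaryCondition("insulation")

    tube = DomainLayer(
        name="tube", r_lo=0.0, r_hi=r1,
        diffusivity=solute.D_aq if feed_in_tube else solute.D_org,
        velocity=v_t,
        bc_z0=inlet if feed_in_tube else outflow,
        bc_zL=outflow if feed_in_tube else solvent_in,
        bc_r_lo=BoundaryCondition("symmetry"),
        grading="hi",
    )
    wall = DomainLayer(
        name="membrane", r_lo=r1, r_hi=r2,
        diffusivity=D_eff, velocity=None,
        bc_z0=insul, bc_zL=insul, grading="both",
    )
    shell = DomainLayer(
        name="shell", r_lo=r2, r_hi=r3,
        diffusivity=solute.D_org if feed_in_tube else solute.D_aq,
        velocity=v_s,
        bc_z0=outflow if feed_in_tube else inlet,
        bc_zL=solvent_in if feed_in_tube else outflow,
        bc_r_hi=insul,
        grading="lo",
    )
    if feed_in_tube:
        # organic-filled membrane meets the aqueous lumen at r1
        interfaces = (InterfaceCondition(jump=solute.m), InterfaceCondition(jump=1.0))
        feed_index, solvent_index = 0, 2
    else:
        # aqueous shell meets the organic-filled membrane at r2
        interfaces = (InterfaceCondition(jump=1.0), InterfaceCondition(jump=1.0 / solute.m))
        feed_index, solvent_index = 2, 0

    return TransportProblem(
        layers=(tube, wall, shell), L=geom.L, interfaces=interfaces,
        feed_index=feed_index, solvent_index=solvent_index,
        geometry=geom, solute=solute, membrane=membrane, flows=flows,
    )
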