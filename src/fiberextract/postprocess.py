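"""Derived quantities: mixing-cup averages, separation percentage, interface
profiles, mass-balance audit and field export."""

from __future__ import annotations

import os
from dataclasses import dataclass, asdict
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd
from scipy.integrate import trapezoid

from .solver import ConcentrationField, axial_face_areas, cell_axial_velocities
from .transport_model import TransportProblem

__all__ = [
    "SeparationSummary",
    "mixing_cup",
    "mixing_cup_axial",
    "separation_percent",
    "interface_profile",
    "mass_balance_residual",
    "summarize",
    "export_field",
]


def _stream_layer_index(problem: TransportProblem, plane: str) -> int:
    if plane == "feed":
        if problem.feed_index is None:
            raise ValueError("problem has no feed stream")
        return problem.feed_index
    if plane == "solvent":
        if problem.solvent_index is None:
            raise ValueError("problem has no solvent stream")
        return problem.solvent_index
    raise ValueError(f"unknown outlet plane {plane!r} (expected 'feed' or 'solvent')")


def mixing_cup_axial(field: ConcentrationField, problem: TransportProblem, layer_index: int) -> np.ndarray:
    """Velocity-weighted bulk concentration of one flowing layer at every axial station."""
    layer = problem.layers[layer_index]
    dmesh = field.mesh.domains[layer_index]
    u = cell_axial_velocities(layer, dmesh)
    w = np.abs(u) * axial_face_areas(dmesh)
    w_sum = w.sum()
    if w_sum <= 0.0:
        raise ValueError(f"layer {layer.name!r} carries no net flow")
    c = field.values[layer.name]
    return (w[:, None] * c).sum(axis=0) / w_sum


def mixing_cup(
    field: ConcentrationField,
    problem: TransportProblem,
    plane: str,
    weighted: bool = True,
) -> float:
    """Bulk (mixing-cup) concentration at a stream outlet [g/mL].

    ``plane`` is ``"feed"`` or ``"solvent"``.  The feed flows in ``+z`` (outlet
    at ``z = L``) and the solvent in ``-z`` (outlet at ``z = 0``).  With
    ``weighted=False`` an unweighted area mean is returned instead (sensitivity
    check only).
    """
    d = _stream_layer_index(problem, plane)
    layer = problem.layers[d]
    dmesh = field.mesh.domains[d]
    j = -1 if plane == "feed" else 0
    c = field.values[layer.name][:, j]
    dA = axial_face_areas(dmesh)
    if weighted:
        u = cell_axial_velocities(layer, dmesh)
        w = np.abs(u) * dA
    else:
        w = dA
    w_sum = w.sum()
    if w_sum <= 0.0:
        raise ValueError(f"zero net flow through the {plane} outlet plane")
    return float((w * c).sum() / w_sum)


def separation_percent(C_inlet: float, C_outlet: float, rtol: float = 1e-6) -> float:
    """Removal percentage ``100 * (1 - C_outlet / C_inlet)``.

    ``C_outlet`` marginally outside ``[0, C_inlet]`` (within ``rtol``) is
    clamped; larger violations indicate a broken solve and raise.
    """
    if C_inlet <= 0.0:
        raise ValueError("inlet concentration must be positive")
    if C_outlet < -rtol * C_inlet or C_outlet > C_inlet * (1.0 + rtol):
        raise ValueError(
            f"outlet concentration {C_outlet} outside [0, {C_inlet}] beyond tolerance"
        )
    sep = 100.0 * (1.0 - C_outlet / C_inlet)
    return float(min(100.0, max(0.0, sep)))


def interface_profile(
    field: ConcentrationField,
    interface: str,
    side: str,
) -> Tuple[np.ndarray, np.ndarray]:
    """Dimensionless axial concentration profile along an interface.

    ``interface`` is ``"r1"`` (between the first two layers) or ``"r2"``
    (between the last two); ``side`` names the layer whose near-interface cell
    row is sampled.  Returns ``(z/L, C/C0)`` with the axial coordinate running
    from the feed inlet (0) to the feed outlet (1); endpoint values follow the
    axial boundary conditions of the sampled layer.
    """
    problem = field.problem
    if interface not in ("r1", "r2"):
        raise ValueError(f"unknown interface {interface!r}")
    pair = (0, 1) if interface == "r1" else (len(problem.layers) - 2, len(problem.layers) - 1)
    d = problem.layer_index(side)
    if d not in pair:
        raise ValueError(f"layer {side!r} does not touch interface {interface!r}")
    row = -1 if d == pair[0] else 0
    layer = problem.layers[d]
    c = field.values[layer.name][row, :]
    if problem.solute is not None:
        C0 = problem.solute.C0
    elif problem.feed_index is not None:
        C0 = problem.feed_layer.bc_z0.value
    else:
        C0 = 1.0
    c0_end = layer.bc_z0.value if layer.bc_z0.kind == "dirichlet" else c[0]
    cL_end = layer.bc_zL.value if layer.bc_zL.kind == "dirichlet" else c[-1]
    z = np.concatenate([[0.0], field.mesh.z_centers, [field.mesh.L]]) / field.mesh.L
    cc = np.concatenate([[c0_end], c, [cL_end]]) / C0
    return z, cc


def _boundary_flux_quadrature(
    field: ConcentrationField, problem: TransportProblem, plane: str, j: int
) -> float:
    """Convective solute flux through one axial plane by independent trapezoid
    quadrature with the analytic velocity profile (per radian), [g/s/rad]."""
    d = _stream_layer_index(problem, plane)
    layer = problem.layers[d]
    dmesh = field.mesh.domains[d]
    rc = dmesh.r_centers
    r = np.concatenate([[dmesh.r_faces[0]], rc, [dmesh.r_faces[-1]]])
    c = field.values[layer.name][:, j]
    c = np.concatenate([[c[0]], c, [c[-1]]])
    v = np.abs(np.asarray(layer.velocity(r), dtype=float))
    return float(trapezoid(c * v * r, r))


def mass_balance_residual(field: ConcentrationField, problem: TransportProblem) -> float:
    """Relative closure error of the solute budget over the three open planes.

    ``|feed_in - feed_out - solvent_out| / feed_in`` with every flux computed
    by quadrature independent of the solver's internal face fluxes, so the
    residual measures genuine discretization error and shrinks on refinement.
    """
    layer = problem.feed_layer
    if layer.bc_z0.kind != "dirichlet":
        raise ValueError("feed inlet is not a fixed-concentration boundary")
    C0 = layer.bc_z0.value
    dmesh = field.mesh.domains[problem.feed_index]
    rc = dmesh.r_centers
    r = np.concatenate([[dmesh.r_faces[0]], rc, [dmesh.r_faces[-1]]])
    v = np.abs(np.asarray(layer.velocity(r), dtype=float))
    feed_in = C0 * float(trapezoid(v * r, r))
    feed_out = _boundary_flux_quadrature(field, problem, "feed", -1)
    if problem.solvent_index is None:
        raise ValueError("mass balance audit requires both streams")
    solvent_out = _boundary_flux_quadrature(field, problem, "solvent", 0)
    return abs(feed_in - feed_out - solvent_out) / feed_in


@dataclass(frozen=True)
class SeparationSummary:
    """Headline numbers of one converged extraction solve."""

    solute: str
    configuration: str
    inlet_concentration: float
    outlet_concentration: float
    separation_percent: float
    mass_balance_residual: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.separation_percent <= 100.0:
            raise ValueError("separation percent out of [0, 100]")
        if self.mass_balance_residual < 0.0:
            raise ValueError("negative mass-balance residual")

    def to_dict(self) -> dict:
        return asdict(self)


def summarize(field: ConcentrationField, problem: TransportProblem) -> SeparationSummary:
    c_out = mixing_cup(field, problem, "feed")
    C0 = problem.solute.C0 if problem.solute is not None else problem.feed_layer.bc_z0.value
    return SeparationSummary(
        solute=problem.solute.name if problem.solute is not None else "?",
        configuration=problem.configuration.value if problem.configuration else "?",
        inlet_concentration=C0,
        outlet_concentration=c_out,
        separation_percent=separation_percent(C0, c_out),
        mass_balance_residual=mass_balance_residual(field, problem),
    )


def _field_frame(field: ConcentrationField) -> pd.DataFrame:
    frames = []
    for dmesh in field.mesh.domains:
        c = field.values[dmesh.name]
        r, z = np.meshgrid(dmesh.r_centers, field.mesh.z_centers, indexing="ij")
        frames.append(
            pd.DataFrame(
                {
                    "domain": dmesh.name,
                    "r": r.ravel(),
                    "z": z.ravel(),
                    "C": c.ravel(),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def _write_vtk_domain(field: ConcentrationField, dmesh, path: str) -> None:
    # legacy ASCII VTK structured grid, one (r, z) sheet per domain
    nz = field.mesh.nz
    nr = dmesh.nr
    c = field.values[dmesh.name]
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\n")
        fh.write(f"concentration field, domain {dmesh.name}\n")
        fh.write("ASCII\nDATASET STRUCTURED_GRID\n")
        fh.write(f"DIMENSIONS {nr} {nz} 1\n")
        fh.write(f"POINTS {nr * nz} double\n")
        for j in range(nz):
            for i in range(nr):
                fh.write(f"{dmesh.r_centers[i]:.9e} {field.mesh.z_centers[j]:.9e} 0.0\n")
        fh.write(f"POINT_DATA {nr * nz}\n")
        fh.write("SCALARS concentration double 1\nLOOKUP_TABLE default\n")
        for j in range(nz):
            for i in range(nr):
                fh.write(f"{c[i, j]:.9e}\n")


def export_field(field: ConcentrationField, path: str, format: str = "csv") -> List[str]:
    """Write the nodal field to disk.

    CSV: one long-format file ``(domain, r, z, C)``.  VTK: one legacy ASCII
    structured-grid file per domain, suffixed with the domain name.  Returns
    the list of files written.
    """
    if format == "csv":
        try:
            _field_frame(field).to_csv(path, index=False)
        except OSError as exc:
            raise OSError(f"could not write field CSV to {path!r}: {exc}") from exc
        return [path]
    if format == "vtk":
        stem, ext = os.path.splitext(path)
        ext = ext or ".vtk"
        written = []
        for dmesh in field.mesh.domains:
            out = f"{stem}_{dmesh.name}{ext}"
            try:
                _write_vtk_domain(field, dmesh, out)
            except OSError as exc:
                raise OSError(f"could not write VTK file {out!r}: {exc}") from exc
            written.append(out)
        return written
    raise ValueError(f"unknown export format {format!r} (expected 'csv' or 'vtk')")
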