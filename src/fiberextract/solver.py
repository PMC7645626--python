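"""Finite-volume discretization and steady solve of the layered transport problem.

The (r, z) rectangle of each annular layer is meshed with a structured,
optionally geometrically graded grid; all layers share one axial grid so that
interface faces coincide.  The discretization is a cell-centered finite-volume
scheme in axisymmetric coordinates (face areas and cell volumes carry the
radial metric), first-order upwind for axial convection (an optional central
scheme is available behind a flag) and two-point fluxes for diffusion.  The
equilibrium jump at the aqueous/organic interface is enforced by eliminating
the interface unknown inside the two-point interface flux, which keeps the
coupling local and exactly conservative.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np
from scipy.sparse import coo_matrix, csr_matrix
from scipy.sparse.linalg import splu

from .geometry_hydro import ContactorGeometry
from .transport_model import DomainLayer, TransportProblem

__all__ = [
    "Resolution",
    "DomainMesh",
    "Mesh",
    "MeshStudyReport",
    "SolverDiagnostics",
    "ConcentrationField",
    "SolverError",
    "SingularSystemError",
    "MeshConvergenceError",
    "graded_faces",
    "build_mesh",
    "cell_axial_velocities",
    "axial_face_areas",
    "assemble",
    "solve_steady",
    "refine_until_converged",
]

# 5-point Gauss-Legendre rule on [-1, 1], used for cell-mean velocities
_GAUSS_X, _GAUSS_W = np.polynomial.legendre.leggauss(5)


class SolverError(RuntimeError):
    """Linear solve failed or produced an invalid field."""

    def __init__(self, message: str, residual_history: Optional[List[float]] = None):
        super().__init__(message)
        self.residual_history = residual_history or []


class SingularSystemError(SolverError):
    """The assembled system is singular (e.g. all-Neumann misconfiguration)."""


@dataclass(frozen=True)
class Resolution:
    """Per-layer radial cell counts, axial cell count, grading ratio, scheme."""

    nr: Tuple[int, ...] = (48, 24, 48)
    nz: int = 200
    ratio: float = 1.15
    scheme: str = "upwind"

    def __post_init__(self) -> None:
        if any(n < 3 for n in self.nr) or self.nz < 3:
            raise ValueError("need at least 3 cells per direction per layer")
        if self.ratio < 1.0:
            raise ValueError("grading ratio must be >= 1")
        if self.scheme not in ("upwind", "central"):
            raise ValueError(f"unknown convection scheme {self.scheme!r}")

    def refined(self, factor: int = 2) -> "Resolution":
        return Resolution(
            nr=tuple(n * factor for n in self.nr),
            nz=self.nz * factor,
            ratio=self.ratio,
            scheme=self.scheme,
        )


def graded_faces(a: float, b: float, n: int, side: str, ratio: float) -> np.ndarray:
    """Face coordinates of ``n`` cells on ``[a, b]`` with geometric grading.

    ``side`` is the boundary toward which spacing shrinks: ``"lo"``, ``"hi"``,
    ``"both"`` or ``"none"`` (uniform).
    """
    if n < 1 or b <= a:
        raise ValueError("degenerate interval or cell count")
    if side == "none" or ratio == 1.0:
        return np.linspace(a, b, n + 1)
    if side == "hi":
        spac = ratio ** (-np.arange(n, dtype=float))
    elif side == "lo":
        spac = ratio ** (-np.arange(n, dtype=float))[::-1]
    elif side == "both":
        n_lo = n // 2
        mid = 0.5 * (a + b)
        left = graded_faces(a, mid, n - n_lo, "hi", ratio)
        right = graded_faces(mid, b, n_lo, "lo", ratio)
        return np.concatenate([left, right[1:]])
    else:
        raise ValueError(f"unknown grading side {side!r}")
    spac *= (b - a) / spac.sum()
    faces = np.concatenate([[a], a + np.cumsum(spac)])
    faces[-1] = b
    return faces


@dataclass(frozen=True)
class DomainMesh:
    """Radial grid of one layer (the axial grid lives on :class:`Mesh`)."""

    name: str
    r_faces: np.ndarray
    r_centers: np.ndarray

    @property
    def nr(self) -> int:
        return self.r_centers.size


@dataclass(frozen=True)
class Mesh:
    """Structured mesh of all layers sharing one axial grid."""

    domains: Tuple[DomainMesh, ...]
    z_faces: np.ndarray
    z_centers: np.ndarray
    L: float

    def __post_init__(self) -> None:
        for a, b in zip(self.domains, self.domains[1:]):
            if not math.isclose(a.r_faces[-1], b.r_faces[0], rel_tol=1e-12):
                raise ValueError(f"domains {a.name!r}/{b.name!r} do not share an interface node")

    @property
    def nz(self) -> int:
        return self.z_centers.size

    @property
    def cell_counts(self) -> Tuple[int, ...]:
        return tuple(d.nr * self.nz for d in self.domains)

    @property
    def total_cells(self) -> int:
        return sum(self.cell_counts)

    def domain(self, name: str) -> DomainMesh:
        for d in self.domains:
            if d.name == name:
                return d
        raise KeyError(f"no mesh domain named {name!r}")


_DEFAULT_GRADINGS = ("hi", "both", "lo")  # tube, membrane, shell


def build_mesh(
    obj: Union[TransportProblem, ContactorGeometry],
    resolution: Optional[Resolution] = None,
) -> Mesh:
    """Mesh a transport problem (or a bare three-layer geometry).

    Radial grading follows each layer's declared ``grading`` side so that the
    finest cells sit against the fluid/membrane interfaces where concentration
    boundary layers form.
    """
    resolution = resolution or Resolution()
    if isinstance(obj, ContactorGeometry):
        spans = [(0.0, obj.r1), (obj.r1, obj.r2), (obj.r2, obj.r3)]
        names = ["tube", "membrane", "shell"]
        gradings = list(_DEFAULT_GRADINGS)
        L = obj.L
    else:
        spans = [(layer.r_lo, layer.r_hi) for layer in obj.layers]
        names = [layer.name for layer in obj.layers]
        gradings = [layer.grading for layer in obj.layers]
        L = obj.L
    if len(resolution.nr) != len(spans):
        raise ValueError(
            f"resolution has {len(resolution.nr)} radial counts for {len(spans)} layers"
        )
    domains = []
    for (r_lo, r_hi), name, grading, n in zip(spans, names, gradings, resolution.nr):
        faces = graded_faces(r_lo, r_hi, n, grading, resolution.ratio)
        centers = 0.5 * (faces[:-1] + faces[1:])
        domains.append(DomainMesh(name=name, r_faces=faces, r_centers=centers))
    z_faces = np.linspace(0.0, L, resolution.nz + 1)
    z_centers = 0.5 * (z_faces[:-1] + z_faces[1:])
    return Mesh(domains=tuple(domains), z_faces=z_faces, z_centers=z_centers, L=L)


def axial_face_areas(dmesh: DomainMesh) -> np.ndarray:
    """Axial (z-normal) face area of each radial cell, per radian of azimuth."""
    rf = dmesh.r_faces
    return 0.5 * (rf[1:] ** 2 - rf[:-1] ** 2)


def cell_axial_velocities(layer: DomainLayer, dmesh: DomainMesh) -> np.ndarray:
    """Signed cell-mean axial velocity per radial cell (Gauss quadrature).

    Cell means are area-weighted, ``int v(r) r dr / int r dr``, so the discrete
    per-fiber volumetric flow matches the analytic one to quadrature accuracy.
    """
    if layer.velocity is None:
        return np.zeros(dmesh.nr)
    rf = dmesh.r_faces
    mid = 0.5 * (rf[:-1] + rf[1:])
    half = 0.5 * (rf[1:] - rf[:-1])
    r_g = mid[:, None] + half[:, None] * _GAUSS_X[None, :]
    v_g = layer.velocity(r_g)
    num = np.sum(_GAUSS_W[None, :] * v_g * r_g, axis=1) * half
    den = 0.5 * (rf[1:] ** 2 - rf[:-1] ** 2)
    return num / den


@dataclass
class LinearSystem:
    """Assembled sparse system with layer offsets into the unknown vector."""

    A: csr_matrix
    b: np.ndarray
    offsets: Tuple[int, ...]
    mesh: Mesh
    problem: TransportProblem


def assemble(problem: TransportProblem, mesh: Mesh, scheme: str = "upwind") -> LinearSystem:
    """Assemble the steady finite-volume system ``A c = b``.

    Axisymmetric metric throughout: radial faces have area ``r_f * dz`` and
    axial faces ``(r_{i+1}^2 - r_i^2)/2`` per radian.  Radial interfaces carry
    diffusion only (velocity is purely axial); the partition jump is folded
    into the interface transmissibility.
    """
    if scheme not in ("upwind", "central"):
        raise ValueError(f"unknown convection scheme {scheme!r}")
    if len(problem.layers) != len(mesh.domains):
        raise ValueError("mesh and problem have different layer counts")
    nz = mesh.nz
    zc = mesh.z_centers
    zf = mesh.z_faces
    dz = np.diff(zf)
    counts = [d.nr * nz for d in mesh.domains]
    offsets = tuple(np.concatenate([[0], np.cumsum(counts)])[:-1].tolist())
    N = sum(counts)

    rows: List[np.ndarray] = []
    cols: List[np.ndarray] = []
    vals: List[np.ndarray] = []
    b = np.zeros(N)

    def add(r, c, v):
        rows.append(np.asarray(r, dtype=np.int64).ravel())
        cols.append(np.asarray(c, dtype=np.int64).ravel())
        vals.append(np.asarray(v, dtype=float).ravel())

    cell_u: List[np.ndarray] = []
    for d, (layer, dmesh) in enumerate(zip(problem.layers, mesh.domains)):
        off = offsets[d]
        nr = dmesh.nr
        rf, rc = dmesh.r_faces, dmesh.r_centers
        D = layer.diffusivity
        dA = axial_face_areas(dmesh)
        u = cell_axial_velocities(layer, dmesh)
        cell_u.append(u)

        def gid(i, j, _off=off, _nz=nz):
            return _off + np.asarray(i) * _nz + np.asarray(j)

        jj = np.arange(nz)

        # --- radial diffusion, interior faces ---
        if nr > 1 and D > 0.0:
            Ti = D * rf[1:-1] / (rc[1:] - rc[:-1])  # (nr-1,)
            g = Ti[:, None] * dz[None, :]  # (nr-1, nz)
            ii = np.arange(1, nr)
            P = gid(ii[:, None] - 1, jj[None, :])
            Q = gid(ii[:, None], jj[None, :])
            add(P, P, g); add(P, Q, -g)
            add(Q, Q, g); add(Q, P, -g)

        # --- radial boundary conditions ---
        if d == 0 and layer.bc_r_lo.kind == "dirichlet" and rf[0] > 0.0 and D > 0.0:
            g = D * rf[0] / (rc[0] - rf[0]) * dz
            P = gid(0, jj)
            add(P, P, g)
            b[P] += g * layer.bc_r_lo.value
        # symmetry/insulation at r_lo: zero flux, no terms (area is 0 on the axis)
        if d == len(problem.layers) - 1 and layer.bc_r_hi.kind == "dirichlet" and D > 0.0:
            g = D * rf[-1] / (rf[-1] - rc[-1]) * dz
            P = gid(nr - 1, jj)
            add(P, P, g)
            b[P] += g * layer.bc_r_hi.value

        # --- axial diffusion, interior faces ---
        if D > 0.0:
            g = (D * dA)[:, None] / (zc[1:] - zc[:-1])[None, :]  # (nr, nz-1)
            ii = np.arange(nr)
            P = gid(ii[:, None], jj[None, 1:] - 1)
            Q = gid(ii[:, None], jj[None, 1:])
            add(P, P, g); add(P, Q, -g)
            add(Q, Q, g); add(Q, P, -g)

        # --- axial convection, interior faces ---
        F = u * dA  # signed volumetric flux per radian, (nr,)
        if np.any(F != 0.0):
            ii = np.arange(nr)
            P = gid(ii[:, None], jj[None, 1:] - 1)
            Q = gid(ii[:, None], jj[None, 1:])
            ones = np.ones(nz - 1)
            if scheme == "upwind":
                Fp = np.maximum(F, 0.0)[:, None] * ones[None, :]
                Fm = np.minimum(F, 0.0)[:, None] * ones[None, :]
                add(P, P, Fp); add(P, Q, Fm)
                add(Q, P, -Fp); add(Q, Q, -Fm)
            else:  # central: distance-weighted face interpolation
                w = ((zc[1:] - zf[1:-1]) / (zc[1:] - zc[:-1]))[None, :]
                Fw = F[:, None] * w * np.ones_like(ones)[None, :]
                F1w = F[:, None] * (1.0 - w)
                add(P, P, Fw); add(P, Q, F1w)
                add(Q, P, -Fw); add(Q, Q, -F1w)

        # --- axial boundaries ---
        for end, bc in (("z0", layer.bc_z0), ("zL", layer.bc_zL)):
            if end == "z0":
                j = 0
                G = -F  # outward volumetric flux per radian through z=0 face
                d_half = zc[0] - zf[0]
            else:
                j = nz - 1
                G = F
                d_half = zf[-1] - zc[-1]
            P = gid(np.arange(nr), j)
            if bc.kind == "dirichlet":
                outflowing = np.maximum(G, 0.0)
                inflowing = np.minimum(G, 0.0)
                add(P, P, outflowing)
                b[P] += -inflowing * bc.value
                if D > 0.0:
                    g = D * dA / d_half
                    add(P, P, g)
                    b[P] += g * bc.value
            elif bc.kind == "outflow":
                add(P, P, np.maximum(G, 0.0))
                # inflow across an outflow plane carries zero concentration
            elif bc.kind in ("insulation", "symmetry"):
                pass

    # --- interface coupling between adjacent layers ---
    for d, iface in enumerate(problem.interfaces):
        inner_layer, outer_layer = problem.layers[d], problem.layers[d + 1]
        inner_mesh, outer_mesh = mesh.domains[d], mesh.domains[d + 1]
        r_if = inner_mesh.r_faces[-1]
        d_in = r_if - inner_mesh.r_centers[-1]
        d_out = outer_mesh.r_centers[0] - r_if
        k = iface.jump  # C_outer = k * C_inner at equilibrium
        if inner_layer.diffusivity <= 0.0 or outer_layer.diffusivity <= 0.0:
            raise SingularSystemError(
                f"interface between {inner_layer.name!r} and {outer_layer.name!r} "
                "requires positive diffusivities on both sides"
            )
        beta = k * d_in / inner_layer.diffusivity + d_out / outer_layer.diffusivity
        jj = np.arange(nz)
        P = offsets[d] + (inner_mesh.nr - 1) * nz + jj
        Q = offsets[d + 1] + 0 * nz + jj
        area = r_if * dz
        T_in = area * k / beta
        T_out = area / beta
        # flux (inner -> outer) = (k*C_in - C_out)/beta per unit area
        add(P, P, T_in); add(P, Q, -T_out)
        add(Q, Q, T_out); add(Q, P, -T_in)

    if not rows:
        raise SingularSystemError(
            "empty system: no diffusion, convection or boundary coupling anywhere"
        )
    A = coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(N, N),
    ).tocsr()
    diag = A.diagonal()
    if np.any(diag == 0.0):
        bad = int(np.flatnonzero(diag == 0.0)[0])
        raise SingularSystemError(
            f"singular system: cell {bad} has no coupling (all-Neumann or "
            "stagnant layer without diffusion)"
        )
    return LinearSystem(A=A, b=b, offsets=offsets, mesh=mesh, problem=problem)


@dataclass
class SolverDiagnostics:
    residual_norms: List[float]
    final_residual: float
    n_unknowns: int


@dataclass
class ConcentrationField:
    """Discrete steady concentration per layer, shape ``(nr, nz)`` each [g/mL]."""

    values: "dict[str, np.ndarray]"
    mesh: Mesh
    problem: TransportProblem
    diagnostics: SolverDiagnostics

    def layer_values(self, index: int) -> np.ndarray:
        return self.values[self.problem.layers[index].name]

    @property
    def max_value(self) -> float:
        return max(float(v.max()) for v in self.values.values())

    @property
    def min_value(self) -> float:
        return min(float(v.min()) for v in self.values.values())


_RESIDUAL_TOL = 1e-10


def _solve_linear(system: LinearSystem) -> Tuple[np.ndarray, List[float]]:
    A, b = system.A, system.b
    b_norm = float(np.linalg.norm(b))
    if b_norm == 0.0:
        b_norm = 1.0  # homogeneous RHS: still factor to detect singularity
    try:
        lu = splu(A.tocsc())
    except RuntimeError as exc:
        raise SingularSystemError(f"sparse factorization failed: {exc}") from exc
    u_diag = np.abs(lu.U.diagonal())
    if u_diag.min() <= 1e-13 * u_diag.max():
        raise SingularSystemError(
            "singular system detected in factorization (all-Neumann misconfiguration?)"
        )
    x = lu.solve(b)
    history = []
    for _ in range(4):  # iterative refinement until the residual contract holds
        r = b - A @ x
        res = float(np.linalg.norm(r)) / b_norm
        history.append(res)
        if res <= _RESIDUAL_TOL:
            break
        x = x + lu.solve(r)
    else:
        r = b - A @ x
        history.append(float(np.linalg.norm(r)) / b_norm)
    if not np.all(np.isfinite(x)):
        raise SolverError("linear solve produced non-finite values", history)
    if history[-1] > _RESIDUAL_TOL:
        raise SolverError(
            f"linear solve stalled at relative residual {history[-1]:.3e} "
            f"(> {_RESIDUAL_TOL:.0e})",
            history,
        )
    return x, history


def solve_steady(
    problem: TransportProblem,
    mesh: Optional[Mesh] = None,
    resolution: Optional[Resolution] = None,
) -> ConcentrationField:
    """Assemble and solve; returns the per-layer concentration field.

    Raises :class:`SolverError` when the residual contract (relative residual
    <= 1e-10) cannot be met or the field violates positivity beyond round-off.
    """
    if mesh is None:
        mesh = build_mesh(problem, resolution)
    scheme = resolution.scheme if resolution is not None else "upwind"
    system = assemble(problem, mesh, scheme=scheme)
    x, history = _solve_linear(system)
    scale = max(float(np.max(np.abs(x))), 1e-300)
    if float(x.min()) < -1e-8 * scale:
        raise SolverError(
            f"negative concentration {x.min():.3e} beyond round-off tolerance", history
        )
    values = {}
    nz = mesh.nz
    for off, dmesh in zip(system.offsets, mesh.domains):
        values[dmesh.name] = x[off : off + dmesh.nr * nz].reshape(dmesh.nr, nz)
    diag = SolverDiagnostics(
        residual_norms=history, final_residual=history[-1], n_unknowns=x.size
    )
    return ConcentrationField(values=values, mesh=mesh, problem=problem, diagnostics=diag)


@dataclass
class MeshStudyReport:
    """Outcome of the uniform-refinement mesh-independence procedure."""

    cell_counts: List[int]
    outlet_concentrations: List[float]
    relative_changes: List[float]
    converged: bool

    def __post_init__(self) -> None:
        if any(b <= a for a, b in zip(self.cell_counts, self.cell_counts[1:])):
            raise ValueError("cell counts must increase monotonically")


class MeshConvergenceError(SolverError):
    def __init__(self, message: str, report: MeshStudyReport):
        super().__init__(message)
        self.report = report


def refine_until_converged(
    problem: TransportProblem,
    tolerance: float = 1e-3,
    max_levels: int = 5,
    base_resolution: Optional[Resolution] = None,
    factor: int = 2,
) -> Tuple[ConcentrationField, MeshStudyReport]:
    """Uniformly refine until the feed-outlet mixing-cup concentration settles.

    Successive levels multiply every cell count by ``factor``; convergence is
    a relative change below ``tolerance`` between consecutive levels.
    """
    from .postprocess import mixing_cup  # local import to avoid a cycle

    if tolerance <= 0.0:
        raise ValueError("tolerance must be positive")
    if base_resolution is None:
        base_resolution = Resolution(nr=tuple(8 for _ in problem.layers), nz=32)
    cells: List[int] = []
    outs: List[float] = []
    changes: List[float] = []
    res = base_resolution
    field = None
    for level in range(max_levels):
        field = solve_steady(problem, resolution=res)
        cells.append(field.mesh.total_cells)
        outs.append(mixing_cup(field, problem, "feed"))
        if level > 0:
            denom = abs(outs[-1]) if outs[-1] != 0.0 else 1.0
            changes.append(abs(outs[-1] - outs[-2]) / denom)
            if changes[-1] < tolerance:
                report = MeshStudyReport(cells, outs, changes, converged=True)
                return field, report
        res = res.refined(factor)
    report = MeshStudyReport(cells, outs, changes, converged=False)
    raise MeshConvergenceError(
        f"outlet concentration not mesh-independent to {tolerance:.1e} "
        f"within {max_levels} levels (last change "
        f"{changes[-1] if changes else float('nan'):.3e})",
        report,
    )
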