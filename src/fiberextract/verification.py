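"""Independent analytic oracles for solver verification.

Three classical benchmarks exercise the discretization through routes that
share no code with the finite-volume path:

* laminar tube mass transfer with a perfectly absorbing wall, checked against
  the eigenfunction series of the confluent Sturm-Liouville problem (computed
  here by shooting, independent of the grid solver);
* steady radial conduction through an annulus, checked against the
  closed-form logarithmic profile;
* the free-surface envelope radius, checked against direct arithmetic and the
  published value;
* global solute conservation on the full extraction problem.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Dict, List, Tuple

import numpy as np
from scipy.integrate import simpson, solve_ivp
from scipy.optimize import brentq

from .geometry_hydro import happel_shell_radius, tube_velocity
from .postprocess import mass_balance_residual, mixing_cup, mixing_cup_axial
from .solver import Resolution, solve_steady
from .transport_model import (
    BoundaryCondition,
    DomainLayer,
    TransportProblem,
)

__all__ = [
    "graetz_eigenpairs",
    "graetz_bulk_series",
    "graetz_sherwood_limit",
    "tube_wall_sink_problem",
    "annulus_conduction_problem",
    "annulus_exact",
    "CheckResult",
    "check_happel_radius",
    "check_graetz",
    "check_annulus",
    "check_conservation",
    "run_all",
]

_ETA0 = 1e-8


def _phi_at_wall(beta: float, dense: bool = False):
    """Integrate the radial eigenfunction ODE from the axis to the wall.

    Equation: ``(eta * phi')' + 2 beta eta (1 - eta^2) phi = 0`` with a
    regular solution at ``eta = 0`` normalized to ``phi(0) = 1``.
    """

    def rhs(eta, y):
        return [y[1] / eta, -2.0 * beta * eta * (1.0 - eta**2) * y[0]]

    sol = solve_ivp(
        rhs,
        (_ETA0, 1.0),
        [1.0, 0.0],
        rtol=1e-11,
        atol=1e-13,
        dense_output=dense,
        method="RK45",
    )
    if dense:
        return sol
    return float(sol.y[0, -1])


@lru_cache(maxsize=8)
def graetz_eigenpairs(n_terms: int = 6) -> List[Tuple[float, float]]:
    """First ``n_terms`` eigenvalues ``beta_n`` and series weights ``w_n``.

    The bulk concentration decays as ``theta_b = sum w_n exp(-beta_n zeta)``
    with ``zeta = D z / (v_mean R^2)``; ``w_n = 2 B_n^2 / N_n`` with
    ``B_n = int_0^1 2 eta (1-eta^2) phi_n``, ``N_n`` the weighted norm.
    """
    pairs: List[Tuple[float, float]] = []
    roots: List[float] = []
    b0, f0 = 0.5, _phi_at_wall(0.5)
    step = 5.0  # smaller than the minimum eigenvalue gap (~18)
    while len(roots) < n_terms:
        b1 = b0 + step
        f1 = _phi_at_wall(b1)
        if f0 == 0.0:
            roots.append(float(b0))
        elif f0 * f1 < 0.0:
            roots.append(float(brentq(_phi_at_wall, b0, b1, xtol=1e-10, rtol=1e-12)))
        b0, f0 = b1, f1
        if b0 > 1e4:  # pragma: no cover - defensive
            raise RuntimeError(f"found only {len(roots)} eigenvalues, wanted {n_terms}")
    eta = np.linspace(_ETA0, 1.0, 4001)
    w_fun = 2.0 * eta * (1.0 - eta**2)
    for beta in roots[:n_terms]:
        sol = _phi_at_wall(beta, dense=True)
        phi = sol.sol(eta)[0]
        B = float(simpson(w_fun * phi, x=eta))
        N = float(simpson(w_fun * phi**2, x=eta))
        pairs.append((beta, 2.0 * B**2 / N))
    return pairs


def graetz_bulk_series(zeta: float, n_terms: int = 6) -> float:
    """Dimensionless bulk concentration at ``zeta`` from the truncated series."""
    return sum(w * math.exp(-beta * zeta) for beta, w in graetz_eigenpairs(n_terms))


def graetz_sherwood_limit(n_terms: int = 1) -> float:
    """Fully developed Sherwood number (equals the smallest eigenvalue)."""
    return graetz_eigenpairs(n_terms)[0][0]


# benchmark geometry for the wall-sink tube: zeta_L = D L / (v R^2) = 0.8
_GRAETZ = dict(R=5e-4, D=1e-9, v_mean=5e-4, L=0.1, C0=1.0)


def tube_wall_sink_problem() -> TransportProblem:
    """Single-layer laminar tube with a perfectly absorbing wall (C = 0 at R)."""
    p = _GRAETZ

    def v(r, _v=p["v_mean"], _R=p["R"]):
        return tube_velocity(r, _v, _R)

    layer = DomainLayer(
        name="tube",
        r_lo=0.0,
        r_hi=p["R"],
        diffusivity=p["D"],
        velocity=v,
        bc_z0=BoundaryCondition("dirichlet", p["C0"]),
        bc_zL=BoundaryCondition("outflow"),
        bc_r_lo=BoundaryCondition("symmetry"),
        bc_r_hi=BoundaryCondition("dirichlet", 0.0),
        grading="hi",
    )
    return TransportProblem(layers=(layer,), L=p["L"], feed_index=0)


def annulus_conduction_problem(
    r_lo: float = 1.1e-4,
    r_hi: float = 1.5e-4,
    C_lo: float = 1.0,
    C_hi: float = 0.2,
    D: float = 1e-10,
) -> TransportProblem:
    """Stagnant annulus with fixed concentrations on both radial boundaries."""
    layer = DomainLayer(
        name="annulus",
        r_lo=r_lo,
        r_hi=r_hi,
        diffusivity=D,
        velocity=None,
        bc_r_lo=BoundaryCondition("dirichlet", C_lo),
        bc_r_hi=BoundaryCondition("dirichlet", C_hi),
        grading="both",
    )
    return TransportProblem(layers=(layer,), L=1e-3)


def annulus_exact(r, r_lo: float, r_hi: float, C_lo: float, C_hi: float):
    """Closed-form radial conduction profile ``C(r) = A + B ln r``."""
    B = (C_hi - C_lo) / math.log(r_hi / r_lo)
    A = C_lo - B * math.log(r_lo)
    return A + B * np.log(np.asarray(r, dtype=float))


@dataclass
class CheckResult:
    name: str
    passed: bool
    measured: float
    expected: float
    tolerance: float
    detail: str = ""


def check_happel_radius() -> CheckResult:
    """Free-surface radius of the base geometry vs the published 3.158e-4 m."""
    r3 = happel_shell_radius(r2=1.5e-4, n=9950, R_module=0.0315)
    expected = 3.158e-4
    rel = abs(r3 - expected) / expected
    return CheckResult(
        name="happel_radius",
        passed=rel < 5e-4,  # agreement to 4 significant figures
        measured=r3,
        expected=expected,
        tolerance=5e-4,
        detail=f"relative deviation {rel:.2e}",
    )


def check_graetz(resolution: Resolution | None = None, n_terms: int = 6) -> Dict[str, CheckResult]:
    """Wall-sink tube vs the eigenfunction series: outlet bulk concentration
    (1% tolerance) and fully developed local Sherwood number (2%)."""
    problem = tube_wall_sink_problem()
    resolution = resolution or Resolution(nr=(64,), nz=800, ratio=1.05)
    fld = solve_steady(problem, resolution=resolution)
    p = _GRAETZ
    zeta_of_z = p["D"] / (p["v_mean"] * p["R"] ** 2)
    zc = fld.mesh.z_centers
    theta = mixing_cup_axial(fld, problem, 0) / p["C0"]

    zeta_out = zeta_of_z * zc[-1]
    theta_exact = graetz_bulk_series(zeta_out, n_terms)
    theta_fv = float(theta[-1])
    rel = abs(theta_fv - theta_exact) / theta_exact
    out = {
        "graetz_outlet": CheckResult(
            name="graetz_outlet",
            passed=rel < 0.01,
            measured=theta_fv,
            expected=theta_exact,
            tolerance=0.01,
            detail=f"relative error {rel:.2e} at zeta={zeta_out:.3f}",
        )
    }
    # local Sherwood from the log-slope of the bulk decay, far downstream
    zeta = zeta_of_z * zc
    j = np.flatnonzero((zeta > 0.45) & (zeta < 0.75))
    slope = np.polyfit(zeta[j], np.log(theta[j]), 1)[0]
    sh_fv = -float(slope)
    sh_exact = graetz_sherwood_limit()
    rel_sh = abs(sh_fv - sh_exact) / sh_exact
    out["graetz_sherwood"] = CheckResult(
        name="graetz_sherwood",
        passed=rel_sh < 0.02,
        measured=sh_fv,
        expected=sh_exact,
        tolerance=0.02,
        detail=f"relative error {rel_sh:.2e} (classical value 3.657)",
    )
    return out


def check_annulus(nr: int = 48) -> CheckResult:
    """Stagnant annulus vs the logarithmic conduction profile (0.1%)."""
    problem = annulus_conduction_problem()
    fld = solve_steady(problem, resolution=Resolution(nr=(nr,), nz=4))
    dmesh = fld.mesh.domains[0]
    layer = problem.layers[0]
    exact = annulus_exact(
        dmesh.r_centers, layer.r_lo, layer.r_hi, layer.bc_r_lo.value, layer.bc_r_hi.value
    )
    num = fld.values["annulus"].mean(axis=1)
    rel = float(np.max(np.abs(num - exact) / np.abs(exact)))
    return CheckResult(
        name="annulus_conduction",
        passed=rel < 1e-3,
        measured=rel,
        expected=0.0,
        tolerance=1e-3,
        detail=f"max relative error {rel:.2e} over {nr} radial cells",
    )


def check_conservation(resolution: Resolution | None = None) -> CheckResult:
    """Solute budget closure on the base extraction case (<= 0.5%)."""
    from .scenarios import table1_case  # deferred: scenarios imports this module's siblings

    case = table1_case("IP")
    resolution = resolution or Resolution(nr=(32, 16, 32), nz=128)
    fld = solve_steady(case.problem, resolution=resolution)
    res = mass_balance_residual(fld, case.problem)
    return CheckResult(
        name="conservation",
        passed=res <= 5e-3,
        measured=res,
        expected=0.0,
        tolerance=5e-3,
        detail=f"mass-balance residual {res:.2e}",
    )


def run_all(verbose: bool = False) -> Dict[str, CheckResult]:
    """Run the full oracle suite; keys map to individual check results."""
    results: Dict[str, CheckResult] = {}
    results["happel_radius"] = check_happel_radius()
    results["annulus_conduction"] = check_annulus()
    results.update(check_graetz())
    results["conservation"] = check_conservation()
    if verbose:
        for res in results.values():
            status = "PASS" if res.passed else "FAIL"
            print(
                f"[{status}] {res.name}: measured={res.measured:.6g} "
                f"expected={res.expected:.6g} ({res.detail})"
            )
    return results
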