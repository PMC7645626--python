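# fiberextract

Steady-state simulator for non-dispersive liquid–liquid extraction of trace
solutes (ibuprofen and 4-isobutylacetophenone from water into octanol) in a
hollow-fiber membrane contactor.

The module bundle is reduced to a single representative fiber with a
concentric free-surface envelope (Happel cell).  On that cell the package
solves the steady axisymmetric convection–diffusion equation over three
coupled annular layers — fiber lumen, porous membrane wall and shell
envelope — with analytic fully developed laminar velocity profiles, an
equilibrium partition jump (`C_org = m · C_aq`) at the aqueous/organic
interface and counter-current feed/solvent streams.  Either stream may carry
the feed (`feed_in_tube` / `feed_in_shell`).

The discretization is a conservative cell-centered finite-volume scheme on a
structured, geometrically graded mesh: first-order upwind convection (an
optional central scheme sits behind a flag), two-point diffusive fluxes, and
the partition jump folded into the interface transmissibility by eliminating
the interface unknown.  The sparse steady system is solved by direct
factorization with iterative refinement to a relative residual of 1e-10.

## Layout

| module | contents |
| --- | --- |
| `fiberextract.geometry_hydro` | Happel cell geometry, packing fraction, free-surface radius, Poiseuille and annular free-surface velocity profiles |
| `fiberextract.transport_model` | solute/membrane specs, boundary and interface conditions, problem assembly for both flow configurations |
| `fiberextract.solver` | graded meshing, finite-volume assembly, steady solve, uniform-refinement mesh-independence procedure |
| `fiberextract.postprocess` | mixing-cup averages, separation %, interface profiles, mass-balance audit, CSV/VTK export |
| `fiberextract.scenarios` | canonical base case, parameter sweeps (flow rate, porosity, fiber count), configuration comparison |
| `fiberextract.verification` | independent analytic oracles: absorbing-wall tube eigenfunction series (Sherwood → 3.657), annular conduction, conservation |

## CLI

```sh
# single case (base parameters, ibuprofen, feed in the fiber lumen)
fiberextract run --solute IP --configuration feed_in_tube --summary-out summary.json

# feed-flow-rate sweep, both solutes, L/min
fiberextract sweep --param Q_aq --values 10,20,30,40,50 --out sweep.csv

# both flow configurations at identical conditions
fiberextract compare --solute 4-IBAP

# analytic oracle suite (exit 0 iff all checks pass)
fiberextract verify
```

`run`, `sweep` and `compare` accept `--config config.yaml` with optional
blocks:

```yaml
solute: IP
configuration: feed_in_tube
flows: {Q_aq_Lmin: 50, Q_org_Lmin: 50}     # whole-module flow rates
membrane: {porosity: 0.40, tortuosity: 2.2}
overrides: {n_fibers: 9950}
numerics: {nr: [48, 24, 48], nz: 200, ratio: 1.15, scheme: upwind}
```

Flow rates are totals for the whole module and are split equally over the
fiber bundle (one Happel cell per fiber).  Everything is deterministic; no
random number generation is used anywhere.

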