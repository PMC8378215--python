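# Methods

`nozzleflow` models the steady, laminar, isothermal flow of shear-thinning
hydrogels through extrusion-bioprinting nozzles, screens nozzle geometries
with a constrained Latin-hypercube design of experiments, attributes the
variation of the maximum shear stress (MSS) to geometric parameters with a
Gaussian-process surrogate, and relates computed MSS to published cell
viability data.  This note records the models, the numerical choices, and
what the tests do and do not establish.

## Physical model

The bioink is a single-phase, incompressible Ostwald–de Waele (power-law)
fluid,

    eta(gamma_dot) = K * gamma_dot^(n-1),        tau = eta * gamma_dot,

with consistency `K` (Pa·s^n) and flow-behaviour index `n` (dimensionless;
`n=1` Newtonian, smaller `n` more strongly shear-thinning).  Built-in
materials (density 1000 kg/m³ each): PF127 (`n=0.127`, `K=406`, typical
drive 200 kPa), Alginate (`n=0.335`, `K=55.7`, 340 kPa) and
Alginate–Gelatin (`n=0.608`, `K=13.3`, 80 kPa).  Cells are not modelled as
a discrete phase; suspended cells much smaller than the nozzle bore leave
the continuum rheology unchanged to leading order.  Temperature dependence,
thixotropy and yield stress are out of scope.

Two nozzle families are parameterized (catalogue ranges in mm: R_small
0.05–0.42, R_middle 1–3.5, R_big 1.5–4.5, L_lower 4–20, L_upper 3–15):

* **blunted** — a barrel of radius `R_big` over `L_upper`, an abrupt
  90° contraction, then a straight tube of radius `R_small` over `L_lower`;
* **conical** — linear tapers `R_big → R_middle` over `L_upper` and
  `R_middle → R_small` over `L_lower`, with the validity constraint
  `R_small < R_middle < R_big`.

The true wall contour of commercial nozzles (fillets, shoulder angles) is
not published; the linear-taper/step idealization is the simplest shape
consistent with the five parameters.

The drive is either a fixed static pressure difference `delta_p` between
inlet and outlet or a fixed volumetric flow rate `Q`.  MSS — the domain
maximum of `eta*gamma_dot` — is the damage surrogate of interest.

## Solvers

### Analytic tube (`nozzleflow.pipe`)

Fully developed power-law Poiseuille flow in a straight tube:
`tau_w = dp·R/(2L)`, `V = n/(3n+1) (dp·R/(2KL))^(1/n) R`, `Q = pi R² V`,
with the exact inverse `dp(Q)` and the analytic velocity profile.  It is
the oracle for both numerical solvers and the classical "lower tube only"
estimate used across the experimental literature.

### Quasi-1D nozzle model (`nozzleflow.reduced`)

Lubrication approximation: at each axial station the wall stress takes the
locally fully developed value `tau_w(z) = K((3n+1)Q/(n·pi·R(z)³))^n` and
the pressure gradient is `2 tau_w/R`.  Because exit velocities reach tens
of m/s, a mechanical-energy (kinetic) term
`alpha(n)·rho/2·(V_out² − V_in²)` is added, with `alpha(n)` the
kinetic-energy flux correction of the fully developed profile
(`alpha(1)=2`, `alpha→1` for plug flow; closed form in `alpha_energy`).
The true correction lies between the plug and fully developed values
because profiles do not fully redevelop after a contraction; both variants
are available (`alpha_mode`).  No empirical entrance-loss coefficient is
added — fitting one against the 2D solver would make the two solvers
circular.  Pressure-driven solves invert `dp(Q)` by bracketed root finding
on log Q (the map is strictly increasing); 400 stations by default
(midpoint rule; the integral is smooth).

Two documented consequences of this construction:

* the quasi-1D MSS is the fully developed wall value — a **lower bound**
  on the 2D MSS, which adds developing-flow and corner concentration;
* at constant pressure the blunted MSS-vs-`R_small` trend rises over most
  of the catalogue range but rolls over mildly at the largest bores, where
  the kinetic-energy share dominates; the 2D solver keeps rising.

### Axisymmetric finite-volume solver (`nozzleflow.fvm`)

Steady incompressible momentum + continuity in (r, z) with rotational
symmetry, discretized finite-volume on a staggered (MAC) rectilinear grid:
axial velocity on axial faces, radial velocity on radial faces, pressure
at cell centres.  The wall is a staircase of cell edges following R(z).
Convection is first-order upwind; viscous terms use the full stress
divergence (shear plus extensional and hoop components) with `eta`
evaluated from the second invariant of the strain-rate tensor at cell
centres and corners.  Because `eta → ∞` as `gamma_dot → 0` for `n < 1`,
the shear rate is floored at `gamma_dot_min = 1e-3 s⁻¹`; MSS moves by
less than 1% when the floor varies between 1e-2 and 1e-4 s⁻¹ (tested).

The nonlinear system is solved by Picard iteration: viscosity and
convecting mass fluxes are lagged, and the *coupled* linear system
(velocities + pressure) is assembled sparse and solved directly each
iteration.  The staggered arrangement is inf-sup stable, so no pressure
stabilization is needed and every iterate satisfies discrete continuity
exactly; convergence is monitored on the relative change of the velocity
field and the flow rate (default 1e-5).  A segregated pressure-correction
scheme was considered and rejected: at these problem sizes the direct
coupled solve converges in 20–60 outer iterations where a segregated loop
needs thousands.  Under-relaxation hooks remain for stiff cases but the
laminar regimes of interest (generalized Metzner–Reed Reynolds numbers up
to ~800; a warning fires above 2000) converge with pure Picard.
Initialization uses the quasi-1D solution (plug profiles carrying its
flow rate), which is also how pressure-driven cases get a bracket-free
start.  The iteration is deterministic: repeated runs are bit-identical.

Boundary conditions: no-slip staircase walls, symmetry at r=0, fixed
static pressures (inlet `delta_p`, outlet 0) in pressure mode, uniform
plug inflow with outlet pressure 0 in flow-rate mode (the inlet sits in
the wide barrel where the profile choice is immaterial).

**Meshing.** Default fine spacings are 0.005 mm radial × 0.010 mm axial —
the reference resolution for reported stresses — applied in a radial fine
zone extending to 1.6× the exit radius and in axial bands at the
contraction and before the outlet; elsewhere spacings grow geometrically
(ratio 1.15, axial cap 0.4 mm).  A uniform-grid mode exists for oracle
studies.  Meshes refuse fewer than 4 cells across the exit radius.

**Stress reporting.** `summarize` takes MSS as the maximum of
`eta*gamma_dot` over cell centres and over the wall-shear profile, where
the wall profile uses the same half-cell one-sided gradient the discrete
no-slip condition imposes (the value a `snGrad`-style post-processor would
read).  Two mesh-dependence regimes matter and are handled differently:

* the **blunted step corner** is a re-entrant singularity — its MSS grows
  without bound under refinement (measured 1.62/1.66/1.84 kPa at
  dr = 7.5/5/2.5 µm for the reference blunted case), so it is only
  meaningful *at* the reference spacing, where it is reported;
* the **conical exit** stress is a developing-boundary-layer maximum that
  converges from below (measured 8.95/9.79/10.55/10.94 kPa at
  dr = 7.5/5/3.3/2.5 µm; first-order Richardson limit ≈ 12 kPa).  A
  staircase wall at a given spacing resolves the wall less faithfully
  than a wall-aligned mesh at the same spacing, so converged comparisons
  for this case use a refined wall (dr = 2 µm).

`grid_refinement_study` automates such sweeps and reports a
Richardson-extrapolated flow rate.

**Exit viscosity.** The reported outlet kinematic viscosity is the
apparent viscosity at the *area-averaged outlet shear rate* divided by
density.  A direct area average of `eta` itself is dominated by the
near-axis region where the shear rate vanishes and the power law
diverges, making that statistic a function of the regularization floor
rather than of the flow; the chosen statistic is floor-insensitive.

## Design of experiments (`nozzleflow.doe`)

Latin-hypercube designs over the catalogue box: one value per
equal-probability bin per parameter, maximin-selected among 50 random
candidates (scaled coordinates), deterministic given a seed.  Conical
designs violating `R_big > R_middle` are repaired by re-permuting the
pairing of the `R_big` column (random re-pairing with a sort-matching
fallback, which is always feasible for the catalogue ranges) — values are
never redrawn, so every 1-D projection keeps exactly one point per bin.
Campaigns evaluate each design with a chosen solver (quasi-1D by default:
1,200 solves run in well under a minute; the 2D solver is available for
subsets) under the material's customary pressure; failures are recorded
per-row and more than 5% of them abort the campaign.

## GP sensitivity (`nozzleflow.gp`)

A stationary anisotropic squared-exponential GP with a fitted nugget,
inputs scaled to [−1, 1] over the design ranges, response standardized;
hyperparameters maximize the marginal likelihood from multiple restarts
(fixed seed).  A treed/fully Bayesian GP would add hyperparameter
posterior spread but the campaign responses are smooth (held-out R² >
0.99), and the questions asked of the surrogate — effect shapes and
relative importance — are insensitive to that refinement.

Main effects are Monte-Carlo averages of the predictive mean over the
other inputs drawn independently uniform on the scaled box (≥ 2,000 draws),
centred over the grid, with a 90% band from the averaged predictive sd.
Sobol first-order and total indices use the Saltelli pick-freeze
estimators applied to the predictive mean under the same product measure,
with bootstrap spreads (≥ 100 resamples).  The uniform product measure
ignores the conical truncation `R_big > R_middle`; the constraint removes
a corner of the box that the fitted surrogate extrapolates into, which is
acceptable for ranking purposes and is the conventional choice.
Parameters are ranked by total index, flagged negligible below 0.05, ties
broken by declaration order.

## Viability linkage (`nozzleflow.viability`)

A packaged fixture tabulates ten published studies (bioink `K`, `n`,
drive, blunted-nozzle size, lower-tube length, reported MSS and live-cell
percentage; two rows lack parameters needed for simulation and are
flagged).  Each simulatable study is re-simulated at its drive endpoints;
a pressure range starting at zero contributes an unprinted (2D-control)
point with MSS 0.  Reported ranges are assumed aligned by severity
(low-stress endpoint ↔ high-viability endpoint).  The nozzle-size column
is interpreted as the bore **diameter** by default: under that reading the
flow-driven rows reproduce their printed stresses essentially
digit-for-digit from the closed form, while the radius reading is off
several-fold; a `nozzle_policy="radius"` switch preserves the alternative.
Missing barrel dimensions default to R_big 3.5 mm / L_upper 4 mm
(catalogue-typical).  The association is quantified per study (endpoint
trend; Spearman where ≥ 3 points exist) and pooled by cell class; no
cell-specific damage model is fitted — the module quantifies association
only.  Residence-time effects, repeatedly flagged in this literature as a
co-factor, are not modelled.

## What the tests show — and what they cannot

The oracle suite establishes that the 2D solver reproduces closed-form
power-law tube flow (flow rate, wall stress, velocity profile) within 2%
across `n` from 0.127 to 1 at dr = R/50, conserves mass through every
cross-section to 0.5%, and is deterministic.  The campaign and GP suites
establish the qualitative structure — conical nozzles reach higher
stresses and flows than blunted ones; exit radius, lower length and (for
conical) middle radius dominate MSS while entrance radius and upper length
are inert — and exact reproducibility given seeds.  None of this validates
the rheological model itself against a physical ink: real bioinks are
viscoelastic, thixotropic and temperature-sensitive, the single-phase
assumption ignores local cell-scale stress amplification, and the
staircase wall limits pointwise stress accuracy near corners (quantified
above).  Comparisons with the published single-nozzle table carry
20–30% bands for exactly these reasons.

## Reference-case discrepancies worth knowing about

* The published flow rate for the blunted R_small = 0.05 mm case
  (0.57 µL/s at 340 kPa) is irreconcilable with the stated geometry: the
  closed form for the lower tube alone gives 1.03 µL/s, and at Re ≈ 0.1
  barrel and entrance losses are negligible (the 2D solver gives
  1.01 µL/s, grid-converged 0.99).  The package reports its computed
  value.
* The published campaign maximum for blunted Alginate (12 kPa) includes
  developing-flow/corner enhancement that the quasi-1D campaign solver
  excludes by construction; its campaign maximum (≈ 4.3 kPa) should be
  read as the fully developed lower bound.
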