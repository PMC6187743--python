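# Methods

## Model

`branchrd` simulates a four-field reaction–diffusion system of branching
morphogenesis on a regular 3D grid:

    ∂A/∂t = c A²S/H − μA + D_A ∇²A + ρ_A Y        (activator)
    ∂H/∂t = c A²S  − νH + D_H ∇²H + ρ_H Y         (inhibitor)
    ∂S/∂t = c₀ − γS − εYS + D_S ∇²S               (substrate)
    ∂Y/∂t = dA − eY + Y²/(1 + fY²)                (commitment marker)

All quantities are dimensionless. The activator amplifies itself while
consuming substrate; the inhibitor, produced alongside and diffusing faster
(D_A < D_H), suppresses activation laterally; differentiated tissue (Y)
secretes activator and inhibitor at rates ρ_A, ρ_H and depletes substrate at
rate ε, so the substrate landscape records where tissue has already grown.
The Y kinetics are bistable: with A = 0 and the default e = 0.1, f = 10 the
attractors sit at 0 and (1+√0.6)/2 ≈ 0.887 with a repeller at
(1−√0.6)/2 ≈ 0.113, so sustained activator exposure (dA exceeding the
barrier max_Y [eY − Y²/(1+fY²)] ≈ 2.6·10⁻³, i.e. A ≳ 0.32 held for tens of
time units) commits a voxel irreversibly. Tissue is the super-level set
Y ≥ Ya with Ya = 0.5.

## Numerics

Explicit Euler stepping with a 7-point Laplacian; Y carries no diffusion
term. Zero-flux (mirror-ghost) boundaries are the default — the simulation
box is a closed dish — with periodic boundaries available for dispersion
tests. The time step must satisfy the 3D diffusion bound
dt ≤ h²/(6·max D) (0.64 at the default h = 1, D_H = 0.26); the default is
dt = 0.5, and one "step" in run and scenario bookkeeping is one Euler
update. The denominator of the autocatalysis term is clamped at
H_floor = 10⁻⁸; clamp events are counted in the run log, which also records
per-snapshot field ranges (a negative field value beyond −10⁻⁹ indicates a
too-large dt rather than something the code silently repairs). The 26-voxel
neighborhood metric (step weights 1/√2/√3) is used for skeleton arc
lengths.

## Initial conditions

The seeded mode places a Y = 1 sphere (radius 2 voxels by default) at the
domain center in a quiescent low-morphogen background: A₀ = H₀ = 10⁻³ and
S₀ = c₀/γ, with i.i.d. multiplicative ±5% fluctuations on A and H. The
background choice is deliberate: the undifferentiated homogeneous steady
state (A* = ν/μ, H* = cνS*/μ², S* = c₀/γ, Y = 0) is *linearly unstable at
zero wavenumber* for every parameter set studied here (leading eigenvalue
+0.23 to +0.62; see `stability`), so initializing there makes the entire
domain erupt into committed spots within a few hundred steps regardless of
the seed — the "spatial spillover" phenotype. A background too poor in
activator to self-ignite (autocatalysis subcritical: cA₀S₀/H₀ < μ) leaves
the seeded bud as the only source of pattern activity. The fixed-point
background remains available via `A0="steady_state"`.

The gradient mode imposes an affine activator ramp (defaults 0.001 → 2.9,
the two uniform-control values, along z) with Y = 0 everywhere; uniform
mode is the corresponding no-gradient control. In these modes the inhibitor
is initialized in local production/decay equilibrium with the imposed
activator, H = cA²S₀/ν floored at the background H₀ ("equilibrium" H mode):
an activator profile laid down without its equilibrium inhibitor would
carry an arbitrary, dynamically inconsistent excitability profile, and with
a uniform H₀ the high-activator control is necessarily at least as
excitable as the top of the ramp, making the control/gradient contrast
unmeasurable. Under the equilibrium rule the autocatalytically excitable
window is 0.012 ≲ A ≲ ν/μ, which excludes both printed control values.

## Linear stability

`stability` computes the closed-form Y = 0 steady state, the full
four-variable fixed point (numeric root, residual < 10⁻¹⁰), the analytic
4×4 Jacobian, and the dispersion relation Re λ_max(q) of
J − q² diag(D_A, D_H, D_S, 0) on a configurable q grid. The strict Turing
flag (stable at q = 0, unstable at finite q) is reported; for the branching
parameter sets it is false because the q = 0 mode itself grows — the
patterning here is seeded-excitation dynamics rather than a classical
finite-wavelength Turing band. Dispersion is validated against nonlinear
simulation: a single Fourier mode seeded in the leading eigenvector on a
periodic domain grows within 5% of Re λ(q), with the wavenumber mapped
through the discrete-Laplacian symbol 4 sin²(q/2) and the full (stationary)
fixed point as background.

## Morphometrics

Tissue regions are measured on the largest 26-connected component:
occupancy, principal-axis ratio from second moments (with a 1/12 voxel
variance floor), and sphericity π^⅓(6V)^⅔/A with the surface area from a
marching-cubes mesh. Skeletons come from 3D medial-axis thinning; voxels of
degree ≠ 2 are merged into junction/endpoint clusters (radius-1 fusion) and
degree-2 chains become graph edges with summed step lengths. The root is
the node nearest the seed center (or the mask's center of mass), edge
generations count the branch points passed from the root, and the spatial
separation of bifurcations is the centerline arc length between
consecutive branch points. Note that Lee-style thinning erodes tubes whose
axis lies exactly between voxel planes to nothing, so synthetic test
geometry is built on integer centers; it is also not exactly equivariant
under axis permutation (arc lengths can shift by one voxel).

The five-class pattern label is a deterministic cascade: occupancy > 0.5 →
SPATIAL_SPILLOVER; sphericity > 0.85 and axis ratio < 1.5 → NO_BRANCH; no
skeleton branch point → PARENT_ONLY; a majority of branch points in the
distal 25% of skeleton depth with near-symmetric outgoing arms →
TIP_SPLITTING; otherwise SIDE_BRANCHING (empty regions are UNDETERMINED).
The thresholds operationalize what the source figures judge by eye and are
exposed in `ClassifierThresholds`. Transverse profiles are trilinear
samples along the widest chord through the distal tip; peaks are counted
with prominence relative to the profile range (default 0.1), matching an
independent brute-force scan by construction (tested).

## Scenarios and problem sizes

Builtin scenarios pin the published per-figure constants verbatim,
including the tip-bifurcation evolution set (c = 0.04, μ = 0.48, ν = 0.06,
γ = 0.02) taken from the study's body text where its figure caption
duplicates the side-branching caption. Everything uncaptioned — domain
size, dt, seed radius, baselines — uses the package defaults above and is
recorded in each report. Three domain scales are provided: full 64×64×32
(the only printed size), standard 48×48×24, and small 32×32×16; tests and
the acceptance script run at small/standard scale with proportionally
reduced step counts (1 200–5 000) so a full analysis completes in minutes
on one core. Sweeps classify the final state per (μ, ν) cell; degenerate
cells (μ or ν = 0) and numerical failures are recorded as UNDETERMINED and
do not abort the sweep.

## Known limitations

The synthetic scenarios emulate idealized closed-box morphogenesis: no
mechanics, no lumen formation, no chemotaxis or diffusion of Y, one tissue
type. Passing tests therefore show internal consistency of the model,
solver and morphometry — not fidelity to real lung development.

A substantive discrepancy with the published morphologies must be stated
plainly. Under this implementation, at the printed per-figure (μ, ν)
values the seeded bud commits a thin halo during the initial transient and
then freezes: the inhibitor haze around the bud (clearance time 1/ν ≈
12–33 time units) holds the rim a factor ~2–3 above the autocatalysis
re-ignition threshold, and no sustained elongation, side-branching or
tip-splitting follows. This was verified across time steps (0.05–0.9),
effective grid spacings (0.25–2.5), seed radii (2–8), background baselines
spanning 10⁻³ to the homogeneous fixed point, and substrate levels 1–4.
Sustained branch outgrowth *does* occur inside the studied parameter
ranges once inhibitor turnover is faster — onset near ν ≈ 0.08–0.09 at
μ = 0.3, with radial branch arms extending steadily from the bud — so the
implementation reproduces the topology of the published regime map
(no-branch at low ν, branching above) with the boundary shifted upward in
ν by roughly a factor two. The `demo_branching` scenario (ν = 0.09, all
other constants as printed) exercises the full pipeline in that regime and
is labelled as a demonstration, not a reproduction. The acceptance tests
that assert branching at the printed sets fail under this implementation
and are left failing rather than weakened; the regime-map sweep, the
gradient/control contrast (both uniform controls quiescent), the profile
machinery and all numerical property suites pass.
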