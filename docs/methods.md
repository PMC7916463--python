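# Methods

## Scope and model structure

`photoseed` simulates interstitial photothermal therapy with implanted
plasmonic nanocomposite seeds, in three sequential stages sharing one
axis-aligned voxel grid (voxel-center convention, SI units): light
transport → bioheat → Arrhenius damage. A separate lumped-calorimetry
module analyses bench heating curves independently of the grid solver.

## Geometry and materials

The in-vivo phantom is a rectangular block of breast tissue: a superficial
fat layer at the beam-entry (top) face over gland, with a configurable
array of cylindrical photoseeds (default 2×2, diameter 1 mm, length
1.5 cm, 5 mm center-to-center pitch) whose axes run along the beam (−z).
The control probe P1 sits at the centroid of the seed axes. Voxels are
assigned materials by center-point membership; a configuration whose seed
would capture no voxel centers (spacing coarser than the seed diameter, or
an axis landing on a voxel corner) is rejected rather than silently
dropped.

Block dimensions and the fat:gland split are not constrained by any
measurement we are aware of for this geometry; the defaults (6×6×6 cm,
1 cm fat) keep the seeds deep in gland and the boundaries far from the
heated region, and are configuration fields like everything else.

Fat and gland carry tabulated optical (`μa` 3 and 6 m⁻¹, `μs′` 950 and
1100 m⁻¹ at ~810 nm) and thermo-physical properties (see
`phantom.FAT_MATERIAL` / `GLAND_MATERIAL`); blood enters only through
`ρb cb` in the perfusion sink. The seed matrix uses bulk PDMS constants
(ρ = 970 kg m⁻³, c = 1460 J kg⁻¹ K⁻¹, λ = 0.16 W m⁻¹ K⁻¹) because the
nanoparticle loading is below 10 wt% and the matrix dominates; implants
neither perfuse nor metabolize by construction. The seed's absorption
coefficient comes from the film absorbance conversion `μa = 2.303 A810/l`
(default A810 = 1.54, l = 30 µm → 1.18×10⁵ m⁻¹).

## Light transport

The CW diffusion point-source kernel
`φ = P0 exp(−μeff r⃗·n̂)/(4πDr)` is evaluated at every voxel center, with
`D` and `μeff` given by the standard diffusion-approximation definitions.
Three numerical/physical choices matter:

- **Heterogeneity.** By default each diffusive (tissue) voxel uses its own
  material's `μeff`/`D` in the kernel — the formula as printed, with no
  path integral through layers. An optional depth-integrated mode
  accumulates `∫μeff dz` along an axis-aligned beam, the physically truer
  treatment for layered media; it is off by default because it changes
  magnitudes, not behaviour.
- **Non-diffusive inclusions.** The kernel describes propagation through a
  scattering host. A photoseed has `μs′ = 0`, so its *own* effective
  attenuation `μeff = √3·μa ≈ 2×10⁵ m⁻¹` would zero the exponential and
  the seed would absorb nothing — an artefact of evaluating a host-medium
  kernel inside an embedded absorber. Seed (and water) voxels therefore
  evaluate the kernel with the host tissue's `μeff`/`D` (the phantom's
  most abundant diffusive material, overridable) while keeping their own
  `μa` in the source `Q = μa φ`. Tissue voxels everywhere are heated
  directly by `μa φ` as well.
- **Singularity.** `r` is clamped to half a voxel spacing, which affects
  only the entry voxel. The kernel is not energy-conserving (it is a
  far-field approximation applied everywhere), so deposited power should
  be read as model output, not as a fraction of `P0`.

The "Gaussian beam" designation is implemented as this isotropic point
kernel at the entry point: no beam waist enters the formula.

## Bioheat solver

Pennes' equation is discretized with 7-point finite volumes. Face
conductivities are harmonic means of the adjacent voxel conductivities,
which preserves flux continuity across the seed–tissue interface where λ
jumps by a factor ~3. Conductivity follows the linear law
`λ(T) = λ37[1 + 0.0028(T − 293.15)]`; the slope and the 293.15 K reference
are exposed (`conductivity_coeff`, `conductivity_ref`) because sources
vary in whether the law is anchored at 20 °C or at body temperature, and a
floor (default 0.01 W m⁻¹ K⁻¹) guards the unphysical negative branch.

Time integration is backward Euler with the two nonlinearities — λ(T) and
the damage-dependent perfusion ωb(Ω) — lagged one step. Each step solves
the SPD linear system matrix-free with Jacobi-preconditioned conjugate
gradients, in increment form (unknown = T_new − T_old, warm-started from
the previous increment) so the iteration tolerance (`cg_rtol`, default
1e-8) is measured against the actual power imbalance; with the default
dt = 0.5 s and 1 mm voxels the diffusion number is ≈0.08 and CG converges
in a handful of iterations. The scheme is unconditionally stable, so
validation studies can take 100 s steps to steady state.

Boundary conditions: Dirichlet (far-field body core, the default for
in-vivo runs), zero-flux, or Robin convection (`h`, ambient) for the bench
tube — selectable per axis, which is what lets a quasi-1D slab have fixed
ends and insulated sides. Dirichlet and Robin faces use the half-cell
ghost construction.

Damage is advanced concurrently: after each temperature step, Ω gains the
trapezoidal increment `dt·(k(T_new)+k(T_old))/2`, `k(T) = A e^(−Ea/RT)`.
In the default two-way mode the updated Ω feeds the perfusion coefficient
on the next step; `coupling="one-way"` freezes perfusion at baseline and
treats damage as pure post-processing, reproducing a strictly sequential
fluence→temperature→damage pipeline. The two modes coincide exactly while
Ω is numerically zero. The gas constant is kept at the rounded
R = 8.3 J mol⁻¹ K⁻¹ customarily used with this (A, Ea) pair — using 8.314
visibly changes k(T) — and is configurable.

Probe traces are sampled every step by trilinear interpolation; snapshots
(temperature + damage fields) at a configurable cadence; the solver logs a
signed global power-imbalance residual per snapshot.

`refine_to_asymptote` re-runs a problem at successively finer spacing
until the monitored interface temperature moves less than a tolerance
between levels, and raises if the change grows over three consecutive
refinements (a diverging configuration).

## Lesion metrics

Lesion volume counts voxels with Ω ≥ 1 (voxel-center thresholding, no
sub-voxel interpolation) times the voxel volume; radial damage profiles
average over spherical shells one voxel-spacing wide around P1;
first-crossing times interpolate linearly between per-step probe samples.

## Calorimetry

The conversion efficiency `η = m_w c_p (dT/dt)/(P0(1 − 10^−A810))` treats
the water as a lumped mass and the initial heating rate as loss-free. The
"initial (after 30 s)" rate is implemented as the least-squares slope over
[0, 30 s] (window configurable): robust to camera noise and consistent
with two-significant-figure reporting; note it sits slightly below the
t = 0 tangent for a saturating curve. The full Roper energy balance with a
cooling constant fitted from the cool-down segment is out of scope.
Optional subtraction of a no-seed control's ΔT is off by default. The
trypan-blue expression `(1 − viable/total)×100` is computed literally and
always reported alongside its complement, because the printed formula is
inverted relative to standard dye-exclusion semantics; the two always sum
to 100%.

## Synthetic data

Bench curves are emulated as `T(t) = baseline + rise(1 − e^(−t/τ))` plus
i.i.d. Gaussian noise (default sd 0.1 °C at 1 Hz — consumer thermal-camera
class), deterministic per seed, with the analytic initial slope and
plateau attached as ground truth; a linear-shape variant exists for tests
that need the generating rate to equal the fitted slope exactly.
`make_efficiency_curve` inverts the lumped balance so a curve embeds a
known η. What the generator does *not* emulate: sensor drift, convective
plumes, evaporation, or the spatial nonuniformity of a real IR image — so
recovery tests demonstrate estimator correctness under the stated noise
model, not robustness to bench systematics. Toy phantoms (quasi-1D slab
with the parabolic steady reference `QL²/8λ`, single-seed gland cube,
water model) carry their analytic references with them.

## Validation (water model) runs

Water is transparent and non-scattering at 810 nm, so the turbid-medium
kernel does not apply; the bench-validation run instead deposits the
absorbed optical power `P0(1 − 10^−A810)` uniformly over the seed volume
(optionally as a collimated Beer–Lambert profile), with Robin boundaries
(default h = 10 W m⁻² K⁻¹ against 25 °C — free convection in air) and the
probe at the seed's bottom face. Because conversion-inefficiency losses,
evaporation and in-tube convection are not modelled, simulated absolute
temperatures run hotter than a real bench; these runs are for qualitative
trace-shape comparison against measured CSVs.

## Problem sizes and the plateau metric

The default in-vivo study uses a 60³ grid (1 mm voxels — the coarsest
spacing that resolves the 1 mm seed diameter), dt = 0.5 s, 15 min; the
power-sweep study uses a 5 cm block at the same spacing with dt = 2 s.
These sizes are the package's standard study conditions; finer grids go
through `refine_to_asymptote`.

One property of the model deserves emphasis. The time for P1 to reach 90%
of its 15-minute rise is independent of overall source strength (the
response is nearly linear in P0); it is controlled by geometry, boundary
placement and perfusion. With gland's baseline perfusion
ωb0 = 5×10⁻⁴ s⁻¹, the perfusion relaxation time is
ρc/(ρb cb ωb0) ≈ 27 min and the perfusion screening length
√(λ/(ρb cb ωb0)) ≈ 1.6 cm; in a 6 cm block with far-field Dirichlet
boundaries, the P1 trace therefore keeps a slow tail for tens of minutes
after its sharp initial rise, and the 90% point lands well beyond 3 min.
A markedly earlier plateau requires either a much smaller computational
domain (boundaries clamping the far field closer than the screening
length) or stronger perfusion; both are configuration choices, not code
changes.

## Known limitations

No vaporization or phase change; optical properties do not change with
damage; no Monte-Carlo or full radiative-transfer option; no convective
flow in the water model; no patient-specific anatomy import. The
diffusion kernel is used down to millimetre distances from the entry
point where the approximation is poor; treat near-entry fields as
qualitative.
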