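# Methods

`fpfdm` simulates susceptibility-induced transverse relaxation (ΔR2, ΔR2*)
and dynamic susceptibility-contrast (DSC) MRI signals from explicit 3D
tissue models.  The pipeline is: build a tissue structure (continuous
primitives → labeled voxel grid) → compute the induced magnetic field shift
(FFT perturber convolution) → evolve the transverse magnetization
(matrix/stencil finite-difference Bloch-Torrey solver, or a Monte-Carlo
random walk as an independent reference) → extract signals, relaxation-rate
changes and dose-response slopes; a kinetics layer drives the whole chain
with contrast-agent concentration curves to synthesize S/S0 time series.

Internal units: lengths in µm, times in ms, fields in Tesla.  The proton
gyromagnetic ratio is γ = 2.675×10⁵ rad·ms⁻¹·T⁻¹.

## Tissue models

The simulation universe is a periodic cube of edge `box_size` (µm),
discretized into N³ voxels.  Each voxel carries one label: 0 = extravascular
extracellular space (EES), 1 = intravascular, 2 = intracellular.
Voxelization tests the voxel *center* against each primitive (binary
indicator; no partial volume), wraps finite primitives across the periodic
faces, and resolves collisions with precedence intravascular > intracellular
> EES.

**Random cylinders** (vessel model): infinite cylinders with uniformly
random axes and positions are added until the voxelized vascular fraction
first reaches the target (2% by default).  **Sphere packings**: random
sequential addition with rejection (feasible up to the RSA saturation
fraction ≈ 0.38), or a face-centered-cubic lattice (limit π/√18 ≈ 0.74)
thinned at random to the target fraction.  **Ellipsoid packings**: cells default to
mildly prolate spheroids (transverse/long axis ratio uniform in [0.6, 0.9];
configurable) with equivalent-sphere radius within ±10% of the requested
mean — strongly flattened cells would shrink the smallest structural
dimension and with it the diffusion-sensitive spin-echo relaxivity.  Packing uses
collective rearrangement: particles start at a reduced scale, overlapping
pairs — detected with the exact algebraic separation test on the pencil of
the two quadrics (two distinct positive generalized eigenvalues ⇔ disjoint)
— are pushed apart along their center line, and the scale is inflated
stepwise to 1.  Two ingredients are essential above the sphere
random-close-packing fraction: an orientational response (each overlapping
ellipsoid rotates its long axis away from the contact direction) and an
annealed push floor (large kicks early, vanishing near convergence, with a
slight deflate-and-regrow step when jammed).  Fractions up to ~0.65 are
reached routinely; convergence time is heavy-tailed across random initial
arrangements, so a stalled arrangement is redrawn (deterministically from
the seed) up to three times.  **Cells around vessels**: the same packer with
the vascular scene as fixed obstacles; a conservative clearance test keeps
every cell's support half-width (its extent along the line to the vessel
axis) away from each vessel, so cells never intersect vessels.  This
iterative route works at moderate cell fractions; the very dense leakage
model described below uses a lattice construction instead.

**Fractal vascular networks**: a root segment bifurcates recursively; at
every junction the daughter radii satisfy Murray's law
r_p³ = r_d1³ + r_d2³ exactly, with the daughter ratio (bifurcation index)
drawn from a configurable range.  Daughter directions deviate from a
reference axis by a branching angle drawn from Δθ, at a rotation azimuth
that is either random or incremented by a fixed angle.  The reference axis
is the parent segment by default; the alternative `branching_reference =
"root"` measures angles from the root axis, so a narrow Δθ produces an
aligned anisotropic network and a wide Δθ an isotropic one (see the
branching-angle study below).  Segment length is `length_to_radius_ratio ×
radius` (default 8; the morphology literature gives no single rule).
Daughters that would collide with existing segments are redrawn a bounded
number of times, then the branch terminates.  Because Murray's law conserves
Σr³, one tree adds roughly its root volume per generation and can exhaust
(all tips below `radius_min`) before the target vascular fraction is met; in
that case additional roots are seeded until the voxelized fraction reaches
the target.

## Field computation

Each labeled voxel is a cubic perturber.  Its far field is the dipole field
of the volume-equivalent embedded sphere weighted by 6/π (which makes the
cube's dipole moment exactly match its volume):

    ΔB_p(r, θ) = (6/π) · (Δχ·B0/3) · (R/r)³ · (3cos²θ − 1),   R = Δx/2.

The total shift is the superposition over all perturbers, computed as a
circular FFT convolution of the compartment indicator with the
single-perturber kernel on a zero-padded grid (default pad: one-tenth of the
box per side; doubling the pad changes the field by <1% RMS for the standard
structures).  Three numerical conventions:

* the kernel's r = 0 sample is set to zero — a perturber voxel sees only the
  field of the *other* perturbers, and no Lorentz-sphere internal shift is
  added (toggleable);
* the kernel's grid mean is subtracted so the dipole field integrates to
  zero over the box (discrete sampling otherwise leaves a spurious uniform
  offset);
* B0 may point along any unit vector; the kernel is regenerated per
  direction.

On grids ≤ 24³ the FFT result matches brute-force pairwise superposition to
rounding error, and a voxelized sphere of radius 8 voxels reproduces the
analytic exterior dipole within 5% at ≥ 2 radii (using the effective radius
implied by the voxel count).

**Susceptibility units.** The dipole formula above is the SI form.  The
DSC-MRI literature's customary values — Δχ = 10⁻⁷ for a typical agent dose,
χm = 0.027×10⁻⁶ mM⁻¹ for Gd-DTPA — are Gaussian-cgs volume susceptibilities;
converting them for the SI kernel requires the factor `CGS_TO_SI = 4π`.
The experiment layer applies this conversion; `concentration_to_dchi`
itself returns χm·C in the customary (cgs) units.  With the conversion, the
classic cylinder configuration yields ΔR2* ≈ 3.5 s⁻¹ and tree dose-response
slopes give kp ≈ 100–140 (mM·s)⁻¹ — the scales reported for such protocols.
Read as SI directly, everything would be 4π ≈ 12.6× smaller.

## Signal evolution

The transverse magnetization M (complex, one entry per voxel) evolves per
time step Δt as M ← (A·M) ∘ Φ, where A is the sparse diffusion transition
matrix (periodic 7-point structure; jump probability D·Δt/d² between
same-compartment neighbors, Pm·cf·Δt/d across a membrane of permeability
Pm, with cf = 1 by default; columns sum to 1) and
Φ_k = exp(i·γ·ΔB_k·Δt)·exp(−Δt/T2_k).  Splitting diffusion before
phase/decay has O(Δt²) error and is exact in every validation limit.
Stability requires all jump probabilities ≤ 1/6; the builder raises an error
naming the offending compartment otherwise.  `Pm = ∞` removes the membranes
entirely (harmonic-mean D across unlike neighbors): water diffuses freely
and the labeled structure acts only as a susceptibility source — the
condition of the classic validation experiments.  Spin echo conjugates M
once at TE/2.  The signal is S(t) = |Σ M| / Σ M0, and
ΔR2 = −ln(S_post/S_pre)/TE (s⁻¹) at the echo.  An `exponentiality_check`
reports the residuals of a log-linear fit of S(t), since mesoscopic decay is
only approximately mono-exponential.

For the common uniform-D free-diffusion case a dedicated stencil solver
(`evolve_free_diffusion`, numba-accelerated with a numpy fallback) applies
the 7-point update directly.  It can evolve the magnetization on a grid
refined by an integer factor while the field stays piecewise-constant on its
native voxels.  This matters for cross-solver comparisons: the jump process
(rare, voxel-length hops) decorrelates the sampled field more slowly than a
continuous Brownian walk, biasing ΔR2* by a few percent at hop = field-voxel
size.  The bias is approximately linear in hop length, so evolving at
refinements 1 and 2 and extrapolating ΔR2* to zero hop (Richardson) removes
the leading error; this is the default in the validation protocol.

The Monte-Carlo reference (`montecarlo.run_walk`) propagates spins with
Gaussian per-axis steps of std √(2DΔt), nearest-voxel field lookup
(trilinear optional), elastic rejection of compartment-crossing steps when
Pm = 0, phase negation at TE/2 for spin echo, and
S = |⟨exp(iφ)⟩|·exp(−TE/T2).  It is the correctness oracle, never the
production solver.

## Contrast-agent kinetics and DSC synthesis

The arterial input function is a gamma-variate
A·(t−t0)^α·exp(−(t−t0)/β) scaled to a 6 mM first-pass peak near 32 s
(t0 = 20 s, α = 3, β = 4 s), plus a dispersed recirculation term (first pass
convolved with a 90 s exponential, weight 0.25) and a slow equilibrium
component (9.5% of the peak, rising over ~1 min and decaying with a ~50 min
clearance constant) that holds the plasma level near 0.4–0.5 mM for the
remainder of the acquisition, as measured single-dose curves do.  Without
the equilibrium term the plasma would empty within two minutes and no late
leakage effects could exist; its level sits in the band where the T1 gain
(which saturates by ~0.3 mM) and the compartmental T2* losses (linear in
concentration) compete visibly, which is the regime the leakage study
demonstrates.  These defaults are plausible bolus-injection values, not
authoritative: the source protocols cite prior patient-derived curves
without printing them.  The EES
concentration follows the two-compartment leakage model
ve·dCe/dt = Ktrans·(Cp − Ce), evaluated by an exact piecewise-linear
convolution recursion (matches adaptive ODE integration to ~10⁻⁸).
Defaults: Ktrans = 0.2 min⁻¹, ve = 0.2.

Per imaging time point the agent is assumed well-mixed within each
compartment.  With the EES as susceptibility reference, the vessel
compartment carries Δχ = χm·(Cp − Ce) and the cells −χm·Ce (cells contain no
agent); both fields are superposed by linearity from two precomputed
unit-susceptibility maps.  Relaxation updates are linear:
1/T1 = 1/T10 + r1·C and 1/T2* = 1/T20* + r2·C with r1 = 3.9,
r2 = 5.3 mM⁻¹s⁻¹ (vessels see Cp — intravascular T2* shortening is included
by default and toggleable — EES sees Ce, cells none).  The T1 effect enters
as the steady-state spoiled-gradient-echo weight
w = (1−E1)·sinα/(1−E1·cosα), E1 = exp(−TR/T1), applied as the initial
per-voxel magnetization; water exchange during TR is neglected, consistent
with impermeable membranes (Pm = 0) during the transverse evolution.  One
finite-difference evolution over TE per time point yields S(t), normalized
to the pre-contrast run.  Defaults follow the standard protocol: B0 = 3 T,
TE = 50 ms, TR = 1500 ms, α = 90°, T20* = 50 ms, D = 1.3 µm²/ms,
150 time points over 9 min.

## Standard studies and problem sizes

All studies run from `fpfdm.cli_io` (also via the `fpfdm replicate` CLI);
`scale="mini"` sizes are the defaults used by the test suite and the
reproduction script, chosen to resolve the relevant physics on a laptop-class
budget.

* **Cross-solver convergence** (`validation_convergence`): random cylinders,
  radii 10 and 15 µm, 2% volume fraction, 1 mm box at 64³, Δχ = 10⁻⁷ (cgs),
  B0 = 1.5 T, D = 1 µm²/ms, GE TE = 60 ms, Δt = 0.2 ms.  FDM with hop-size
  extrapolation vs 20 000-spin MC on the same 30 structures per radius.
  Agreement: ≲3–7% with 5-structure averages, ≲1–2% with 30.
* **Vessel-size dependence** (`fig2a`): the box scales with the radius
  (40·r at 64³) so each radius is resolved by the same number of voxels; a
  fixed box voxelizes sub-voxel vessels into voxel-sized perturbers and
  erases the SE curve's rising branch.  Shows the SE peak near 5–10 µm and
  the GE plateau.
* **Packing-shape study** (`fig3`): 9 µm cells in a 64 µm box at 48³,
  Δχ = 5×10⁻⁸ (cgs), B0 = 1.5 T, GE TE = 40 / SE TE = 80 ms.  Ellipsoids
  exceed spheres at matched fractions; the ellipsoid ΔR2* rises then falls
  across fractions 0.15 → 0.40 → 0.62.
* **Branching-angle study** (`branching_angle_kp`): root-referenced trees
  (root along +z), fixed bifurcation index 0.85, radii 8–45 µm, 2% vp, 1 mm
  box at 64³, B0 = 4.7 T, GE TE = 40 ms, concentrations 0.875–3.5 mM,
  B0 averaged over a fixed 5-orientation set (z, x, y, two diagonals).
  kp = dose-response slope / vascular volume fraction.  Note that with
  orientation-uniform averaging and parent-relative branching the Δθ effect
  cancels exactly for an orientationally additive response — the aligned
  narrow-angle network is what makes branching-angle heterogeneity visible.
* **Leakage phenomenology** (`fig6`/`leakage_tissue_model`): ~60%
  spherical cells (5 or 15 µm class) around a ~4–5% vascular segment, box
  scaled to the cell size (≈44 µm at 32³ / ≈88 µm at 48³ so cells span ≥4
  voxels and the stability bound holds at Δt = 0.2 ms).  Cell fractions this
  high around vessels defeat iterative random packing in reasonable time, so
  the cells sit on a face-centered-cubic lattice sized for a 70% full
  packing, with vessel-intersecting cells deleted and the rest thinned to
  the target — deterministic and exactly non-overlapping.  The ordered
  arrangement lowers absolute relaxivity relative to a random packing, but
  the cell-size dependence survives (cell-compartment ΔR2* at 1 mM:
  ≈4.4 s⁻¹ for the small cells vs ≈8.0 s⁻¹ for the large).  40 time points
  over 9 min in the mini protocol.  Reproduces the T1/T2* competition:
  small cells with long T10 overshoot baseline after the first pass, large
  cells stay depressed (stronger compartmentalized T2* effect).

## What the synthetic data does and does not emulate

The generators produce idealized periodic tissue: monodisperse-ish convex
cells, non-overlapping by construction, strictly binary compartments,
vessels without flow, curvature-free membranes, and contrast agent that is
well-mixed per compartment with globally uniform kinetics.  Real tissue has
polydisperse irregular cells, open vasculature with flow and hematocrit
gradients, finite membrane permeability, B0-dependent background gradients
and noise.  Passing tests therefore demonstrate the numerics (field solver,
Bloch-Torrey evolution, kinetics) and the qualitative structure-contrast
relationships, not quantitative prediction for any particular tissue.
Imaging-derived masks can be imported (NIfTI / TIFF / raw+JSON), but no
segmentation or denoising is provided.

## Numerical choices and degenerate inputs

* Voxel centers at (i+0.5)·Δx, 0-based indices, periodic wrap everywhere.
* Stability guard: D·Δt/Δx² ≤ 1/6 enforced at matrix build and in the
  stencil solver (refinement tightens the bound by refine²).
* The single-precision stencil option (complex64) changes ΔR2* by <10⁻⁵
  relative — far below the discretization error it helps remove — and is
  used only inside the refined validation runs.
* Ellipsoid pair test tolerances: eigenvalues within 10⁻⁷ of real/positive
  are treated conservatively (near-tangency counts as overlap during
  packing).
* Degenerate requests: zero volume fraction → empty scene; zero diffusion →
  identity transition matrix; Δχ = 0 → exact pure-decay signal; Ktrans = 0 →
  Ce ≡ 0; infeasible packing fractions raise `PackingError` carrying the
  achieved fraction.
* Determinism: every generator draws from `numpy.random.default_rng(seed)`;
  identical (parameters, seed) reproduce bit-identical scenes and grids.
  Packing retries and tree re-roots derive their streams from the same seed.

## Known limitations

* The FPM field model handles piecewise-constant susceptibility only (a few
  discrete compartments); continuous susceptibility distributions are out of
  scope.
* Contrast-agent spatial diffusion within compartments is not modeled (the
  agent concentration is uniform per compartment per time point).
* The MC walker's membrane handling is the elastic-rejection limit; finite
  Pm is meaningful only in the matrix solver.
* Packing beyond ~0.65–0.70 total fraction, or dense cells around thick
  vessel networks, may exhaust the retry budget and raise rather than run
  unboundedly.
* kp values depend visibly on network construction (alignment, radii, box):
  the branching-angle study fixes one documented protocol rather than
  claiming universality.
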