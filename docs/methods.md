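# Methods

## The model

`ahflow` simulates steady aqueous-humor (AH) circulation in a 2-D
cross-section of the human anterior segment. Aqueous is secreted by the
ciliary body into the posterior chamber (PC), passes between iris and lens
through the pupil into the anterior chamber (AC), circulates by natural
convection in the temperature gradient between the cornea (~34 °C) and the
interior tissues (~37 °C), and drains through the trabecular meshwork (TM)
at the chamber angles. The macroscopic model is the incompressible
Navier-Stokes equations under the Boussinesq approximation,

    ∇·u = 0
    ∂u/∂t + ∇·(uu) = −∇p + ν∇²u − g β (T − T₀)
    ∂T/∂t + ∇·(uT) = α ∇²T,

with Darcy seepage `u = −(K/μ)∇p` describing outflow through the porous TM.
Temperature is a passive scalar; all fluid properties are constant except
the buoyancy density. The thermal diffusivity is derived from the tabulated
conductivity as α = k/(ρ c_p); with k = 0.58 W/m·°C, ρ = 993 kg/m³ and the
heat capacity of water c_p = 4178 J/kg·K this gives Pr = ν/α = 5.02, in
agreement with the tabulated Prandtl number 5.03.

## Numerics

**Velocity lattice.** A 9-direction incompressible LBGK model whose
equilibria are written in pressure rather than density:
`f_i^eq = {−4σ, λ, γ}·p/c² + s_i(u)` with the canonical coefficients
λ = 1/3, γ = 1/12, σ = λ + γ = 5/12 and the standard second-order velocity
polynomial `s_i`. Velocity and pressure are population moments; viscosity is
ν = (2τ−1)/6 in lattice units. Both the moment identities and the ν(τ)
relation are pinned by tests (moment round-trips to round-off; plane
Poiseuille flow and a decaying shear wave recover ν within 1%).

**Thermal lattice.** A 4-direction lattice with equilibria
`T_i^eq = (T/4)(1 + 2 e_i·u/c)` and diffusivity α = (2τ_T−1)/4, verified to
2% by the free diffusion of a Gaussian spot. With τ = 1.0 fixed, τ_T is
derived from the Prandtl number (τ_T ≈ 0.566 for aqueous humor), not free.

**Coupling.** Buoyancy enters as a force on the two lattice directions
aligned with gravity, `F_i = −(Δt/2c) e_i·g β(T−T₀)`, added directly to the
post-collision populations; its first moment reassembles the continuum
Boussinesq force exactly. `standing` orients gravity in-plane across the
chamber; `lying` orients it along the pupil axis toward the cornea — this
sign reproduces the two counter-rotating supine convection cells; the
opposite sign selects a weaker four-cell pattern in this geometry.

**Unit mapping.** The lattice spacing dx fixes lengths and
dt = ν_lat·dx²/ν follows from viscosity matching at the chosen τ. Because
ν, α (through Pr) and g are all mapped consistently, the Rayleigh number of
the physical problem (Ra ≈ 2.4×10³ on the 3 mm chamber depth and the 3 °C
cornea-interior difference) is preserved automatically. Temperatures are
carried in °C unscaled.

**Boundaries.** Walls are halfway bounce-back (no slip). The ciliary inlet
and the TM outlet are velocity boundaries realised by setting the boundary
node to equilibrium at the imposed velocity and the adjacent fluid node's
pressure. The fully-relaxed form is used deliberately: schemes that recycle
the neighbour's non-equilibrium part (non-equilibrium extrapolation) or
reflect it (anti-bounce-back for the thermal field) support undamped or
self-exciting modes on the nearly-enclosed fluid nodes in the chamber-angle
wedge, which destabilise the coupled run. For the same reason the thermal
Dirichlet condition holds all non-fluid nodes at reservoir equilibrium
`T_wall/4` (cornea 34 °C, every other wall, the inlet and the TM at 37 °C);
this places the effective wall at the wall-node centre and is first-order
accurate, which the conduction-slab benchmark (≤0.5% error) accounts for.

**Outflow and IOP.** Darcy seepage at each TM node uses the one-sided
pressure difference between the adjacent fluid node and the fixed reference
pressure beyond the outlet, over one lattice spacing, clamped to forbid
backflow. The incompressible model determines pressure only up to a
constant; that constant is anchored every step by requiring the
instantaneous TM outflux to balance the secretion influx. The intraocular
pressure is the fluid-area-averaged absolute pressure. The outlet reference
pressure (default 1943.6 Pa) is a calibration constant chosen so the normal
eye (K = 7.0×10⁻¹⁵ m², Q = 2.5 µL/min, which converts to an inlet speed of
2.0×10⁻⁶ m/s over the two 0.5 mm PC entrances) settles at 1950 Pa at desk
resolution. Because the anchored TM drop is proportional to μ·Q/K, IOP
trends (hyperbolic decrease in K, linear increase in Q, steeper for low K)
are structural properties of the model; the drop is also proportional to μ,
so IOP retains a small linear viscosity dependence (~14 Pa per ±50% μ —
negligible against the 1950 Pa level).

**Steady state.** The solver alternates velocity step (with buoyancy),
boundary application, and thermal step from a quiescent start; temperature
is pre-conditioned by a sparse steady-conduction solve, which removes the
slow thermal transient. Convergence is the relative L2 change of the
velocity field over 1000 ticks dropping below 10⁻⁶; divergence (non-finite
populations or lattice speeds above 0.3c) raises with the tick and peak
speed. The solver contains no random numbers; reruns are bit-identical.

## Geometry

The cross-section is assembled from a posterior corneal arc (radius 6.8 mm,
chord 12.8 mm), an anterior lens arc (radius 10 mm) whose pole sits 3.0 mm
behind the corneal apex, straight iris walls from each angle to the pupil
margin held at least 0.1 mm off the lens, PC channels of 0.5 mm entrance
height ending in inlet nodes, and 0.7 mm TM patches at both angles. Values
the reference geometry does not fix (AC depth 3.0 mm, corneal radius
6.8 mm, iris-lens clearance 0.1 mm, TM extent 0.7 mm, iris thickness
0.4 mm) are standard adult ocular anatomy and all overridable. Morphological
variants: flat central corneal indentation of depth d (cornea clipped at
the plane y = d), semi-elliptic iris crypts, lateral pupil-axis shift for
asymmetric chambers, and pupil-diameter presets 2.76/3.69/4.91 mm.

Rasterisation is half-open (a node is fluid when its centre lies strictly
inside), with node rows half-offset from multiples of dx so flat surfaces
never alias onto node rows, and with a two-node minimum channel width where
the iris hugs the lens so the pupil pathway stays connected at any usable
resolution (dx ≤ pc_inlet_height/4). Fluid-sliver components below 5% of
the main region (possible with noisy image-derived contours) are pruned;
larger disconnections are construction errors.

An image-derived geometry replaces the parametric corneal arc with the
contour extracted from an edge map: for each column between the
user-selected angle points A and B, the first edge pixel above the chords
AC/CB is recorded (C sits below the apex), refined to sub-pixel position at
the zero-crossing of the filter response, with gaps interpolated and a
segmentation failure raised above 30% empty columns.

## Image filters

The speckle denoiser is a gradient-gated lattice diffusion: per 4-neighbour
direction, intensity hops with passing rate g = exp(−(|∇ρ|/κ)²), a
combination of a (MΔh²/18Δt)-weighted second difference and a
(MΔh/9Δt)-weighted central gradient that telescopes into an upwind-weighted
Laplacian. The scheme is monotone (exact discrete extremum principle) under
M ≤ 9/4, enforced. κ defaults to the 90th percentile of the image's
gradient-magnitude histogram, making the filter parameter-free per image;
the default 20 iterations halve speckle variance on the synthetic fixtures
while moving edges by well under a pixel. Edges are zero-crossings of the
prefactored Laplacian-of-Gaussian response (1/3)(τ−1/2)∇²(G_σ*ρ), gated by
a minimum smoothed gradient magnitude (default 5% of the smoothed range).

## Synthetic fixtures

OCT-like test images render the wall bands of a known geometry (0.5 mm
thick, the anatomical corneal thickness) as bright tissue over a dark
background with multiplicative gamma speckle (unit mean, variance 1/L,
default L = 4 looks, seeded). They emulate the speckle statistics and
edge geometry of anterior-segment OCT but none of the physics of image
formation (no depth attenuation, coherence effects, refraction or motion),
so pipeline tests demonstrate correct segmentation behaviour under
multiplicative noise, not clinical-grade performance on real scans.
Analytic cases (Poiseuille, conduction slab, diffusion spot, decaying shear
wave) provide closed-form solutions that pin the transport coefficients.

## Desk scale and reference quantities

The studies run at dx = 0.05 mm (≈1.1×10⁴ fluid nodes; coarsening to
0.1 mm changes the standing maximum speed by 2.9%, so the fields are
effectively grid-converged). Runs finer than 0.1 mm use mesh continuation —
the solver first converges on the 0.1 mm lattice and the interpolated
solution warm-starts the fine run — and a numba-compiled tick kernel that
reproduces the numpy operators to round-off (asserted by an equivalence
test). At this scale the model reproduces, from the tabulated properties
alone: a single clockwise standing-posture vortex with maximum speed
≈7.1×10⁻⁴ m/s on the pupil axis; two
counter-rotating mirror cells in the lying posture; monotonically
decreasing maximum speed under increasing corneal indentation; IOP falling
hyperbolically with TM permeability (fast below 5×10⁻¹⁵ m²), rising with
secretion rate (faster in low-permeability eyes), and nearly unaffected in
absolute terms by viscosity.

## Known limitations

- 2-D cross-section: out-of-plane circulation and true 3-D vortex
  structure are not represented; absolute speeds can differ from 3-D or
  image-specific geometries by tens of percent.
- The lying posture at these parameters is only marginally supercritical
  (Ra ≈ 2.4×10³), so the convection amplitude is small and sensitive to
  chamber depth and β; asymmetric (image-derived) chambers are forced
  directly and convect much harder.
- The staggered (checkerboard) momentum mode is an exact invariant of
  BGK+bounce-back at τ = 1.0; it is unexcited by smooth starts (measured
  at 10⁻⁵ of max speed in production runs) but visible in artificial
  rough-initialised box tests.
- First-order thermal wall accuracy (reservoir scheme); wall position
  effectively at the wall-node centre.
- The TM is a lumped Darcy resistance over one lattice spacing; Schlemm's
  canal and segmental outflow are out of scope, and the absolute IOP level
  is calibrated, not predicted.
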