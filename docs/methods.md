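# Methods

## Physical model and assumptions

The device is idealised as a one-dimensional resonator in cylindrical
coordinates (r, z): the piezo actuator is an effective pressure boundary at
z = 0, the reflector a rigid boundary at z = L, and both are pressure
antinodes, so resonance requires L = nλ/2 and the first-order pressure is
p(r, z, t) = p₀E(r)cos(kz)cos(ωt). No piezoelectric physics, acoustic
streaming, attenuation or thermal gradients are modelled. The radial decay
of the actuator field is represented by a pluggable envelope, Gaussian by
default, E(r) = exp(−r²/2σ_r²) with E(0) = 1 and E non-increasing.

Particles are spheres, rigid when modelling aggregates (`rigid` flag zeroes
the compressibility) and weakly compressible when modelling cells. Forces:

- **Radiation force** F = −∇U with U = 2πa³Φ E_ac(r) cos(2kz) G(2ka);
  E_ac = (p₀E)²/(4ρ_f c²); Φ = f₁/3 + f₂/2 as usual. With Φ > 0 (all
  defaults here) the axial trap minimum is at a pressure node and the radial
  gradient of E_ac pulls the particle toward the axis.
- **Finite size.** G(x) = 3(sin x − x cos x)/x³ is the volume average of the
  point-force density over the sphere (G(0) = 1, first zero at x ≈ 4.4934).
  It is an analytic stand-in for the surface-integrated stress a full
  scattering model would provide, and reproduces the qualitative regime
  change when the diameter approaches the wavelength. Its sign structure is
  a known artefact discussed under limitations.
- **Stokes drag** −6πμa·v (quiescent fluid, no history or added-mass terms,
  no wall or inter-particle hydrodynamics).
- **Buoyant weight** (ρₚ−ρ_f)Vg along −z, on by default.

The normative suspension-stability rule for an aggregate is the wavelength
criterion — stable iff diameter < λ (strict) — with λ = 937.5 µm at the
default medium and drive. The trajectory sweep is a validation layer, not
the classifier.

## Parameters, units, defaults

All internal quantities are SI; config files carry explicit unit suffixes.

| parameter | default | meaning |
|---|---|---|
| c | 1500 m/s | sound speed of the culture medium (water); fixed so λ = c/f = 937.5 µm exactly. Temperature dependence not modelled |
| f | 1.6 MHz | actuator drive/resonance frequency |
| L | 67.5 mm | cavity height, the half-wave resonance (n = 144) nearest the device's 67.52 mm |
| p₀ | 1.0 MPa | drive pressure amplitude. The physical device's amplitude is unknown; every amplitude-dependent output (settle times, absolute stresses, confinement thicknesses) is conditional on p₀ |
| σ_r | 10 mm | Gaussian envelope width, set to the actuator radius |
| R_a, R_v | 10 mm, 20 mm | actuator and vessel inner radii (20-mm disc; 50-mm OD tube with 5-mm wall) |
| d_cell, ρₚ | 30 µm, 1050 kg/m³ | single-cell sphere |
| κₚ | 4.0e−10 Pa⁻¹ | cell compressibility, literature-typical for mammalian cells; `rigid=True` reproduces the rigid-matter assumption |
| settle tol | 5 µm (≈ λ/200) | distance to a node below which a particle counts as settled (convention) |
| capture radius | 60 µm (2 cell diameters) | single-linkage distance for positional clustering (convention) |
| φ | 0.74 | packing fraction of cells in a compacted aggregate (dense sphere packing); measured values unknown |
| h_max | 200 µm | axial height cap of the disc model, the measured mean aggregate height |

## Numerics

- **Overdamped mode** (default for single cells; momentum relaxation
  ρₚd²/18μ ≈ 5·10⁻⁵ s ≪ trap time): midpoint steps on dx/dt = F/γ with
  adaptive sub-stepping so no sub-step displaces a particle more than λ/20;
  exceeding the sub-step budget raises an instability error rather than
  silently degrading.
- **Inertial mode** (default for ≥ 200-µm aggregates, whose relaxation time
  reaches seconds): semi-implicit Euler, drag taken implicitly, sub-step
  capped at 5 % of the stiffest trap oscillation period present, and by the
  same λ/20 displacement cap. The trap oscillation frequency
  ω = k√(6ΦE_acG/ρₚ) is radius-independent, ≈ 2.9·10³ rad/s at the stiffest
  sweep entry.
- Boundaries reflect by clamping with velocity zeroing; every clamp is
  counted on the trajectory.
- Linearised trap relaxation τ = 3μ/(4Φk²a²E_ac) (≈ 13.5 ms for the default
  cell on axis) and the flank travel time
  T = ln(tan kz̃₀ / tan kz̃_f)/(2kv₀) serve as closed-form oracles for the
  integrator; both are met to ≤ 1 %. Settle times scale as 1/p₀².
- Surface stress samples are (2/π)·p₀E(r_c)·⟨|cos kz|⟩ with the sphere-surface
  average reduced analytically to a 1-D |cos| integral (the spherical surface
  measure is uniform in the axial coordinate); the 2/π factor is the
  full-cycle average of |cos ωt|, appropriate because the 2-ms sampling clock
  is asynchronous with the 1.6-MHz carrier. The envelope is evaluated at the
  centre radius (it varies on the cm scale, the sphere on the sub-mm scale).
- Stochastic draws use one integer seed per generator call;
  morphometry series use two child streams (diameters, heights) spawned from
  the seed and consume exactly one uniform per output index (inverse-CDF
  zero-truncated normal), so draws are bit-reproducible, the two series are
  independent, and the first min(n, n′) values are invariant to n.

## What the synthetic data emulates — and what it does not

`generate_suspension` reproduces only the *initial condition* of a seeding
run: positions uniform in the cavity cylinder (area-correct in r). It does
not model cell sedimentation during pouring, polydispersity, or flow.
`sample_morphometry` draws independent normal diameters (470 ± 220 µm) and
heights (200 ± 24 µm) truncated at zero. Because zero sits only 2.14 σ below
the diameter mean, the generator's population mean is ≈ 479.1 µm rather than
the nominal 470 (shift σφ(α)/(1−Φ(α)); heights are unaffected, zero being
8.3 σ away). Truncation is by distribution (inverse CDF), not clamping, so
no atom forms at the bound. Passing tests therefore demonstrate that the
pipeline recovers the *generator's* distribution, not that real aggregates
are normally distributed or that diameter and height are uncorrelated — no
covariance was measured.

## Design choices where the design was open

- **Boundary convention.** Both ends pressure antinodes: the simplest 1-D
  resonator consistent with a height-tuned stable standing wave. The
  measured 67.52-mm optimum differs from the ideal 67.5 mm by 20 µm (λ/47);
  that offset comes from 3-D piezo/reflector physics outside this model, so
  the field object records detuning rather than pretending to resolve it.
- **Gravity on by default.** The observation that very large particles stay
  in constant motion is most naturally a competition between the attenuated
  trap and weight; both gravity modes are supported everywhere.
- **Stress definition.** "Stress applied to the particle surface" is not
  defined by any measurement available to this model; we adopt the
  surface-averaged absolute first-order pressure with the analytic 2/π
  carrier factor — the simplest quantity consistent with compressive loading
  by the sound field that needs no scattering solver. Absolute values
  (e.g. a 12-Pa trap average or a 500-Pa ceiling) are conditional on both p₀
  and this definition and are deliberately not reproduced. For scale: a
  500-Pa amplitude contour lies 200 µm wide (±100 µm about a node) only if
  the local amplitude p₀E(r) ≈ 805 Pa; at the default 1 MPa it lies 0.15 µm
  from the node. `confinement_band`/`cap_height_from_field` expose exactly
  this inversion.
- **Disc model.** The aggregate is a sphere until its packed volume exceeds
  the sphere of diameter h_max, then a flat-sided disc of height h_max.
  Volume and height are continuous at the cap; the diameter necessarily
  jumps by √(2/3) there (a sphere and a cylinder of equal height and volume
  cannot share a diameter), and discs within 1.5× of the cap count are
  narrower than they are tall. Counts and dimensions round-trip within one
  cell volume.

## Known limitations

- The finite-size factor G changes sign at d ≈ 670 µm (x = 4.4934), beyond
  which spheres are attracted to pressure *antinodes*. Consequently the 1-s
  trajectory sweep cannot dynamically flag ≥ 1000-µm aggregates as unstable:
  they re-trap with bounded (< λ/4) axial excursion at any reasonable
  amplitude. Distinguishing trapping from escape at d ≈ λ requires the full
  scattering (surface-integrated traction) treatment that is out of scope;
  the wavelength classifier is normative for exactly this reason.
- For the same reason the mean surface stress is *not* monotone in diameter
  across the 200–1400 µm sweep: the surface-averaged |p| saturates at
  (2/π)p₀E once the sphere spans about half a wavelength (measured Spearman
  rank correlation with diameter ≈ 0.54). A monotone size–stress trend as
  observed experimentally would require the scattered-field contribution
  that grows with ka; the corresponding acceptance check is left failing
  rather than redefining the quantity to pass.
- Overdamped and inertial modes agree for single cells but the inertial
  sweep retains undamped oscillations for multi-hundred-µm aggregates over
  1 s; excursion *from the start point* can therefore transiently exceed the
  distance-to-node bound (the trapping-cell notion used in tests).
- No adhesion, coalescence mechanics, compaction dynamics, acoustic
  streaming, secondary (inter-particle) radiation forces, or elastic-sphere
  resonances.

## Problem sizes used in the shipped checks

The test suite and the acceptance script run at desk scale by design:
seeding runs use 200–300 particles over 0.3–0.5 s windows (the settling
physics is per-particle, so counts beyond a few hundred only tighten
statistics), the aggregate sweep is the full seven-diameter, 1-s window at
the 2-ms sampling grid, and morphometry recovery uses n = 10⁵ draws, where
the standard error of the height mean is 0.076 µm.
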