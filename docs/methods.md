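# Methods

This note documents the models, numerical choices and deliberate
simplifications behind `blasthead`, in the order the pipeline runs.

## 1. Blast source: 1D spherical multi-material hydrocode

**Model.** The charge is initialised as constant-volume-burnt
detonation products: JWL gas at the solid explosive density
(ρ₀ = 1630 kg/m³) carrying the full chemical energy
(e₀ = 4.29 MJ/kg, the Lee-standard TNT value; JWL constants
A = 371.2 GPa, B = 3.231 GPa, R₁ = 4.15, R₂ = 0.95, ω = 0.30), at rest.
The surrounding air is a calorically perfect gas (γ = 1.4,
ρ = 1.225 kg/m³) whose internal energy is set so the initial pressure
is one standard atmosphere, so the field relaxes back toward ambient
after the wave passes.  Instantaneous constant-volume burn replaces a
programmed detonation: at a standoff of ~30 charge radii the
transmitted air shock is insensitive to burn detail, and the "balloon"
source needs no burn-front tracking.

**Numerics.** Staggered-grid Lagrangian finite-volume scheme
(von Neumann–Richtmyer): node velocities and positions leapfrogged
against cell-centred density/energy/pressure; quadratic + linear
artificial viscosity (coefficients 1.5 and 0.06) at compressions; CFL
0.4 with a 10 % per-step growth cap.  Both EOS are linear in internal
energy, so the trapezoidal (time-centred) energy update is solved in
closed form per cell — this is what keeps the global energy balance at
the 10⁻⁵ level.  The Lagrangian frame tracks the products/air contact
exactly; no mixture closure is ever needed.  This choice (rather than a
Eulerian Godunov scheme) also reuses the same numerical family as the
tissue column.

**Grid.** Uniform cells (default 1 mm) from the origin out to the
standoff + 0.3 m; beyond that the spacing grows geometrically (ratio
1.05, capped at 25 cells) to R_max = standoff + 2.5 m.  The stretched
outer region is a sponge: the outer constant-pressure boundary is never
reached by the shock within the 5 ms window at the default geometry, so
no boundary reflection contaminates the gauge.  The charge itself gets
at least 40 cells.  Peak overpressure at 1 m changes by under 2 % when
the cell size is halved (checked in the acceptance suite).

**Gauge.** Side-on (static) pressure is interpolated each step at the
fixed Eulerian gauge radius from the moving cell centres, then
resampled to a uniform 1 µs interval.  The trace is absolute pressure
with the ambient value recorded in its metadata.

**Known behaviour.** The constant-volume-burn 1D source produces a
longer, deeper suction phase than an ideal Friedlander wave, including
a weak secondary shock; at 5 ms the gauge has recovered to within a few
percent of the *signal amplitude* but not necessarily to within 5 % of
the ambient *pressure*, especially for the heavier charges.  Solver
verification therefore normalises late-time recovery by the peak
overpressure.

**Friedlander fit.** Least squares of ΔP(1−τ)e^(−bτ) over
[t_a, t_a + 2t_d̂], with t_a pinned at the overpressure maximum and the
initial duration estimate t_d̂ from the first zero crossing.  Residuals
are weighted e^(−τ): the ideal waveform describes the front of the
positive phase well but not the balloon-source tail, and unweighted
fitting lets the tail drag the fitted peak several percent below the
recorded maximum.

**Empirical cross-check.** `incident_overpressure_oracle` implements
the classic Brode point-source fit in scaled distance Z = R/m^⅓
(near branch 6.7/Z³ + 1 bar above 10 bar, far branch
0.975/Z + 1.455/Z² + 5.85/Z³ − 0.019 bar down to 0.1 bar).  It is a
test oracle only — agreement with the hydrocode is asserted at the
20 % level that separates independent empirical fits from each other in
this range — and never feeds the simulation.

## 2. Tissue column: planar uniaxial-strain Lagrangian wavecode

**Reduction.** The 3D head is reduced to an ordered planar column along
the blast axis.  This keeps the constitutive laws and through-thickness
transmission physics exact while discarding curvature, diffraction and
3D pressure relief; in-brain magnitudes are therefore upper bounds.
Orientation enters only through layer thicknesses.

**Default stacks** (conventional adult anatomy, not subject-specific):
scalp 5 mm / skull 7 mm (anterior), 4 mm (right-lateral), 9 mm
(posterior) / CSF 3 mm / brain 150 mm.  Eight brain gauges at 5–145 mm
into the brain layer.  The nasal cavity material is implemented and
selectable but off the default mid-column path.

**Loading.** A blocked surface experiences reflected, not incident,
pressure, so the free-field overpressure history is mapped pointwise
through the γ = 1.4 normal-reflection factor
2ΔP(7P₀ + 4ΔP)/(7P₀ + ΔP) (exact at the peak; a surrogate elsewhere on
the waveform) and applied as a traction on the scalp face.  The distal
face carries an acoustic-impedance absorber (traction −ρc·u), standing
in for the tissue continuing beyond the modelled column.

**Constitutive updates.** Volumetric: P = Kμ for elastic and brain
cells, the shock Hugoniot P = ρ₀C₀²μ(1+μ)/(1−(s−1)μ)² for skull and
CSF (tension linearised to ρ₀C₀²μ; no spall).  Deviatoric: axial
deviatoric strain rate is ⅔ of the axial strain rate; elastic layers
use their shear modulus; the brain uses the hereditary integral of
G(t) = G∞ + (G₀−G∞)e^(−βt) in recursive exponential-integrator form —
one internal variable per cell, exact for piecewise-linear strain and
unconditionally stable.  Setting G₀ = G∞ recovers the elastic solution
to round-off, which is how the update is verified.  Von Mises stress in
uniaxial strain is (3/2)|s_axial|.

**Conservation.**  Cell masses are constant by construction; the
interior momentum update telescopes, so the per-step momentum-balance
residual against the boundary impulse is at round-off (asserted
< 10⁻⁶).  A quadratic stored-energy diagnostic (½Kμ² plus deviatoric
branch energies) plus kinetic energy is recorded per step; it is
non-increasing once the surface load ends (artificial viscosity and
shear relaxation only dissipate).  The diagnostic is quadratic, i.e.
exact only at small strain — which is the regime of the monotonicity
test.

## 3. Injury metrics and classification

Peak positive/negative pressures are plain extrema of the gauge
overpressure.  The 1 ms peak-to-peak metric is the maximum over all
contiguous windows of ≤ 1 ms of (window max − window min): both
extremes must lie inside one window, which makes the definition
order-independent; it is computed with a sliding-window view and
verified against an O(n·w) scan.  Ward boundaries: both 173 and
235 kPa fall in the middle band (the criterion reads "below 173" and
"more than 235").  Zhang thresholds are tolerances, so each threshold
value enters the higher band.  The Ward index applies to brain gauges
only — it was stated for cerebral contusion and does not transfer to
the spinal cord.  Attenuation between two gauges is reported as an
integer percent (100·(1 − distal/proximal), rounded), with a
full-precision fraction available.

## 4. Scenario pipeline

Each (mass, orientation) case runs: detonate (cached per mass — the
free-field wave is orientation-independent) → reflect → propagate →
classify, with both the peak-pressure and the peak-to-peak severity
variants reported per gauge.  Everything is deterministic; the seed is
recorded in the report and forwarded to stochastic consumers.  A
`quick` mode coarsens the blast grid to 4 mm and the column to 1 mm for
exploratory sweeps; peaks shift by a few percent.  Default study sizes:
1 mm blast cells over a 3.5 m domain (~1440 cells), 0.25 mm column
cells (~660 cells), 5 ms window, 1 µs output sampling.

## 5. Synthetic gauge traces

The generator emulates the statistical structure the analysis assumes:
a Friedlander pulse (instantaneous rise, exponential-modified linear
decay, negative phase), geometric peak attenuation (1−a)^k and constant
arrival lag across a gauge suite, and additive Gaussian noise
(default off; 1 % of the peak is the intended scale) seeded for
bit-for-bit reproducibility.  It does **not** emulate: reverberation
between tissue interfaces, the late-developing von Mises histories of
deep structures (synthetic von Mises channels are scaled copies of the
pressure for plumbing tests only), secondary shocks, or any 3D
focusing.  Passing tests on synthetic suites therefore demonstrates the
correctness of the metric and classification plumbing, not fidelity of
the physics to real gauge data.

## 6. Limitations

* The planar column cannot reproduce 3D gauge values: no skull
  curvature or flexure, no foramen-magnum funneling, no CSF cavitation,
  no skull–brain sliding, no coup–contrecoup geometry.  Its in-brain
  pressures are systematically high (blocked-face loading) and its
  shear stresses systematically low (uniaxial strain limits deviatoric
  response); both are reported as surrogate quantities.
* Homogeneous-brain attenuation with depth is physically tiny for
  millisecond pulses in a planar geometry; the monotone-decay property
  is exercised with a short (20 µs) pulse where viscoelastic
  dissipation is visible above the numerical noise floor.
* The air model is a perfect gas: real-gas effects at the strongest
  near-charge states are neglected (immaterial at ~30 charge radii).
* Tension handling is a linearised continuation of each EOS — no spall
  or cavitation thresholds anywhere.
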