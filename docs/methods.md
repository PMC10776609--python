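# Methods

This note records the model equations as implemented, the defaults and why
they were chosen, the numerical choices, and what the verification suite
does and does not demonstrate.

## Kinetics (`jetcryst.kinetics`)

Solubility of lovastatin in methanol/water blends:

```
C*(w_as, T) = 0.001 · exp(15.45763 · (1 − 296/T)) · p(w_as)   [kg/kg solvents]
p(w) = −2.7455e−4 w³ + 3.3716e−2 w² − 1.6704 w + 33.089   (w ≤ 45.67)
p(w) = −1.7884e−2 w + 1.7888                              (w > 45.67)
```

`w_as` is water weight-percent on a solute-free solvents basis; `C` is kg
solute per kg solvents.  The published upper-branch slope (+1.7884)
produces an ~86× discontinuity at w = 45.67; the sign/exponent-corrected
slope above restores continuity to 0.03 % and is the default
(`branch_mode="continuity_restored"`).  The literal form stays available
(`"as_printed"`) so the discontinuity can be examined rather than hidden.

Nucleation (homogeneous + heterogeneous) and growth are 23 °C isothermal
fits in the supersaturation ratio `S = C/C*`; both vanish in the limit
`S → 1⁺`, so `S ≤ 1` returns exactly zero (negative `ln S` is unphysical
for these laws).  No temperature correction is available; the correlations
are applied at all temperatures, and the constants can be overridden in
the run configuration.  No dissolution rate law exists for lovastatin
here, so undersaturated states simply stop growth; the dissolution branch
of the transport scheme is exercised with imposed rates instead.

## Size-coordinate scheme (`jetcryst.pbe`)

Crystal sizes live on a uniform grid of `N` classes (default 30 × 2 µm
spanning 0–60 µm; the span and count are configurable).  The semi-discrete
update for class `j` is the conservative flux difference

```
df_j/dt = −(H_{j+1/2} − H_{j−1/2})/Δr
```

with upwind-biased MUSCL face states: growth uses the left reconstruction
`f_j + (Δr/2)(f_r)_j`, dissolution the right reconstruction
`f_{j+1} − (Δr/2)(f_r)_{j+1}`.  Slopes come from the three-candidate
minmod limiter with `θ = 1.5` (`θ ∈ [1, 2]`).  End classes use
zero-gradient ghost values, which zeroes their limited slope; an
unlimited one-sided slope there can reconstruct more material than the
cell holds and break positivity under a CFL step.

Boundaries: the inner face carries only the nucleation flux (nuclei enter
the first class, the smallest resolvable size — the grid starts at 0 so
that class is 0–2 µm); the outer face is zero-flux in reactor runs (the
span is chosen wide enough that essentially nothing arrives there; the
top-class mass fraction is reported as an audit) and open ("outflow") in
pure-advection studies.

Mass basis: `f_w,j = ρ_c k_v f_j [(r_{j+1/2})⁴ − (r_{j−1/2})⁴]/4`, the
exact third-moment integral over the class for a class-wise constant
number *density* (#/m⁴).  Note the same integral written with per-class
*numbers* (#/m³) carries an extra 1/Δr; mixing the two bases inflates
crystal mass by Δr⁻¹ (~5×10⁵ here) and pushes any reactor model into a
spurious depletion-controlled regime.  `k_v` defaults to π/6
(volume-equivalent spheres); it only rescales mass-basis outputs.
Aggregation and breakage are neglected (micron-sized organic crystals
following the streamlines).

Time integration of pure advection studies uses SSP-RK2 at CFL 0.45.

### Accuracy, measured

* Smooth data: L1 order 1.88 (least-squares over Δr = 4, 2, 1, 0.5 µm)
  for a σ = 16 µm Gaussian advected 30 µm on a 0–180 µm span.  The wide
  profile/long span matter: the order measurement requires the coarsest
  grid to resolve the profile, and TVD limiters clip smooth extrema, so
  under-resolved pulses (e.g. σ = 4 µm on 0–60 µm) show pre-asymptotic
  orders near 1.6 at these resolutions.
* A deliberately first-order upwind control converges at order ≈ 1.0.
* Step profiles converge at ≈ 0.72, consistent with the theoretical
  O(h^(2/3)) rate for contact discontinuities under TVD limiters.
* TVD audit: 100 randomized non-negative profiles advected across the
  grid produce no new maxima and no negative values beyond 1e−12 of the
  peak.

## Micromixing (`jetcryst.micromixing`)

Three environments: (1) solution feed, mixture fraction 1; (2) water feed,
mixture fraction 0; (3) mixed.  Transported quantities are P1, P2, P3 and
the probability-weighted environment-3 composition `s3 = P3·Φ3`
(mixture fraction, solute, methanol, water, and the crystal classes —
crystals exist only in environment 3).  Engulfment:

```
γ   = ε_ξ / [P1(1−P1)(1−⟨ξ⟩3²) + P2(1−P2)⟨ξ⟩3²]
ε_ξ = C_φ ⟨ξ'²⟩ ε/k,  C_φ = 2
⟨ξ'²⟩ = P1(1−P1) − 2P1P3⟨ξ⟩3 + P3(1−P3)⟨ξ⟩3²
```

with probability sources `−γP1(1−P1)`, `−γP2(1−P2)`,
`+γ[P1(1−P1)+P2(1−P2)]` and the matching weighted-composition source; the
spurious-dissipation corrections (`γ_s`, driven by resolved ⟨ξ⟩3
gradients) are zero in 0-D compartments and evaluated by central
differences on the 1-D chain template.  Total probability is conserved
identically (`ΣP_n = 1`; the occasionally-quoted shortcut "P3 = P1 + P2"
contradicts that normalisation and is not used).  When the γ denominator
falls below 1e−14 nothing remains to engulf and all sources return zero.
The sources leave the cell mean of every conserved scalar exactly
unchanged — verified to machine precision.

## Reactor coupling (`jetcryst.reactor`)

The 3-D flow field is replaced by a flow-balanced network of well-mixed
compartments with prescribed turbulence.  Per compartment the state is
(P1, P2, P3, weighted ⟨ξ⟩3, weighted solute/methanol/water concentrations
in kg per m³ of suspension, the environment-3-weighted crystal number
densities, and T).  Because the growth operator is linear in `f` and the
feeds carry no crystals, the weighted crystal field can be advanced
directly; nucleation enters as `P3·B(S3)` and the solute sink equals the
total crystal mass production rate exactly, closing the mass balance by
construction (closed-cell solute + crystal drift ~1e−16 relative).

Energy: `S_h = S3_solvents·(−ΔH_mix) + (Σ_j S_{f_w,j})·(−ΔH_crys)` with
`dT/dt = S_h/(ρ c_p)` plus flow exchange; the three environments are in
thermal equilibrium.  `ΔH_mix = −3.4e4 J` per kg of solvents engulfed is
**calibrated** so the equal-mass-flow adiabatic case heats by ≈ +10 K (no
published numeric value exists); `ΔH_crys = −1.0e5 J/kg` is the
enthalpy-of-fusion scale and contributes < 0.1 K at the default
conversion.  `c_p = 3000 J/(kg·K)` is a methanol/water blend value.
Density enters only through inlet volumetric-flow conversion (ideal
volume-additive mixing) and the thermal mass.

### Templates and defaults

* `mixed_cell` — one compartment (also the MSMPR verification vehicle).
* `pfr_chain` — equal-volume series with resolved 1-D ⟨ξ⟩3 gradients.
* `impinging_jet` — impingement compartment (20 % of the volume) feeding
  a chain of 4 chamber compartments.

Nozzle area defaults to 3.3339e−7 m² per inlet (d ≈ 0.65 mm), chosen so
that the published anti-solvent flow of 498.6e−6 kg/s corresponds to
1.5 m/s.  Inlet solute loading is set by the supersaturation ratio
relative to the *stream's own* (w_as, T) solubility.

**Control volume.**  `total_volume` defaults to 5e−10 m³ (0.5 mm³) — the
active impingement/mixing zone of a millimetre-nozzle device, a few jet
diameters across, giving millisecond residence times.  This is the single
most consequential default and is a regime choice, not a fit: reported
jet-crystallizer operation is kinetics-limited (outlet crystal flow is a
tiny fraction of the solute feed; the in-device supersaturation is
insensitive to jet velocity).  A well-mixed network at full-chamber volume
instead runs depletion-controlled — nearly all solute converts, and the
production rate then *rises* with jet velocity (throughput wins), the
opposite of observed behavior.  With the active-zone volume, conversion
scales like τ⁴ (nuclei must both form and grow within the transit), which
yields the observed directions: production and mean size fall steeply
with velocity, rise with inlet supersaturation, and fall with the
solution/anti-solvent mass-flow ratio (less water → higher solubility →
lower S).  Quantities downstream of the active zone (slow growth in the
dilute chamber) are outside the model.

**Turbulence.**  `ε/k` is scaled from the characteristic jet velocity as
`ε/k = c·v/d_jet` with `c = 10` in the impingement compartment (jet
impingement dissipates order v³/d; mixing times are sub-millisecond) and a
geometric decay of 0.5 per chamber.  This gives a mixed-environment
fraction P3 ≈ 0.94 at the outlet for the reference case, consistent with
near-complete micromixing.  Flat per-compartment values (or k and ε
separately, plus D_t) can be prescribed instead.

### Integration and steady state

The coupled ODE system (typically 5 compartments × 38 states) is advanced
with adaptive explicit Runge–Kutta (`RK45` default; `LSODA`/`BDF`
switchable) in chunks of one residence time; absolute tolerances are set
per block (probabilities ~1e−10, concentrations ~1e−7 kg/m³, number
densities 1 #/m⁴, temperature ~3e−8 K).  The stepper is not
positivity-preserving, so negative number densities are clipped at chunk
boundaries and audited (count and worst magnitude are reported).  Steady
state is declared when the largest block-relative change over one
residence time falls below `steady_tol` (default 1e−6); non-convergence
within `max_residence_times` raises with the residual.  The whole pipeline
is deterministic given a configuration.

## Verification (`jetcryst.verification`)

Oracles are implemented independently of the production flux/limiter code:
exact translation for constant-rate growth, the exponential
`(B/G)exp(−r/Gτ)` MSMPR steady state (exact class averages), a first-order
upwind control scheme, and closure audits (probability, scalar means,
solute + crystal mass, steady flow balances).  The 0-D mixed cell with
imposed constant B and G reproduces the MSMPR distribution within 0.6 %
L1 at Δr = 0.5 µm.  Published volume-averaged CFD quantities are *not*
oracle targets: a desk-scale compartment model cannot reproduce
volume averages of a strongly inhomogeneous 3-D field, so the operating
sweeps are asserted directionally (strict monotonicity across the three
operating points of each sweep), not numerically.

The class-width sensitivity procedure (Δr = 4 → 2 → 1 µm on the reference
case) shows the mean size changing 19 % across the first refinement and
2.7 % across the second (σ: 25 % then 0.2 %), supporting 2 µm classes as
the accuracy/cost compromise.

## What the tests do not show

Synthetic study conditions emulate the published operating points (feed
compositions, velocities, temperatures, flow ratios) on a reduced
geometry.  They do not capture: spatial inhomogeneity of supersaturation
and turbulence inside a real chamber (volume-averaged magnitudes of S, B,
G are therefore not comparable); crystal growth in the dilute downstream
chamber; aggregation/breakage; size-dependent growth; polymorph
selection; or temperature dependence of the nucleation/growth constants
beyond the 23 °C fits.  Directional trends and all conservation/accuracy
properties are the validated claims.

## Known limitations

* The energy balance assumes equal and constant ρ·c_p across streams.
* Nuclei deposited uniformly into the first class acquire the class-mean
  r³ mass (≈ that of a 1.3 µm crystal on the default grid) immediately —
  the standard class-method artifact, negligible at the default
  conversion but visible if the first class is made very wide.
* Dissolution in live-kinetics mode is inactive (no rate law); imposed
  negative growth rates exercise the scheme instead.
* `steady_tol` below ~1e−8 can chase integrator noise; tighten `rtol`
  together with it.
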