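# Methods

## Constitutive model

The chorionic artery wall is modelled as an incompressible, homogeneous
thick-wall cylinder.  Its stress-free reference configuration is the open
sector a radially cut ring relaxes into; the *opening angle* OA is the gap
angle subtended at the sector centre by the two cut faces, so the material
spans 2π − OA and the closure factor is k = 2π/(2π − OA).  Closing the
sector, stretching axially by λ_z and pressurising maps stress-free radius
R ∈ [R_i, R_o] to

    r(R)² = r_i² + (R² − R_i²)/(k·λ_z),
    λ_θ(R) = k·r(R)/R,   λ_r = 1/(λ_θ·λ_z),

which satisfies pointwise incompressibility exactly.  The strain energy is
the isotropic reduction of the Fung exponential (equal stiffness in the
three principal directions, no cross or shear coupling):

    W(E) = c/2 · (exp(b1·(E_θ² + E_z² + E_r²)) − 1),   E = (λ² − 1)/2.

`c` is a stress-like scale carrying the unit of the pressure data (mmHg
throughout this package — the published group values state no unit, and all
recovery checks are unit-consistent by construction); `b1` is the
dimensionless strain-stiffening exponent.  With the hydrostatic pressure
eliminated, radial equilibrium of the tube under luminal pressure P and
zero outer gauge pressure gives

    P = ∫_{r_i}^{r_o} (σ_θ − σ_r) dr/r,
    σ_θ − σ_r = c·b1·e^Q·(λ_θ²E_θ − λ_r²E_r),  Q = b1(E_θ²+E_z²+E_r²).

The analytical supplement of the originating experimental work is not
public; this standard incompressible thick-wall formulation is adopted as
the canonical one.  The measured unloaded ring dimensions (outer diameter,
wall thickness) are used directly as the stress-free sector radii: a
wall/lumen thickness ratio t/D_i and outer diameter D_o give
R_o = D_o/2 and R_i = R_o/(1 + 2·t/D_i).  The ratio is defined against the
*luminal* diameter — against the outer diameter a ratio near 0.6 would
imply a wall thicker than the radius, which is geometrically impossible.

### Forward prediction and fitting

- The zero-pressure (residually stressed, axially stretched) state is the
  root of P(r_i) = 0; P(r_i) is strictly increasing for physical
  parameters, so every state is found by bracketed Brent root-finding.
- The observable reported is the outer-diameter stretch
  λ = D_outer(P)/D_outer(0), matching what a camera tracks in an inflation
  test.
- Equilibrium integrals use 200-point Gauss–Legendre quadrature over the
  stress-free radial coordinate (doubling the points changes P by < 1e-6
  relative; a 10⁵-point trapezoid oracle agrees to < 1e-5).
- `fit_fung` minimises the sum of squared **pressure** residuals at the
  measured stretches — pressure is the controlled, low-noise channel — by
  Nelder–Mead in (log c, log b1), which enforces positivity without
  constraints.  Eight log-spaced starts cover c ∈ [10, 1000] mmHg,
  b1 ∈ [1, 60]; the best run is returned together with R² on pressures.
  Axial stretch is fixed at 1.1 (the specimen is restretched to its in
  situ length) and configurable.
- The Fung exponent is guarded at 700; scalar energy/stress evaluations
  raise beyond it, while vectorised root-finding paths clip so brackets
  can be probed safely.

## Pressure–diameter analysis

Cycles are detected by threshold crossings: a cycle starts when pressure
rises above 2 mmHg, must peak at ≥ 38 mmHg to count as complete, and ends
when pressure falls below 2 mmHg again; incomplete excursions are flagged
with a reason, never silently dropped.  The last three complete cycles'
**loading** limbs (the injection protocol's controlled phase) are linearly
interpolated onto the fixed grid 0, 1, …, 40 mmHg and averaged pointwise;
each limb is extended backwards into the preceding near-zero-pressure
dwell so the reference state is sampled.  The reference diameter D0 is the
averaged zero-pressure diameter, so λ(0) = 1 exactly and preconditioning
drift does not bias λ (D0 comes from the analysis cycles, not cycle 1).
Monotonicity is not enforced on noisy curves; `monotone_violation()`
reports the largest decrease.

Distensibility dλ/dP at pressure P* is the ordinary-least-squares slope
over grid points within P* ± 2.5 mmHg (window configurable, ≥ 3 points
required); evaluation defaults to {10, 15, 20, 25, 30, 35} mmHg.  On the
curve λ(P) = 1 + 0.5(1 − e^(−P/10)) the windowed slope reproduces the
analytic derivative at 10 mmHg to well under 2% (the leading error is
f'''·window²/10).  Whether limbs should be averaged before or after
differentiation is not determined by the protocol; this package averages
first.

## Windkessel network

Each compartment i contributes a resistance R_i (mmHg·s/ml) between nodes
i−1 and i and a compliance C_i (ml/mmHg) at node i.  Node 0 follows the
prescribed inlet pressure; the node after the last resistance is held at
the constant venous pressure (5.3 mmHg), making the final compartment's
capacitor inert and placing all 23 resistances in series for the mean
flow: cycle-mean Q = (mean p_in − P_v)/ΣR exactly, independent of every
compliance — the mechanism behind mean flow being insensitive to
compliance while pulsatility is not.

The interior-node ODEs C_i·dP_i/dt = Q_{R,i} − Q_{R,i+1} form a linear
system integrated with an implicit trapezoidal scheme (stiff-safe), 400
steps per cycle, repeating cycles until every node's cycle-mean pressure
changes < 1e-6 relative (error with the convergence trace after 200
cycles).  Inlet pressure shapes are Doppler-like waveforms affinely
rescaled to 50/25 mmHg (normal) or 80/25 mmHg (IUGR).

Default geometry (the originating study's per-generation table is not
public, so these are package defaults, all overridable): first placental
artery generation 1.5 mm radius, radius ratio 0.79 and doubling vessel
count per generation, 15 mm segments; veins mirror arteries at 1.3×
radius; umbilical vessels 2.0/2.6 mm radius and 500 mm length; blood
viscosity 3.5 mPa·s; Poiseuille R = 8μL/(πr⁴n); compliance
C = nπr²L·β.  The lumped microvilli compartment's resistance equals the
summed resistance of all vessels (≥ 50% of the total).  The effective area
distensibility defaults to β = 1e-4 mmHg⁻¹, calibrated so the baseline
normal case reproduces a typical umbilical flow pattern — RI ≈ 0.62 with
no reversed diastolic flow; a physiologic-looking β an order of magnitude
larger makes the network time constant exceed the cardiac period and the
baseline already exhibits reversed flow, which contradicts the normal
condition being modelled.

Multiplier fits scale every R by k_R and every C by k_C and minimise the
normalised L2 waveform mismatch of umbilical flow plus squared RI and PI
mismatches (equal weights), Nelder–Mead in log-multipliers from four fixed
starts.  The parametric sweep defaults to 20×20 log-spaced multipliers in
[0.25, 4]: within that range RI and PI rise monotonically with both
multipliers, reversal is absent at (1, 1) and present at the high-R/high-C
corner.  Far beyond it (k_R·k_C ≳ 50, network time constant several
cardiac periods) RI saturates near ~1.3 and recedes, so the default range
deliberately covers the physiologically interpretable monotone regime.

In the bundled synthetic study, the IUGR flow target carries pulsatility
beyond what resistance rescaling alone can produce at its mean flow, so
matching it forces k_C above both 1 and the normal case's value —
reproducing the qualitative conclusion that elevated Doppler indices
require a compliance change, not just a resistance change.

## Tree morphometry

Segments are maximal unbranched chains; the root segment is generation 1
and every branching event increments the generation of all daughters.
Branching ratio is the daughter/mother segment radius ratio, with the
segment radius the median of its node radii (robust to junction
artifacts).  The branching angle is measured between the mother's incoming
and each daughter's outgoing direction — the daughter–daughter angle is an
alternative convention; mother–daughter is implemented and documented —
with directions from least-squares line fits to centerline points within a
5 mm arc-length window of the branch point (configurable).  Ratios are
scale-invariant and angles rigid-motion-invariant by construction.

## Synthetic data: what it emulates, and what not

- **Inflation records**: eight linear 0→40→0 mmHg pressure cycles (40 s
  up, 10 s down, 5 Hz sampling — the experimental sampling rates are not
  published; these are package choices), diameters from the forward
  constitutive model, additive Gaussian diameter noise (default sd
  0.01 mm; pressure is treated as transducer-accurate), and a
  preconditioning diameter offset halving each cycle and exactly zero from
  cycle 6, so the analysed last three cycles are stationary.  Default
  vessel scale: 2 mm unloaded outer diameter.
- **Doppler-like waveforms**: raised-cosine systolic pulse over a
  configurable systolic fraction plus an exponential diastolic decay
  pinned to the prescribed minimum, affinely normalised so the resistance
  index is met exactly; a target RI > 1 (reversed trough) must be
  requested explicitly.
- **Vessel trees**: binary trees with prescribed radius ratio, branching
  half-angle and segment length, with optional multiplicative jitter and
  random branch-plane azimuths.

Passing round-trip tests therefore shows the analysis chain is
self-consistent and correctly implemented; it does not validate the
constitutive model against real tissue, emulate video-tracking artifacts,
hysteresis/viscoelasticity, Doppler measurement physics, or casting/CT
segmentation errors.

## Known limitations

- With `c` carrying pressure units at the published group magnitudes
  (c ≈ 100–350, b1 ≈ 9–27), the predicted outer-diameter excursion over
  0–40 mmHg is only a few µm for the stiff normal/IUGR parameter sets.
  The default 0.01 mm diameter noise then dominates the signal and noisy
  fits are not identifiable (they collapse to c → 0 with negative R²).
  Parameter-recovery demonstrations are therefore run noiseless; noisy
  recovery is only informative for substantially softer walls (e.g. a
  c-scale two orders of magnitude smaller, as would follow if the
  published values were in Pa — their unit is not stated).
- The unit of `c` is unknowable from the published table; absolute
  comparison of fitted c against other studies requires fixing that unit.
- Whether the published fits used pressure or diameter residuals, and
  loading or unloading limbs, is unstated; this package fits pressure
  residuals on loading limbs and documents both choices.
- The per-generation Windkessel geometry and the exact branching-angle
  formula come from a non-public supplement; both are configuration here,
  with defaults stated above.
- No anisotropic or shear-coupled Fung variants, no viscoelasticity, no
  distributed (wave-propagation) hemodynamics, no inertial elements, and
  no statistical hypothesis testing (summaries are mean ± SE only).
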