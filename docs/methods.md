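# Methods

`pulseheat` simulates the thermal dose delivered to a liver tumor by bursts of
high-frequency nanosecond electric pulses applied through a pair of needle
electrodes, and builds the treatment-planning layer (parameter sweep, safe
envelope, closed-form temperature law) on top of the field/heat solver.

## Physical model

**Electric field.** Pulse periods (1–10 µs) are far longer than the dielectric
relaxation time of tissue, so the potential is quasi-static:

    -∇·(σ ∇φ) = 0,       E = -∇φ,   J = σE,   Q = σ|E|²,

with φ fixed on the two electrode surfaces (one energized at the pulse
amplitude V, the other grounded) and zero normal current on all other
boundaries, including the insulated needle sheath and the outer liver surface.

**Electroporation switch.** Tissue conductivity is a two-state step model:
where |E| reaches the irreversible-electroporation threshold (800 V/cm) the
conductivity jumps from its base value (liver 0.067 → 0.241 S/m, tumor
0.135 → 0.426 S/m) and never reverts within the burst. Because the switch
redistributes the field, the solver iterates {solve φ → threshold |E| →
rebuild σ} to a fixed point; the porated set grows monotonically, so the
iteration terminates (capping the iterations at 1 recovers single-pass
behavior). Both states carry a linear temperature multiplier
1 + α(T − 37 °C) with α = 1.5 %/°C.

**Heat transfer.** Tissue temperature obeys the Pennes bioheat equation

    ρc ∂T/∂t = ∇·(k ∇T) + ρ_b c_b ω_b (T_b − T) + Q_m + s(t)·Q,

where the perfusion term relaxes tissue toward arterial blood at
T_b = 37 °C, Q_m is metabolic heat and s(t) gates the Joule source by the
pulse train. The perfusion term is implemented as a sink, ρ_b c_b ω_b (T_b −
T); a source with the opposite sign would let perfusion heat tissue without
bound, which contradicts the physics of the model. A solver flag
(`pennes_printed_sign`) flips the sign for sensitivity studies.

**Thermal damage.** Cumulative first-order Arrhenius damage

    Ω(t) = A ∫ exp(-E_a / (R T_K(τ))) dτ,     P(%) = 100 (1 − e^(−Ω)),

with protein-coagulation kinetics by default (A = 7.39e39 1/s,
E_a = 2.577e5 J/mol); microvascular stasis and whole-cell death kinetics ship
as presets. Thresholds: Ω ≥ 0.53 marks damage onset, Ω = 1 ↔ 63 % kill,
Ω = 4.6 ↔ 99 % kill (boundaries inclusive upward — the study conditions never
land exactly on a boundary, so the convention only needs to be stated).

## Geometry and discretization

The domain is a 10 cm × 10 cm liver cylinder with a 1 cm tumor sphere at
mid-height. Two 1 mm needles run parallel to the axis, 5.4 mm apart,
symmetric about the tumor. The energized segment (6 mm) is centered on the
tumor's equatorial plane; above it the needle is insulated sheath up to the
liver surface. The source geometry does not dimension the insulated extent;
this placement is isolated in `meshing.active_z_range` so alternatives are
one-line changes. Tips are flat cylinder ends.

Space is discretized on a graded tensor-product voxel grid: uniform fine
spacing in a band around the needles, growing geometrically (ratio ≤ 1.5) to
2.5 mm in the far field. Cells are labeled by voxel-center containment in
priority order electrode → insulation → tumor → liver → outside; outside
cells never enter any solve. Two measures keep the near-electrode field
well-posed on the staircased geometry:

- **Embedded-boundary distances (Shortley–Weller).** Fluxes between a tissue
  cell and an electrode cell are measured over the distance from the cell
  center to the *true* cylinder surface along the face direction, not to the
  voxel face. The same distances are used when differentiating φ, so the
  reported |E| is consistent with the discrete fluxes.
- **Sliver absorption (cut-cell merging).** Cells whose center lies closer
  than half a cell to the needle wall are absorbed into the needle label;
  otherwise their near-zero gap produces near-singular conductances.

Both electrostatic and thermal operators are 7-point finite-volume stencils
with harmonic face averaging of σ and k, assembled once per grid. The
electrostatic system is solved with Jacobi-preconditioned conjugate
gradients (relative residual 1e-8); warm starts make the repeated re-solves
during a burst cheap.

### The peak-temperature observable is scale-defined

The continuum field is singular at the electrode edges: |E| ~ s^(−1/3) at the
flat tip rim and ~ s^(−1/2) at the electrode/insulation junction. The
spatial *maximum* of |E| — and therefore of the burst-end temperature —
consequently grows without bound as the grid is refined; `grid_convergence`
reproduces this (the successive differences do not shrink). Any reported
"maximum instantaneous temperature" is thus meaningful only together with a
sampling scale. The default grid evaluates the observable at the coarsest
electrode-resolving scale: fine spacing equal to the needle radius (0.5 mm),
comparable to the 0.4 mm near-electrode element size of the finite-element
study this pipeline re-implements. Volume-integrated and diffusion-smoothed
quantities (end-of-window temperature, damage away from the singular rim,
total current) are insensitive to this choice.

## Time integration

One burst (100 µs) plus its observation window (1 s):

- **Burst phase — explicit forward Euler.** In `exact` mode the Joule source
  is gated by the pulse train at 10 ns steps; in `averaged` mode it is scaled
  by the duty cycle and applied continuously with 1 µs steps. Both deposit
  identical energy; the peaks differ by at most one single-pulse increment
  (property-tested), and in averaged mode the step size only controls the
  diffusion number (~2e-3 per step at the default grid), so refining it is a
  no-op to < 0.01 °C (also tested). The stability bound dt < min(w_i/A_ii)
  (≈ Δx²ρc/6k, tens of ms here) is asserted before stepping.
- **Field refresh.** σ(T) drifts during the burst; the field is re-solved
  whenever max|T − T_at_last_solve| exceeds 1 °C (configurable), warm-started
  from the previous potential and poration mask.
- **Cooling phase — implicit backward Euler**, 1 ms steps with the source
  off. The BE matrix is strongly diagonally dominant at this step size, so
  warm-started CG converges in a few iterations; tiny systems (< 5000 cells,
  e.g. the verification blocks) use a direct factorization instead.
- **Damage** accumulates on the fly by streaming trapezoidal integration of
  the Arrhenius rate over the same time discretization (equal to batch
  integration to round-off; second-order in dt), so no temperature history is
  stored.

Temperatures are °C throughout; Kelvin appears only inside the Arrhenius
kernel. Reported maxima are taken over tumor-labeled voxels (domain-wide
maxima are recorded alongside).

## Sweep, fit and safe envelope

`run_sweep` executes one burst per lattice point over (V, p_w, f) — the study
lattice is 4 × 4 × 4 = 64 points — reusing one grid (the grid does not depend
on the protocol) and caching finished points by parameter hash. Sweeps
default to `averaged` mode, justified by the exact/averaged agreement
property. The sweep preset grid keeps the default's near-electrode sampling
(0.5 mm) with a leaner 4 mm far field.

The burst-end and end-of-window maxima follow the one-coefficient law

    T ≈ T₀ + a · p_w · f · V² · N     (p_w in ns, f in kHz, V in volts),

fitted by least squares through the fixed intercept T₀ = 37 °C (the
functional form pins the intercept; a free intercept is deliberately not
offered). R² is reported against the mean. The law is linear in the number
of bursts N as an upper bound — inter-burst cooling is neglected, so it is
only trusted "for N not too large". Multi-burst behavior is handled by this
analytic extrapolation only; the transient solver simulates a single burst.

The 44 °C safe envelope is read off the simulated response by linear
interpolation along the free axis — in V² when the free axis is voltage,
which makes the interpolation exact under the law above. Combinations whose
response never reaches the limit are reported as "unbounded within sweep
range" rather than raising. The 3-D isosurface stitches the per-(V, p_w)
crossing frequencies into triangles; the region toward the origin satisfies
the limit.

## Verification fixtures (synthetic data)

The fixtures module generates scenarios with closed-form answers and runs
them through the *production* solvers (a slab is a grid with planar electrode
voxels, not a special-cased 1-D path):

- **Uniform slab**: |E| = V/d, Q = σV²/d², adiabatic rise Q/(ρc) per second
  of on-time; exercises the Laplace solver, the Joule formula and the
  poration switch (0.1 % tolerance; the discrete solution is exact here, the
  slack covers round-off).
- **Two-layer slab**: series-resistor field partition, E₁/E₂ = σ₂/σ₁
  (interface cells average gradients across the jump and are excluded).
- **Uniform block ODEs**: metabolic heating T₀ + Q_m t/(ρc) and perfusion
  relaxation toward T_b at rate ρ_b c_b ω_b/(ρc) (0.5 % at default steps).
- **Synthetic sweeps**: tables generated from the exact scaling law with
  optional seeded Gaussian noise; noiseless recovery is machine-precision
  exact, noisy recovery is checked by Monte-Carlo coverage (3 standard
  errors over 200 seeds).
- **Constant-temperature series**: Ω = A t exp(−E_a/RT_K) to 1e-6.

What the fixtures do *not* emulate: conforming tetrahedral discretizations,
tissue heterogeneity beyond the two-compartment liver/tumor model, nonlinear
or frequency-dependent conductivity, and measurement noise. Passing fixtures
therefore validates the numerics of this pipeline, not the biological
fidelity of the underlying tissue model.

## Key parameters

| Parameter | Default | Units | Meaning |
|---|---|---|---|
| liver σ (base → porated) | 0.067 → 0.241 | S/m | step conductivity model |
| tumor σ (base → porated) | 0.135 → 0.426 | S/m | step conductivity model |
| poration threshold | 800 | V/cm | irreversible-electroporation field |
| α | 0.015 | 1/°C | temperature coefficient of σ |
| liver ρ, c_p, k | 1080, 3540, 0.52 | kg/m³, J/kg/K, W/m/K | |
| tumor ρ, c_p, k | 1220, 4180, 0.6 | | |
| liver ω_b, Q_m | 5e-4, 4200 | 1/s, W/m³ | perfusion, metabolism |
| tumor ω_b, Q_m | 2e-3, 42000 | | both above liver values |
| blood ρ_b, c_b, T_b | 1000, 4200, 37 | kg/m³, J/kg/K, °C | |
| burst length / rate | 100 / 1 | µs / Hz | one burst simulated |
| damage kinetics | 7.39e39, 2.577e5 | 1/s, J/mol | protein coagulation |
| grid (fine/coarse/ratio) | 0.5 / 2.5 / 1.5 | mm | see sampling-scale note |
| steps (exact/averaged/cool) | 10 ns / 1 µs / 1 ms | | |

Electrode and insulation rows of the source property table interleave their
thermal/electrical columns ambiguously; this package assigns the
conductor-like set (k = 18 W/m/K, σ = 1e8 S/m) to the stainless-steel
electrodes and the insulator-like set (k = 0.026 W/m/K, σ = 1e-5 S/m) to the
sheath — the only physically coherent reading. Electrode σ is nearly
irrelevant anyway: electrode surfaces carry Dirichlet conditions and the
metal interior is excluded from the electric solve.

## Degenerate inputs and tie-breaks

- Zero voltage (or a grid without both electrodes) skips the field solve and
  integrates pure bioheat.
- Duty cycle is validated ≤ 1 at protocol construction and again for every
  (width, rate) pair before a sweep starts.
- Sweep points that fail to converge are recorded and skipped; the sweep
  continues and reports them.
- A fit requires at least two rows with distinct p_w·f·V²; anything less is a
  degenerate-design error.
- Damage thresholds classify inclusively upward at exactly 0.53 / 1 / 4.6.

## Known limitations

- Single burst only in the transient solver; the linear-in-N law
  overestimates multi-burst peaks because inter-burst cooling is ignored.
- Two parallel needles only; no arbitrary electrode arrangements.
- No dynamic pore-density electroporation model, no dispersive dielectrics,
  no temperature dependence of k or c, no CEM43 dose metric.
- The peak-temperature observable is tied to the stated 0.5 mm sampling
  scale (see above); refining the grid raises it without bound by sampling
  the electrode-edge singularities more deeply.
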