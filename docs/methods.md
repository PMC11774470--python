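# Methods

This note records the models implemented in `mpsbarrier`, the assumptions
behind them, the numerical choices, and their known limits. The package
analyses a pillar-array interfacial barrier for microphysiological systems
(MPS): a single row of circular pillars of height `h_b` inside a shallow
slot that separates a cell chamber from its media channels. Three physical
questions are addressed: when does liquid burst across the barrier
(capillary valving), how fast do biomolecules cross it (tunable diffusion),
and whether the cardiac microtissues it supports stay oxygenated and how
their total oxygen consumption scales with tissue size.

## Geometry

The barrier is parameterised by pore size `g`, pillar diameter `d`, pillar
count `n`, pillar height `h_b`, and the strip footprint `L_b × w_b`. The
default layout places `n` pillars with `n+1` equal pores spanning `L_b`,
so `d = (L_b − (n+1)g)/n`.

Porosity (void fraction) is exposed under two conventions, because the
void fraction depends on which footprint one normalises by: `strip`
divides the pillar cross-section by the full `L_b × w_b` strip, and
`pillar_band` by the `L_b × d` band the pillars actually occupy. Both are
independent of `h_b` (void and total volume scale together). An analytic
circle-area formula is used; tests validate it against brute-force pixel
rasterisation at 0.1 μm.

The pore between two adjacent pillars is a converging–diverging channel:
at station `s ∈ [−d/2, d/2]` along the crossing direction the local gap is
`w(s) = (d+g) − 2√((d/2)² − s²)` and the signed wall divergence angle is
`β(s) = arctan(d(w/2)/ds)`. The throat (`s = 0`) has `w = g`; together
with the slot height this sets the hydraulic diameter
`D_h = 2 h_b g/(h_b + g)` (4·area/perimeter of the rectangular throat).
The reference device (2 μm × 8 μm throat) gives `D_h = 3.2` μm.

## Capillary burst valve

Two models estimate the pressure at which water bursts across a fenestra,
reported both in Pa and as the non-dimensional pressure
`p* = Δp·D_h/γ` (γ = 0.072 N/m, advancing contact angle θc = 66° by
default).

**Quasi-static pinning model.** An advancing meniscus on a wall diverging
at angle β pins with an apparent angle `θ* = min(θc + max(β,0), 180°)`.
The local Laplace pressure across a gap `w(s)` of height `h` is

    Δp(s) = −2γ [cos θ*(s)/w(s) + cos θv/h],

with `θv = θc` inside the fenestra and `θv = θ*` at the exit expansion,
where the meniscus pins in both transverse directions (β = 90°). The burst
pressure is the maximum over the path including the exit plane. For a
wetting liquid (θc < 90°) the interior terms are negative — the fenestra
wicks spontaneously — and the exit expansion is the barrier.

**Reduced planar two-phase simulator.** A desk-scale, depth-averaged
(Hele-Shaw) two-phase model on a top-view grid: water fraction `c(x,y)`
advected conservatively (first-order upwind plus a conservative
phase-field sharpening term keeping the interface ≈ 2 cells thick) by a
Darcy flow with face conductance `H³/12μ(c)` on the local depth map
`H(x,y)`. Capillarity enters as (a) the resolved in-plane interface
curvature (continuum-surface-force form, with wall contact-angle ghost
values) and (b) a depth-averaged out-of-plane capillary pressure
`2γ cos θc/H`.

The out-of-plane term needs one closure: with θc < 90° it is a pure
forward suction at every depth, so without pinning the model would burst
any geometry at zero pressure, contradicting the observed valve behaviour.
Faces where the advancing water meets a depth expansion are therefore
treated as *capillary diode* faces — the planar analogue of edge pinning:
they pass displaced air freely (the meniscus sits inside the exit cell)
but carry zero water flux until the phase pressure difference exceeds the
pinned Laplace threshold

    Δp_pin = 2γ(−cos θ*)(1/H_shallow + 1/w_span),   θ* = min(θc+90°, 180°),

where `w_span` is the local in-plane wall-to-wall span of the donor cell.
This is exactly the quasi-static exit formula, so the two methods share
that closure (the simulator independently resolves the in-plane path
physics and the flood after depinning, not the pinned-exit coefficient).
The condition is solved as a small complementarity iteration inside each
time step; sub-threshold pinned menisci are genuinely static. Since a
wetting slot wicks at any applied pressure, runs by default start with the
barrier slot pre-wetted (`prefill_barrier=True`) and resolve only the
pinned-exit decision and the subsequent flood. Burst is declared when the
water volume fraction of the media region beyond the exit plane exceeds a
small threshold (default 5%) — with the diode semantics any water beyond
the exit implies depinning; the criterion is deliberately volume-based
because the post-burst stream is diffuse and drains through the open
outlet, so a pointwise `c ≈ 1` test on the exit line is unreliable.
`find_burst_pressure` bisects the applied pressure between a no-burst and
a burst outcome.

Defaults: grid 2.5 μm, interface thickness ≈ 2 cells, per-step interface
advance capped at 0.25 cell (the run is quasi-static; the time axis is a
pseudo-time), bisection tolerance 1 kPa in the examples and scripts.
Domain: 30 μm of chamber (20 μm deep), the 125 μm barrier strip (slot
2 μm), 30 μm of media (20 μm deep), one/two pillar periods wide with
half-pore margins so the row tiles periodically.

**What this model concludes.** Both methods agree that at matched
`D_h = 3.2` μm the *straight* 8-μm channel has the higher burst pressure:
its exit expansion is pinned across a narrow 8 μm span, while the pillar
pore has already widened to `d+g ≈ 87` μm at its exit, so its in-plane
pinning is much weaker (quasi-static: 82 kPa vs 67 kPa; simulated:
p\* ≈ 2.8 vs ≈ 2.6). Equilibrium capillarity in this geometry therefore
cannot produce a pillar-over-straight burst ratio; transient 3D interface
dynamics outside this model's scope would be needed. The simulated
absolute `p*` values are an order of magnitude above the ≈ 0.2 scale
sometimes quoted for such valves from transient 3D level-set runs, whose
meshes and burst criteria are typically under-reported; the scale of
those runs is not recoverable from a quasi-static planar model.

## Biomolecular transport

Dextran (70 kDa, D = 45.8 μm²/s) is injected into the media channels at a
set flow rate and crosses the barrier into the chamber. The planar model
keeps the depth map everywhere: pressure-driven flow uses lubrication
conductances `∝ H³/12μ`, molecular diffusion uses depth-linear
conductances `∝ H·D`. A shallow barrier therefore throttles convection
(cubically) much harder than diffusion (linearly) — the mechanism behind
the barrier's diffusion-dominant, height-tunable transport. (A single
shared `h/H` factor for both processes would understate the flow
throttling by `(H/h_b)²`; the lubrication scaling is used instead.)

Flow: uniform mass inflow over the media inlet rows, zero gauge pressure
at the outlet rows, no-slip walls; the Reynolds number is computed from
the solved field, not assumed. Transport: inlet feed at `c0`
(7 mmol/m³), outflow outlet, no-flux walls; first-order upwind advection
and central diffusion, integrated with backward Euler on a geometric Δt
ladder (a few distinct step sizes → a few sparse LU factorisations; the
scheme is unconditionally stable and monotone, which is why implicit
advection replaces an explicit CFL-bound scheme that would need ~10⁷
steps to reach the hours-long diffusion times; an explicit mode with a
CFL guard is kept for validation). The diffusion time is the first time
the average over a 50 μm square at the chamber centre reaches 0.9·c0
(region size and threshold are configurable; neither is standardised in
the field).

The near-Fickian figure of merit compares the centre trace against a
reference run whose advection is zeroed on chamber-interior faces (solute
still reaches the chamber boundary by flow; inside it moves by diffusion
only): `max_t |c̄ − c̄_ref|/c0`. This deviation grows with the
channel-length pressure drop and hence with device length and flow rate;
at the v1 preset and 80 μL/min it is well above 0.1, dropping below 0.1
only around 20 μL/min — worth noting when comparing against qualitative
"diffusion-dominant" claims made for specific operating points.

## Oxygen reaction–diffusion and the population of models

Steady state of `∇·(D∇c) + R = 0` with Michaelis–Menten consumption
`R = −sOCR·ρc·c/(km + c)` on box tissue domains:

| parameter | default | note |
|---|---|---|
| D (tissue O₂ diffusivity) | 2.0×10⁻⁹ m²/s | not measured for this tissue; typical soft-tissue value, exposed for sensitivity analysis |
| km | 6.9×10⁻³ mol/m³ | cardiac-tissue literature value |
| ρc (cell density) | 1.95×10¹⁴ cell/m³ | measured cohort mean |
| c_side | 0.21 mol/m³ | media oxygen at the four lateral faces (Dirichlet) |
| bottom | no flux | glass floor |
| top | Robin, k_top = 10⁻⁵ m/s, c_amb = 0.21 | oxygen through the PDMS roof; parameters are an assumption — a `no_flux` option brackets it from below |

Geometry presets V1 (243.8×621.6×62.35 μm), V2 (same footprint, double
height) and V3 (288×950×124.7 μm) span the measured tissue cohort. Tissue
mass is proxied by the box volume (the printed cohort volumes differ from
the box products of the printed dimensions by ~15%; the box products are
used consistently).

Discretisation: cell-centred finite volumes on a uniform grid (default
32×64×16; the boundary conditions enter through half-cell and
film-in-series conductances), damped Picard iteration on the sink
(damping 0.7, relative residual ≤ 10⁻⁸), sparse-direct inner solves below
5000 cells and Jacobi-preconditioned CG above. Because the finite-volume
equations telescope, the surface-integral tissue OCR
`B = Σ ∮ D ∂c/∂n dS` and the volume-integrated sink agree to solver
precision at convergence — this is asserted (0.1%) on every solve.

The population of models (PoM) re-solves the steady model for many sOCR
draws (lognormal, mean 4.67×10⁻¹⁷ mol/s, cv 0.69) per geometry.
Duplicate draws share one solve; distinct draws are solved in ascending
order with warm starts and undamped Picard (the field stays far from the
strongly nonlinear `c → 0` regime; cold standalone solves keep damping).
The PoM default grid is 12×24×10 — roughly 1% of the default grid's
cells; B changes by <1% when the default grid spacing is halved, so the
coarse PoM grid is adequate for distribution-level statistics. The
package's standard PoM runs use 500 draws per geometry.

## Finite-size scaling collapse

If `p(B|m) = B^(−β) F(B/m^α)`, plotting `y = p(B)·B^β·m^γ` against
`x = B/m^α` in log–log collapses the per-mass distributions onto one
master curve. β is fixed at 1 (normalisation convention); (α, γ) are
estimated by minimising a probability-contiguity residual: every ordered
pair of rescaled curves is compared by linear interpolation on the
overlap of their supports, with the L_q mean (q = 1) of |Δy| over all
pairs and points. Pairs with fewer than 5 overlapping points are charged
a fixed penalty (10³) and fully disjoint sets return +∞, steering the
optimiser away from degenerate rescalings. The two-exponent ansatz (α
for the abscissa, γ for the amplitude) spans both one- and two-exponent
readings of the scaling form; γ is interpreted as an amplitude exponent.

Because the empirical densities are binned once (30 log-spaced bins) and
a candidate (α, γ) only shifts each group's log–log curve rigidly by
(−α ln m, +γ ln m), the optimisation is cheap; differential evolution
(population multiplier 30, up to 500 generations, polished, fixed seed
2025 by default) makes the fit deterministic and robust to the
residual's non-smoothness. Exponent-recovery tests on constructed
`B = m^0.9·Z` families bound the estimator bias at ±0.02 for 1000
samples/group over a 4× mass span.

At the default oxygen parameters the tissue stays far above km nearly
everywhere, so B is close to proportional to volume and the fitted mass
exponent lands near 1 (weakly sub-linear). A strongly allometric exponent
would require deeper oxygen depletion (smaller D, larger sOCR·ρc, or
larger tissues) than these defaults produce; the exponent is therefore
reported as a computed outcome, not calibrated to any particular value.

## Synthetic data generators

All generators are pure functions of (parameters, seed) via
`numpy.random.default_rng`.

* **sOCR**: lognormal with exactly moment-matched parameters
  (σ² = ln(1+cv²), μ = ln mean − σ²/2); defaults mean 4.67×10⁻¹⁷ mol/s,
  cv 0.69. The measured distribution is only known through its mean, cv
  and a right-skewed histogram; lognormal is chosen for positivity and
  heavy right tail, and the spec object keeps the family explicit.
* **Tissue morphometry cohort**: box dimensions from truncated lognormals
  at the measured means/cv (243.8, 621.6, 124.7 μm; cv 0.05, 0.28, 0.95),
  truncated to [0.2×, 3×] the mean because a cv of 0.95 would otherwise
  produce unphysical heights; density lognormal (1.95×10¹⁴ cell/m³,
  cv 0.26); volume is the product of the dimensions and cell count its
  product with density, rounded. Dimensions and density are drawn
  independently (no correlation data exist). Truncation pulls the mean
  height (and hence mean cell count) several percent below the
  untruncated values — the count check is correspondingly loose (±10%).
* **Respirometry traces**: four piecewise-constant segments
  (basal → oligomycin → FCCP → rotenone+antimycin) at fractions
  (1, 0.35, 1.6, 0.1) of the per-well basal rate — oligomycin removes
  ATP-synthase-linked respiration, FCCP uncouples to the maximal rate,
  rotenone+antimycin leave non-mitochondrial consumption — with Gaussian
  noise. The basal rate is an sOCR draw times the cells per well, so
  normalising the basal segment by cell count recovers the single-cell
  distribution (closed loop verified in tests). Injection kinetics are
  not modelled.

What the generators do *not* emulate: measurement drift and plate
effects in respirometry, correlations between tissue dimensions and
density, and any sOCR distribution shape information beyond (mean, cv).
Tests passing on these synthetic inputs validate the pipeline's
statistical machinery, not the biological fidelity of the distribution
family.

## Scaled-down problem sizes

The default test and script runs use: 5 μm (tests) / 2.5 μm (scripts)
grids and a single/double pillar-period domain for the two-phase runs;
the 12×24×10 PoM grid with 500 draws per geometry; a two-pillar-period
device at 5 μm for transport sweeps (the full v1 preset for the
near-Fickian figure, which depends on device length). These sizes are
chosen so each analysis re-runs from scratch in minutes on one core;
grid-halving checks in the tests bound the discretisation error of the
headline quantities.

## Known limitations

* The planar two-phase model shares its pinned-exit closure between both
  burst methods; neither resolves transient 3D meniscus dynamics, and the
  model concludes the straight fenestra out-pins the pillar pore at
  matched D_h (see above).
* The transport model is depth-averaged; true 3D secondary flows near
  the pillar row are not resolved, and the near-Fickian figure depends
  strongly on the modelled channel length and flow rate.
* The oxygen model assumes a uniform cell density and a literature km; D
  and the PDMS film coefficient are assumptions whose sensitivity should
  be reported alongside any headline number.
* The scaling collapse assumes the single-variable finite-size ansatz;
  model selection among alternative scaling forms is out of scope.
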