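# mpsbarrier

Computational models of a **pillar-array interfacial barrier** for
microphysiological systems (MPS, "organ-on-chip" devices). A single row
of circular pillars inside a shallow slot separates the cell chamber from
the media channels; tuning the pore size `g` and pillar height `h_b`
tunes three things at once, and this package models all three:

1. **Capillary burst valving** — during cell loading the advancing
   liquid meniscus pins at the barrier, with burst pressure reported as
   the non-dimensional `p* = Δp·D_h/γ` (`D_h = 2 h_b g/(h_b+g)` is the
   pore's hydraulic diameter). Two models: a quasi-static Young–Laplace
   pinning scan with `θ* = min(θ_c + β, 180°)` on diverging walls, and a
   reduced planar two-phase (depth-averaged Hele-Shaw + phase field)
   simulator with pressure bisection.
2. **Tunable biomolecular diffusion** — depth-averaged
   advection–diffusion of 70 kDa dextran (D = 45.8 μm²/s) from the media
   channels across the barrier; flow is throttled by the slot as
   `h_b³` (lubrication) while diffusion only as `h_b`, which is what
   makes the barrier a diffusion-dominant, height-tunable interface.
3. **Tissue oxygenation and metabolic scaling** — steady Michaelis–Menten
   oxygen reaction–diffusion, `∇·(D∇c) = sOCR·ρ_c·c/(k_m+c)`, in box
   microtissues (presets V1/V2/V3) with Dirichlet media contact on the
   lateral faces, a no-flux glass floor and a PDMS-flux roof. A
   population-of-models (PoM) driver propagates the measured single-cell
   OCR variability (lognormal, mean 4.67×10⁻¹⁷ mol/s, cv 0.69) into
   per-geometry distributions of the tissue OCR
   `B = ∮ D ∂c/∂n dS`, and a finite-size scaling collapse
   `p(B|m) = B^(−β) F(B/m^α)` (probability-contiguity residual minimised
   by differential evolution, β = 1) estimates the metabolic scaling
   exponent α.

Seed-reproducible generators for every statistical input (sOCR draws,
tissue morphometry cohorts, four-segment respirometry traces) are part of
the package, not test fixtures. See `docs/methods.md` for model details,
assumptions and limitations.

## Worked example

```python
from mpsbarrier import (
    TissueGeometry, OxygenParams, solve_oxygen, tissue_ocr,
    sample_socr, run_pom, fit_collapse, CollapseParams,
    straight_path, gap_profile, quasi_static_burst,
)

# burst pressures at matched hydraulic diameter 3.2 um
for name, path in [
    ("straight", straight_path(8e-6, 2e-6, 125e-6)),
    ("pillar", gap_profile(79.5e-6, 8e-6, height=2e-6)),
]:
    r = quasi_static_burst(path)
    print(f"{name}: dp_b = {r.burst_pressure:.3e} Pa, p* = {r.p_star:.2f}")

# steady oxygen in the largest tissue at a high single-cell OCR
field = solve_oxygen(TissueGeometry.preset("V3"), OxygenParams(), socr=6.1e-17)
print(f"min c = {field.min_c:.3f} mol/m^3, B = {tissue_ocr(field):.3e} mol/s")

# population of models + scaling collapse
geoms = [TissueGeometry.preset(k) for k in ("V1", "V2", "V3")]
pom = run_pom(geoms, OxygenParams(), sample_socr(500, seed=11))
fit = fit_collapse(pom.distribution_set(), CollapseParams())
print(f"alpha = {fit.alpha:.3f}, gamma = {fit.gamma:.3f}")
```

prints

```
straight: dp_b = 8.222e+04 Pa, p* = 3.65
pillar: dp_b = 6.728e+04 Pa, p* = 2.99
min c = 0.161 mol/m^3, B = 3.911e-13 mol/s
alpha = 0.989, gamma = -0.015
```

Reading the numbers: the quasi-static valve model puts the burst of the
straight 2×8 μm fenestra at 82 kPa and the matched-`D_h` pillar pore at
67 kPa — both barriers are set by exit-expansion pinning, and the narrow
straight mouth pins harder than the wide, smooth pillar exit. The V3
tissue's minimum oxygen concentration, 0.161 mol/m³, stays far above the
0.04 mol/m³ hypoxia threshold even at a high single-cell OCR, and its
whole-tissue uptake is 3.9×10⁻¹³ mol/s. Across V1→V2→V3 the collapse of
the PoM tissue-OCR distributions gives a mass exponent α ≈ 0.99: at these
transport parameters oxygen supply barely limits consumption, so tissue
metabolism scales almost isometrically with volume.

A thin CLI wraps the same functions, e.g.

```bash
mpsbarrier geometry --preset cardiac_mps_v1
mpsbarrier burst --geometry pillar --method quasistatic
mpsbarrier oxygen --geom V3 --socr 6.1e-17
mpsbarrier synth socr --n 1000 --seed 7 -o socr.csv
```

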