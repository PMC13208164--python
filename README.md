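# cyanoshade

Quantitative UV–Vis spectroscopy of iron–cyanide complexes, and a layered
lake model of their ability to act as prebiotic "sunscreens".

Ferrocyanide ([Fe(CN)₆]⁴⁻) and nitroprusside ([Fe(CN)₅(NO)]²⁻) absorb
strongly in the UV. In a stagnant, closed-basin lake on the early Earth they
could shield photosensitive prebiotic compounds (polynucleotides, ATP,
NADH) deeper in the water column while surface photochemistry proceeds.
`cyanoshade` is for researchers in prebiotic chemistry and astrobiology who
want to (a) reduce raw spectrometer counts into molar attenuation
coefficients for these species and (b) propagate those coefficients through
a depth- and time-resolved photochemical model of such a lake.

## The two computations

**Spectral reduction and quantitation.** A measurement is a count triplet:
sample *n*ₘ(λ), source-off background *n*_b(λ) and water-blank reference
*n*_ref(λ). The relative absorbance is

    r(λ) = 1 − (nₘ − n_b)/(n_ref − n_b) = 1 − I/I₀ = 1 − e^(−τ(λ)),

with bins excluded when the signal-to-noise ratio α = (nₘ − n_b)/n_b < 3.
Optical depths are additive over species, τ(λ) = Σᵢ σᵢ(λ) nᵢ β, with
σᵢ the attenuation cross-section, nᵢ the number density and β the cuvette
path (0.1 dm). Regressing ln(1 − r) against concentration gives a gradient
m = −β N_A σ(λ), hence the decadal molar attenuation coefficient
ε(λ) = −m/(β ln 10) with Δε = ε·Δm/m, applied independently at every 1 nm
bin of a standard series.

**Lake model.** After a post-impact haze phase (HCN rain-out accumulates
ferrocyanide; lightning-driven NOx supplies nitrate), each 1 cm layer
evolves under

    d[A]/dt = −k₁[A]·(NO₃⁻ term) − k₂[A]
    d[B]/dt = +k₁[A]·(NO₃⁻ term) − k₂[B]
    d[NO₃⁻]/dt = C·l_r·r_NOx·σ_lake/V_lake − k₁[A]·(NO₃⁻ term)

with [A] ferrocyanide, [B] nitroprusside, k₁ = 2.59×10⁻⁷ s⁻¹
(photo-oxidation, driven by 200–300 nm light) and k₂ = 5.13×10⁻⁵ s⁻¹
(photo-aquation, 300–400 nm). Both rates are attenuated per layer by the
band-integrated flux ratio χₙ(t) = ∫F⁽ⁿ⁾dλ / ∫F⁽⁰⁾dλ, computed from
Beer–Lambert transmission through everything above: kₙ = χₙ·k⁰. The model
outputs per-layer survival times, the near-linear survival-vs-depth
"shadow slope" (days m⁻¹), the transient nitroprusside layer, and protected
lifetimes for compounds such as NADH.

A `synthetic` module generates every input with known ground truth —
1/d² source fall-off, Gaussian-peak attenuation fixtures anchored at the
measured coefficients (ε_ferro(340) = 2.2×10³, ε_np(340/400/500) =
4.1×10²/1.71×10²/62.1 dm² mol⁻¹), Poisson counting noise — so the whole
chain is testable without an instrument.

## Worked example

`examples/lake_survival.py` runs a 1 m lake (100 × 1 cm layers) starting at
0.1 M ferrocyanide:

```
depth (m)  survival (days)
   0.045         5.1
   0.245        25.5
   0.495        50.9
   0.745        76.3
   0.995       101.7

shadow slope: 101.7 days/m (R^2 = 1.000000)
peak nitroprusside across layers: 4.26e-04 M

NADH at the 1 m lake floor: exposed after 101 days;
total lifetime 0.78 years (vs 0.5 years unprotected)
```

Layers bleach sequentially — each opaque centimetre shields everything
below it until its own ferrocyanide is destroyed — so survival time grows
linearly with depth (R² ≈ 1). A transient nitroprusside layer of order
10⁻¹ mM forms at the bleaching front and adds its own shading ("the shadow
of a shadow"). NADH, photolysed by 300–400 nm light with a six-month
unprotected half-life, gains the full exposure delay of its depth.

The other examples cover the spectroscopy half; e.g.
`examples/calibration_curve.py` recovers the generating attenuation
coefficients from nine noisy replicates per standard:

```
wavelength  eps_fit  eps_err  eps_true  R^2
    340 nm    514.9     0.50     515.5  1.00000
    400 nm    435.9     0.48     435.2  1.00000
    500 nm    116.3     0.43     116.5  0.99996
```

(`eps_true` is the fixture curve evaluated at the bin, i.e. the peak height
plus the tails of the neighbouring features.)

A thin CLI wraps the same library: `cyanoshade reduce` (triplets →
absorbance tables), `cyanoshade fit` (standards → ε curve + peak report),
`cyanoshade lake` (YAML config → trajectories, survival table, summary).
Every run writes a `manifest.json`; deterministic runs reproduce
byte-identical outputs.

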