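# Methods

This note records the scientific and numerical choices behind `cyanoshade`:
what is modelled, what the defaults mean, where the design was genuinely
open, and what the synthetic tests do and do not demonstrate about real
data.

## Spectral reduction

A measurement triplet (sample, background, reference) reduces to relative
absorbance r(λ) = 1 − (nₘ − n_b)/(n_ref − n_b). Choices:

* **SNR masking.** α = (nₘ − n_b)/n_b with cutoff 3; the bin is *retained*
  iff α ≥ 3 (the boundary is kept — "exclude iff α < cutoff" read
  literally). Bins with n_b = 0 or n_ref ≤ n_b are masked. Raising the
  cutoff can only remove bins (monotonicity, property-tested).
* **Out-of-range r.** Noise can push sample counts below background
  (r > 1) or above reference (r < 0). r is clipped to 1 — the log-domain
  transforms diverge there, and such bins are excluded from calibration
  fits — while negative r is kept for replicate averaging (dropping it
  would bias near-blank means upward) and excluded from log fits.
* **Replicates.** Nine spectra per standard (three bench distances × three
  repeats) are averaged bin-wise with the **sample** (n−1) standard
  deviation. A bin survives aggregation only if it survives in *every*
  replicate (intersection). The union alternative would average trusted
  with untrusted values; intersection is conservative and loses more bins
  at high optical depth, which mirrors how heavily absorbing standards
  lose their saturated cores.

## Quantitation

σ(λ) = −ln(1 − r)/(β N_A c) and ε = N_A σ/ln 10 (dm² mol⁻¹; equal to
0.1 × M⁻¹ cm⁻¹). The per-wavelength calibration regresses y = ln(1 − r)
on concentration; ε = −m/(β ln 10), Δε = ε Δm/m with Δm the standard error
of the gradient, R² reported per bin.

* **Free intercept by default.** Beer–Lambert predicts a zero intercept,
  but baseline offsets are real in bench data and the slope is what the
  conversion consumes either way; a through-origin mode is available
  (`fit_intercept=False`).
* **Error transfer** uses the fractional-error identity only (Δε/ε = Δm/m),
  not full covariance propagation; combined-mixture uncertainty treats the
  total cross-section error as the linear sum of the constituents'.
* Bins with fewer than three usable standards are left undefined (NaN)
  rather than extrapolated.

## Synthetic data: what it emulates, what it does not

The generator reproduces the measurement chain's structure: a broadband
source whose received signal falls exactly as (d_ref/d)² (reference
position 81 mm; standard positions 81/231/581 mm), Beer–Lambert
transmission through a 0.1 dm cuvette with additive optical depths, a flat
detector background (default 100 counts/bin), Poisson counting noise, and
an optional fractional concentration jitter standing in for
weighing/dilution error. Attenuation fixtures are sums of Gaussians with
peak heights anchored at the measured coefficients; the widths default to
60 nm because no width is tabulated — they are a modelling choice and are
configurable everywhere.

Not emulated: exposure-time optimisation, dark-current drift, wavelength
calibration error, stray light, scattering by concentrated solutions, and
any non-Gaussian structure of the true attenuation curves. Passing tests
therefore demonstrate that the *pipeline algebra* is exact and that the
statistical precision under counting noise is as expected — not that the
Gaussian fixtures match the real curves off-peak (see "Known
limitations").

## Lake model

Geometry and constants (all configurable): depth 1 or 5 m in 1 cm layers,
surface area 10³ m², catchment factor C = 500, k₁ = 2.59×10⁻⁷ s⁻¹,
k₂ = 5.13×10⁻⁵ s⁻¹, lightning energy flux 6.5×10⁻⁵ J m⁻² s⁻¹, NOx yield
2×10⁻⁹ mol J⁻¹, HCN rain-out 10⁸ molecules cm⁻² s⁻¹ over a 10³ yr haze,
ferrocyanide ceiling 0.1 M, dt = 0.07 days, 1 nm bins, photo-oxidation
band [200, 300) nm, photo-aquation band [300, 400) nm.

* **Initial conditions.** Catchment-amplified HCN rain-out over the haze
  phase yields ≈ 4.4 mM ferrocyanide for the 1 m lake (six cyanides per
  complex) — comfortably below the 0.1 M ceiling. The favourable upper
  limit the model explores is therefore set explicitly:
  `initial_ferrocyanide` defaults to 0.1 M, with the rain-out calculation
  available via `initial_ferrocyanide=None`. Nitrate accumulates at the
  lightning supply rate for the whole haze phase (≈ 2.1 mM for 1 m;
  supply scales as 1/depth).
* **Nitrate kinetics.** k₁ is quoted in s⁻¹ although the production term is
  written bimolecularly. The default "saturated" mode reads the printed
  unit at face value: production = k₁[A] whenever nitrate is present,
  consuming nitrate mole-per-mole with consumption clamped at what the
  layer holds plus the step's supply. This reproduces transient
  nitroprusside of order 10⁻¹ mM per layer, consistent with the closed-form
  single-layer peak k₁A₀/(k₂e) ≈ 1.9×10⁻⁴ M at A₀ = 0.1 M. A
  "bimolecular" mode (k₁ as dm³ mol⁻¹ s⁻¹) is provided for sensitivity
  analysis; with millimolar nitrate it produces ~10²–10³ times less
  nitroprusside.
* **Radiative transfer.** Per layer, z(λ) = 10^(−Σᵢ εᵢcᵢβ_layer); the rate
  constants of layer n use the flux arriving at its **top** (exclusive
  cumulative optical depth), so the surface layer is never self-shielded.
  χ is the band-integrated flux ratio; the surface actinic spectrum enters
  only through band weighting (the rates are surface-calibrated), and a
  flat in-band weighting is the default with a 5772 K blackbody
  alternative — in the optically thick regime the choice moves the shadow
  slope by well under 10% (tested).
* **Nitroprusside below 300 nm** is unmeasured; its ε defaults to zero in
  the photo-oxidation band, with a "mirror" option holding its 340 nm
  value flat below 300 nm for the qualitative sensitivity argument.
* **Extra absorbers** (e.g. ferrous-lake ions) are accepted as
  user-supplied curve/concentration pairs and enter the per-layer optical
  depth statically; none are shipped as authoritative values.
* **Integration.** Within a step the radiation field is frozen and the
  then-linear chemistry pair is advanced with its exact exponential
  solution (the nitrate clamp rescales the production channel once if it
  would overdraw the pool). At dt = 0.07 days the fastest rate gives
  k₂·dt ≈ 0.31, where a plain forward-Euler update would decay ~20% too
  fast per step; the exponential update is exact for constant χ, meets the
  closed-form single-layer checks to <0.5%, and shifts survival times by
  <2% under dt halving (the residual being the one-step radiation lag).
  Configurations whose k·dt ≥ 1 are rejected outright as unresolved.
  The stepped model was additionally cross-checked against an adaptive
  ODE integration of the same layered equations (tested to 5%).
* **Survival.** A layer "survives" until [A] ≤ 1% of its initial value
  (checked from t = 0 with ≤, so a 100% threshold gives zero survival).
  The 1% figure is an implementation choice, not a measured one; the slope
  of survival vs depth is insensitive to it because the bleaching front
  advances periodically, while absolute survival times shift by
  ln(threshold)/k_eff. The shadow slope is an ordinary least-squares fit
  (with intercept) of survival time against layer mid-depth, censored
  layers excluded.
* **Exposure delay** for a depth is the survival time of the layer
  immediately above it; protected lifetimes add that delay to a compound's
  unprotected lifetime.

## Problem sizes

The acceptance script runs the full 5 m × 500-layer simulations
(≈ 7300 steps at 0.1 M, ≈ 100 at 0.1 mM; under a minute on one CPU). The
test suite uses 1-layer to 100-layer lakes and 0.06–0.2 m stacks for the
closed-form, cross-integration and dt-robustness checks, and 601-bin
spectra with nine replicates per standard for the noise-recovery checks.

## Known limitations

* The shadow slope in the optically thick (0.1 M) regime is governed by
  the per-layer *logarithmic* band optical depth, i.e. by the off-peak
  shape of the attenuation curves across 300–400 nm, which the Gaussian
  fixtures only approximate; with measured full curves the slope can
  differ substantially (see `examples/width_sensitivity.py` for the
  quantitative sweep — the optically thin 0.1 mM slope is proportionally
  far more shape-sensitive). The layer thickness is likewise part of the
  model, not a converged discretisation: a layer bleaches as a unit at the
  rate its top receives, so thinner layers slow the front logarithmically.
* No diffusion, convection or mixing (the bleaching front outruns ~31 yr
  diffusion timescales); no thermal degradation; no photo-aquation
  reversibility or sulphite recycling; no solid-phase ferrocyanide
  exchange with the lake floor; k₂ is the single favourable
  (pH 8–9, 280 K) value.
* The quantitation module performs only the additive two-species
  combination, not general spectral unmixing, and no baseline-drift
  correction.
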