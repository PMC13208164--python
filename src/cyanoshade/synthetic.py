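"""Synthetic spectrometer data with known ground truth.

Emulates the measurement chain end to end: a broadband source whose
received irradiance falls off as 1/d^2 with distance, Beer-Lambert
transmission through a 0.1 dm cuvette of one or two species with
Gaussian-peak attenuation curves, a constant detector background, and
Poisson counting noise.  Every downstream stage of the pipeline can be
exercised against the generating truth without any instrument.

The default attenuation fixtures anchor the Gaussian peak heights at the
measured coefficients: ferrocyanide has a single 340 nm feature at
2.2e3 dm^2 mol^-1; nitroprusside has features at 340, 400 and 500 nm with
heights 4.1e2, 1.71e2 and 62.1 dm^2 mol^-1.  Peak widths are not tabulated
anywhere, so a common 60 nm Gaussian width is used and is configurable.
"""

from __future__ import annotations

from collections.abc import Sequence
from dataclasses import dataclass, field

import numpy as np
from scipy.constants import c as _c_light, h as _h, k as _k_B

from .spectra import AttenuationCurve, CountSpectrum, FluxSpectrum, MixtureSample

#: the nearest bench position of the cuvette to the source (mm); the 1/d^2
#: law is expressed relative to this distance.
REFERENCE_DISTANCE_MM = 81.0

#: the three bench positions at which standards are measured (mm)
STANDARD_DISTANCES_MM = (81.0, 231.0, 581.0)


def default_wavelength_grid() -> np.ndarray:
    """1 nm grid over the spectrometer range, 200-800 nm inclusive."""
    return np.arange(200.0, 801.0)


@dataclass
class EpsilonPeakSpec:
    """One Gaussian absorption feature: centre (nm), height (dm^2 mol^-1),
    width (nm, Gaussian standard deviation)."""

    center: float
    height: float
    width: float

    def __post_init__(self) -> None:
        if self.height < 0:
            raise ValueError("peak height must be nonnegative")
        if self.width <= 0:
            raise ValueError("peak width must be positive")


def make_epsilon_curve(
    peaks: Sequence[EpsilonPeakSpec],
    grid: np.ndarray | None = None,
    species: str = "",
) -> AttenuationCurve:
    """Sum-of-Gaussians attenuation curve on a 1 nm grid.

    epsilon(lambda) = sum_p height_p * exp(-(lambda - center_p)^2 / (2 width_p^2)).
    An empty peak list yields the zero curve.
    """
    if grid is None:
        grid = default_wavelength_grid()
    grid = np.asarray(grid, dtype=float)
    if grid.size > 1 and np.any(np.diff(grid) <= 0):
        raise ValueError("wavelength grid must be strictly ascending")
    eps = np.zeros_like(grid)
    for p in peaks:
        eps = eps + p.height * np.exp(-((grid - p.center) ** 2) / (2.0 * p.width**2))
    return AttenuationCurve(grid, eps, species=species)


def ferrocyanide_curve(grid: np.ndarray | None = None, width: float = 60.0) -> AttenuationCurve:
    """Default ferrocyanide fixture: one 340 nm peak at 2.2e3 dm^2 mol^-1."""
    return make_epsilon_curve(
        [EpsilonPeakSpec(340.0, 2.2e3, width)], grid, species="ferrocyanide"
    )


def nitroprusside_curve(grid: np.ndarray | None = None, width: float = 60.0) -> AttenuationCurve:
    """Default nitroprusside fixture: 340/400/500 nm peaks at the measured heights."""
    return make_epsilon_curve(
        [
            EpsilonPeakSpec(340.0, 4.1e2, width),
            EpsilonPeakSpec(400.0, 1.71e2, width),
            EpsilonPeakSpec(500.0, 62.1, width),
        ],
        grid,
        species="nitroprusside",
    )


@dataclass
class SourceModel:
    """Broadband source as seen by the detector.

    ``base_counts`` is the noiseless reference signal (counts above
    background per bin) at ``reference_distance`` mm; it may be a scalar for
    a flat profile or an array on ``wavelength``.  Received irradiance
    scales exactly as (d_ref / d)^2.  ``distance`` is the current cuvette
    position on the bench.
    """

    wavelength: np.ndarray = field(default_factory=default_wavelength_grid)
    base_counts: float | np.ndarray = 5.0e4
    reference_distance: float = REFERENCE_DISTANCE_MM
    distance: float = REFERENCE_DISTANCE_MM

    def __post_init__(self) -> None:
        self.wavelength = np.asarray(self.wavelength, dtype=float)
        base = np.broadcast_to(np.asarray(self.base_counts, dtype=float), self.wavelength.shape)
        if np.any(base <= 0):
            raise ValueError("base source counts must be strictly positive on the grid")
        if self.reference_distance <= 0 or self.distance <= 0:
            raise ValueError("distances must be positive")

    def received_signal(self, distance: float | None = None) -> np.ndarray:
        """Noiseless above-background counts at ``distance`` mm (1/d^2 law)."""
        d = self.distance if distance is None else distance
        if d <= 0:
            raise ValueError("distance must be positive")
        base = np.broadcast_to(np.asarray(self.base_counts, dtype=float), self.wavelength.shape)
        return base * (self.reference_distance / d) ** 2

    def at(self, distance: float) -> "SourceModel":
        return SourceModel(self.wavelength, self.base_counts, self.reference_distance, distance)


@dataclass
class NoiseModel:
    """Detector background and counting-noise configuration.

    With ``kind="none"`` and ``replicate_jitter=0`` the generated counts are
    deterministic.  ``kind="poisson"`` draws every count from a Poisson law
    with the noiseless value as its mean.  ``replicate_jitter`` is a
    fractional Gaussian scatter applied to the sample concentrations,
    standing in for weighing/dilution error between replicates.
    """

    background_level: float = 100.0
    kind: str = "poisson"
    replicate_jitter: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("none", "poisson"):
            raise ValueError("noise kind must be 'none' or 'poisson'")
        if self.background_level < 0:
            raise ValueError("background level must be nonnegative")
        if self.replicate_jitter < 0:
            raise ValueError("replicate jitter must be nonnegative")


def simulate_count_triplet(
    source: SourceModel,
    mixture: MixtureSample,
    curves: Sequence[AttenuationCurve],
    noise: NoiseModel | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[CountSpectrum, CountSpectrum, CountSpectrum]:
    """Generate one (background, reference, sample) measurement triplet.

    The noiseless sample obeys Beer-Lambert transmission,

        n_m = n_b + (n_ref - n_b) * 10^(-sum_i epsilon_i c_i beta),

    so reducing a noiseless triplet recovers the generating optical depth
    exactly.  ``rng`` overrides the generator derived from ``noise.seed``;
    identical seeds give bit-identical triplets.
    """
    noise = noise or NoiseModel(kind="none")
    if len(curves) != len(mixture.concentrations):
        raise ValueError(f"{len(curves)} curves but {len(mixture.concentrations)} concentrations")
    if rng is None:
        rng = np.random.default_rng(noise.seed)

    grid = source.wavelength
    signal = source.received_signal()
    bg = np.full(grid.shape, float(noise.background_level))

    concs = np.array(mixture.concentrations, dtype=float)
    if noise.replicate_jitter > 0:
        concs = np.clip(concs * (1.0 + noise.replicate_jitter * rng.standard_normal(concs.shape)), 0.0, None)

    decadal = np.zeros_like(grid)
    for curve, c in zip(curves, concs):
        decadal = decadal + curve.interpolate(grid) * c * mixture.path_length
    transmitted = signal * 10.0 ** (-decadal)

    nb, nref, nm = bg, bg + signal, bg + transmitted
    if noise.kind == "poisson":
        nb = rng.poisson(nb).astype(float)
        nref = rng.poisson(nref).astype(float)
        nm = rng.poisson(nm).astype(float)
    return (
        CountSpectrum(grid, nb, role="background"),
        CountSpectrum(grid, nref, role="reference"),
        CountSpectrum(grid, nm, role="sample"),
    )


def simulate_replicate_triplets(
    source: SourceModel,
    mixture: MixtureSample,
    curves: Sequence[AttenuationCurve],
    noise: NoiseModel,
    distances: Sequence[float] = STANDARD_DISTANCES_MM,
    repeats: int = 3,
) -> list[tuple[CountSpectrum, CountSpectrum, CountSpectrum]]:
    """Measurement campaign for one standard: ``repeats`` triplets at each
    bench distance (3 x 3 = 9 by default), with independent noise streams
    spawned deterministically from ``noise.seed``."""
    children = np.random.SeedSequence(noise.seed).spawn(len(distances) * repeats)
    out = []
    i = 0
    for d in distances:
        src = source.at(d)
        for _ in range(repeats):
            rng = np.random.default_rng(children[i])
            i += 1
            out.append(simulate_count_triplet(src, mixture, curves, noise, rng=rng))
    return out


def make_actinic_flux(
    kind: str = "flat",
    grid: np.ndarray | None = None,
    value: float = 1.0,
    temperature: float = 5772.0,
    normalization: float | None = None,
) -> FluxSpectrum:
    """Actinic flux binned to 1 nm: flat, or a blackbody at ``temperature``.

    The blackbody uses the Planck spectral radiance shape and, when
    ``normalization`` is given, is rescaled so its trapezoidal integral over
    the grid equals it.  The grid must cover at least 200-400 nm at steps no
    coarser than 1 nm.
    """
    if grid is None:
        grid = np.arange(200.0, 401.0)
    grid = np.asarray(grid, dtype=float)
    steps = np.diff(grid)
    if grid.size < 2 or np.any(steps <= 0):
        raise ValueError("flux grid must be strictly ascending")
    if np.any(steps > 1.0 + 1e-9):
        raise ValueError("flux grid must be binned at 1 nm or finer")
    if grid[0] > 200.0 or grid[-1] < 400.0:
        raise ValueError("flux grid must cover at least 200-400 nm")

    if kind == "flat":
        flux = np.full(grid.shape, float(value))
    elif kind == "blackbody":
        lam = grid * 1e-9  # m
        flux = (2.0 * _h * _c_light**2 / lam**5) / np.expm1(_h * _c_light / (lam * _k_B * temperature))
    else:
        raise ValueError("flux kind must be 'flat' or 'blackbody'")

    if normalization is not None:
        integral = np.trapezoid(flux, grid)
        if integral <= 0:
            raise ValueError("cannot normalize a zero-integral flux")
        flux = flux * (normalization / integral)
    return FluxSpectrum(grid, flux)
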