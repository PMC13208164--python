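"""Layered stagnant-lake photochemistry of ferrocyanide and nitroprusside.

The model follows a closed-basin lake through a post-impact scenario.
During an initial haze phase no UV reaches the surface; HCN rain-out
(amplified by the catchment) accumulates ferrocyanide while lightning-driven
NOx deposition accumulates nitrate.  Once the haze clears, each 1 cm layer
evolves under the coupled kinetics

    d[A]/dt    = -k1 [A] (nitrate term) - k2 [A]
    d[B]/dt    = +k1 [A] (nitrate term) - k2 [B]
    d[NO3-]/dt = C l_r r_NOx sigma_lake / V_lake - k1 [A] (nitrate term)

where [A] is ferrocyanide, [B] nitroprusside, k1 the photo-oxidation rate
(ferrocyanide + nitrate -> nitroprusside, driven by 200-300 nm light) and
k2 the photo-aquation rate destroying both complexes (300-400 nm light).
Both rate constants are surface-calibrated for early-Sun irradiation and
are attenuated per layer by the band-integrated flux ratio

    chi_n(t) = integral_band F_n(lambda, t) dlambda / integral_band F_0(lambda, t) dlambda,

with the flux between layers following Beer-Lambert transmission through
the current ferrocyanide/nitroprusside column (plus any user-supplied
static absorbers).  k_n = chi_n * k0 for each band.

Because k1 is quoted in s^-1 while Eq-style bimolecular kinetics would
require dm^3 mol^-1 s^-1, the default "saturated" nitrate mode treats the
production term as k1*[A] whenever nitrate is present, consuming nitrate
mole-per-mole and clamping consumption at the available nitrate per step;
a "bimolecular" mode (k1 read as dm^3 mol^-1 s^-1) is provided for
sensitivity analysis.

Within a time step the radiation field is frozen and the then-linear
chemistry is advanced with its exact (exponential) solution, so single-layer
trajectories under constant illumination match the closed forms to machine
precision and the scheme is robust at dt = 0.07 days.
"""

from __future__ import annotations

from collections.abc import Sequence
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.constants import N_A

from .spectra import AttenuationCurve, FluxSpectrum
from . import synthetic

SECONDS_PER_DAY = 86400.0
DAYS_PER_YEAR = 365.25
SECONDS_PER_YEAR = DAYS_PER_YEAR * SECONDS_PER_DAY

#: number of cyanide ligands locked up per ferrocyanide complex
CYANIDES_PER_COMPLEX = 6


@dataclass
class LakeConfig:
    """Geometry, rates and numerics of one lake run.

    Units: depths and areas in m; concentrations in mol dm^-3; rate
    constants in s^-1 (converted internally to day^-1); ``dt`` in days.
    ``initial_ferrocyanide`` sets the post-haze starting concentration
    directly (default 0.1 M, the favourable upper limit the model
    explores); set it to ``None`` to take the concentration from the
    HCN-rainout accumulation capped at ``ferrocyanide_cap``.
    """

    depth: float = 1.0  # m
    surface_area: float = 1.0e3  # m^2
    catchment: float = 500.0  # dimensionless drainage amplification
    layer_thickness: float = 0.01  # m
    k1: float = 2.59e-7  # s^-1, photo-oxidation (200-300 nm band)
    k2: float = 5.13e-5  # s^-1, photo-aquation (300-400 nm band)
    lightning_rate: float = 6.5e-5  # J m^-2 s^-1
    nox_yield: float = 2.0e-9  # mol J^-1
    hcn_rainout: float = 1.0e8  # molecules cm^-2 s^-1
    haze_duration_years: float = 1.0e3
    ferrocyanide_cap: float = 0.1  # mol dm^-3 (solubility-style ceiling)
    initial_ferrocyanide: float | None = 0.1  # mol dm^-3
    dt: float = 0.07  # days
    band_k1: tuple[float, float] = (200.0, 300.0)  # nm, half-open
    band_k2: tuple[float, float] = (300.0, 400.0)
    nitrate_mode: str = "saturated"  # or "bimolecular"
    survival_threshold: float = 0.01  # fraction of a layer's initial [A]
    horizon_days: float = 3650.0
    nitroprusside_uv: str = "zero"  # epsilon below 300 nm: "zero" or "mirror"
    extra_absorbers: tuple[tuple[AttenuationCurve, float], ...] = ()
    record_every: int = 10  # trajectory thinning, in steps

    def __post_init__(self) -> None:
        if min(self.k1, self.k2, self.lightning_rate, self.nox_yield, self.hcn_rainout) < 0:
            raise ValueError("all rates must be nonnegative")
        if self.depth <= 0 or self.surface_area <= 0 or self.layer_thickness <= 0:
            raise ValueError("depth, surface area and layer thickness must be positive")
        n = self.depth / self.layer_thickness
        if abs(n - round(n)) > 1e-9:
            raise ValueError("depth must be an integer multiple of layer_thickness")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.nitrate_mode not in ("saturated", "bimolecular"):
            raise ValueError("nitrate_mode must be 'saturated' or 'bimolecular'")
        if self.nitroprusside_uv not in ("zero", "mirror"):
            raise ValueError("nitroprusside_uv must be 'zero' or 'mirror'")
        if not (0.0 <= self.survival_threshold <= 1.0):
            raise ValueError("survival_threshold must be a fraction in [0, 1]")
        # accuracy guard: the time step must resolve the fastest photo-rate
        for name, k in (("k1", self.k1), ("k2", self.k2)):
            if k * SECONDS_PER_DAY * self.dt >= 1.0:
                raise ValueError(
                    f"dt = {self.dt} days does not resolve {name} = "
                    f"{k * SECONDS_PER_DAY:.3g} day^-1 (k*dt must stay below 1)"
                )

    @property
    def n_layers(self) -> int:
        return int(round(self.depth / self.layer_thickness))

    @property
    def volume(self) -> float:
        """Lake volume in m^3."""
        return self.surface_area * self.depth

    @property
    def k1_per_day(self) -> float:
        return self.k1 * SECONDS_PER_DAY

    @property
    def k2_per_day(self) -> float:
        return self.k2 * SECONDS_PER_DAY

    @property
    def layer_thickness_dm(self) -> float:
        return self.layer_thickness * 10.0

    @property
    def layer_depths(self) -> np.ndarray:
        """Mid-depth of each layer in metres, surface first."""
        return (np.arange(self.n_layers) + 0.5) * self.layer_thickness


@dataclass
class LakeState:
    """Per-layer concentrations (mol dm^-3) at one instant."""

    time: float  # days since the haze cleared
    ferrocyanide: np.ndarray  # [A]
    nitroprusside: np.ndarray  # [B]
    nitrate: np.ndarray  # [NO3-]

    def __post_init__(self) -> None:
        self.ferrocyanide = np.asarray(self.ferrocyanide, dtype=float)
        self.nitroprusside = np.asarray(self.nitroprusside, dtype=float)
        self.nitrate = np.asarray(self.nitrate, dtype=float)


def nitrate_supply_rate(config: LakeConfig) -> float:
    """Lightning-driven nitrate supply in mol dm^-3 s^-1.

    rate = C * l_r * r_NOx * sigma_lake / V_lake; the areal NOx production
    over the catchment is stirred into the lake volume.
    """
    if config.volume <= 0:
        raise ValueError("lake volume must be positive")
    per_m3 = (
        config.catchment
        * config.lightning_rate
        * config.nox_yield
        * config.surface_area
        / config.volume
    )
    return per_m3 / 1000.0  # mol m^-3 -> mol dm^-3


def init_haze_phase(config: LakeConfig) -> LakeState:
    """State at the end of the haze phase (t = 0 of the irradiated run).

    Ferrocyanide accumulates from catchment-amplified HCN rain-out (six
    cyanides per complex), uniformly mixed over the column and capped at
    ``ferrocyanide_cap``; with ``initial_ferrocyanide`` set, that value
    (still capped) is used instead.  Nitrate accumulates at the lightning
    supply rate for the whole haze duration; no nitroprusside forms in the
    dark.
    """
    n = config.n_layers
    t_haze_s = config.haze_duration_years * SECONDS_PER_YEAR
    if config.initial_ferrocyanide is not None:
        a0 = min(config.ferrocyanide_cap, config.initial_ferrocyanide)
    else:
        depth_cm = config.depth * 100.0
        molecules_per_cm2 = config.catchment * config.hcn_rainout * t_haze_s
        mol_per_cm3 = molecules_per_cm2 / depth_cm / (CYANIDES_PER_COMPLEX * N_A)
        a0 = min(config.ferrocyanide_cap, mol_per_cm3 * 1000.0)
    no3 = nitrate_supply_rate(config) * t_haze_s
    return LakeState(
        time=0.0,
        ferrocyanide=np.full(n, a0),
        nitroprusside=np.zeros(n),
        nitrate=np.full(n, no3),
    )


def _band_mask(grid: np.ndarray, band: tuple[float, float]) -> np.ndarray:
    lo, hi = band
    return (grid >= lo) & (grid < hi)


def _epsilon_matrix(
    config: LakeConfig,
    curves: Sequence[AttenuationCurve],
    grid: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(eps_A, eps_B, static extra decadal OD per layer) on ``grid``."""
    ferro, nitro = curves
    eps_a = ferro.interpolate(grid)
    eps_b = nitro.interpolate(grid)
    below = grid < 300.0
    if config.nitroprusside_uv == "zero":
        eps_b = np.where(below, 0.0, eps_b)
    else:  # mirror: hold the (unmeasured) far-UV value at the 340 nm level
        eps_b = np.where(below, np.interp(340.0, nitro.wavelength, nitro.epsilon), eps_b)
    extra_od = np.zeros_like(grid)
    for curve, conc in config.extra_absorbers:
        extra_od = extra_od + curve.interpolate(grid) * conc * config.layer_thickness_dm
    return eps_a, eps_b, extra_od


def layer_transmission(
    state: LakeState,
    curves: Sequence[AttenuationCurve],
    config: LakeConfig,
    grid: np.ndarray | None = None,
) -> np.ndarray:
    """Per-layer, per-bin flux ratio z(lambda) across one layer thickness.

    z = 10^(-(eps_A [A] + eps_B [B]) * beta_layer - extra), with beta_layer
    the layer thickness in dm.  Shape (n_layers, n_bins), surface first.
    """
    if grid is None:
        grid = np.arange(200.0, 400.0)
    eps_a, eps_b, extra_od = _epsilon_matrix(config, curves, grid)
    od = (
        state.ferrocyanide[:, None] * eps_a[None, :]
        + state.nitroprusside[:, None] * eps_b[None, :]
    ) * config.layer_thickness_dm + extra_od[None, :]
    return 10.0 ** (-od)


def chi(
    flux: FluxSpectrum,
    transmissions: np.ndarray,
    band: tuple[float, float],
) -> np.ndarray:
    """Band-integrated flux ratio chi_n for the top of each layer.

    ``transmissions`` stacks per-layer z(lambda) surface-first, on the same
    grid as ``flux``.  Entry 0 of the result is the surface (chi_0 = 1);
    entry n is the flux arriving below the first n layers, relative to the
    surface.  Deeper is never brighter.
    """
    grid = flux.wavelength
    z = np.asarray(transmissions, dtype=float)
    if z.ndim != 2 or z.shape[1] != grid.size:
        raise ValueError("transmissions must have shape (n_layers, n_bins) on the flux grid")
    m = _band_mask(grid, band)
    f0 = flux.flux[m]
    total = f0.sum()
    if total <= 0:
        raise ValueError(f"flux has no power inside the band {band}")
    cum = np.cumprod(z[:, m], axis=0)
    out = np.empty(z.shape[0] + 1)
    out[0] = 1.0
    out[1:] = cum @ f0 / total
    return out


def _advance(
    state: LakeState,
    chi1: np.ndarray,
    chi2: np.ndarray,
    config: LakeConfig,
    supply_per_day: float,
) -> LakeState:
    """One exact-exponential step with per-layer rates frozen at chi*k0."""
    dt = config.dt
    a, b, no3 = state.ferrocyanide, state.nitroprusside, state.nitrate
    k1n = config.k1_per_day * chi1
    k2n = config.k2_per_day * chi2

    if config.nitrate_mode == "bimolecular":
        # k1 read as dm^3 mol^-1 day^-1; effective first-order rate in [A]
        k1_eff = k1n * no3
    else:
        k1_eff = np.where(no3 > 0, k1n, 0.0)

    def consumed(k1_eff: np.ndarray) -> np.ndarray:
        ktot = k1_eff + k2n
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(ktot > 0, k1_eff / np.where(ktot > 0, ktot, 1.0), 0.0)
        return a * frac * -np.expm1(-ktot * dt)

    # nitrate actually available this step bounds the production channel
    avail = no3 + supply_per_day * dt
    used = consumed(k1_eff)
    over = used > avail
    if np.any(over):
        with np.errstate(over="ignore"):
            scale = np.where(over, avail / np.where(used > 0, used, 1.0), 1.0)
        k1_eff = k1_eff * scale
        used = np.minimum(consumed(k1_eff), avail)

    ktot = k1_eff + k2n
    decay2 = np.exp(-k2n * dt)
    a_new = a * np.exp(-ktot * dt)
    # exact increment of the linear pair over the step
    b_new = b * decay2 + a * decay2 * -np.expm1(-k1_eff * dt)
    no3_new = np.maximum(no3 + supply_per_day * dt - used, 0.0)
    return LakeState(
        time=state.time + dt,
        ferrocyanide=np.maximum(a_new, 0.0),
        nitroprusside=np.maximum(b_new, 0.0),
        nitrate=no3_new,
    )


def step(
    state: LakeState,
    chi_k1: np.ndarray,
    chi_k2: np.ndarray,
    config: LakeConfig,
) -> LakeState:
    """Advance every layer by one time step under given attenuation factors.

    ``chi_k1``/``chi_k2`` are the per-layer band attenuation factors (one
    value per layer, at the top of the layer).  Concentrations stay
    nonnegative; ferrocyanide never increases.
    """
    chi_k1 = np.broadcast_to(np.asarray(chi_k1, dtype=float), state.ferrocyanide.shape)
    chi_k2 = np.broadcast_to(np.asarray(chi_k2, dtype=float), state.ferrocyanide.shape)
    return _advance(state, chi_k1, chi_k2, config, nitrate_supply_rate(config) * SECONDS_PER_DAY)


@dataclass
class SimulationResult:
    """Trajectories and summary outputs of one lake run."""

    config: LakeConfig
    times: np.ndarray  # recorded instants, days
    ferrocyanide: np.ndarray  # (n_records, n_layers)
    nitroprusside: np.ndarray
    nitrate: np.ndarray
    chi_k1: np.ndarray  # (n_records, n_layers), at the top of each layer
    chi_k2: np.ndarray
    survival_days: np.ndarray  # per layer; NaN where censored
    censored: np.ndarray  # per layer, bool
    peak_nitroprusside: np.ndarray  # per layer running maximum of [B]
    initial: LakeState

    @property
    def layer_depths(self) -> np.ndarray:
        return self.config.layer_depths

    def survival_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "depth_m": self.layer_depths,
                "survival_days": self.survival_days,
                "censored": self.censored,
                "peak_nitroprusside_M": self.peak_nitroprusside,
            }
        )

    def trajectory_frame(self) -> pd.DataFrame:
        """Long-format table (time, layer, depth, concentrations, chi)."""
        nrec, nlay = self.ferrocyanide.shape
        return pd.DataFrame(
            {
                "time_days": np.repeat(self.times, nlay),
                "layer": np.tile(np.arange(nlay), nrec),
                "depth_m": np.tile(self.layer_depths, nrec),
                "ferrocyanide_M": self.ferrocyanide.ravel(),
                "nitroprusside_M": self.nitroprusside.ravel(),
                "nitrate_M": self.nitrate.ravel(),
                "chi_k1": self.chi_k1.ravel(),
                "chi_k2": self.chi_k2.ravel(),
            }
        )

    def exposure_delay(self, depth: float) -> float:
        """Days until the layer at ``depth`` loses the shielding above it.

        Operationally: the survival time of the layer immediately above.
        The surface is exposed from t = 0.  NaN if the layer above never
        depletes within the horizon (censored).
        """
        idx = min(int(np.floor(depth / self.config.layer_thickness - 1e-9)), self.config.n_layers - 1)
        if idx <= 0:
            return 0.0
        return float(self.survival_days[idx - 1])

    def shadow_slope(self) -> "ShadowSlope":
        return shadow_slope(self.layer_depths, self.survival_days)


@dataclass
class ShadowSlope:
    """Linear growth of ferrocyanide survival time with depth."""

    slope: float  # days per metre
    intercept: float  # days
    slope_err: float
    r_squared: float
    n_points: int

    def predict(self, depth) -> np.ndarray:
        """Extrapolated total survival time (days) at ``depth`` metres."""
        return self.slope * np.asarray(depth, dtype=float) + self.intercept


def shadow_slope(depths: np.ndarray, survival_days: np.ndarray) -> ShadowSlope:
    """Least-squares slope of survival time against depth (days m^-1).

    Censored layers (NaN survival) are excluded; at least three points must
    remain.
    """
    depths = np.asarray(depths, dtype=float)
    survival = np.asarray(survival_days, dtype=float)
    keep = np.isfinite(survival)
    if keep.sum() < 3:
        raise ValueError("need at least 3 uncensored survival points to fit a slope")
    fit = stats.linregress(depths[keep], survival[keep])
    return ShadowSlope(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        slope_err=float(fit.stderr),
        r_squared=float(fit.rvalue**2),
        n_points=int(keep.sum()),
    )


def survival_time(result: SimulationResult, threshold_fraction: float | None = None) -> np.ndarray:
    """Per-layer days until [A] first falls below a fraction of its start.

    With the default (the threshold the run was configured with) the exact
    crossing times tracked during stepping are returned; any other fraction
    is evaluated on the recorded (thinned) trajectory, so its resolution is
    ``record_every`` steps.  Censored layers are NaN.
    """
    if threshold_fraction is None or threshold_fraction == result.config.survival_threshold:
        return result.survival_days.copy()
    if not (0.0 <= threshold_fraction <= 1.0):
        raise ValueError("threshold_fraction must be in [0, 1]")
    a0 = result.initial.ferrocyanide
    thresh = threshold_fraction * a0
    below = result.ferrocyanide <= thresh[None, :]
    out = np.full(result.config.n_layers, np.nan)
    for j in range(out.size):
        hits = np.nonzero(below[:, j])[0]
        if hits.size:
            out[j] = result.times[hits[0]]
    return out


def protected_lifetime(exposure_delay_days: float, unprotected_lifetime_days: float) -> float:
    """Total lifetime of a photosensitive compound sitting below the shield.

    The compound is safe until its depth becomes exposed and then lives out
    its unprotected lifetime: the two durations add.
    """
    if exposure_delay_days < 0 or unprotected_lifetime_days < 0:
        raise ValueError("durations must be nonnegative")
    return exposure_delay_days + unprotected_lifetime_days


def run(
    config: LakeConfig,
    curves: Sequence[AttenuationCurve] | None = None,
    flux: FluxSpectrum | None = None,
) -> SimulationResult:
    """Integrate the lake from the end of the haze phase.

    ``curves`` is the (ferrocyanide, nitroprusside) attenuation pair; the
    Gaussian-peak fixtures are used by default.  ``flux`` is the surface
    actinic spectrum on a 1 nm grid covering both bands (flat by default;
    since the rate constants are surface-calibrated the spectrum enters only
    through the band weighting of chi).  The run stops when every layer's
    ferrocyanide has fallen below the survival threshold, or at
    ``horizon_days`` (remaining layers are then censored).
    """
    if curves is None:
        curves = (synthetic.ferrocyanide_curve(), synthetic.nitroprusside_curve())
    if flux is None:
        flux = synthetic.make_actinic_flux("flat")

    grid = flux.wavelength
    for band in (config.band_k1, config.band_k2):
        if not np.any(_band_mask(grid, band)):
            raise ValueError(f"flux grid does not cover the band {band}")
    eps_a, eps_b, extra_od = _epsilon_matrix(config, curves, grid)
    m1 = _band_mask(grid, config.band_k1)
    m2 = _band_mask(grid, config.band_k2)
    f1, f2 = flux.flux[m1], flux.flux[m2]
    if f1.sum() <= 0 or f2.sum() <= 0:
        raise ValueError("flux must be positive somewhere inside each band")

    state = init_haze_phase(config)
    n = config.n_layers
    a0 = state.ferrocyanide.copy()
    thresh = config.survival_threshold * a0
    supply_day = nitrate_supply_rate(config) * SECONDS_PER_DAY

    survival = np.full(n, np.nan)
    # crossing uses <=, checked from t = 0: a 100% threshold (or a layer that
    # never held ferrocyanide) yields survival 0
    crossed = a0 <= thresh
    survival[crossed] = 0.0
    peak_b = np.zeros(n)
    beta = config.layer_thickness_dm

    def chis(st: LakeState) -> tuple[np.ndarray, np.ndarray]:
        od = (
            st.ferrocyanide[:, None] * eps_a[None, :]
            + st.nitroprusside[:, None] * eps_b[None, :]
        ) * beta + extra_od[None, :]
        # flux at the top of layer i: attenuation by layers above it only
        cum = np.cumsum(od, axis=0) - od
        trans = 10.0 ** (-np.minimum(cum, 300.0))
        c1 = trans[:, m1] @ f1 / f1.sum()
        c2 = trans[:, m2] @ f2 / f2.sum()
        return c1, c2

    times = [state.time]
    rec_a = [state.ferrocyanide.copy()]
    rec_b = [state.nitroprusside.copy()]
    rec_n = [state.nitrate.copy()]
    c1, c2 = chis(state)
    rec_c1 = [c1.copy()]
    rec_c2 = [c2.copy()]
    initial = LakeState(0.0, a0.copy(), state.nitroprusside.copy(), state.nitrate.copy())

    istep = 0
    while state.time < config.horizon_days - 1e-12 and not crossed.all():
        c1, c2 = chis(state)
        state = _advance(state, c1, c2, config, supply_day)
        istep += 1
        np.maximum(peak_b, state.nitroprusside, out=peak_b)
        newly = (~crossed) & (state.ferrocyanide <= thresh)
        if newly.any():
            survival[newly] = state.time
            crossed |= newly
        if istep % config.record_every == 0 or crossed.all():
            times.append(state.time)
            rec_a.append(state.ferrocyanide.copy())
            rec_b.append(state.nitroprusside.copy())
            rec_n.append(state.nitrate.copy())
            rec_c1.append(c1.copy())
            rec_c2.append(c2.copy())

    return SimulationResult(
        config=config,
        times=np.array(times),
        ferrocyanide=np.vstack(rec_a),
        nitroprusside=np.vstack(rec_b),
        nitrate=np.vstack(rec_n),
        chi_k1=np.vstack(rec_c1),
        chi_k2=np.vstack(rec_c2),
        survival_days=survival,
        censored=~crossed,
        peak_nitroprusside=peak_b,
        initial=initial,
    )
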