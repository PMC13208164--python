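"""Beer-Lambert quantitation: cross-sections, mixtures and regressions.

The optical depth of a cuvette holding N absorbing species is additive,

    tau(lambda) = sum_i sigma_i(lambda) * n_i * beta,

with sigma_i the per-molecule attenuation cross-section (dm^2), n_i the
number density (dm^-3) and beta the path length (dm).  Per species the
relative absorbance r inverts to

    sigma_i(lambda) = -ln(1 - r(lambda)) / (beta * N_A * c_i),

and the decadal molar attenuation coefficient follows as
epsilon = N_A * sigma / ln(10), so that -log10(1 - r) = epsilon * c * beta.

A Beer-Lambert calibration regresses y = ln(1 - r) against concentration;
the gradient m = -beta * N_A * sigma(lambda) yields

    epsilon(lambda) = -m / (beta * ln 10),      Delta_epsilon = epsilon * Delta_m / m,

with Delta_m the standard error of the gradient.  Applying the fit
independently at every wavelength bin of a set of standards produces the
full attenuation curve epsilon(lambda).
"""

from __future__ import annotations

from collections.abc import Sequence
from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.constants import N_A

from .spectra import (
    AbsorbanceSpectrum,
    AttenuationCurve,
    LN10,
    MixtureSample,
    check_common_grid,
)


def cross_section_from_absorbance(r, c: float, beta: float = 0.1):
    """Attenuation cross-section sigma (dm^2) from relative absorbance.

    Implements sigma = -ln(1 - r) / (beta * N_A * c).  ``r`` may be a scalar
    or an array; bins with r >= 1 are saturated (the log diverges) and come
    back as NaN, i.e. reported missing.  Requires c > 0 and beta > 0.
    """
    if c <= 0:
        raise ValueError("concentration must be positive to invert to a cross-section")
    if beta <= 0:
        raise ValueError("path length must be positive")
    r = np.asarray(r, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        sigma = np.where(r < 1.0, -np.log1p(-np.clip(r, None, 1.0 - 1e-300)) / (beta * N_A * c), np.nan)
    return sigma if sigma.ndim else float(sigma)


def epsilon_from_cross_section(sigma):
    """Decadal molar attenuation coefficient epsilon = N_A * sigma / ln 10."""
    return np.asarray(sigma, dtype=float) * N_A / LN10


def combine_spectra(
    curves: Sequence[AttenuationCurve], mixture: MixtureSample
) -> AbsorbanceSpectrum:
    """Predict the absorbance of a mixture from single-species curves.

    Optical depths add: tau = sum_i ln(10) * epsilon_i * c_i * beta, and
    r = 1 - exp(-tau).  The combined uncertainty treats the total
    cross-section as the linear sum of the constituent cross-section errors,
    so Delta_tau = sum_i ln(10) * Delta_epsilon_i * c_i * beta and
    Delta_r = exp(-tau) * Delta_tau.
    """
    if len(curves) != len(mixture.concentrations):
        raise ValueError(
            f"{len(curves)} curves but {len(mixture.concentrations)} concentrations"
        )
    grid = check_common_grid(*(c.wavelength for c in curves))
    beta = mixture.path_length
    tau = np.zeros_like(grid)
    dtau = np.zeros_like(grid)
    have_err = False
    for curve, c in zip(curves, mixture.concentrations):
        tau = tau + LN10 * curve.epsilon * c * beta
        if curve.epsilon_err is not None:
            have_err = True
            dtau = dtau + LN10 * curve.epsilon_err * c * beta
    r = -np.expm1(-tau)
    r_err = np.exp(-tau) * dtau if have_err else None
    mask = np.isfinite(r)
    return AbsorbanceSpectrum(grid, r, mask=mask, r_err=r_err)


@dataclass
class RegressionResult:
    """One Beer-Lambert calibration fit at a single wavelength."""

    slope: float  # m, dm^3 mol^-1
    slope_err: float  # Delta_m, standard error of the gradient
    intercept: float
    epsilon: float  # dm^2 mol^-1
    epsilon_err: float
    r_squared: float
    n_points: int
    nonphysical: bool = False  # positive slope: absorbance falling with c


def fit_epsilon_at_wavelength(
    points: Sequence[tuple[float, float]],
    beta: float = 0.1,
    fit_intercept: bool = True,
) -> RegressionResult:
    """Least-squares Beer-Lambert fit of y = ln(1 - r) against concentration.

    Points with r outside [0, 1) cannot enter the log domain and are
    dropped; at least three usable points with non-identical concentrations
    are required.  The free intercept absorbs baseline offsets (Beer-Lambert
    predicts zero); set ``fit_intercept=False`` to force the line through
    the origin.  A positive fitted slope is non-physical and flagged rather
    than rejected.
    """
    if beta <= 0:
        raise ValueError("path length must be positive")
    pts = [(float(c), float(r)) for c, r in points if 0.0 <= r < 1.0 and np.isfinite(r)]
    if len(pts) < 3:
        raise ValueError(f"need at least 3 usable points with 0 <= r < 1, got {len(pts)}")
    c = np.array([p[0] for p in pts])
    y = np.log1p(-np.array([p[1] for p in pts]))
    if np.ptp(c) == 0:
        raise ValueError("concentrations must not all be identical")

    if fit_intercept:
        fit = stats.linregress(c, y)
        m, dm, b = fit.slope, fit.stderr, fit.intercept
        r2 = fit.rvalue**2
    else:
        sxx = float(np.dot(c, c))
        m = float(np.dot(c, y)) / sxx
        resid = y - m * c
        dof = len(c) - 1
        dm = float(np.sqrt(np.dot(resid, resid) / dof / sxx)) if dof > 0 else np.nan
        b = 0.0
        syy = float(np.dot(y, y))
        r2 = 1.0 - float(np.dot(resid, resid)) / syy if syy > 0 else 1.0

    epsilon = -m / (beta * LN10)
    # Delta_eps = eps * Delta_m / m, which for this linear map is Delta_m/(beta ln10)
    epsilon_err = abs(dm) / (beta * LN10) if np.isfinite(dm) else np.nan
    return RegressionResult(
        slope=m,
        slope_err=dm,
        intercept=b,
        epsilon=epsilon,
        epsilon_err=epsilon_err,
        r_squared=r2,
        n_points=len(c),
        nonphysical=bool(m > 0),
    )


def epsilon_curve_from_standards(
    standards: Sequence[tuple[float, AbsorbanceSpectrum]],
    beta: float = 0.1,
    fit_intercept: bool = True,
    min_points: int = 3,
    species: str = "",
) -> AttenuationCurve:
    """Per-bin Beer-Lambert regression over a concentration series.

    ``standards`` pairs each concentration (mol dm^-3) with its (typically
    replicate-aggregated) absorbance spectrum.  At each wavelength bin the
    fit uses only standards whose bin is unmasked and has 0 <= r < 1; bins
    with fewer than ``min_points`` usable standards are left undefined
    (NaN).  Returns the curve with per-bin uncertainty, R^2 and the number
    of points that entered each fit.
    """
    if len(standards) < min_points:
        raise ValueError(f"need at least {min_points} standards, got {len(standards)}")
    grid = check_common_grid(*(spec.wavelength for _, spec in standards))
    concs = np.array([float(c) for c, _ in standards])
    if np.any(concs < 0):
        raise ValueError("standard concentrations must be nonnegative")
    rmat = np.vstack([spec.r for _, spec in standards])
    usable = np.vstack([spec.mask for _, spec in standards]) & (rmat >= 0) & (rmat < 1)

    nbins = grid.size
    eps = np.full(nbins, np.nan)
    eps_err = np.full(nbins, np.nan)
    r2 = np.full(nbins, np.nan)
    npts = np.zeros(nbins, dtype=int)
    for j in range(nbins):
        sel = usable[:, j]
        if sel.sum() < min_points or np.ptp(concs[sel]) == 0:
            continue
        fit = fit_epsilon_at_wavelength(
            list(zip(concs[sel], rmat[sel, j])), beta=beta, fit_intercept=fit_intercept
        )
        npts[j] = fit.n_points
        r2[j] = fit.r_squared
        # clamp tiny negative estimates from noise so the curve stays physical
        eps[j] = max(fit.epsilon, 0.0)
        eps_err[j] = fit.epsilon_err
    return AttenuationCurve(
        grid, eps, epsilon_err=eps_err, species=species, r_squared=r2, n_points=npts
    )
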