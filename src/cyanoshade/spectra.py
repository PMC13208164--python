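"""Spectral data containers and plain-text I/O.

Everything downstream operates on four light-weight containers: raw detector
counts (:class:`CountSpectrum`), reduced relative absorbance
(:class:`AbsorbanceSpectrum`), per-species molar attenuation curves
(:class:`AttenuationCurve`) and wavelength-binned actinic flux
(:class:`FluxSpectrum`).  All carry a wavelength grid in nanometres.

Files are written as tab-separated text with ``#``-prefixed header lines,
matching the two-column wavelength/value tables a bench spectrometer exports.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.constants import N_A

LN10 = float(np.log(10.0))

ROLES = ("sample", "background", "reference")


def _as_float_array(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional, got shape {arr.shape}")
    return arr


@dataclass
class CountSpectrum:
    """Raw detector counts per wavelength bin.

    ``role`` distinguishes the three measurements a reduction needs: the
    sample itself, the source-off background, and the water-blank reference.
    """

    wavelength: np.ndarray
    counts: np.ndarray
    role: str = "sample"

    def __post_init__(self) -> None:
        self.wavelength = _as_float_array(self.wavelength, "wavelength")
        self.counts = _as_float_array(self.counts, "counts")
        if self.wavelength.shape != self.counts.shape:
            raise ValueError("wavelength and counts must have the same length")
        if not np.all(np.isfinite(self.counts)):
            raise ValueError("counts must be finite")
        if self.role not in ROLES:
            raise ValueError(f"role must be one of {ROLES}, got {self.role!r}")

    def __len__(self) -> int:
        return self.wavelength.size


@dataclass
class AbsorbanceSpectrum:
    """Relative absorbance r(lambda) = 1 - I/I0 with a validity mask.

    ``mask`` is True where the bin is trusted (reference above background and
    signal-to-noise acceptable).  ``r_err`` holds the replicate standard
    deviation when the spectrum is an aggregate, else None.
    """

    wavelength: np.ndarray
    r: np.ndarray
    mask: np.ndarray | None = None
    r_err: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.wavelength = _as_float_array(self.wavelength, "wavelength")
        self.r = _as_float_array(self.r, "r")
        if self.mask is None:
            self.mask = np.ones(self.r.shape, dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
        if self.r_err is not None:
            self.r_err = _as_float_array(self.r_err, "r_err")
            if self.r_err.shape != self.r.shape:
                raise ValueError("r_err must match r in length")
        if self.wavelength.shape != self.r.shape or self.mask.shape != self.r.shape:
            raise ValueError("wavelength, r and mask must have the same length")

    @property
    def is_empty(self) -> bool:
        """True when every bin has been masked out."""
        return not bool(self.mask.any())

    def __len__(self) -> int:
        return self.wavelength.size


@dataclass
class AttenuationCurve:
    """Molar attenuation coefficient epsilon(lambda) for one species.

    epsilon is in dm^2 mol^-1 (decadal convention; 1 dm^2 mol^-1 equals
    0.1 M^-1 cm^-1).  Undefined bins are NaN.  The per-molecule attenuation
    cross-section follows as sigma = ln(10) * epsilon / N_A.
    """

    wavelength: np.ndarray
    epsilon: np.ndarray
    epsilon_err: np.ndarray | None = None
    species: str = ""
    r_squared: np.ndarray | None = None
    n_points: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.wavelength = _as_float_array(self.wavelength, "wavelength")
        self.epsilon = _as_float_array(self.epsilon, "epsilon")
        if self.wavelength.shape != self.epsilon.shape:
            raise ValueError("wavelength and epsilon must have the same length")
        defined = np.isfinite(self.epsilon)
        if np.any(self.epsilon[defined] < 0):
            raise ValueError("epsilon must be nonnegative where defined")
        if self.epsilon_err is not None:
            self.epsilon_err = _as_float_array(self.epsilon_err, "epsilon_err")

    @property
    def cross_section(self) -> np.ndarray:
        """sigma(lambda) in dm^2 per molecule."""
        return LN10 * self.epsilon / N_A

    def interpolate(self, grid: np.ndarray) -> np.ndarray:
        """epsilon evaluated on ``grid`` (nm); rejects extrapolation."""
        grid = np.asarray(grid, dtype=float)
        if grid.min() < self.wavelength.min() or grid.max() > self.wavelength.max():
            raise ValueError(
                f"curve for {self.species or 'species'} covers "
                f"{self.wavelength.min():g}-{self.wavelength.max():g} nm; "
                f"requested {grid.min():g}-{grid.max():g} nm"
            )
        return np.interp(grid, self.wavelength, self.epsilon)

    def __len__(self) -> int:
        return self.wavelength.size


@dataclass
class FluxSpectrum:
    """Actinic flux per 1 nm wavelength bin (arbitrary units)."""

    wavelength: np.ndarray
    flux: np.ndarray

    def __post_init__(self) -> None:
        self.wavelength = _as_float_array(self.wavelength, "wavelength")
        self.flux = _as_float_array(self.flux, "flux")
        if self.wavelength.shape != self.flux.shape:
            raise ValueError("wavelength and flux must have the same length")
        if np.any(self.flux < 0):
            raise ValueError("flux must be nonnegative")

    def __len__(self) -> int:
        return self.wavelength.size


@dataclass
class MixtureSample:
    """Concentrations (mol dm^-3) of the species in a cuvette.

    ``concentrations`` aligns positionally with whatever list of
    :class:`AttenuationCurve` it is used with.  ``path_length`` is the cuvette
    path beta in dm (default 0.1 dm = 1 cm).
    """

    concentrations: tuple[float, ...]
    path_length: float = 0.1

    def __post_init__(self) -> None:
        self.concentrations = tuple(float(c) for c in np.atleast_1d(self.concentrations))
        if any(c < 0 for c in self.concentrations):
            raise ValueError("concentrations must be nonnegative")
        if self.path_length <= 0:
            raise ValueError("path_length must be positive")


def check_common_grid(*grids: np.ndarray) -> np.ndarray:
    """Return the shared wavelength grid or raise on any mismatch."""
    first = np.asarray(grids[0], dtype=float)
    for g in grids[1:]:
        g = np.asarray(g, dtype=float)
        if g.shape != first.shape or not np.array_equal(g, first):
            raise ValueError("wavelength grids do not match")
    return first


# ---------------------------------------------------------------------------
# plain-text I/O


def _write_table(path: str | Path, frame: pd.DataFrame, header: str) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for line in header.splitlines():
            fh.write(f"# {line}\n")
        frame.to_csv(fh, sep="\t", index=False)


def _read_table(path: str | Path) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep="\t", comment="#")
    except Exception as exc:  # noqa: BLE001 - re-raise with the file named
        raise ValueError(f"could not parse spectral table {path}: {exc}") from exc


def write_count_spectrum(path: str | Path, spectrum: CountSpectrum) -> None:
    frame = pd.DataFrame({"wavelength_nm": spectrum.wavelength, "counts": spectrum.counts})
    _write_table(path, frame, f"detector counts, role={spectrum.role}")


def read_count_spectrum(path: str | Path, role: str) -> CountSpectrum:
    frame = _read_table(path)
    if frame.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns (wavelength, counts)")
    return CountSpectrum(frame.iloc[:, 0].to_numpy(), frame.iloc[:, 1].to_numpy(), role=role)


def write_absorbance(path: str | Path, spectrum: AbsorbanceSpectrum) -> None:
    frame = pd.DataFrame(
        {
            "wavelength_nm": spectrum.wavelength,
            "r": spectrum.r,
            "r_err": spectrum.r_err if spectrum.r_err is not None else np.nan,
            "mask": spectrum.mask.astype(int),
        }
    )
    _write_table(path, frame, "relative absorbance r = 1 - (n_m-n_b)/(n_ref-n_b); mask 1 = retained")


def read_absorbance(path: str | Path) -> AbsorbanceSpectrum:
    frame = _read_table(path)
    r_err = frame["r_err"].to_numpy() if "r_err" in frame and frame["r_err"].notna().any() else None
    mask = frame["mask"].to_numpy().astype(bool) if "mask" in frame else None
    return AbsorbanceSpectrum(frame["wavelength_nm"].to_numpy(), frame["r"].to_numpy(), mask=mask, r_err=r_err)


def write_attenuation_curve(path: str | Path, curve: AttenuationCurve) -> None:
    data = {"wavelength_nm": curve.wavelength, "epsilon_dm2_mol": curve.epsilon}
    if curve.epsilon_err is not None:
        data["epsilon_err_dm2_mol"] = curve.epsilon_err
    if curve.r_squared is not None:
        data["r_squared"] = curve.r_squared
    if curve.n_points is not None:
        data["n_points"] = curve.n_points
    _write_table(path, pd.DataFrame(data), f"molar attenuation coefficient, species={curve.species}")


def read_attenuation_curve(path: str | Path, species: str = "") -> AttenuationCurve:
    frame = _read_table(path)
    if frame.shape[1] < 2:
        raise ValueError(f"{path}: expected at least two columns (wavelength, epsilon)")
    err = frame["epsilon_err_dm2_mol"].to_numpy() if "epsilon_err_dm2_mol" in frame else None
    return AttenuationCurve(
        frame.iloc[:, 0].to_numpy(), frame.iloc[:, 1].to_numpy(), epsilon_err=err, species=species
    )
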