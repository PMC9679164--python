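"""Spectral curves and photoreceptor sensitivity functions.

Spectral power distributions (SPDs) of display primaries and photoreceptor
spectral sensitivities are both represented as :class:`SpectralCurve` objects:
a value per wavelength on a uniform ascending grid in nanometres.

Because authoritative colorimetric tables are deliberately not bundled, the
built-in receptor set is produced by a parametric photopigment template — a
Gaussian in log wavelength — evaluated at standard peak wavelengths
(L 566 nm, M 541 nm, S 441 nm, rod 497 nm).  This is a synthetic
approximation of standard-observer sensitivities, adequate for the silencing
algebra (which only needs four linearly independent, broadband sensitivity
curves), and is clearly not a substitute for measured fundamentals when
calibrating a physical display.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "SpectralCurve",
    "ReceptorSet",
    "DEFAULT_GRID",
    "pigment_template",
    "standard_receptors",
    "gaussian_primary",
    "read_curve",
    "write_curve",
]

#: Standard colorimetric wavelength grid: 390-780 nm at 1 nm.
DEFAULT_GRID = np.arange(390.0, 781.0, 1.0)


@dataclass(frozen=True)
class SpectralCurve:
    """A non-negative function of wavelength on a uniform ascending grid."""

    wavelength_nm: np.ndarray
    value: np.ndarray

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelength_nm, dtype=float)
        v = np.asarray(self.value, dtype=float)
        if wl.ndim != 1 or v.ndim != 1 or wl.size != v.size:
            raise ValueError("wavelength and value must be 1-D and equal length")
        if wl.size < 2:
            raise ValueError("need at least two samples")
        steps = np.diff(wl)
        if np.any(steps <= 0):
            raise ValueError("wavelength grid must be strictly increasing")
        if not np.allclose(steps, steps[0], rtol=1e-8, atol=1e-9):
            raise ValueError("wavelength grid must have a constant step")
        if np.any(v < 0):
            raise ValueError("spectral values must be non-negative")
        object.__setattr__(self, "wavelength_nm", wl)
        object.__setattr__(self, "value", v)

    @property
    def step_nm(self) -> float:
        return float(self.wavelength_nm[1] - self.wavelength_nm[0])

    def resample(self, grid: np.ndarray) -> "SpectralCurve":
        """Linear-interpolation resampling; zero outside the tabulated range."""
        grid = np.asarray(grid, dtype=float)
        v = np.interp(grid, self.wavelength_nm, self.value, left=0.0, right=0.0)
        return SpectralCurve(grid, v)

    def scaled(self, factor: float) -> "SpectralCurve":
        return SpectralCurve(self.wavelength_nm, self.value * factor)

    def peak_normalized(self) -> "SpectralCurve":
        peak = self.value.max()
        if peak <= 0:
            raise ValueError("cannot peak-normalize an all-zero curve")
        return SpectralCurve(self.wavelength_nm, self.value / peak)


RECEPTOR_NAMES = ("L", "M", "S", "rod")


@dataclass(frozen=True)
class ReceptorSet:
    """Peak-normalized spectral sensitivities for L, M, S cones and rods."""

    fundamentals: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [r for r in RECEPTOR_NAMES if r not in self.fundamentals]
        if missing:
            raise ValueError(f"missing receptor curves: {missing}")
        normed = {
            name: curve.peak_normalized()
            for name, curve in self.fundamentals.items()
        }
        object.__setattr__(self, "fundamentals", normed)

    def __getitem__(self, name: str) -> SpectralCurve:
        return self.fundamentals[name]

    def curves(self) -> list:
        return [self.fundamentals[r] for r in RECEPTOR_NAMES]


def pigment_template(
    peak_nm: float, grid: np.ndarray = DEFAULT_GRID, log_width: float = 0.08
) -> SpectralCurve:
    """Gaussian-on-log-wavelength photopigment absorbance template.

    ``log_width`` is the standard deviation of ln(lambda / peak); 0.08 gives a
    full width at half maximum of roughly 100 nm at 540 nm, comparable to the
    bandwidth of human cone fundamentals.
    """
    grid = np.asarray(grid, dtype=float)
    z = np.log(grid / peak_nm) / log_width
    return SpectralCurve(grid, np.exp(-0.5 * z * z))


#: Conventional peak wavelengths (nm) of the human photopigments.
STANDARD_PEAKS_NM = {"L": 566.0, "M": 541.0, "S": 441.0, "rod": 497.0}


def standard_receptors(
    grid: np.ndarray = DEFAULT_GRID, log_width: float = 0.08
) -> ReceptorSet:
    """Template-generated stand-in for the standard observer receptor set."""
    return ReceptorSet(
        {
            name: pigment_template(peak, grid, log_width)
            for name, peak in STANDARD_PEAKS_NM.items()
        }
    )


def gaussian_primary(
    peak_nm: float,
    fwhm_nm: float = 30.0,
    power: float = 1.0,
    grid: np.ndarray = DEFAULT_GRID,
) -> SpectralCurve:
    """Gaussian-shaped display primary SPD (synthetic display model)."""
    grid = np.asarray(grid, dtype=float)
    sigma = fwhm_nm / 2.355
    v = power * np.exp(-0.5 * ((grid - peak_nm) / sigma) ** 2)
    return SpectralCurve(grid, v)


def read_curve(path: str | Path) -> SpectralCurve:
    """Read a two-column delimited text file (wavelength_nm, value)."""
    data = np.loadtxt(path, comments="#", delimiter=None, ndmin=2)
    if data.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns (wavelength_nm, value)")
    return SpectralCurve(data[:, 0], data[:, 1])


def write_curve(curve: SpectralCurve, path: str | Path) -> None:
    np.savetxt(
        path,
        np.column_stack([curve.wavelength_nm, curve.value]),
        header="wavelength_nm value",
    )
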