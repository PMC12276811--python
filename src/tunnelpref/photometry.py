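"""Photon-flux arithmetic for LED stimulus calibration.

Converts measured spectral irradiance E(lambda) [W cm^-2 nm^-1] to photon
flux by integrating E(lambda) * lambda / (h c) over a wavelength band, and
solves for the linear (PWM duty-cycle) scale that brings a channel to an
isoquantal target — nominally ~3.5e11 photons cm^-2 s^-1 at the tunnel
floor, so that stimuli of different wavelengths deliver equal quanta.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.constants import c as _C, h as _H

#: Isoquantal calibration target at the tunnel floor, photons cm^-2 s^-1.
ISOQUANTAL_TARGET = 3.5e11


@dataclass(frozen=True)
class Spectrum:
    """Spectral irradiance on an ascending wavelength grid.

    wavelength_nm : nm; irradiance : W cm^-2 nm^-1 (both >= 0).
    """

    wavelength_nm: np.ndarray
    irradiance: np.ndarray

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelength_nm, float)
        ir = np.asarray(self.irradiance, float)
        if wl.ndim != 1 or wl.shape != ir.shape:
            raise ValueError("wavelength and irradiance must be matching 1D arrays")
        if wl.size < 2 or np.any(np.diff(wl) <= 0):
            raise ValueError("wavelength grid must be strictly ascending (>= 2 points)")
        if np.any(ir < 0):
            raise ValueError("irradiance must be >= 0")
        object.__setattr__(self, "wavelength_nm", wl)
        object.__setattr__(self, "irradiance", ir)

    def scaled(self, factor: float) -> "Spectrum":
        return Spectrum(self.wavelength_nm, self.irradiance * factor)


def read_spectrum(path: str | Path) -> Spectrum:
    """Read a two-column (nm, W cm^-2 nm^-1) text export."""
    data = np.loadtxt(path)
    return Spectrum(data[:, 0], data[:, 1])


def write_spectrum(spectrum: Spectrum, path: str | Path) -> None:
    np.savetxt(
        path,
        np.column_stack([spectrum.wavelength_nm, spectrum.irradiance]),
        header="wavelength_nm irradiance_W_cm2_nm",
    )


def photon_flux(
    spectrum: Spectrum,
    band: tuple[float, float] | None = None,
) -> float:
    """Photon flux [photons cm^-2 s^-1] over ``band`` (whole grid if None).

    Trapezoidal integral of E(lambda) * lambda / (h c); flux is additive
    over disjoint bands and linear in irradiance.  The band must lie within
    the measured grid.
    """
    wl = spectrum.wavelength_nm
    # photons per (cm^2 s nm): E * lambda / (h c); lambda in meters.
    # Converting before any band clipping keeps flux exactly additive over
    # disjoint bands (edge values are interpolated on the density itself).
    density = spectrum.irradiance * (wl * 1e-9) / (_H * _C)
    if band is not None:
        lo, hi = float(band[0]), float(band[1])
        if lo >= hi:
            raise ValueError("band must satisfy lo < hi")
        if lo < wl[0] or hi > wl[-1]:
            raise ValueError(
                f"band [{lo}, {hi}] nm outside measured grid [{wl[0]}, {wl[-1]}] nm"
            )
        grid = np.unique(np.concatenate([[lo, hi], wl[(wl > lo) & (wl < hi)]]))
        vals = np.interp(grid, wl, density)
    else:
        grid, vals = wl, density
    return float(np.trapezoid(vals, grid))


def solve_isoquantal_scale(
    spectrum: Spectrum,
    target_flux: float = ISOQUANTAL_TARGET,
    band: tuple[float, float] | None = None,
) -> float:
    """Linear scale factor bringing the channel to ``target_flux`` exactly.

    Assumes PWM duty cycle proportional to irradiance, so the scaled
    spectrum closes on the target: ``photon_flux(scale * E) == target``.
    """
    flux = photon_flux(spectrum, band)
    if flux <= 0:
        raise ValueError("spectrum has zero photon flux; cannot scale to target")
    return target_flux / flux
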