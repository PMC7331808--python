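"""Chromophore absorption reference data.

Molar extinction coefficients of oxygenated and deoxygenated hemoglobin
(cm^-1 / (mol/L)) on the 400-700 nm, 10 nm grid, resampled from the standard
compiled tabulations of hemoglobin extinction data, plus a power-law melanin
absorption model. Values are converted to specific absorption per unit volume
fraction (mm^-1 per vol%) assuming whole blood with 150 g/L hemoglobin and a
molecular weight of 64500 g/mol.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._cie import WAVELENGTHS_NM

# Molar extinction, cm^-1/M, oxygenated hemoglobin, 400-700 nm step 10.
_EPS_HBO2 = np.array([
    266232.0, 466840.0, 480360.0, 246072.0, 102580.0, 62816.0, 44480.0,
    33209.0, 26629.0, 23684.0, 20932.0, 20035.0, 24202.0, 39956.0,
    53236.0, 43016.0, 32613.0, 44496.0, 50104.0, 14400.0, 3200.0,
    1506.0, 942.0, 610.0, 442.0, 368.0, 319.0, 294.0, 277.0, 276.0, 290.0,
])

# Molar extinction, cm^-1/M, deoxygenated hemoglobin.
_EPS_HB = np.array([
    223296.0, 303956.0, 407560.0, 528600.0, 413280.0, 200000.0, 116000.0,
    62000.0, 40000.0, 27000.0, 20862.0, 23500.0, 29000.0, 39036.0,
    46592.0, 52276.0, 53412.0, 48000.0, 37020.0, 22000.0, 14677.0,
    9443.0, 7109.0, 5148.0, 4346.0, 3750.0, 3227.0, 2795.0, 2407.0,
    2051.0, 1794.0,
])

# mm^-1 per vol% = ln(10) * eps * (150/64500 mol/L) / 10 mm/cm / 100 vol%.
_EPS_TO_SPEC = np.log(10.0) * (150.0 / 64500.0) / 10.0 / 100.0


def melanin_specific_absorption(wavelengths_nm: np.ndarray) -> np.ndarray:
    """Specific absorption of melanin, mm^-1 per vol% melanosome.

    Power-law model mu_a = 6.6e11 * lambda^-3.33 cm^-1 for the melanosome
    interior, scaled to 1 vol% and expressed per mm.
    """
    wl = np.asarray(wavelengths_nm, dtype=float)
    return 6.6e11 * wl ** -3.33 / 10.0 / 100.0


@dataclass(frozen=True)
class AbsorptionLibrary:
    """Specific absorption spectra at unit concentration (mm^-1 per vol%).

    Attributes
    ----------
    wavelengths : ndarray
        Wavelength grid in nm, strictly increasing, within 400-700 nm.
    melanin, hbo2, hb : ndarray
        Specific absorption of melanin, oxygenated and deoxygenated
        hemoglobin at 1 vol% on that grid.
    """

    wavelengths: np.ndarray = field(default_factory=lambda: WAVELENGTHS_NM.copy())
    melanin: np.ndarray = None  # type: ignore[assignment]
    hbo2: np.ndarray = None  # type: ignore[assignment]
    hb: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        if wl.ndim != 1 or wl.size < 2 or np.any(np.diff(wl) <= 0):
            raise ValueError("wavelength grid must be 1-D and strictly increasing")
        if wl[0] < 400.0 - 1e-9 or wl[-1] > 700.0 + 1e-9:
            raise ValueError("absorption library grid must lie within 400-700 nm")
        object.__setattr__(self, "wavelengths", wl)
        if self.melanin is None:
            object.__setattr__(self, "melanin", melanin_specific_absorption(wl))
        if self.hbo2 is None:
            object.__setattr__(
                self, "hbo2", np.interp(wl, WAVELENGTHS_NM, _EPS_HBO2) * _EPS_TO_SPEC
            )
        if self.hb is None:
            object.__setattr__(
                self, "hb", np.interp(wl, WAVELENGTHS_NM, _EPS_HB) * _EPS_TO_SPEC
            )
        for name in ("melanin", "hbo2", "hb"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != wl.shape:
                raise ValueError(f"{name} spectrum does not match the wavelength grid")
            if np.any(~np.isfinite(arr)) or np.any(arr < 0):
                raise ValueError(f"{name} spectrum must be finite and non-negative")
            object.__setattr__(self, name, arr)

    def at(self, wavelength_nm: float) -> tuple[float, float, float]:
        """Look up (melanin, HbO2, Hb) specific absorption at one wavelength."""
        wl = float(wavelength_nm)
        if wl < self.wavelengths[0] or wl > self.wavelengths[-1]:
            raise ValueError(f"wavelength {wl} nm outside library grid")
        return (
            float(np.interp(wl, self.wavelengths, self.melanin)),
            float(np.interp(wl, self.wavelengths, self.hbo2)),
            float(np.interp(wl, self.wavelengths, self.hb)),
        )
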