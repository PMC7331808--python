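"""CIE colorimetry tables on the package's 400-700 nm, 10 nm working grid.

The CIE 1931 2-degree standard observer colour-matching functions and the
CIE D65 relative spectral power distribution, resampled to 10 nm intervals
from the standard published tabulations.
"""

from __future__ import annotations

import numpy as np

#: Working wavelength grid, nm (31 points).
WAVELENGTHS_NM = np.arange(400, 701, 10, dtype=float)

# CIE 1931 2-deg colour-matching functions x̄, ȳ, z̄ at 10 nm steps, 400-700 nm.
CIE_1931_XBAR = np.array([
    0.0143, 0.0435, 0.1344, 0.2839, 0.3483, 0.3362, 0.2908, 0.1954,
    0.0956, 0.0320, 0.0049, 0.0093, 0.0633, 0.1655, 0.2904, 0.4334,
    0.5945, 0.7621, 0.9163, 1.0263, 1.0622, 1.0026, 0.8544, 0.6424,
    0.4479, 0.2835, 0.1649, 0.0874, 0.0468, 0.0227, 0.0114,
])
CIE_1931_YBAR = np.array([
    0.0004, 0.0012, 0.0040, 0.0116, 0.0230, 0.0380, 0.0600, 0.0910,
    0.1390, 0.2080, 0.3230, 0.5030, 0.7100, 0.8620, 0.9540, 0.9950,
    0.9950, 0.9520, 0.8700, 0.7570, 0.6310, 0.5030, 0.3810, 0.2650,
    0.1750, 0.1070, 0.0610, 0.0320, 0.0170, 0.0082, 0.0041,
])
CIE_1931_ZBAR = np.array([
    0.0679, 0.2074, 0.6456, 1.3856, 1.7471, 1.7721, 1.6692, 1.2876,
    0.8130, 0.4652, 0.2720, 0.1582, 0.0782, 0.0422, 0.0203, 0.0087,
    0.0039, 0.0021, 0.0017, 0.0011, 0.0008, 0.0003, 0.0002, 0.0000,
    0.0000, 0.0000, 0.0000, 0.0000, 0.0000, 0.0000, 0.0000,
])

# CIE standard illuminant D65, relative SPD (100 at 560 nm), 400-700 nm.
D65_SPD = np.array([
    82.75, 91.49, 93.43, 86.68, 104.86, 117.01, 117.81, 114.86,
    115.92, 108.81, 109.35, 107.80, 104.79, 107.69, 104.41, 104.05,
    100.00, 96.33, 95.79, 88.69, 90.01, 89.60, 87.70, 83.29,
    83.70, 80.03, 80.21, 82.28, 78.28, 69.72, 71.61,
])


def observer_cmfs(wavelengths: np.ndarray | None = None) -> np.ndarray:
    """Return the 2-deg CMFs as a (n, 3) array, interpolated if needed."""
    if wavelengths is None:
        return np.column_stack([CIE_1931_XBAR, CIE_1931_YBAR, CIE_1931_ZBAR])
    wl = np.asarray(wavelengths, dtype=float)
    _check_range(wl)
    return np.column_stack([
        np.interp(wl, WAVELENGTHS_NM, CIE_1931_XBAR),
        np.interp(wl, WAVELENGTHS_NM, CIE_1931_YBAR),
        np.interp(wl, WAVELENGTHS_NM, CIE_1931_ZBAR),
    ])


def illuminant_d65(wavelengths: np.ndarray | None = None) -> np.ndarray:
    """Return the D65 relative SPD, interpolated to ``wavelengths`` if given."""
    if wavelengths is None:
        return D65_SPD.copy()
    wl = np.asarray(wavelengths, dtype=float)
    _check_range(wl)
    return np.interp(wl, WAVELENGTHS_NM, D65_SPD)


def _check_range(wl: np.ndarray) -> None:
    if wl.min() < WAVELENGTHS_NM[0] or wl.max() > WAVELENGTHS_NM[-1]:
        raise ValueError(
            "wavelengths outside the tabulated 400-700 nm range cannot be interpolated"
        )
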