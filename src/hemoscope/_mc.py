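"""Photon-transport kernel for layered slabs (numba-compiled).

Standard variance-reduced random walk for a plane-parallel layered medium:
pencil beam at normal incidence, exponential step sampling, weight deposition
at each interaction (w * mu_a / mu_t), Henyey-Greenstein scattering, and
statistical Fresnel reflection/transmission at the external boundaries.
Internal layer boundaries are index-matched. Because the geometry is laterally
infinite and only total tallies are needed, the photon state reduces to
(z, uz, w, layer).

Termination deposits sub-threshold weight into the absorbed tally, so every
launched unit of weight is accounted for exactly (specular + diffuse
reflectance + transmittance + absorbed = 1 to floating-point rounding).
"""

from __future__ import annotations

import numpy as np
from numba import njit

_WEIGHT_MIN = 1e-4
_MAX_STEPS = 10_000_000


@njit(cache=True, fastmath=True)
def _fresnel(cos_i: float, n_in: float, n_out: float) -> float:
    """Unpolarized Fresnel reflectance for |cos| of the incident angle."""
    if n_in == n_out:
        return 0.0
    sin_t2 = (n_in / n_out) ** 2 * (1.0 - cos_i * cos_i)
    if sin_t2 >= 1.0:
        return 1.0  # total internal reflection
    cos_t = np.sqrt(1.0 - sin_t2)
    rs = (n_in * cos_i - n_out * cos_t) / (n_in * cos_i + n_out * cos_t)
    rp = (n_in * cos_t - n_out * cos_i) / (n_in * cos_t + n_out * cos_i)
    return 0.5 * (rs * rs + rp * rp)


@njit(cache=True, fastmath=True)
def transport_spectrum(
    mu_a: np.ndarray,  # (n_layers, n_wl)
    mu_s: np.ndarray,  # (n_layers, n_wl)
    g: np.ndarray,  # (n_layers,)
    boundaries: np.ndarray,  # (n_layers + 1,) cumulative z, boundaries[0] = 0
    n_tissue: float,
    n_above: float,
    n_below: float,
    photons: int,
    seed: int,
) -> np.ndarray:
    """Run the walk for every wavelength; return (n_wl, 4) tallies.

    Columns: specular reflectance, diffuse reflectance, transmittance,
    absorbed fraction. Each row sums to 1 within floating-point rounding.
    """
    np.random.seed(seed)
    n_layers, n_wl = mu_a.shape
    out = np.zeros((n_wl, 4))
    z_bottom = boundaries[n_layers]

    r_sp = _fresnel(1.0, n_above, n_tissue)

    for iw in range(n_wl):
        refl = 0.0
        trans = 0.0
        absorbed = 0.0
        for _ in range(photons):
            w = 1.0 - r_sp
            z = 0.0
            uz = 1.0
            layer = 0
            s = 0.0  # dimensionless step remainder
            steps = 0
            while True:
                steps += 1
                if steps > _MAX_STEPS:  # pathological input guard
                    absorbed += w
                    break
                if s <= 0.0:
                    s = -np.log(np.random.random())
                mt = mu_a[layer, iw] + mu_s[layer, iw]
                d = s / mt
                # distance to the layer boundary along the flight direction
                if uz > 0.0:
                    db = (boundaries[layer + 1] - z) / uz
                elif uz < 0.0:
                    db = (boundaries[layer] - z) / uz  # positive: both negative
                else:
                    db = 1e300
                if db <= d:
                    s -= db * mt
                    if uz < 0.0 and layer == 0:
                        z = 0.0
                        r = _fresnel(-uz, n_tissue, n_above)
                        if np.random.random() < r:
                            uz = -uz
                        else:
                            refl += w
                            break
                    elif uz > 0.0 and layer == n_layers - 1:
                        z = z_bottom
                        r = _fresnel(uz, n_tissue, n_below)
                        if np.random.random() < r:
                            uz = -uz
                        else:
                            trans += w
                            break
                    elif uz > 0.0:
                        layer += 1
                        z = boundaries[layer]
                    else:
                        z = boundaries[layer]
                        layer -= 1
                else:
                    z += uz * d
                    s = 0.0
                    # absorb
                    dw = w * mu_a[layer, iw] / mt
                    absorbed += dw
                    w -= dw
                    # Henyey-Greenstein scatter; only uz is tracked
                    gg = g[layer]
                    if gg != 0.0:
                        tmp = (1.0 - gg * gg) / (1.0 - gg + 2.0 * gg * np.random.random())
                        ct = (1.0 + gg * gg - tmp * tmp) / (2.0 * gg)
                        if ct > 1.0:
                            ct = 1.0
                        elif ct < -1.0:
                            ct = -1.0
                        st = np.sqrt(1.0 - ct * ct)
                        phi = 2.0 * np.pi * np.random.random()
                        if uz > 0.99999:
                            uz = ct
                        elif uz < -0.99999:
                            uz = -ct
                        else:
                            uz = uz * ct - np.sqrt(1.0 - uz * uz) * st * np.cos(phi)
                    else:
                        # isotropic: the outgoing direction is uniform on the
                        # sphere regardless of the incoming one
                        uz = 2.0 * np.random.random() - 1.0
                    if w < _WEIGHT_MIN:
                        absorbed += w
                        break
        inv = 1.0 / photons
        out[iw, 0] = r_sp
        out[iw, 1] = refl * inv
        out[iw, 2] = trans * inv
        out[iw, 3] = absorbed * inv
    return out
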