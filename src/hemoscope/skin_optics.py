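"""Two-layer skin forward model and the XYZ-to-concentration regression.

The skin is modelled as a thin melanin-bearing epidermis over a
hemoglobin-bearing dermis. Diffuse reflectance spectra are computed by Monte
Carlo photon transport, converted to CIE tristimulus values, and an affine
regression (the N2 matrix) from [1, X, Y, Z] to the three chromophore
concentrations is fitted on a seeded reference set of simulated spectra.
Applying the fitted regression to measured XYZ values yields melanin,
oxygenated- and deoxygenated-hemoglobin concentrations in vol%.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import qmc

from ._chromophores import AbsorptionLibrary
from ._cie import WAVELENGTHS_NM, illuminant_d65, observer_cmfs
from ._mc import transport_spectrum

__all__ = [
    "LayerOpticalProperties",
    "ChromophoreSet",
    "ReflectanceSpectrum",
    "TristimulusValue",
    "ConcentrationRegression",
    "AbsorptionLibrary",
    "default_skin_geometry",
    "simulate_slab",
    "simulate_reflectance",
    "build_reference_set",
    "spectrum_to_tristimulus",
    "fit_concentration_regression",
    "estimate_concentrations",
    "apply_concentration_regression",
    "total_hemoglobin",
    "reference_set_to_csv",
    "reference_set_from_csv",
    "DEFAULT_CONCENTRATION_RANGES",
]

#: Default sampling ranges for the reference set, vol%.
DEFAULT_CONCENTRATION_RANGES = {
    "c_m": (1.0, 10.0),
    "c_hbo": (0.1, 5.0),
    "c_hbr": (0.1, 5.0),
}

#: Default photon count per wavelength for desk-scale simulations.
DEFAULT_PHOTONS = 100_000


@dataclass(frozen=True)
class LayerOpticalProperties:
    """Optical properties of one slab layer on a wavelength grid.

    ``mu_a`` is the background absorption of the layer (chromophore
    contributions are added on top by :func:`simulate_reflectance`);
    ``mu_a`` and ``mu_s`` are in mm^-1, ``thickness`` in mm.
    """

    mu_a: np.ndarray
    mu_s: np.ndarray
    g: float
    thickness: float
    refractive_index: float = 1.4

    def __post_init__(self) -> None:
        mu_a = np.atleast_1d(np.asarray(self.mu_a, dtype=float))
        mu_s = np.atleast_1d(np.asarray(self.mu_s, dtype=float))
        if mu_a.shape != mu_s.shape:
            raise ValueError("mu_a and mu_s must share a wavelength grid")
        if np.any(~np.isfinite(mu_a)) or np.any(~np.isfinite(mu_s)):
            raise ValueError("optical properties must be finite")
        if np.any(mu_a < 0) or np.any(mu_s < 0):
            raise ValueError("mu_a and mu_s must be non-negative")
        if not -1.0 <= self.g <= 1.0:
            raise ValueError("anisotropy g must lie in [-1, 1]")
        if not self.thickness > 0:
            raise ValueError("layer thickness must be positive")
        if self.refractive_index < 1.0:
            raise ValueError("refractive index must be >= 1")
        object.__setattr__(self, "mu_a", mu_a)
        object.__setattr__(self, "mu_s", mu_s)


@dataclass(frozen=True)
class ChromophoreSet:
    """Melanin and hemoglobin volume fractions (vol%).

    ``clamped`` marks estimates whose raw affine inversion produced a
    negative concentration that was clamped to zero.
    """

    c_m: float
    c_hbo: float
    c_hbr: float
    clamped: bool = False

    def __post_init__(self) -> None:
        for name in ("c_m", "c_hbo", "c_hbr"):
            v = float(getattr(self, name))
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and non-negative")
            object.__setattr__(self, name, v)

    @property
    def c_hbt(self) -> float:
        """Total hemoglobin, the sum of oxy- and deoxy- fractions."""
        return self.c_hbo + self.c_hbr


@dataclass(frozen=True)
class ReflectanceSpectrum:
    """Diffuse reflectance I(lambda) = S/S0 with full energy tallies."""

    wavelengths: np.ndarray
    reflectance: np.ndarray
    specular: np.ndarray | None = None
    transmittance: np.ndarray | None = None
    absorbed: np.ndarray | None = None

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        r = np.asarray(self.reflectance, dtype=float)
        if wl.shape != r.shape or wl.ndim != 1:
            raise ValueError("wavelengths and reflectance must be matching 1-D arrays")
        if np.any(np.diff(wl) <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        if np.any(r < -1e-12) or np.any(r > 1 + 1e-12):
            raise ValueError("reflectance must lie in [0, 1]")
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "reflectance", np.clip(r, 0.0, 1.0))

    def energy_balance(self) -> np.ndarray:
        """Per-wavelength total of all tallies (equals 1 for a full simulation)."""
        if self.specular is None or self.transmittance is None or self.absorbed is None:
            raise ValueError("spectrum does not carry full tallies")
        return self.reflectance + self.specular + self.transmittance + self.absorbed


@dataclass(frozen=True)
class TristimulusValue:
    """CIE 1931 tristimulus values; Y = 100 for a perfect reflector."""

    x: float
    y: float
    z: float

    def __post_init__(self) -> None:
        for name in ("x", "y", "z"):
            v = float(getattr(self, name))
            if not np.isfinite(v) or v < -1e-9:
                raise ValueError(f"tristimulus {name} must be finite and non-negative")
            object.__setattr__(self, name, max(v, 0.0))

    def as_array(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z])


@dataclass(frozen=True)
class ConcentrationRegression:
    """Affine map [1, X, Y, Z] -> [Cm, CHbO, CHbR] (the N2 matrix).

    ``matrix`` rows correspond to the alpha (melanin), beta (oxy-) and
    gamma (deoxy-hemoglobin) coefficient rows; ``residual_sd`` and
    ``r_squared`` summarize the training fit per chromophore.
    """

    matrix: np.ndarray
    residual_sd: np.ndarray = field(default_factory=lambda: np.zeros(3))
    r_squared: np.ndarray = field(default_factory=lambda: np.ones(3))

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (3, 4):
            raise ValueError("regression matrix must be 3x4")
        if np.any(~np.isfinite(m)):
            raise ValueError("regression matrix must be finite")
        object.__setattr__(self, "matrix", m)
        object.__setattr__(self, "residual_sd", np.asarray(self.residual_sd, dtype=float))
        object.__setattr__(self, "r_squared", np.asarray(self.r_squared, dtype=float))

    def to_json(self, path) -> None:
        rows = dict(zip(("alpha", "beta", "gamma"), self.matrix.tolist()))
        payload = {
            "rows": rows,
            "residual_sd": self.residual_sd.tolist(),
            "r_squared": self.r_squared.tolist(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "ConcentrationRegression":
        with open(path) as fh:
            payload = json.load(fh)
        matrix = np.array([payload["rows"][k] for k in ("alpha", "beta", "gamma")])
        return cls(
            matrix,
            np.asarray(payload.get("residual_sd", np.zeros(3))),
            np.asarray(payload.get("r_squared", np.ones(3))),
        )


def default_skin_geometry(
    wavelengths: np.ndarray | None = None,
    *,
    g: float = 0.0,
    epidermis_thickness: float = 0.06,
    dermis_thickness: float = 4.94,
    refractive_index: float = 1.4,
) -> list[LayerOpticalProperties]:
    """Epidermis-over-dermis template with power-law reduced scattering.

    Reduced scattering follows mus'(lambda) = mus'(500) * (lambda/500)^-b
    with mus'(500) = 6.67 mm^-1, b = 1.2 for the epidermis and mus'(500) =
    4.53 mm^-1, b = 1.29 for the dermis (typical published skin values).
    By default the layers use the similarity-transformed isotropic
    representation (g = 0, mus = mus'), which leaves diffuse reflectance
    nearly unchanged while cutting the photon step count by ~1/(1-g);
    passing ``g`` converts mus = mus'/(1-g) for explicit anisotropic
    sampling. Background absorption is zero; chromophores are added per
    concentration by the simulator.
    """
    wl = WAVELENGTHS_NM.copy() if wavelengths is None else np.asarray(wavelengths, float)
    zeros = np.zeros_like(wl)
    musp_e = 6.67 * (wl / 500.0) ** -1.2
    musp_d = 4.53 * (wl / 500.0) ** -1.29
    epidermis = LayerOpticalProperties(
        zeros, musp_e / (1.0 - g), g, epidermis_thickness, refractive_index
    )
    dermis = LayerOpticalProperties(
        zeros, musp_d / (1.0 - g), g, dermis_thickness, refractive_index
    )
    return [epidermis, dermis]


def simulate_slab(
    layers: list[LayerOpticalProperties],
    photons: int,
    seed: int,
    *,
    wavelengths: np.ndarray | None = None,
    n_above: float = 1.0,
    n_below: float | None = None,
) -> ReflectanceSpectrum:
    """Low-level transport through an arbitrary layer stack.

    ``n_below`` defaults to the tissue index (matched deep boundary: photons
    crossing the bottom are tallied as transmitted). All layers must share a
    refractive index; Fresnel reflection happens only at the external
    boundaries.
    """
    if photons < 1:
        raise ValueError("photon count must be >= 1")
    if not layers:
        raise ValueError("at least one layer is required")
    n_tissue = layers[0].refractive_index
    if any(abs(l.refractive_index - n_tissue) > 1e-12 for l in layers):
        raise NotImplementedError("layers must share a refractive index")
    n_wl = layers[0].mu_a.size
    if any(l.mu_a.size != n_wl for l in layers):
        raise ValueError("all layers must share the wavelength grid")
    wl = np.arange(n_wl, dtype=float) if wavelengths is None else np.asarray(wavelengths, float)
    if wl.size != n_wl:
        raise ValueError("wavelength axis does not match the optical property grids")

    mu_a = np.vstack([l.mu_a for l in layers])
    # the kernel needs mu_t > 0; a tiny scattering floor keeps steps finite
    mu_s = np.vstack([np.maximum(l.mu_s, 1e-12) for l in layers])
    g = np.array([l.g for l in layers])
    boundaries = np.concatenate([[0.0], np.cumsum([l.thickness for l in layers])])
    tallies = transport_spectrum(
        mu_a,
        mu_s,
        g,
        boundaries,
        n_tissue,
        float(n_above),
        n_tissue if n_below is None else float(n_below),
        int(photons),
        int(seed) % 2**31,
    )
    return ReflectanceSpectrum(
        wavelengths=wl,
        reflectance=tallies[:, 1],
        specular=tallies[:, 0],
        transmittance=tallies[:, 2],
        absorbed=tallies[:, 3],
    )


def simulate_reflectance(
    chromophores: ChromophoreSet,
    geometry: list[LayerOpticalProperties] | None = None,
    absorption_lib: AbsorptionLibrary | None = None,
    photons: int = DEFAULT_PHOTONS,
    seed: int = 0,
) -> ReflectanceSpectrum:
    """Diffuse reflectance of skin with the given chromophore content.

    Melanin absorption (scaled by ``c_m``) is added to the first
    (epidermis) layer; oxy- and deoxy-hemoglobin absorption (scaled by
    ``c_hbo`` and ``c_hbr``) to the second (dermis) layer. Identical
    (seed, inputs) give bitwise-identical spectra.
    """
    lib = absorption_lib or AbsorptionLibrary()
    geom = geometry or default_skin_geometry(lib.wavelengths)
    if len(geom) != 2:
        raise ValueError("skin geometry must have exactly two layers (epidermis, dermis)")
    if geom[0].mu_a.size != lib.wavelengths.size:
        raise ValueError("geometry and absorption library grids differ")
    epidermis = replace(geom[0], mu_a=geom[0].mu_a + chromophores.c_m * lib.melanin)
    dermis = replace(
        geom[1],
        mu_a=geom[1].mu_a + chromophores.c_hbo * lib.hbo2 + chromophores.c_hbr * lib.hb,
    )
    return simulate_slab(
        [epidermis, dermis], photons, seed, wavelengths=lib.wavelengths
    )


def build_reference_set(
    n: int = 300,
    concentration_ranges: dict[str, tuple[float, float]] | None = None,
    photons: int = DEFAULT_PHOTONS,
    seed: int = 0,
    absorption_lib: AbsorptionLibrary | None = None,
    geometry: list[LayerOpticalProperties] | None = None,
) -> list[tuple[ChromophoreSet, ReflectanceSpectrum]]:
    """Seeded Latin-hypercube reference set of (chromophores, spectrum) pairs."""
    if n < 1:
        raise ValueError("reference set size must be >= 1")
    ranges = dict(DEFAULT_CONCENTRATION_RANGES)
    ranges.update(concentration_ranges or {})
    for key, (lo, hi) in ranges.items():
        if not 0 <= lo < hi:
            raise ValueError(f"range for {key} must satisfy 0 <= low < high")
    lib = absorption_lib or AbsorptionLibrary()
    sampler = qmc.LatinHypercube(d=3, seed=int(seed) % 2**31)
    unit = sampler.random(n)
    lows = np.array([ranges[k][0] for k in ("c_m", "c_hbo", "c_hbr")])
    highs = np.array([ranges[k][1] for k in ("c_m", "c_hbo", "c_hbr")])
    concs = qmc.scale(unit, lows, highs)
    out = []
    for i, (c_m, c_hbo, c_hbr) in enumerate(concs):
        cs = ChromophoreSet(c_m, c_hbo, c_hbr)
        spec = simulate_reflectance(
            cs, geometry, lib, photons=photons, seed=(int(seed) + 7919 * (i + 1)) % 2**31
        )
        out.append((cs, spec))
    return out


def spectrum_to_tristimulus(
    spectrum: ReflectanceSpectrum,
    illuminant: np.ndarray | None = None,
    observer: np.ndarray | None = None,
) -> TristimulusValue:
    """Weighted-summation XYZ of a reflectance spectrum.

    Uses D65 and the CIE 1931 2-deg observer by default, both resampled to
    the spectrum grid. The normalization constant makes a perfect reflector
    give Y = 100 under the chosen illuminant.
    """
    wl = spectrum.wavelengths
    s = illuminant_d65(wl) if illuminant is None else np.asarray(illuminant, float)
    cmfs = observer_cmfs(wl) if observer is None else np.asarray(observer, float)
    if s.shape != wl.shape:
        raise ValueError("illuminant grid does not match the spectrum")
    if cmfs.shape != (wl.size, 3):
        raise ValueError("observer must be an (n, 3) CMF table on the spectrum grid")
    denom = float(np.sum(s * cmfs[:, 1]))
    if denom <= 0:
        raise ValueError("illuminant has no luminous power on this grid")
    k = 100.0 / denom
    xyz = k * (s * spectrum.reflectance) @ cmfs
    return TristimulusValue(*xyz)


def fit_concentration_regression(
    reference_set: list[tuple[ChromophoreSet, TristimulusValue]],
) -> ConcentrationRegression:
    """Least-squares fit of concentrations on [1, X, Y, Z].

    Order-invariant; requires at least four samples with full-rank design.
    """
    if len(reference_set) < 4:
        raise ValueError("at least 4 reference samples are required")
    design = np.array([[1.0, *xyz.as_array()] for _, xyz in reference_set])
    target = np.array([[cs.c_m, cs.c_hbo, cs.c_hbr] for cs, _ in reference_set])
    if np.linalg.matrix_rank(design) < 4:
        raise ValueError("reference design is rank deficient")
    coeff, _, _, _ = np.linalg.lstsq(design, target, rcond=None)
    pred = design @ coeff
    resid = target - pred
    sd = resid.std(axis=0, ddof=min(4, len(reference_set) - 1))
    ss_res = np.sum(resid**2, axis=0)
    ss_tot = np.sum((target - target.mean(axis=0)) ** 2, axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = np.where(ss_tot > 0, 1.0 - ss_res / ss_tot, 1.0)
    return ConcentrationRegression(coeff.T, sd, r2)


def apply_concentration_regression(
    xyz: np.ndarray, regression: ConcentrationRegression
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized affine estimate for an (..., 3) XYZ array.

    Returns (concentrations (..., 3), clamped boolean mask (...,)) with
    negative raw estimates clamped to zero.
    """
    arr = np.asarray(xyz, dtype=float)
    if arr.shape[-1] != 3:
        raise ValueError("xyz array must have 3 components on the last axis")
    design = np.concatenate([np.ones(arr.shape[:-1] + (1,)), arr], axis=-1)
    raw = design @ regression.matrix.T
    clamped = np.any(raw < 0, axis=-1)
    return np.maximum(raw, 0.0), clamped


def estimate_concentrations(
    xyz: TristimulusValue, regression: ConcentrationRegression
) -> ChromophoreSet:
    """Apply the fitted N2 regression to one tristimulus value."""
    conc, clamped = apply_concentration_regression(xyz.as_array(), regression)
    return ChromophoreSet(*conc, clamped=bool(clamped))


def total_hemoglobin(cs: ChromophoreSet) -> float:
    """Total hemoglobin C_HbT = C_HbO + C_HbR (vol%), independent of melanin."""
    return cs.c_hbt


def reference_set_to_csv(
    reference_set: list[tuple[ChromophoreSet, ReflectanceSpectrum]], path
) -> None:
    """Persist a reference set as a flat CSV (concentrations + reflectances)."""
    rows = []
    for cs, spec in reference_set:
        row = {"c_m": cs.c_m, "c_hbo": cs.c_hbo, "c_hbr": cs.c_hbr}
        row.update(
            {f"R{int(w)}": r for w, r in zip(spec.wavelengths, spec.reflectance)}
        )
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def reference_set_from_csv(path) -> list[tuple[ChromophoreSet, ReflectanceSpectrum]]:
    df = pd.read_csv(path)
    wl_cols = [c for c in df.columns if c.startswith("R") and c[1:].isdigit()]
    wl = np.array(sorted(int(c[1:]) for c in wl_cols), dtype=float)
    out = []
    for _, row in df.iterrows():
        cs = ChromophoreSet(row["c_m"], row["c_hbo"], row["c_hbr"])
        refl = np.array([row[f"R{int(w)}"] for w in wl])
        out.append((cs, ReflectanceSpectrum(wl, refl)))
    return out
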