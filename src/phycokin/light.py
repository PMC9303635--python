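"""Diel solar irradiance and the spectral light gradient inside a flat-panel culture.

The reactor is a flat horizontal panel illuminated from one side; depth ``z``
runs from the illuminated surface (``z = 0``) into the culture. Light transport
is plain Lambert-Beer attenuation per wavelength on the PAR grid (400-700 nm,
1 nm steps); no scattering or ray tracing.

Unit conventions
----------------
Surface irradiance is handled in the field's customary µmol_ph·m⁻²·s⁻¹ at the
API boundary; :func:`local_absorption_rate` and the per-wavelength profiles
work in mol_ph·m⁻²·s⁻¹ (stated per function). Biomass inside the light field is
molar (mol_x·m⁻³); cross-sections are stored per gram and converted with the
24 g·mol⁻¹ biomass "molecule" convention.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PAR_WAVELENGTHS",
    "BIOMASS_MOLAR_MASS",
    "DielLight",
    "SpectralDistribution",
    "AbsorptionSpectrum",
    "diel_irradiance",
    "daily_photon_dose",
    "spectral_surface",
    "light_at_depth",
    "local_absorption_rate",
]

#: PAR wavelength grid, 400-700 nm inclusive at 1 nm: 301 bins.
PAR_WAVELENGTHS: np.ndarray = np.arange(400.0, 701.0)

#: Molar mass adopted for the C-mole-like biomass unit, g·mol⁻¹.
BIOMASS_MOLAR_MASS: float = 24.0

_SECONDS_PER_DAY = 86400.0


@dataclass(frozen=True)
class DielLight:
    """Sinusoidal diel light program: zero at night, half-sine between
    sunrise and sunset with ``peak_irradiance`` at solar noon.

    Defaults reproduce a tropical summer-solstice day (peak
    1900 µmol_ph·m⁻²·s⁻¹, 12 h photoperiod from 6:00 to 18:00).
    """

    peak_irradiance: float = 1900.0  # µmol_ph·m⁻²·s⁻¹
    sunrise_h: float = 6.0
    sunset_h: float = 18.0
    #: continuous illumination at peak_irradiance (24/24 h lab chemostats)
    constant: bool = False

    def __post_init__(self) -> None:
        if self.peak_irradiance < 0:
            raise ValueError("peak_irradiance must be >= 0")
        if not self.sunset_h > self.sunrise_h:
            raise ValueError("sunset_h must be after sunrise_h")

    @property
    def daylight_hours(self) -> float:
        return self.sunset_h - self.sunrise_h


@dataclass(frozen=True)
class SpectralDistribution:
    """Normalized spectral shape of the incident light over the PAR grid.

    ``weights`` are unitless fractions of the total photon flux per 1-nm bin;
    they are non-negative and sum to one.
    """

    weights: np.ndarray
    wavelengths: np.ndarray = field(default_factory=lambda: PAR_WAVELENGTHS.copy())

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "weights", w)
        if w.shape != PAR_WAVELENGTHS.shape:
            raise ValueError(f"expected {PAR_WAVELENGTHS.size} spectral bins, got {w.size}")
        if np.any(w < 0):
            raise ValueError("spectral weights must be non-negative")
        if abs(w.sum() - 1.0) > 1e-12:
            raise ValueError("spectral weights must sum to 1 (within 1e-12)")

    @classmethod
    def flat(cls) -> "SpectralDistribution":
        """Flat-quantum shape: equal photon flux in every 1-nm bin."""
        n = PAR_WAVELENGTHS.size
        return cls(weights=np.full(n, 1.0 / n))

    @classmethod
    def daylight(cls, temperature_k: float = 5800.0) -> "SpectralDistribution":
        """Smooth daylight-like PAR shape: blackbody *photon* flux at the
        solar effective temperature, truncated to 400-700 nm and normalized.

        A crude but smooth stand-in for a measured solar spectrum; at the high
        culture densities of interest results are weakly sensitive to it.
        """
        lam = PAR_WAVELENGTHS * 1e-9  # m
        hc_over_k = 6.62607015e-34 * 2.99792458e8 / 1.380649e-23  # m·K
        # photon flux ∝ λ⁻⁴ / (exp(hc/λkT) − 1)
        flux = lam**-4 / np.expm1(hc_over_k / (lam * temperature_k))
        w = flux / flux.sum()
        # renormalise exactly so the Σ=1 invariant holds to 1e-12
        return cls(weights=w / w.sum())


@dataclass(frozen=True)
class AbsorptionSpectrum:
    """Dry-weight specific absorption cross-section spectrum of a strain.

    ``cross_section`` is in m²·g⁻¹ on the 400-700 nm / 1 nm grid, as produced
    by an integrating-sphere spectrophotometer scan. The molar cross-section
    (m²·mol_x⁻¹) follows from the 24 g·mol⁻¹ biomass convention.
    """

    cross_section: np.ndarray  # m²·g⁻¹
    wavelengths: np.ndarray = field(default_factory=lambda: PAR_WAVELENGTHS.copy())

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        a = np.asarray(self.cross_section, dtype=float)
        if wl.shape != a.shape:
            raise ValueError("wavelengths and cross_section must have equal length")
        if np.any(a < 0):
            raise ValueError("absorption cross-sections must be non-negative")
        if wl.shape != PAR_WAVELENGTHS.shape or not np.allclose(wl, PAR_WAVELENGTHS):
            warnings.warn(
                "absorption spectrum not on the 400-700 nm / 1 nm grid; "
                "interpolating linearly",
                stacklevel=2,
            )
            a = np.interp(PAR_WAVELENGTHS, wl, a)
            wl = PAR_WAVELENGTHS.copy()
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "cross_section", a)

    @property
    def molar_cross_section(self) -> np.ndarray:
        """Per-wavelength cross-section in m²·mol_x⁻¹."""
        return self.cross_section * BIOMASS_MOLAR_MASS

    @property
    def mean_cross_section(self) -> float:
        """PAR-average dry-weight cross-section, m²·g⁻¹."""
        return float(self.cross_section.mean())

    @classmethod
    def grey(cls, cross_section: float) -> "AbsorptionSpectrum":
        """Wavelength-independent (grey) spectrum at the given m²·g⁻¹ value."""
        return cls(cross_section=np.full(PAR_WAVELENGTHS.size, float(cross_section)))


def diel_irradiance(t_hours, light: DielLight):
    """Surface irradiance (µmol_ph·m⁻²·s⁻¹) at clock time ``t_hours`` ∈ [0, 24).

    Half-sine between sunrise and sunset, zero at night, continuous at the
    day/night transitions. Accepts scalars or arrays.
    """
    t = np.asarray(t_hours, dtype=float)
    if light.constant:
        out = np.full_like(t, light.peak_irradiance)
        return float(out) if np.isscalar(t_hours) else out
    phase = (t - light.sunrise_h) / light.daylight_hours
    out = np.where(
        (phase > 0.0) & (phase < 1.0),
        light.peak_irradiance * np.sin(np.pi * np.clip(phase, 0.0, 1.0)),
        0.0,
    )
    return float(out) if np.isscalar(t_hours) else out


def daily_photon_dose(light: DielLight) -> float:
    """Photon dose integrated over one diel cycle, mol_ph·m⁻²·day⁻¹.

    Closed form of the half-sine integral: (2/π)·peak·daylight_seconds,
    converted µmol → mol. The default program gives 52.25 (prints as 52.3).
    """
    if light.constant:
        return light.peak_irradiance * 1e-6 * _SECONDS_PER_DAY
    daylight_s = light.daylight_hours * 3600.0
    return (2.0 / np.pi) * light.peak_irradiance * 1e-6 * daylight_s


def spectral_surface(total, shape: SpectralDistribution) -> np.ndarray:
    """Decompose a total surface irradiance into per-wavelength intensities.

    Units follow the input: the output sums to ``total`` exactly.
    """
    if total < 0:
        raise ValueError("total irradiance must be >= 0")
    return float(total) * shape.weights


def light_at_depth(
    surface: np.ndarray,
    spectrum: AbsorptionSpectrum,
    biomass_conc: float,
    z,
):
    """Attenuated light at depth ``z`` (m) under Lambert-Beer.

    Parameters
    ----------
    surface
        Per-wavelength surface intensities (same units in = units out).
    biomass_conc
        Culture density in mol_x·m⁻³.
    z
        Depth(s) from the illuminated surface, m; scalar or array.

    Returns
    -------
    (total, profile)
        ``total`` is the wavelength-summed irradiance at each depth;
        ``profile`` has shape ``(n_wavelengths,)`` for scalar z, else
        ``(n_depths, n_wavelengths)``.
    """
    if biomass_conc < 0:
        raise ValueError("biomass_conc must be >= 0")
    zz = np.asarray(z, dtype=float)
    if np.any(zz < 0):
        raise ValueError("depth z must be >= 0")
    surface = np.asarray(surface, dtype=float)
    a = spectrum.molar_cross_section  # m²·mol⁻¹
    profile = surface * np.exp(-np.multiply.outer(zz, a) * biomass_conc)
    total = profile.sum(axis=-1)
    if np.isscalar(z) or zz.ndim == 0:
        return float(total), profile
    return total, profile


def local_absorption_rate(
    surface: np.ndarray,
    spectrum: AbsorptionSpectrum,
    biomass_conc: float,
    z,
):
    """Specific photon absorption rate φ(z) = Σ_λ a_λ·I_λ(z), mol_ph·mol_x⁻¹·s⁻¹.

    ``surface`` must be per-wavelength intensities in mol_ph·m⁻²·s⁻¹. For a
    grey spectrum this reduces to a_x·I(z) exactly. Scalar or array ``z``.
    """
    if biomass_conc < 0:
        raise ValueError("biomass_conc must be >= 0")
    zz = np.asarray(z, dtype=float)
    if np.any(zz < 0):
        raise ValueError("depth z must be >= 0")
    surface = np.asarray(surface, dtype=float)
    a = spectrum.molar_cross_section
    phi = (surface * a) @ np.exp(-np.multiply.outer(a, zz) * biomass_conc)
    if np.isscalar(z) or zz.ndim == 0:
        return float(phi)
    return phi
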