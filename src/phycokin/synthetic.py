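"""Synthetic data generators emulating the study's measurement campaigns.

Three generators produce inputs with the statistical structure the estimation
pipeline assumes, so every stage is testable without the original raw data:

* :func:`gen_chemostat_obs` — daily steady-state records of light-limited
  chemostat runs. The noiseless steady state obeys Pirt's law exactly: at a
  dilution rate D the specific photon consumption is q_ph = (D + µ_e)/Y, and
  the generator solves the Lambert-Beer light balance for the density C_x
  that absorbs exactly that flux.
* :func:`gen_pi_records` — biological-oxygen-monitor (BOM) oxygen-evolution
  records along a light ladder, following the tanh photosynthesis-irradiance
  response, optionally with the high-light decline artifact caused by
  oxygen-supersaturation bubble formation.
* :func:`gen_absorption_spectrum` — a chlorophyte-like dry-weight specific
  absorption spectrum (sum of Gaussian pigment bands on the 400-700 nm grid).

Measurement noise is multiplicative lognormal parameterized by a coefficient
of variation (concentrations and irradiances are positive quantities). All
generators are pure functions of their parameters and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import brentq

from .estimation import ChemostatObservation, PIRecord
from .light import PAR_WAVELENGTHS, AbsorptionSpectrum
from .simulate import SpeciesParams

__all__ = [
    "SyntheticScenario",
    "gen_chemostat_obs",
    "gen_pi_records",
    "gen_absorption_spectrum",
    "DEFAULT_LIGHT_LADDER",
    "DEFAULT_PIGMENT_PEAKS",
]

_SECONDS_PER_DAY = 86400.0

#: BOM light-step ladder, µmol_ph·m⁻²·s⁻¹ (a plausible 0-2000 sequence).
DEFAULT_LIGHT_LADDER: tuple[float, ...] = (
    0.0, 25.0, 50.0, 100.0, 200.0, 400.0, 600.0, 800.0,
    1000.0, 1200.0, 1500.0, 1800.0, 2000.0,
)

#: Gaussian pigment bands (center nm, width nm, relative height):
#: chlorophyll Soret and red bands plus a carotenoid shoulder.
DEFAULT_PIGMENT_PEAKS: tuple[tuple[float, float, float], ...] = (
    (440.0, 22.0, 1.0),
    (480.0, 28.0, 0.55),
    (675.0, 12.0, 0.75),
)


@dataclass(frozen=True)
class SyntheticScenario:
    """Configuration of one synthetic chemostat campaign."""

    true_params: SpeciesParams
    dilution_grid: Sequence[float]  # day⁻¹
    incident: float = 100.0  # µmol_ph·m⁻²·s⁻¹
    optical_depth: float = 0.014  # m
    noise_cv: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        if self.incident <= 0 or self.optical_depth <= 0:
            raise ValueError("incident and optical_depth must be > 0")
        net_mu_max = self.true_params.mu_max - self.true_params.maintenance_rate
        bad = [d for d in self.dilution_grid if d >= net_mu_max]
        if bad:
            raise ValueError(
                f"dilution rates {bad} are not sustainable (>= mu_max - mu_e "
                f"= {net_mu_max:.3f} /d)"
            )


def _lognormal_factors(rng: np.random.Generator, cv: float, n: int) -> np.ndarray:
    """Mean-one multiplicative lognormal noise factors with the given CV."""
    if cv == 0:
        return np.ones(n)
    sigma = np.sqrt(np.log1p(cv**2))
    return rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=n)


def _steady_state_density(
    sc: SyntheticScenario, dilution: float
) -> tuple[float, float]:
    """Solve the light balance for the steady-state density at one D.

    Pirt's law fixes the target photon consumption q* = (D + µ_e)/Y
    (mol_ph·g⁻¹·day⁻¹); Lambert-Beer fixes the absorbed flux at density C_x.
    The root of absorbed(C_x)/C_x = q* is bracketed and solved with Brent's
    method (rtol 1e-12). Returns (C_x in g·L⁻¹, I_out in µmol·m⁻²·s⁻¹).
    """
    sp = sc.true_params
    if sp.absorption is None:
        raise ValueError("true_params must carry an absorption spectrum")
    q_target = (dilution + sp.maintenance_rate) / sp.yield_max
    a_per_g = sp.absorption.cross_section  # m²·g⁻¹
    # assume the surface spectrum is flat across PAR for the lab LED
    w = np.full(a_per_g.size, 1.0 / a_per_g.size)
    inc_mol_day = sc.incident * 1e-6 * _SECONDS_PER_DAY  # mol·m⁻²·day⁻¹

    def transmitted_fraction(c_gl: float) -> float:
        return float(w @ np.exp(-a_per_g * c_gl * 1000.0 * sc.optical_depth))

    def qph(c_gl: float) -> float:
        absorbed = inc_mol_day * (1.0 - transmitted_fraction(c_gl))
        return absorbed / (c_gl * 1000.0 * sc.optical_depth)

    q_thin_limit = inc_mol_day * float(w @ a_per_g)  # C_x → 0
    if q_target >= q_thin_limit:
        raise ValueError(
            f"D = {dilution} /d needs q_ph = {q_target:.3f} mol/g/d, above the "
            f"optically-thin limit {q_thin_limit:.3f}; not light-limited"
        )
    hi = 1.0
    while qph(hi) > q_target:
        hi *= 2.0
        if hi > 1e4:
            raise RuntimeError("failed to bracket the steady-state density")
    c_star = brentq(lambda c: qph(c) - q_target, 1e-9, hi, rtol=1e-14, xtol=1e-15)
    i_out = sc.incident * transmitted_fraction(c_star)
    return float(c_star), float(i_out)


def gen_chemostat_obs(
    sc: SyntheticScenario, n_days_steady: int = 7
) -> list[ChemostatObservation]:
    """Generate daily steady-state chemostat observations for a whole campaign.

    For each dilution rate in the scenario grid, emits ``n_days_steady``
    consecutive daily records at the Pirt-consistent steady state, with
    independent multiplicative lognormal noise (CV ``sc.noise_cv``) on the
    biomass density and outgoing irradiance. Day indices restart at 0 for
    each run, which is how downstream consumers delimit runs.
    """
    if n_days_steady < 1:
        raise ValueError("n_days_steady must be >= 1")
    rng = np.random.default_rng(sc.seed)
    out: list[ChemostatObservation] = []
    for d in sc.dilution_grid:
        c_star, i_out = _steady_state_density(sc, d)
        fc = _lognormal_factors(rng, sc.noise_cv, n_days_steady)
        fi = _lognormal_factors(rng, sc.noise_cv, n_days_steady)
        for day in range(n_days_steady):
            out.append(
                ChemostatObservation(
                    dilution_rate=d,
                    incident_irradiance=sc.incident,
                    outgoing_irradiance=min(i_out * fi[day], sc.incident),
                    biomass_conc=c_star * fc[day],
                    optical_depth=sc.optical_depth,
                    timestamp=float(day),
                )
            )
    return out


def gen_pi_records(
    true_mumax: float,
    sp: SpeciesParams,
    light_levels: Sequence[float] = DEFAULT_LIGHT_LADDER,
    n_reps: int = 3,
    noise_cv: float = 0.0,
    artifact_threshold: float | None = None,
    seed: int = 0,
    nitrogen_source: str = "urea",
    cuvette_biomass: float = 0.24,
    artifact_decline_per_umol: float = 5e-4,
) -> list[PIRecord]:
    """Generate BOM oxygen-evolution records along a light ladder.

    The underlying growth response is the tanh photosynthesis-irradiance
    curve µ(I) = µ_m·tanh(Y_mol·a_x·I/µ_m) − µ_e with the strain's PAR-mean
    cross-section; growth rates are converted to volumetric oxygen rates by
    the nitrogen-source stoichiometry. Above ``artifact_threshold`` (when
    set) rates decline linearly, mimicking the loss of dissolved oxygen to
    bubbles once the liquid phase oversaturates.
    """
    if not light_levels:
        raise ValueError("light_levels must be non-empty")
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if sp.absorption is None:
        raise ValueError("species needs an absorption spectrum")
    rng = np.random.default_rng(seed)
    a_molar = sp.absorption.mean_cross_section * sp.stoichiometry.biomass_molar_mass
    y_mol = sp.yield_max_molar
    x_ox = sp.stoichiometry.x_ox(nitrogen_source)
    c_mol = cuvette_biomass / sp.stoichiometry.biomass_molar_mass  # mol·L⁻¹

    def mu_of(i_umol: float) -> float:
        drive = y_mol * a_molar * i_umol * 1e-6 * _SECONDS_PER_DAY  # day⁻¹
        mu = true_mumax * np.tanh(drive / true_mumax) - sp.maintenance_rate
        if artifact_threshold is not None and i_umol > artifact_threshold:
            mu_thr = (
                true_mumax
                * np.tanh(y_mol * a_molar * artifact_threshold * 1e-6 * _SECONDS_PER_DAY / true_mumax)
                - sp.maintenance_rate
            )
            mu = mu_thr * (1.0 - artifact_decline_per_umol * (i_umol - artifact_threshold))
        return float(mu)

    records: list[PIRecord] = []
    for lvl in light_levels:
        mu = mu_of(lvl)
        r_o_true = mu * x_ox * c_mol  # mol_O2·L⁻¹·day⁻¹
        factors = _lognormal_factors(rng, noise_cv, n_reps)
        for rep in range(n_reps):
            records.append(
                PIRecord(
                    light_level=lvl,
                    o2_rate=r_o_true * factors[rep],
                    cuvette_biomass=cuvette_biomass,
                    nitrogen_source=nitrogen_source,
                )
            )
    return records


def gen_absorption_spectrum(
    mean_cross_section: float = 0.2,
    peaks: Sequence[tuple[float, float, float]] | None = DEFAULT_PIGMENT_PEAKS,
    baseline: float = 0.25,
    seed: int | None = None,
    jitter_cv: float = 0.02,
) -> AbsorptionSpectrum:
    """Synthetic chlorophyte-like absorption spectrum on the PAR grid.

    Sum of Gaussian pigment bands over a flat baseline, rescaled so the
    400-700 nm mean equals ``mean_cross_section`` (m²·g⁻¹) exactly. With an
    empty ``peaks`` list the spectrum is flat (grey). A seed adds small
    multiplicative wiggle per wavelength; without one the output is
    deterministic.
    """
    if mean_cross_section <= 0:
        raise ValueError("mean_cross_section must be > 0")
    wl = PAR_WAVELENGTHS
    shape = np.full(wl.size, float(baseline))
    for center, width, height in peaks or ():
        if height < 0:
            raise ValueError("peak heights must be non-negative")
        if width <= 0:
            raise ValueError("peak widths must be > 0")
        shape = shape + height * np.exp(-0.5 * ((wl - center) / width) ** 2)
    if seed is not None:
        rng = np.random.default_rng(seed)
        shape = shape * _lognormal_factors(rng, jitter_cv, wl.size)
    cross = shape * (mean_cross_section / shape.mean())
    return AbsorptionSpectrum(cross_section=cross)
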