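"""Kinetic simulation of a flat-panel photobioreactor chemostat over a diel cycle.

The growth model couples three classical pieces:

* a spectral Lambert-Beer light gradient over the panel depth,
* the Jassby-Platt hyperbolic-tangent photosynthesis-irradiance response,
* Pirt's maintenance term, subtracted as a constant biomass sink,

so the local specific growth rate at depth z is

    µ(z) = µ_m · tanh( Y_mol · φ(z) / µ_m ) − µ_e

with φ(z) the specific photon absorption rate (mol_ph·mol_x⁻¹·day⁻¹ on the
common per-day time base) and Y_mol = Y_x/ph^m / 24 the molar yield on light.
The culture is assumed ideally mixed, so every cell sees the depth-average µ.

State variables are the culture density C_x and the cumulative harvested
biomass M_x (both mol_x·m⁻³); the chemostat balance

    dC_x/dt = (µ(C_x, t) − D(t))·C_x,      dM_x/dt = D(t)·C_x

is integrated with classical fixed-step 4th-order Runge-Kutta. Dilution is
by default gated to daylight: a stated daily rate D (total volume fractions
exchanged per day) is delivered uniformly between sunrise and sunset, i.e.
at instantaneous rate D·24/daylight_hours, and is zero at night.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .estimation import Stoichiometry
from .light import (
    BIOMASS_MOLAR_MASS,
    AbsorptionSpectrum,
    DielLight,
    SpectralDistribution,
    daily_photon_dose,
    diel_irradiance,
    local_absorption_rate,
    spectral_surface,
)

__all__ = [
    "SpeciesParams",
    "ReactorConfig",
    "OperatingSchedule",
    "EnergyConstants",
    "SimResult",
    "local_growth_rate",
    "depth_avg_growth",
    "simulate_chemostat",
    "areal_productivity",
    "yield_on_light",
    "photosynthetic_efficiency",
    "optimize_dilution",
]

_SECONDS_PER_DAY = 86400.0

#: Theoretical ceiling of the biomass yield on light (g_x·mol_ph⁻¹, urea).
YIELD_MAX_CEILING = 1.8

#: Day-over-day pointwise agreement below which the diel cycle is pseudo-steady.
PSEUDO_STEADY_TOL = 0.005


@dataclass(frozen=True)
class SpeciesParams:
    """Biological parameter set of one strain for the growth model."""

    name: str
    yield_max: float  # Y_x/ph^m, g_x·mol_ph⁻¹
    maintenance_rate: float  # µ_e, day⁻¹
    mu_max: float  # µ_m, day⁻¹
    stoichiometry: Stoichiometry = field(default_factory=Stoichiometry)
    absorption: AbsorptionSpectrum | None = None

    def __post_init__(self) -> None:
        if not 0 < self.yield_max <= YIELD_MAX_CEILING:
            raise ValueError(
                f"yield_max must be in (0, {YIELD_MAX_CEILING}] g/mol (theoretical ceiling)"
            )
        if self.maintenance_rate < 0:
            raise ValueError("maintenance_rate must be >= 0")
        if self.mu_max <= self.maintenance_rate:
            raise ValueError("mu_max must exceed maintenance_rate")

    @property
    def yield_max_molar(self) -> float:
        """Y_mol, mol_x·mol_ph⁻¹."""
        return self.yield_max / BIOMASS_MOLAR_MASS


@dataclass(frozen=True)
class ReactorConfig:
    """Flat-panel geometry and depth discretisation."""

    depth: float = 0.015  # m
    n_layers: int = 100

    def __post_init__(self) -> None:
        if self.depth <= 0:
            raise ValueError("depth must be > 0")
        if self.n_layers < 2:
            raise ValueError("n_layers must be >= 2")


@dataclass(frozen=True)
class OperatingSchedule:
    """Chemostat operating program over the simulated period."""

    daily_dilution: float  # day⁻¹, total volume fractions exchanged per day
    initial_biomass: float  # g·L⁻¹
    daylight_only: bool = True
    n_days: int = 10
    dt: float = 60.0  # s

    def __post_init__(self) -> None:
        if self.daily_dilution < 0:
            raise ValueError("daily_dilution must be >= 0")
        if self.initial_biomass <= 0:
            raise ValueError("initial_biomass must be > 0")
        if self.n_days < 1:
            raise ValueError("n_days must be >= 1")
        if self.dt <= 0 or abs(_SECONDS_PER_DAY / self.dt - round(_SECONDS_PER_DAY / self.dt)) > 1e-9:
            raise ValueError("dt must divide one day evenly")


@dataclass(frozen=True)
class EnergyConstants:
    """Constants for normalising productivity to full-spectrum solar energy."""

    biomass_enthalpy: float = 22.5  # kJ·g⁻¹ combustion enthalpy of biomass
    mean_par_photon_energy: float = 217.5  # kJ·mol_ph⁻¹ over the PAR band
    par_fraction_of_solar: float = 0.43  # PAR share of total solar energy

    def __post_init__(self) -> None:
        if min(self.biomass_enthalpy, self.mean_par_photon_energy) <= 0:
            raise ValueError("energy constants must be positive")
        if not 0 < self.par_fraction_of_solar < 1:
            raise ValueError("par_fraction_of_solar must be in (0, 1)")


@dataclass
class SimResult:
    """Trajectory and day-10 performance figures of one simulation."""

    time_days: np.ndarray  # step grid, days
    biomass_conc: np.ndarray  # C_x, mol_x·m⁻³
    harvested: np.ndarray  # M_x cumulative, mol_x·m⁻³
    irradiance: np.ndarray  # surface, µmol_ph·m⁻²·s⁻¹
    dilution: np.ndarray  # instantaneous D, day⁻¹
    areal_productivity: float  # r_x,area, g·m⁻²·day⁻¹ (final day)
    areal_productivity_mol: float  # mol_x·m⁻²·day⁻¹
    yield_on_light: float  # Y_x/ph observed, g_x·mol_ph⁻¹
    pe_percent: float  # photosynthetic efficiency vs full solar spectrum, %
    daily_dose: float  # mol_ph·m⁻²·day⁻¹
    pseudo_steady: bool

    @property
    def biomass_g_per_L(self) -> np.ndarray:
        return self.biomass_conc * BIOMASS_MOLAR_MASS / 1000.0


def local_growth_rate(phi, sp: SpeciesParams):
    """Local specific growth rate (day⁻¹) at photon absorption rate ``phi``.

    ``phi`` is in mol_ph·mol_x⁻¹·s⁻¹ (as returned by the light field); it is
    put on the per-day base internally. Bounded in [−µ_e, µ_m − µ_e).
    """
    phi_arr = np.asarray(phi, dtype=float)
    if np.any(phi_arr < 0):
        raise ValueError("photon absorption rate must be >= 0")
    drive = sp.yield_max_molar * phi_arr * _SECONDS_PER_DAY  # day⁻¹
    mu = sp.mu_max * np.tanh(drive / sp.mu_max) - sp.maintenance_rate
    return float(mu) if np.isscalar(phi) else mu


def depth_avg_growth(
    biomass_conc: float,
    surface_total: float,
    sp: SpeciesParams,
    rc: ReactorConfig,
    shape: SpectralDistribution,
) -> float:
    """Depth-averaged specific growth rate (day⁻¹) of the mixed culture.

    Trapezoid average of the local rate over ``rc.n_layers`` uniform depth
    intervals; ``surface_total`` is the incident irradiance in
    µmol_ph·m⁻²·s⁻¹ and ``biomass_conc`` in mol_x·m⁻³.
    """
    if biomass_conc <= 0:
        raise ValueError("biomass_conc must be > 0")
    if sp.absorption is None:
        raise ValueError(f"species {sp.name!r} has no absorption spectrum")
    if surface_total <= 0:
        return -sp.maintenance_rate
    z = np.linspace(0.0, rc.depth, rc.n_layers + 1)
    surface = spectral_surface(surface_total * 1e-6, shape)  # mol units
    phi = local_absorption_rate(surface, sp.absorption, biomass_conc, z)
    mu = local_growth_rate(phi, sp)
    return float(np.trapezoid(mu, z) / rc.depth)


def simulate_chemostat(
    sp: SpeciesParams,
    rc: ReactorConfig,
    sched: OperatingSchedule,
    light: DielLight,
    shape: SpectralDistribution,
    energy: EnergyConstants = EnergyConstants(),
) -> SimResult:
    """Integrate the diel chemostat over ``sched.n_days`` identical days.

    Classical RK4 at fixed step ``sched.dt``; dilution daylight-gated per the
    schedule. Aborts with a diagnostic if the state goes non-finite or the
    density crosses zero (step too coarse or washout).
    """
    steps_per_day = int(round(_SECONDS_PER_DAY / sched.dt))
    n_steps = steps_per_day * sched.n_days
    h = 1.0 / steps_per_day  # day

    if sched.daylight_only:
        d_inst = sched.daily_dilution * 24.0 / light.daylight_hours
    else:
        d_inst = sched.daily_dilution

    def dilution_at(t_day: float) -> float:
        if not sched.daylight_only:
            return d_inst
        t_h = (t_day % 1.0) * 24.0
        return d_inst if light.sunrise_h <= t_h < light.sunset_h else 0.0

    def mu_at(c: float, t_day: float) -> float:
        irr = diel_irradiance((t_day % 1.0) * 24.0, light)
        if irr <= 0.0:
            return -sp.maintenance_rate
        return depth_avg_growth(c, irr, sp, rc, shape)

    c0 = sched.initial_biomass * 1000.0 / BIOMASS_MOLAR_MASS  # mol·m⁻³
    time = np.arange(n_steps + 1) * h
    cx = np.empty(n_steps + 1)
    mx = np.empty(n_steps + 1)
    cx[0], mx[0] = c0, 0.0

    def deriv(c: float, t_day: float) -> tuple[float, float]:
        d = dilution_at(t_day)
        mu = mu_at(c, t_day)
        return (mu - d) * c, d * c

    for k in range(n_steps):
        t = time[k]
        c = cx[k]
        k1c, k1m = deriv(c, t)
        k2c, k2m = deriv(c + 0.5 * h * k1c, t + 0.5 * h)
        k3c, k3m = deriv(c + 0.5 * h * k2c, t + 0.5 * h)
        k4c, k4m = deriv(c + h * k3c, t + h)
        cx[k + 1] = c + (h / 6.0) * (k1c + 2 * k2c + 2 * k3c + k4c)
        mx[k + 1] = mx[k] + (h / 6.0) * (k1m + 2 * k2m + 2 * k3m + k4m)
        if not np.isfinite(cx[k + 1]) or cx[k + 1] <= 0.0:
            raise RuntimeError(
                f"integration failed at t = {time[k + 1]:.4f} d: "
                f"C_x = {cx[k + 1]!r} (step too coarse, or washout at D = "
                f"{sched.daily_dilution} /d)"
            )

    irr = diel_irradiance((time % 1.0) * 24.0, light)
    dil = np.array([dilution_at(t) for t in time])

    if sched.n_days >= 2:
        day9 = cx[(sched.n_days - 2) * steps_per_day : (sched.n_days - 1) * steps_per_day + 1]
        day10 = cx[(sched.n_days - 1) * steps_per_day :]
        pseudo = bool(np.max(np.abs(day10 - day9) / day9) < PSEUDO_STEADY_TOL)
    else:
        pseudo = False
    if not pseudo:
        warnings.warn(
            f"{sp.name}: no pseudo-steady diel cycle after {sched.n_days} days",
            stacklevel=2,
        )

    res = SimResult(
        time_days=time,
        biomass_conc=cx,
        harvested=mx,
        irradiance=irr,
        dilution=dil,
        areal_productivity=np.nan,
        areal_productivity_mol=np.nan,
        yield_on_light=np.nan,
        pe_percent=np.nan,
        daily_dose=daily_photon_dose(light),
        pseudo_steady=pseudo,
    )
    if sched.n_days >= 2:
        r_mol = areal_productivity(res, rc)
        res.areal_productivity_mol = r_mol
        res.areal_productivity = r_mol * BIOMASS_MOLAR_MASS
        if res.daily_dose > 0:  # dark runs have no yield on light
            res.yield_on_light = yield_on_light(r_mol, res.daily_dose) * BIOMASS_MOLAR_MASS
            res.pe_percent = photosynthetic_efficiency(
                res.areal_productivity, res.daily_dose, energy
            )
    return res


def areal_productivity(res: SimResult, rc: ReactorConfig) -> float:
    """Areal biomass productivity over the final simulated day, mol_x·m⁻²·day⁻¹.

    r_x,area = [ΔC_x + ΔM_x] · l over the last day: net density change plus
    harvest, scaled by the panel depth.
    """
    t = res.time_days
    t_end = t[-1]
    if t_end < 2.0 - 1e-9:
        raise ValueError("trajectory must span at least 2 days for a day-over-day rate")
    i9 = int(np.searchsorted(t, t_end - 1.0))
    if abs(t[i9] - (t_end - 1.0)) > 1e-9:
        raise ValueError("time grid does not contain the start of the final day")
    d_cx = res.biomass_conc[-1] - res.biomass_conc[i9]
    d_mx = res.harvested[-1] - res.harvested[i9]
    return (d_cx + d_mx) * rc.depth


def yield_on_light(r_areal_mol: float, dose: float) -> float:
    """Observed biomass yield on light Y_x/ph (mol_x·mol_ph⁻¹)."""
    if dose <= 0:
        raise ValueError("photon dose must be > 0")
    return r_areal_mol / dose


def photosynthetic_efficiency(
    r_areal_g: float, dose: float, ec: EnergyConstants = EnergyConstants()
) -> float:
    """Photosynthetic efficiency (%) normalised to the full solar spectrum.

    Combustion energy of the biomass produced per m² and day, over the total
    incident solar energy (PAR dose scaled up by 1/par_fraction).
    """
    if dose <= 0:
        raise ValueError("photon dose must be > 0")
    solar_energy = dose * ec.mean_par_photon_energy / ec.par_fraction_of_solar  # kJ·m⁻²
    return 100.0 * r_areal_g * ec.biomass_enthalpy / solar_energy


def optimize_dilution(
    sp: SpeciesParams,
    rc: ReactorConfig,
    light: DielLight,
    shape: SpectralDistribution,
    search_range: tuple[float, float] = (0.1, 1.2),
    resolution: float = 0.01,
    initial_biomass: float = 3.0,
    n_days: int = 10,
    dt: float = 60.0,
) -> tuple[float, float, dict[float, float]]:
    """Grid search for the productivity-maximising daily dilution rate.

    Scans ``search_range`` at ``resolution`` (day⁻¹); each run is warm-started
    from the previous grid point's final density so the pseudo-steady cycle is
    reached quickly. Returns ``(d_star, r_star, curve)`` with the productivity
    (g·m⁻²·day⁻¹) per grid point; ties break toward the lower rate.
    """
    if resolution <= 0:
        raise ValueError("resolution must be > 0")
    lo, hi = search_range
    if not 0 < lo <= hi:
        raise ValueError("search_range must be within (0, mu_max)")
    grid = np.arange(lo, hi + 0.5 * resolution, resolution)
    if grid.size == 0:
        raise ValueError("empty dilution grid")
    curve: dict[float, float] = {}
    c_start = initial_biomass
    for d in grid:
        sched = OperatingSchedule(
            daily_dilution=float(d), initial_biomass=c_start, n_days=n_days, dt=dt
        )
        try:
            res = simulate_chemostat(sp, rc, sched, light, shape)
        except RuntimeError:  # washout: beyond the feasible range
            curve[float(d)] = np.nan
            continue
        curve[float(d)] = res.areal_productivity
        c_start = max(float(res.biomass_g_per_L[-1]), 0.05)
    finite = {d: r for d, r in curve.items() if np.isfinite(r)}
    if not finite:
        raise RuntimeError("no feasible dilution rate in the search range")
    d_star = min(finite, key=lambda d: (-finite[d], d))
    return d_star, finite[d_star], curve
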