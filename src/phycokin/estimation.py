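"""Growth-parameter estimation from light-limited chemostats and PI curves.

Three strain parameters are extracted here:

* the maximal biomass yield on light Y_x/ph^m (g_x·mol_ph⁻¹) and the specific
  maintenance rate µ_e (day⁻¹), via Pirt's linear law fitted to chemostat
  steady states — the specific photon consumption rate q_ph plotted against
  the specific growth rate µ (= dilution rate D at steady state) is a line
  with slope 1/Y and positive intercept m_s = µ_e/Y;
* the maximal specific growth rate µ_max (day⁻¹), read off the plateau of a
  photosynthesis-irradiance (PI) curve measured as oxygen evolution in a
  biological oxygen monitor (BOM), converted to a growth rate by the
  photosynthetic stoichiometry of the nitrogen source.

All rates are per day; concentrations in g·L⁻¹ at the API boundary, with the
24 g·mol⁻¹ biomass molar-mass convention applied internally.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .light import BIOMASS_MOLAR_MASS

__all__ = [
    "Stoichiometry",
    "ChemostatObservation",
    "PIRecord",
    "PirtFit",
    "PICurveResult",
    "mu_from_oxygen",
    "mumax_from_pi_curve",
    "dilution_from_harvest",
    "qph_from_observation",
    "fit_pirt",
    "steady_state_filter",
]

_SECONDS_PER_DAY = 86400.0

#: Recommended BOM cuvette density window, g·L⁻¹ (cell shading negligible).
CUVETTE_DENSITY_RANGE = (0.1, 0.4)

#: Steady-state acceptance rule: relative variation below this over a
#: rolling window of at least this many consecutive daily samples.
STEADY_STATE_MAX_VARIATION = 0.15
STEADY_STATE_MIN_DAYS = 3


@dataclass(frozen=True)
class Stoichiometry:
    """Photosynthetic oxygen stoichiometry of biomass formation.

    ``x_ox_*`` is the mol O2 evolved per mol biomass formed; it depends on the
    nitrogen source because nitrate must be reduced before assimilation.
    """

    x_ox_urea: float = 1.11
    x_ox_nitrate: float = 1.44
    biomass_molar_mass: float = BIOMASS_MOLAR_MASS  # g·mol⁻¹

    def __post_init__(self) -> None:
        if min(self.x_ox_urea, self.x_ox_nitrate, self.biomass_molar_mass) <= 0:
            raise ValueError("stoichiometric constants must be strictly positive")

    def x_ox(self, nitrogen_source: str) -> float:
        try:
            return {"urea": self.x_ox_urea, "nitrate": self.x_ox_nitrate}[nitrogen_source]
        except KeyError:
            raise ValueError(
                f"unknown nitrogen source {nitrogen_source!r}; expected 'urea' or 'nitrate'"
            ) from None


@dataclass(frozen=True)
class ChemostatObservation:
    """One daily steady-state record from a light-limited chemostat run."""

    dilution_rate: float  # day⁻¹
    incident_irradiance: float  # µmol_ph·m⁻²·s⁻¹
    outgoing_irradiance: float  # µmol_ph·m⁻²·s⁻¹
    biomass_conc: float  # g·L⁻¹
    optical_depth: float  # m
    timestamp: float = 0.0  # day index

    def __post_init__(self) -> None:
        if self.dilution_rate < 0:
            raise ValueError("dilution_rate must be >= 0")
        if not 0 <= self.outgoing_irradiance <= self.incident_irradiance:
            raise ValueError("need 0 <= outgoing <= incident irradiance")
        if self.biomass_conc <= 0:
            raise ValueError("biomass_conc must be > 0")
        if self.optical_depth <= 0:
            raise ValueError("optical_depth must be > 0")


@dataclass(frozen=True)
class PIRecord:
    """One oxygen-evolution measurement at one light level in the BOM."""

    light_level: float  # µmol_ph·m⁻²·s⁻¹
    o2_rate: float  # mol_O2·L⁻¹·day⁻¹ (net; negative = net respiration)
    cuvette_biomass: float  # g·L⁻¹
    nitrogen_source: str = "urea"

    def __post_init__(self) -> None:
        if self.light_level < 0:
            raise ValueError("light_level must be >= 0")
        if self.cuvette_biomass <= 0:
            raise ValueError("cuvette_biomass must be > 0")
        if self.nitrogen_source not in ("urea", "nitrate"):
            raise ValueError(f"unknown nitrogen source {self.nitrogen_source!r}")
        lo, hi = CUVETTE_DENSITY_RANGE
        if not lo <= self.cuvette_biomass <= hi:
            warnings.warn(
                f"cuvette biomass {self.cuvette_biomass} g/L outside the "
                f"recommended {lo}-{hi} g/L window; cell shading may bias µ",
                stacklevel=2,
            )


@dataclass(frozen=True)
class PirtFit:
    """Result of the Pirt regression q_ph = µ/Y + µ_e/Y."""

    yield_max: float  # Y_x/ph^m, g_x·mol_ph⁻¹
    maintenance_rate: float  # µ_e, day⁻¹
    specific_maintenance_consumption: float  # m_s = µ_e/Y, mol_ph·g⁻¹·day⁻¹
    r_squared: float
    n_points: int

    def __post_init__(self) -> None:
        if self.n_points < 2:
            raise ValueError("a Pirt fit needs at least 2 points")


@dataclass(frozen=True)
class PICurveResult:
    """Per-light-level aggregated PI curve with its maximum."""

    mu_max: float  # day⁻¹
    light_at_max: float  # µmol_ph·m⁻²·s⁻¹
    light_levels: np.ndarray = field(repr=False)
    mu_mean: np.ndarray = field(repr=False)
    mu_sd: np.ndarray = field(repr=False)
    sd_at_max: float = float("nan")


def mu_from_oxygen(rec: PIRecord, stoich: Stoichiometry = Stoichiometry()) -> float:
    """Specific growth rate (day⁻¹) from a net oxygen-evolution record.

    µ = r_o / (x_ox · C_x,cuvette) with the cuvette biomass expressed in
    mol·L⁻¹. The sign follows the oxygen rate: net respiration in darkness
    gives a negative µ.
    """
    x_ox = stoich.x_ox(rec.nitrogen_source)
    c_mol = rec.cuvette_biomass / stoich.biomass_molar_mass  # mol·L⁻¹
    return rec.o2_rate / (x_ox * c_mol)


def mumax_from_pi_curve(
    records: Sequence[PIRecord], stoich: Stoichiometry = Stoichiometry()
) -> PICurveResult:
    """Maximal specific growth rate from a PI curve.

    Replicates are averaged per light level first (SD reported per level);
    µ_max is the largest per-level mean and ``light_at_max`` the level where
    it occurs. All records must share one nitrogen source.
    """
    if not records:
        raise ValueError("empty PI record list")
    sources = {r.nitrogen_source for r in records}
    if len(sources) > 1:
        raise ValueError(f"mixed nitrogen sources in one PI curve: {sorted(sources)}")
    levels = np.array(sorted({r.light_level for r in records}))
    if len(records) < 3 or levels.size < 2:
        raise ValueError("need >= 3 records spanning >= 2 distinct light levels")
    mus = {lvl: [] for lvl in levels}
    for r in records:
        mus[r.light_level].append(mu_from_oxygen(r, stoich))
    mean = np.array([np.mean(mus[lvl]) for lvl in levels])
    sd = np.array([np.std(mus[lvl], ddof=1) if len(mus[lvl]) > 1 else 0.0 for lvl in levels])
    i = int(np.argmax(mean))
    return PICurveResult(
        mu_max=float(mean[i]),
        light_at_max=float(levels[i]),
        light_levels=levels,
        mu_mean=mean,
        mu_sd=sd,
        sd_at_max=float(sd[i]),
    )


def dilution_from_harvest(
    harvest_mass: float, reactor_volume: float = 0.38, medium_density: float = 1030.0
) -> float:
    """Dilution rate D (day⁻¹) from the daily harvest mass.

    D = M_h / (V_r·ρ): the harvest is weighed, so the exchanged volume is the
    harvest mass over the medium density. Defaults: 0.38 L working volume,
    1030 g·L⁻¹ seawater-medium density.
    """
    if reactor_volume <= 0 or medium_density <= 0:
        raise ValueError("reactor_volume and medium_density must be > 0")
    if harvest_mass < 0:
        raise ValueError("harvest_mass must be >= 0")
    return harvest_mass / (reactor_volume * medium_density)


def qph_from_observation(obs: ChemostatObservation) -> float:
    """Specific photon consumption rate q_ph (mol_ph·g⁻¹·day⁻¹).

    q_ph = (I_in − I_out) / (C_x·d): absorbed photon flux per unit of ground
    area, normalised by the areal biomass density. Irradiances are converted
    µmol·m⁻²·s⁻¹ → mol·m⁻²·day⁻¹ and biomass g·L⁻¹ → g·m⁻³.
    """
    absorbed = (obs.incident_irradiance - obs.outgoing_irradiance) * 1e-6 * _SECONDS_PER_DAY
    areal_biomass = obs.biomass_conc * 1000.0 * obs.optical_depth  # g·m⁻²
    return absorbed / areal_biomass


def fit_pirt(
    points: Iterable[tuple[float, float]],
    weights: Sequence[float] | None = None,
) -> PirtFit:
    """Fit Pirt's law to (µ, q_ph) steady-state points.

    Ordinary least squares of q_ph on µ (optionally weighted). The slope is
    1/Y_x/ph^m, the intercept the specific maintenance consumption
    m_s = µ_e/Y, hence µ_e = m_s·Y. A negative fitted slope means the data
    were not light limited and triggers a warning, not an error.
    """
    pts = np.asarray(list(points), dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 2:
        raise ValueError("need at least 2 (mu, qph) points")
    mu, qph = pts[:, 0], pts[:, 1]
    if np.ptp(mu) == 0:
        raise ValueError("degenerate regression: all µ values identical")
    w = np.ones_like(mu) if weights is None else np.asarray(weights, dtype=float)
    sw = np.sqrt(w)
    design = np.column_stack([mu, np.ones_like(mu)])
    coef, *_ = np.linalg.lstsq(design * sw[:, None], qph * sw, rcond=None)
    slope, intercept = float(coef[0]), float(coef[1])
    if slope <= 0:
        warnings.warn(
            "non-positive Pirt slope: data are not light-limited; "
            "yield estimate is non-physical",
            stacklevel=2,
        )
    resid = qph - design @ coef
    ss_tot = float(np.sum(w * (qph - np.average(qph, weights=w)) ** 2))
    r2 = 1.0 - float(np.sum(w * resid**2)) / ss_tot if ss_tot > 0 else 1.0
    yield_max = 1.0 / slope
    return PirtFit(
        yield_max=yield_max,
        maintenance_rate=intercept * yield_max,
        specific_maintenance_consumption=intercept,
        r_squared=r2,
        n_points=int(mu.size),
    )


def steady_state_filter(
    series: Sequence[tuple[float, float, float]],
    max_variation: float = STEADY_STATE_MAX_VARIATION,
    min_days: int = STEADY_STATE_MIN_DAYS,
):
    """Locate the earliest steady window in a (timestamp, C_x, D) series.

    Steady means the relative range (max − min)/mean of *both* biomass
    concentration and dilution rate stays below ``max_variation`` over at
    least ``min_days`` consecutive daily samples. Returns
    ``(is_steady, (t_start, t_end))``; the window is ``None`` when no stretch
    qualifies.
    """
    arr = np.asarray(list(series), dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 3:
        raise ValueError("series rows must be (timestamp, biomass_conc, dilution_rate)")
    t = arr[:, 0]
    if np.any(np.diff(t) <= 0):
        raise ValueError("timestamps must be strictly increasing")
    if arr.shape[0] < min_days:
        return False, None

    def rel_range(x: np.ndarray) -> float:
        m = x.mean()
        return np.inf if m == 0 else float(np.ptp(x) / m)

    for i in range(arr.shape[0] - min_days + 1):
        win = arr[i : i + min_days]
        if (
            rel_range(win[:, 1]) < max_variation
            and rel_range(win[:, 2]) < max_variation
        ):
            return True, (float(win[0, 0]), float(win[-1, 0]))
    return False, None
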