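"""Built-in strain parameterizations.

Growth parameters for the three strains measured in flat-panel chemostat and
biological-oxygen-monitor experiments: *Picochlorum* sp. (BPE23),
*Nannochloropsis* sp. and *Neochloris oleoabundans*, plus the hypothetical
fast *Picochlorum celeri* variant (the BPE23 parameter set with the
literature µ_max of 7.9 day⁻¹ substituted).

Measured absorption spectra are not distributed with the package; by default
each strain carries a synthetic chlorophyte-like spectrum with a PAR-mean
cross-section of 0.2 m²·g⁻¹ (see :mod:`phycokin.synthetic`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .simulate import SpeciesParams
from .synthetic import gen_absorption_spectrum

__all__ = ["StrainDefaults", "STRAINS", "species_params"]


@dataclass(frozen=True)
class StrainDefaults:
    """Full default parameterization of one built-in strain."""

    name: str
    yield_max: float  # g_x·mol_ph⁻¹
    maintenance_rate: float  # day⁻¹
    mu_max_urea: float  # day⁻¹
    mu_max_nitrate: float  # day⁻¹
    best_daily_dilution: float  # day⁻¹, productivity-maximising chemostat rate
    initial_biomass: float  # g·L⁻¹, near the pseudo-steady density
    dilution_grid: tuple[float, ...] = ()  # day⁻¹, chemostat experiment ladder

    def mu_max(self, nitrogen_source: str = "urea") -> float:
        if nitrogen_source == "urea":
            return self.mu_max_urea
        if nitrogen_source == "nitrate":
            return self.mu_max_nitrate
        raise ValueError(f"unknown nitrogen source {nitrogen_source!r}")


STRAINS: dict[str, StrainDefaults] = {
    "picochlorum": StrainDefaults(
        name="Picochlorum sp. (BPE23)",
        yield_max=1.38,
        maintenance_rate=0.079,
        mu_max_urea=4.98,
        mu_max_nitrate=3.79,
        best_daily_dilution=0.68,
        initial_biomass=2.9,
        dilution_grid=(0.18, 0.27, 0.31, 0.35, 0.48, 0.48, 0.57, 0.69, 0.90),
    ),
    "nannochloropsis": StrainDefaults(
        name="Nannochloropsis sp.",
        yield_max=1.23,
        maintenance_rate=0.099,
        mu_max_urea=2.10,
        mu_max_nitrate=2.48,
        best_daily_dilution=0.44,
        initial_biomass=3.6,
        dilution_grid=(0.1, 0.2, 0.4, 0.5, 0.6),
    ),
    "neochloris": StrainDefaults(
        name="Neochloris oleoabundans",
        yield_max=1.78,
        maintenance_rate=0.104,
        mu_max_urea=2.45,
        mu_max_nitrate=2.44,
        best_daily_dilution=0.47,
        initial_biomass=3.6,
        dilution_grid=(0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 1.2),
    ),
    # thought experiment: BPE23 biology with the P. celeri literature mu_max
    "celeri": StrainDefaults(
        name="Picochlorum celeri (hypothetical)",
        yield_max=1.38,
        maintenance_rate=0.079,
        mu_max_urea=7.9,
        mu_max_nitrate=7.9,
        best_daily_dilution=0.68,
        initial_biomass=2.9,
        dilution_grid=(0.18, 0.27, 0.31, 0.35, 0.48, 0.48, 0.57, 0.69, 0.90),
    ),
}


def species_params(
    key: str,
    nitrogen_source: str = "urea",
    mean_cross_section: float = 0.2,
) -> SpeciesParams:
    """Build :class:`SpeciesParams` for a built-in strain.

    The absorption spectrum is the synthetic chlorophyte default rescaled to
    ``mean_cross_section`` (m²·g⁻¹); pass a custom spectrum by constructing
    :class:`SpeciesParams` directly.
    """
    try:
        d = STRAINS[key]
    except KeyError:
        raise ValueError(
            f"unknown strain {key!r}; choose from {sorted(STRAINS)}"
        ) from None
    return SpeciesParams(
        name=d.name,
        yield_max=d.yield_max,
        maintenance_rate=d.maintenance_rate,
        mu_max=d.mu_max(nitrogen_source),
        absorption=gen_absorption_spectrum(mean_cross_section=mean_cross_section),
    )
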