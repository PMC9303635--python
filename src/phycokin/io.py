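"""CSV schemas, scenario configuration and run manifests.

All files are comma-separated, dot-decimal, UTF-8 with a mandatory header
row. The schemas here are the package's external data contracts:

* chemostat observations: ``species, day, dilution_rate_per_day,
  incident_umol_m2_s, outgoing_umol_m2_s, biomass_g_per_L, optical_depth_m``
* PI records: ``species, nitrogen_source, light_umol_m2_s,
  o2_rate_mol_per_L_day, biomass_g_per_L, replicate``
* absorption spectra: ``wavelength_nm, cross_section_m2_per_g``
* solar shape: ``wavelength_nm, weight``

Scenario configs are YAML with nested sections (species, reactor, light,
schedule, energy); every simulation default is overridable. Each CLI run
writes one JSON manifest recording the command, a config digest, the seed
and the produced files, so identical config + seed reproduces identical
outputs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from importlib.metadata import PackageNotFoundError, version as pkg_version
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd
import yaml

from .estimation import ChemostatObservation, PIRecord
from .light import PAR_WAVELENGTHS, AbsorptionSpectrum, SpectralDistribution

__all__ = [
    "CHEMOSTAT_COLUMNS",
    "PI_COLUMNS",
    "RunManifest",
    "SchemaError",
    "read_chemostat_csv",
    "write_chemostat_csv",
    "read_pi_csv",
    "write_pi_csv",
    "read_absorption_csv",
    "write_absorption_csv",
    "read_spectral_shape_csv",
    "load_scenario_config",
    "write_manifest",
]

CHEMOSTAT_COLUMNS = [
    "species",
    "day",
    "dilution_rate_per_day",
    "incident_umol_m2_s",
    "outgoing_umol_m2_s",
    "biomass_g_per_L",
    "optical_depth_m",
]

PI_COLUMNS = [
    "species",
    "nitrogen_source",
    "light_umol_m2_s",
    "o2_rate_mol_per_L_day",
    "biomass_g_per_L",
    "replicate",
]


class SchemaError(ValueError):
    """Raised when an input file does not match its documented schema."""


@dataclass
class RunManifest:
    command: str
    config_digest: str
    seed: int | None
    versions: dict[str, str]
    outputs: list[str]


def _require_columns(df: pd.DataFrame, columns: Sequence[str], path: Path) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")


def _numeric(df: pd.DataFrame, columns: Sequence[str], path: Path) -> pd.DataFrame:
    out = df.copy()
    for c in columns:
        parsed = pd.to_numeric(out[c], errors="coerce")
        bad = parsed.isna() & out[c].notna()
        if bad.any():
            row = int(bad.idxmax()) + 2  # header is line 1
            raise SchemaError(f"{path}: non-numeric value in column {c!r} at line {row}")
        out[c] = parsed
    return out


def read_chemostat_csv(path: str | Path) -> dict[str, list[ChemostatObservation]]:
    """Read chemostat observations grouped by species (row order preserved)."""
    path = Path(path)
    df = pd.read_csv(path)
    _require_columns(df, CHEMOSTAT_COLUMNS, path)
    df = _numeric(df, CHEMOSTAT_COLUMNS[1:], path)
    grouped: dict[str, list[ChemostatObservation]] = {}
    for i, row in df.iterrows():
        try:
            obs = ChemostatObservation(
                dilution_rate=row["dilution_rate_per_day"],
                incident_irradiance=row["incident_umol_m2_s"],
                outgoing_irradiance=row["outgoing_umol_m2_s"],
                biomass_conc=row["biomass_g_per_L"],
                optical_depth=row["optical_depth_m"],
                timestamp=row["day"],
            )
        except ValueError as e:
            raise SchemaError(f"{path}: invalid record at line {int(i) + 2}: {e}") from e
        grouped.setdefault(str(row["species"]), []).append(obs)
    return grouped


def write_chemostat_csv(
    path: str | Path, per_species: dict[str, list[ChemostatObservation]]
) -> None:
    rows = []
    for species, obs_list in per_species.items():
        for o in obs_list:
            rows.append(
                {
                    "species": species,
                    "day": o.timestamp,
                    "dilution_rate_per_day": o.dilution_rate,
                    "incident_umol_m2_s": o.incident_irradiance,
                    "outgoing_umol_m2_s": o.outgoing_irradiance,
                    "biomass_g_per_L": o.biomass_conc,
                    "optical_depth_m": o.optical_depth,
                }
            )
    pd.DataFrame(rows, columns=CHEMOSTAT_COLUMNS).to_csv(path, index=False)


def read_pi_csv(path: str | Path) -> dict[tuple[str, str], list[PIRecord]]:
    """Read PI records grouped by (species, nitrogen_source)."""
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        return {}
    if df.empty:
        return {}
    _require_columns(df, PI_COLUMNS, path)
    df = _numeric(df, ["light_umol_m2_s", "o2_rate_mol_per_L_day", "biomass_g_per_L"], path)
    grouped: dict[tuple[str, str], list[PIRecord]] = {}
    for i, row in df.iterrows():
        try:
            rec = PIRecord(
                light_level=row["light_umol_m2_s"],
                o2_rate=row["o2_rate_mol_per_L_day"],
                cuvette_biomass=row["biomass_g_per_L"],
                nitrogen_source=str(row["nitrogen_source"]),
            )
        except ValueError as e:
            raise SchemaError(f"{path}: invalid record at line {int(i) + 2}: {e}") from e
        grouped.setdefault((str(row["species"]), rec.nitrogen_source), []).append(rec)
    return grouped


def write_pi_csv(
    path: str | Path, per_group: dict[tuple[str, str], list[PIRecord]]
) -> None:
    rows = []
    for (species, _source), recs in per_group.items():
        rep_counter: dict[float, int] = {}
        for r in recs:
            rep = rep_counter.get(r.light_level, 0) + 1
            rep_counter[r.light_level] = rep
            rows.append(
                {
                    "species": species,
                    "nitrogen_source": r.nitrogen_source,
                    "light_umol_m2_s": r.light_level,
                    "o2_rate_mol_per_L_day": r.o2_rate,
                    "biomass_g_per_L": r.cuvette_biomass,
                    "replicate": rep,
                }
            )
    pd.DataFrame(rows, columns=PI_COLUMNS).to_csv(path, index=False)


def read_absorption_csv(path: str | Path) -> AbsorptionSpectrum:
    path = Path(path)
    df = pd.read_csv(path)
    _require_columns(df, ["wavelength_nm", "cross_section_m2_per_g"], path)
    df = _numeric(df, ["wavelength_nm", "cross_section_m2_per_g"], path)
    return AbsorptionSpectrum(
        cross_section=df["cross_section_m2_per_g"].to_numpy(),
        wavelengths=df["wavelength_nm"].to_numpy(),
    )


def write_absorption_csv(path: str | Path, spectrum: AbsorptionSpectrum) -> None:
    pd.DataFrame(
        {
            "wavelength_nm": spectrum.wavelengths,
            "cross_section_m2_per_g": spectrum.cross_section,
        }
    ).to_csv(path, index=False)


def read_spectral_shape_csv(path: str | Path) -> SpectralDistribution:
    path = Path(path)
    df = pd.read_csv(path)
    _require_columns(df, ["wavelength_nm", "weight"], path)
    df = _numeric(df, ["wavelength_nm", "weight"], path)
    w = np.interp(
        PAR_WAVELENGTHS, df["wavelength_nm"].to_numpy(), df["weight"].to_numpy()
    )
    return SpectralDistribution(weights=w / w.sum())


def load_scenario_config(path: str | Path) -> dict[str, Any]:
    """Load and minimally validate a YAML scenario config."""
    path = Path(path)
    with open(path, "r", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise SchemaError(f"{path}: config root must be a mapping")
    allowed = {"species", "reactor", "light", "schedule", "energy", "optimize", "seed"}
    unknown = set(cfg) - allowed
    if unknown:
        raise SchemaError(
            f"{path}: unknown config section(s) {sorted(unknown)}; allowed: {sorted(allowed)}"
        )
    return cfg


def config_digest(obj: Any) -> str:
    return hashlib.sha256(
        json.dumps(obj, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def write_manifest(
    out_dir: str | Path,
    command: str,
    config: Any,
    seed: int | None,
    outputs: Sequence[str | Path],
) -> Path:
    try:
        own = pkg_version("phycokin")
    except PackageNotFoundError:
        own = "unknown"
    manifest = RunManifest(
        command=command,
        config_digest=config_digest(config),
        seed=seed,
        versions={"phycokin": own, "numpy": np.__version__, "pandas": pd.__version__},
        outputs=[str(Path(p).name) for p in outputs],
    )
    path = Path(out_dir) / "manifest.json"
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(asdict(manifest), fh, indent=2)
        fh.write("\n")
    return path
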