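# phycokin

Growth-parameter estimation and flat-panel photobioreactor simulation for
microalgae.

Productivity models for microalgal cultivation stand or fall with three
strain-specific biological parameters: the maximal biomass yield on light
Y<sub>x/ph</sub><sup>m</sup> (g<sub>x</sub>·mol<sub>ph</sub>⁻¹), the specific
maintenance rate µ<sub>e</sub> (day⁻¹) and the maximal specific growth rate
µ<sub>max</sub> (day⁻¹). `phycokin` implements the full workflow around these
parameters for phototrophic strains such as *Picochlorum* sp.,
*Nannochloropsis* sp. and *Neochloris oleoabundans*:

* **Estimation** from the two standard laboratory assays:
  * light-limited chemostat steady states, via Pirt's law — the specific
    photon consumption rate
    *q*<sub>ph</sub> = µ/Y<sub>x/ph</sub><sup>m</sup> + µ<sub>e</sub>/Y<sub>x/ph</sub><sup>m</sup>
    is linear in the dilution rate D (= µ at steady state), so an ordinary
    least-squares line gives 1/Y from the slope and µ<sub>e</sub> from the
    intercept;
  * photosynthesis–irradiance (PI) curves measured as oxygen evolution in a
    biological oxygen monitor, converted to growth rates by
    µ = r<sub>O₂</sub>/(x<sub>ox</sub>·C<sub>x</sub>) with the
    nitrogen-source stoichiometry (x<sub>ox</sub> = 1.11 mol O₂ per mol
    biomass on urea, 1.44 on nitrate; biomass "molar mass" 24 g·mol⁻¹).
* **Simulation** of a flat-panel chemostat under a diel solar cycle with a
  kinetic model coupling wavelength-resolved Lambert–Beer light attenuation
  (400–700 nm, 1 nm), the Jassby–Platt hyperbolic-tangent
  photosynthesis–irradiance response with Pirt maintenance,
  µ(z) = µ<sub>m</sub>·tanh(Y·φ(z)/µ<sub>m</sub>) − µ<sub>e</sub>,
  and daylight-gated dilution, integrated with classical RK4 at one-minute
  steps. Outputs are the areal biomass productivity r<sub>x,area</sub>
  (g·m⁻²·day⁻¹), the observed yield on light Y<sub>x/ph</sub> and the
  photosynthetic efficiency normalised to the full solar spectrum.
* **Synthetic data generation** for all of the above — chemostat campaigns
  that obey Pirt's law exactly at zero noise, BOM oxygen records on a tanh
  PI curve (optionally with the high-light oxygen-bubble decline artifact),
  and chlorophyte-like absorption spectra — so the whole pipeline is
  testable without access to raw instrument data.

## Worked example

```python
import numpy as np
import phycokin as pk

# --- estimate growth parameters from a (here synthetic) chemostat campaign
strain = pk.STRAINS["picochlorum"]
sc = pk.SyntheticScenario(
    true_params=pk.species_params("picochlorum"),
    dilution_grid=strain.dilution_grid, noise_cv=0.05, seed=1,
)
obs = pk.gen_chemostat_obs(sc)
per_run = {}
for o in obs:
    per_run.setdefault(o.dilution_rate, []).append(pk.qph_from_observation(o))
points = [(d, float(np.mean(q))) for d, q in sorted(per_run.items())]
fit = pk.fit_pirt(points)
print(f"Y_x/ph^m = {fit.yield_max:.3f} g/mol_ph   mu_e = {fit.maintenance_rate:.4f} /day")

# --- simulate the diel flat-panel chemostat with those parameters
res = pk.simulate_chemostat(
    pk.species_params("picochlorum"), pk.ReactorConfig(),
    pk.OperatingSchedule(daily_dilution=0.68, initial_biomass=2.9),
    pk.DielLight(), pk.SpectralDistribution.daylight(),
)
print(f"daily photon dose  = {res.daily_dose:.1f} mol_ph/m2/day")
print(f"areal productivity = {res.areal_productivity:.1f} g/m2/day")
print(f"photosynthetic efficiency = {res.pe_percent:.1f} %")
```

prints

```
Y_x/ph^m = 1.376 g/mol_ph   mu_e = 0.0763 /day
daily photon dose  = 52.3 mol_ph/m2/day
areal productivity = 32.3 g/m2/day
photosynthetic efficiency = 2.8 %
```

The fitted yield and maintenance rate recover the generating parameters
(1.38 g·mol⁻¹, 0.079 day⁻¹) to within the 5% measurement noise. The
simulated summer-solstice day (half-sine, peak 1900 µmol·m⁻²·s⁻¹, 12 h
photoperiod) delivers 52.3 mol photons per m² and day; at a daily dilution
of 0.68 day⁻¹ the 15 mm panel settles into a repeating diel cycle producing
32.3 g dry weight per m² of ground area per day, i.e. 2.8% of the incident
full-spectrum solar energy fixed as biomass combustion energy.

## Command line

```sh
phycokin synth    --out data/ --seed 7 --noise-cv 0.05   # synthetic campaign
phycokin estimate --chemostat-csv data/chemostat.csv \
                  --pi-csv data/pi_records.csv --out est/ # parameter table
phycokin simulate --config scenario.yaml --out sim/       # diel simulation
phycokin optimize --config scenario.yaml --out opt/       # best dilution rate
```

Every run writes a `manifest.json` (command, config digest, seed, versions),
and identical config + seed reproduces byte-identical outputs.

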