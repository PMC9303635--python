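# Methods

This note documents the models implemented in `phycokin`, the assumptions
behind them, the defaults and why they were chosen, and what the synthetic
data generators do and do not emulate.

## Growth-parameter estimation

### Pirt regression (yield on light and maintenance rate)

Under strict light limitation every absorbed photon is used at maximal
efficiency, so the specific photon consumption rate of a chemostat culture
is linear in its specific growth rate:

    q_ph = µ / Y_x/ph^m + µ_e / Y_x/ph^m,

with µ = D at steady state. The package computes q_ph per daily observation
as (I_in − I_out)/(C_x·d) — absorbed photon flux per ground area over areal
biomass — converting irradiance to mol·m⁻²·day⁻¹ and biomass to g·m⁻³, and
fits an unweighted ordinary least-squares line of q_ph on µ. The inverse of
the slope is the maximal yield on light; the intercept is the specific
maintenance photon consumption m_s, and µ_e = m_s·Y. The identity
m_s·Y = µ_e holds exactly for every returned fit.

Sign convention: the maintenance term *raises* photon consumption at a given
growth rate, so the fitted intercept is positive for any organism with a
nonzero maintenance demand. The regression makes no sign constraint; a
negative fitted slope (non-light-limited data) triggers a warning rather
than an error, because the estimate is then diagnostic, not usable.

Weighted fits (per-point steady-state variance) are available via the
`weights` argument but off by default: with the standard 5–9 point designs
the weighting changes the estimates by far less than their standard errors
and an unweighted line is the transparent default.

### Steady-state screening

A chemostat run qualifies as steady when the relative range (max − min)/mean
of both the biomass concentration and the measured dilution rate stays below
15% over at least three consecutive daily samples; the earliest qualifying
window is used and later samples in the run are averaged into a single
(µ, q_ph) point. The relative range is the strictest of the simple
variation statistics (it dominates the CV and the mean absolute deviation),
which is the conservative reading of a "<15% variation for three days" rule.

### PI curves and µ_max

Oxygen-evolution records are converted to specific growth rates with

    µ = r_O2 / (x_ox · C_x,cuvette),

where x_ox is 1.11 mol O₂ per mol biomass on urea and 1.44 on nitrate, and
the cuvette biomass is expressed in mol·L⁻¹ with the 24 g·mol⁻¹ biomass
convention. Replicates are averaged per light level *before* the argmax (SD
reported per level), and µ_max is the largest per-level mean together with
the light level where it occurs. Cuvette densities outside 0.1–0.4 g·L⁻¹
warn (in-culture shading biases µ low). The measured maximum is net of
respiration; no maintenance correction is added back. The high-light decline
caused by oxygen-bubble formation in oversaturated cuvettes is detected
implicitly (the argmax moves to the onset light level) but not corrected.

## Light field

The incident light is decomposed over the 400–700 nm PAR grid at 1 nm
(301 bins) with a normalized spectral shape, and attenuated per wavelength
by Lambert–Beer:

    I_λ(z) = I_λ(0) · exp(−a_x,λ · C_x · z),

with a_x,λ the dry-weight specific absorption cross-section (stored in
m²·g⁻¹, used molar via the factor 24) and z the depth from the illuminated
surface of a one-sided, flat horizontal panel. No scattering or ray tracing
is modelled. The local specific photon absorption rate is the spectral sum
φ(z) = Σ_λ a_x,λ·I_λ(z); for a grey (wavelength-flat) spectrum this
collapses to the scalar product a_x·I(z) exactly, which is what the
closed-form tests exploit.

The diel program is a half-sine between sunrise and sunset with the peak at
noon; the daily photon dose has the closed form (2/π)·peak·daylight_seconds.
Defaults (peak 1900 µmol·m⁻²·s⁻¹, 6:00–18:00) represent a cloud-free
low-latitude summer-solstice day and integrate to 52.3 mol·m⁻²·day⁻¹. A
`constant` flag reproduces the continuously illuminated laboratory
chemostats and is used by the steady-state verification tests.

Two built-in spectral shapes are provided: a flat-quantum shape and a smooth
daylight-like shape (5800 K blackbody photon flux truncated to PAR), the
latter being the simulation default. Measured solar spectra can be supplied
as CSV.

## Growth and reactor model

The local growth rate couples the Jassby–Platt saturation response with a
constant maintenance sink:

    µ(z) = µ_m · tanh( Y_mol · φ(z) / µ_m ) − µ_e,

with Y_mol = Y_x/ph^m/24 in mol_x·mol_ph⁻¹ and all rates per day. The
culture is ideally mixed, so the growth rate applied to the biomass balance
is the trapezoid depth-average of µ(z) over 100 uniform layers (doubling the
layer count changes the result by < 0.1% at the default optical depths).

The chemostat balance

    dC_x/dt = (µ(C_x, t) − D(t))·C_x,      dM_x/dt = D(t)·C_x,

is integrated with classical fixed-step 4th-order Runge–Kutta at dt = 60 s
over ten identical days. Dilution semantics: a stated daily rate D is the
total volume fraction exchanged per day, delivered uniformly during
daylight — instantaneous rate D·24/12 between 6:00 and 18:00, zero at night
(a `daylight_only=False` switch gives constant dilution). This reading
reproduces the expected harvest magnitude D·C_x·l per day; the alternative
(instantaneous rate D applied only during daylight) halves the harvest and
is not used.

Day-10 performance figures:

* areal productivity r_x,area = (ΔC_x + ΔM_x)·l over the final day
  (mol·m⁻²·day⁻¹; ×24 for g),
* observed yield on light Y_x/ph = r_x,area / daily photon dose,
* photosynthetic efficiency
  PE = 100·r_x,area[g]·H_x / (dose·E_ph/f_PAR), with combustion enthalpy
  H_x = 22.5 kJ·g⁻¹, mean PAR photon energy E_ph = 217.5 kJ·mol⁻¹ and PAR
  fraction of total solar energy f_PAR = 0.43. These three constants are
  package defaults chosen from standard literature values for green-algal
  biomass and the AM1.5 solar spectrum; they are config-exposed because any
  full-spectrum normalisation depends on the exact solar spectrum assumed.

A simulation is flagged pseudo-steady when the day-9 and day-10 biomass
curves agree pointwise within 0.5%. The dilution optimiser is a plain grid
search (default resolution 0.01 day⁻¹) over full simulations, warm-starting
each run from the previous grid point's final density; ties break toward
the lower rate.

### Numerical choices and degenerate inputs

* RK4 at dt = 60 s is far inside the stability/accuracy region for these
  dynamics (halving dt changes day-10 figures by < 0.05%); dt must divide
  one day evenly so that day boundaries fall on grid points.
* The integrator aborts with a diagnostic if the state becomes non-finite
  or non-positive (too-coarse steps or washout).
* Dark or zero-light inputs short-circuit to µ = −µ_e without evaluating
  the spectral field.
* Zero photon dose (all-dark scenarios) leaves yield-on-light and PE
  undefined (NaN) instead of dividing by zero.

## Synthetic data generators

The generators emulate the *structure* of the two laboratory campaigns, not
any particular instrument:

* **Chemostat campaigns.** For each dilution rate the generator solves the
  light-balance equation for the density C_x at which the absorbed photon
  flux per biomass equals the Pirt demand (D + µ_e)/Y — a bracketed Brent
  root solve at 1e-12 relative tolerance — and emits seven daily
  observations with independent multiplicative lognormal noise (mean-one,
  CV-parameterized) on biomass and outgoing irradiance. Lognormal noise is
  the natural choice for strictly positive measured quantities; the assay
  itself reports only averages ± SD, so the error model is a documented
  assumption. At zero noise the estimation pipeline recovers the generating
  parameters to machine precision, which is the package's central
  round-trip property. Dilution grids default to the per-strain experiment
  ladders; incident light 100 µmol·m⁻²·s⁻¹, optical depth 14 mm.
* **PI records.** Growth follows the same tanh response evaluated with the
  strain's PAR-mean cross-section; rates are converted to volumetric oxygen
  rates by inverting the stoichiometric relation at a cuvette density of
  0.24 g·L⁻¹. An optional artifact threshold makes rates decline linearly
  above it (default 0.05%/µmol), mimicking oxygen loss to bubbles in
  oversaturated cuvettes; with the threshold at 1500 µmol·m⁻²·s⁻¹ the
  recovered argmax reproduces that level. The default light ladder spans
  0–2000 µmol·m⁻²·s⁻¹ in 13 steps, a typical BOM program.
* **Absorption spectra.** A sum of Gaussian pigment bands (chlorophyll
  Soret 440 nm, carotenoid shoulder 480 nm, chlorophyll red 675 nm) over a
  flat baseline, rescaled so the PAR mean is exactly the requested value
  (default 0.2 m²·g⁻¹, a typical low-light-acclimated chlorophyte
  magnitude). An empty band list yields a grey spectrum, which makes the
  spectral machinery collapse to scalar closed forms for testing.

What the generators do **not** emulate: real measured absorption spectra
(band widths, the depth of the green window and packaging effects differ per
strain), instrument drift and autocorrelated noise, day-to-day biology
(acclimation, settling), and measured solar spectra or weather. Passing
round-trip tests therefore demonstrates the correctness and noise-robustness
of the estimators, not the field accuracy of any particular parameter value.

## Known limitations

* Simulated productivities of strains with low µ_max are sensitive to the
  spectral shape of the absorption cross-section: more spectral structure
  (deep green window) lets weakly absorbed wavelengths drive growth deep in
  the panel and raises productivity substantially. With the generic
  synthetic spectrum the fast strain's productivity matches published
  flat-panel figures closely while slower strains come out 15–25% lower
  than runs using measured spectra would give. Supplying measured spectra
  via CSV removes this gap.
* The model is light-only: no temperature, nutrient, pH or O₂-inhibition
  kinetics, no photoacclimation, no reactor orientation or diffuse/direct
  geometry.
* The PE normalisation constants are fixed approximations of a solar
  spectrum integral; absolute PE values carry that uncertainty.
* Problem sizes used by the shipped tests and the acceptance script: full
  10-day, 1-min, 100-layer simulations for the four headline scenarios;
  the dilution-optimisation tests use a coarse grid (0.2 day⁻¹) with
  shortened 4-day runs, which is sufficient for the unimodality and
  ranking properties they check.
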