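# isopulse

Analysis tools for **¹³CO₂ pulse-chase labeling experiments** in grassland
warming studies: chamber CO₂ flux computation, isotopic partitioning of soil
respiration, excess-¹³C pool accounting, mean-residence-time estimation, and
driver–lag analysis — together with a synthetic experiment generator so the
whole pipeline can be exercised, tested and calibrated without field data.

## Who this is for

Ecosystem ecologists tracing recently photosynthesized carbon through a
plant–soil system: a canopy is exposed for about an hour to ¹³CO₂-enriched
air (40–60 atom-% ¹³C), and the label is then chased for days through shoots,
roots, extractable organic carbon (EOC), microbial biomass (MB) and
soil-respired CO₂ (SR). The reference design is a geothermally warmed
subarctic grassland: 14 plots spanning 0–8.7 °C of soil warming above a
10.2 °C ambient, half of them fertilized with 50 kg N ha⁻¹ yr⁻¹.

## What it computes

**Isotope arithmetic** (`isopulse.isotope`) — δ¹³C (‰ vs VPDB, with
R_VPDB = 0.0111802) ↔ atom fraction x = ¹³C/(¹²C+¹³C); Keeling-plot source
signatures (OLS of δ on 1/[CO₂], intercept = source δ¹³C); the two-pool
geogenic mixing model

    f_geo = (δ_mix − δ_bio) / (δ_geo − δ_bio),   δ_geo = −4.7 ‰, δ_bio = −28 ‰

used to strip geothermal CO₂ out of measured SR; microbial-biomass isotope
mass balance from chloroform fumigation–extraction; two-point analyzer
calibration.

**Chamber fluxes** (`isopulse.fluxes`) — steady-state (flow-through):
SR = ΔCO₂ · flow / area; closed-chamber: F = (dC/dt) · (V/A) · n_air with
ideal-gas molar density at 101.325 kPa; GPP = ER − NEE (sink-negative NEE
convention); the ¹³C atom fraction of SR from isotopologue mass balance
x¹³_SR = Δ[¹³CO₂]/Δ[CO₂]; NDVI = (ρ₈₄₀ − ρ₆₆₀)/(ρ₈₄₀ + ρ₆₆₀).

**Tracer accounting** (`isopulse.tracer`) — excess ¹³C per pool,
(x_after − x_before) · C_pool, relative recovery as % of the shoot excess
immediately after labeling, and cumulative SR recovery by trapezoidal
integration of the excess-¹³C export rate.

**Decay kinetics** (`isopulse.kinetics`) — y = A·e^(−bt) fits (nonlinear
least squares, log-linear initialization, b > 0) with mean residence time
MRT = 1/b; SR fits drop the first 2.4 h measurement cycle, where physically
back-diffused tracer (a few % of the label, ~25 min turnover) contaminates
the signal.

**Lag analysis** (`isopulse.lags`) — standardized-coefficient scans of SR
responses against diel drivers (PAR, soil temperature, SWC) over stepwise
shifts (2.4 h steps within ±20 h; negative = driver leads), and one-way
permutation ANOVA (exhaustive enumeration when feasible, seeded Monte Carlo
otherwise) for treatment effects on per-plot lags.

**Synthetic experiment** (`isopulse.simulate`) — a first-order compartment
chain shoot → root → EOC → MB → SR with respiratory losses at each transfer,
solved exactly by matrix exponential (label conserved to machine precision),
warming/N treatment effects injected multiplicatively, diel driver forcing,
and chamber-level records generated by inverting the flux equations.

## Worked example

```bash
isopulse run-all --outdir demo --seed 42
```

simulates the 14-plot experiment (10-day chase, 2.4-h SR cycles) and runs
every analysis stage. From `demo/decay_fits.csv`, shoot decay fits (units:
days) on fertilized plots:

```
plot_id  warming_dt  n_addition       A     b   mrt
     F1         0.3          50 307.495 0.439 2.276
     F2         0.8          50 270.519 0.310 3.230
```

A is the fitted peak excess (mg ¹³C m⁻²; the simulated pulse is 300),
b the decay constant (d⁻¹) and MRT = 1/b the mean residence time: recently
fixed carbon leaves the shoots of these lightly warmed plots in ~2–3 days.
SR fits (units: hours) show the warming response — e.g. MRT 282 h at
ΔT = 0.3 °C against 171 h at ΔT = 5.1 °C — i.e. belowground turnover of the
label accelerates with warming. `demo/lag_best.csv` holds the driver lags:

```
plot_id  warming_dt  n_addition              response  best_lag_h  best_coefficient
     F1         0.3          50         sr_total_flux        -4.8             0.929
     F1         0.3          50 sr13_excess_rate_mg_h        -9.6             0.738
```

(negative = PAR leads soil respiration; lightly warmed fertilized plots lag
4.8 h in CO₂ and ~9.6 h in ¹³CO₂ excess, while strongly warmed plots run
nearly synchronized with PAR). `demo/permutation_tests.json` reports the
permutation ANOVA of those lags: at this seed, warming p = 0.019
(exhaustive, 3003 assignments) and N addition p = 0.020 (3432 assignments).
`demo/sr_recovery.csv` shows that ~40–50 % of the assimilated label is
respired from soil within the 10-day chase.

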