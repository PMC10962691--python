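# Methods

This note records the models, conventions and numerical choices behind
`isopulse`, what the synthetic experiment generator does and does not
emulate, and the known limitations.

## Isotope scales and conversions

All label arithmetic runs on the atom-fraction scale x = ¹³C/(¹²C+¹³C),
converting from the δ¹³C reporting scale with

    R = (δ/1000 + 1) · R_VPDB,    x = R/(1+R),    R_VPDB = 0.0111802.

The Chang & Li value of R_VPDB is the one in common IRMS use; alternatives
(e.g. 0.011180 vs 0.0112372) shift atom fractions by <0.6 % relatively and
cancel in excess (difference) quantities. δ ≤ −1000 ‰ is rejected (R ≤ 0).
The conversion pair is exact to round-off; the suite asserts a <1e-9 ‰
round trip over δ ∈ [−50, 5000].

## Two-pool geogenic mixing

The study site sits on a geothermal field that vents abiotic CO₂. Measured
SR signatures are partitioned linearly **in δ space** between the geogenic
(−4.7 ‰) and biogenic (−28 ‰) end-members; mixing on the atom-fraction
scale is available behind `space="atom_fraction"` and differs by <0.1 % of
the inferred fraction over this δ range. Fractions outside [0, 1]
(analytical noise past an end-member) are clipped and flagged, never
raised, and the raw value is preserved; the corrected biogenic flux is
therefore always within [0, SR_total].

## Keeling plots

Source δ¹³C is the intercept of OLS of δ on 1/[CO₂] (statsmodels OLS; the
intercept SE comes from the parameter covariance). Geometric-mean
regression is available (`method="gmr"`) but off by default: with CO₂ on
the x-axis measured far more precisely than δ, OLS is the appropriate
errors-in-variables compromise. Note one genuine approximation: when a
mixture is constructed exactly in isotopologue concentrations, δ is not
exactly linear in 1/[CO₂]; over a 400→1000 ppm accumulation this leaves a
few-thousandths-permil intercept offset, which is why tests of the
accumulation route use a 0.01 ‰ tolerance rather than machine precision.

## Chamber fluxes

* Steady state: SR = (mean CO₂_chamber − mean CO₂_buffer) · flow / area,
  with window means taken over the trailing 80 % of each 6/8-min cycle to
  skip the valve-switch transient (the settling treatment is a package
  choice; the fraction is configurable).
* Closed chamber: flux = OLS slope (ppm s⁻¹) · (V/A) · n_air, with
  n_air = P/RT at the measured air temperature and P fixed at 101.325 kPa
  (no barometric record is assumed; a ±2 kPa weather swing moves fluxes by
  ±2 %). QC is a deterministic r² ≥ 0.9 rule replacing manual visual
  screening; a flat ramp yields zero flux, undefined r², and a QC failure.
* GPP is reported as the positive uptake magnitude ER − NEE. With the
  sink-negative NEE convention a verbal "difference of NEE and ER" is
  sign-ambiguous; this orientation makes a dark deployment (NEE = ER) give
  exactly zero photosynthesis.
* The ¹³C atom fraction of SR is the isotopologue mass balance of what the
  chamber added over the buffer, x¹³ = Δ[¹³CO₂]/Δ[¹²CO₂+¹³CO₂]; it is
  undefined (raised) when the chamber added no CO₂.
* NDVI uses the standard Tucker form (ρ₈₄₀ − ρ₆₆₀)/(ρ₈₄₀ + ρ₆₆₀).

## Excess-¹³C accounting

Pool excess is (x_after − x_before) · C_pool with the day −1 natural
abundance sample as baseline; the quantity carries the C_pool mass basis
(reported in mg m⁻²). Relative recovery normalizes by the shoot excess
immediately after labeling, which is taken as the canopy's total label
uptake, making shoot day-0 recovery 100 % by construction. The SR route is
a flux, so its excess export rate converts µmol CO₂ m⁻² s⁻¹ to tracer mass
explicitly with M(¹³C) = 13.00335 g mol⁻¹, and cumulative recovery is a
trapezoidal integral at the native sampling resolution. At the field 2.4-h
cycle the trapezoid discretization error on a decaying pulse is of order
0.1 %, so exact (1e-6) conservation checks run on finely sampled noiseless
generator output, while 2.4-h integration is validated at the 1 % level.

Negative excess within 2 SD of the supplied baseline noise is clamped to
zero and flagged `clamped`; larger negatives are flagged `excluded` (NaN)
and logged, so batch runs continue.

## Decay kinetics and MRT

Single-exponential fits y = A·e^(−bt) use bounded Levenberg-Marquardt-style
least squares (scipy `curve_fit`, trf with b ≥ 0, tolerances 1e-12,
initialized from log-linear OLS over positive observations). A fit that
collapses onto the b → 0 boundary (no resolvable decay) is returned
unconverged with NaN MRT instead of raising. MRT = 1/b; the DecayFit
carries its time unit (shoots fitted in days, SR in hours) and fits are
per plot. SR fits exclude every point with t ≤ 2.4 h (closed boundary):
immediately after labeling, tracer that physically back-diffuses from soil
pore space (a few percent of the label with ~25-min turnover) masquerades
as fast respiratory decay, and the first measurement cycle contains
essentially all of it.

## Lag analysis

Series are averaged onto the 2.4-h measurement-cycle grid (within-bin
means; incomplete bins drop out pairwise). For each shift s on the grid
(±20 h span → multiples of 2.4 h in [−19.2, +19.2]), both series are
z-scored over their overlap and the response is regressed on the shifted
driver; the univariate standardized coefficient is the Pearson r, and the
best lag is the shift with the maximum signed coefficient (ties break
toward zero; an absolute-value mode and a joint multivariate mode — scanned
driver shifted, others held at lag 0 — are provided behind flags, the
univariate signed scan being the default because the per-driver coefficient
curves are the object of interest). Negative lags mean the driver leads.

Two practical points. First, any purely 24-h-periodic driver makes shifts
s and s ± 24 h exactly aliased on a ±20 h grid; identification rests on
day-to-day amplitude variability (weather), which the generator therefore
includes. Second, a decaying tracer pulse superimposes a slow trend that
can dominate the scan, so the pipeline removes a centered one-day moving
mean from both series before scanning (`detrend="diel"`). The same linear
filter is applied to both series, so an exact integer-bin shift between
them survives detrending exactly.

Treatment effects on per-plot lags use one-way permutation ANOVA. The
internal permutation statistic is the between-group sum of squares, a
monotone function of F under label permutation (total SS is invariant)
that remains defined for single-observation groups. When the number of
distinct assignments (the multinomial coefficient) is ≤ 10,000 the null is
enumerated exhaustively and p is the exact proportion of assignments with
statistic ≥ observed; otherwise p = (1 + exceedances)/(1 + n_perm) over
seeded Monte-Carlo draws (default n_perm = 9,999), so p ≥ 1/(n_perm+1).
For presentation and testing, plots group into low (≤1.5 °C) and high
(≥5.1 °C) warming.

## The synthetic experiment generator

Ground truth comes from a linear first-order compartment chain

    shoot → root → EOC → microbial biomass,

with a respiratory branch at every transfer: fraction f of each outflow
moves downstream, 1 − f is respired (aboveground for shoots; into SR for
root, EOC and microbial outflow). The six-state system (four pools plus
running integrals of cumulative SR and shoot respiration) is propagated
exactly with the matrix exponential; the generator matrix has zero column
sums, so pools + cumulative respiration equal the pulse to machine
precision at every instant — the anchor for all conservation tests.

Defaults represent the study conditions: the 14-plot warming × N design
(ΔT 0–8.7 °C, 0/50 kg N ha⁻¹ yr⁻¹, ambient soil 10.2 °C), a 300 mg ¹³C m⁻²
canopy pulse at 0.5 atom fraction, pool sampling at days 0/1/3/6/10 with a
day −1 baseline, SR cycles every 2.4 h for 10 days, a 0.5 µmol m⁻² s⁻¹
geogenic flux at −4.7 ‰, and 10 % relative observation noise on tracer
quantities. Rate constants (shoot 0.35, root 0.90, EOC 1.20, MB 0.30 d⁻¹;
transfer fractions 0.45/0.50/0.50) give shoot MRTs of ~3 days and SR ¹³C
decline resolvable within the 10-day chase, the shapes a pulse-chase in a
productive grassland produces. Treatment effects are multiplicative and
directional: warming scales every rate by 1.06 per °C (faster turnover,
shorter MRT) and shifts allocation from roots (−0.012 per °C) to microbes
(+0.012 per °C); N addition scales belowground rates by 0.88 (longer SR
MRT) and adds 0.05 to root allocation. Driver–SR lags shrink toward
synchrony with warming and the CO₂ lag lengthens by 2.4 h under N, so lag
and permutation machinery have realistic signal to find. All magnitudes
are configurable; only the directions are fixed by default.

Diel forcing: PAR is a truncated sinusoid (daylight 06–18 h) times a fixed
irregular day factor (±40 % synoptic modulation, anticorrelated between
consecutive days) — without day-to-day variability the ±24 h lag alias
would be strictly unidentifiable, and with weakly varying weather it is
barely identifiable under noise. Soil temperature is ambient + ΔT plus a
1.5 °C diel sinusoid lagging PAR by 2 h; SWC is flat at 40 vol-% (no diel
variation, never limiting). The SR CO₂ diel component is additive on the
warmed baseline; the SR ¹³C diel component is multiplicative on the
decaying envelope (export tracks substrate supply), which keeps its
signal-to-noise ratio constant through the chase. An optional
back-diffusion transient (default off; 4 % of the pulse, 25-min turnover)
feeds the first-cycle-exclusion tests.

Chamber-level records invert the flux equations exactly (flow-through
pairs: 4.5-cm chamber, 0.5 L min⁻¹, 6/8-min windows; closed ramps:
50×50×50 cm chamber, 5-s sampling, accumulation sampling at 1/3/5/15/30
min), so flux computation is tested as an inverse problem.

What the generator does **not** emulate: nonlinear or saturating kinetics,
seasonal phenology and NDVI dynamics, soil heat transport, water dynamics,
instrument drift, or autocorrelated measurement noise. Passing tests
demonstrate that the estimators invert the stated generative model at
realistic noise, not that the model captures every feature of field data.

## Problem sizes

Defaults keep any full run small: 14 plots × 100 SR cycles, 5 sampling
days, exhaustive permutation enumeration up to 10,000 assignments,
200-replicate noise studies, 500-replicate null-lag scans, 5,000-replicate
type-I calibration (vectorized over the 924 assignments of the 6+6
design), and 100-seed directional studies; the whole suite and the
acceptance script each complete in well under a minute of CPU apiece.
The 6+6 design for type-I calibration is the smallest two-group layout
whose exact-test discreteness (rejection set 46/924 ≈ 0.0498) sits at the
nominal 5 % level; smaller designs cannot express a 5 % rejection region.

## Known limitations

* Keeling δ-space linearity is approximate (see above) — irrelevant at
  field precision, visible at 1e-3 ‰.
* The lag grid is the measurement cycle (2.4 h); true lags between grid
  points resolve to a neighboring grid point, and under heavy noise a lag
  can occasionally flip to its ±24 h alias, exactly as in field scans of
  diel signals.
* Exponential fits to the SR ¹³C series are a deliberate
  mis-specification early in the chase (the envelope rises while upstream
  pools fill before it decays); fitted b is an effective decay rate, which
  is the quantity the MRT comparison needs, not the microscopic rate of
  any single pool.
* The excess of a pool uses the atom-fraction-difference mass basis (Δx · C_pool); the SR
  flux route converts moles to ¹³C mass explicitly. The generator inverts
  each formula when constructing observations, so accounting is internally
  consistent; comparing absolute excesses across conventions from outside
  data requires attention to that basis.
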