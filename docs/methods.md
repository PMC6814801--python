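# Methods

This note documents the models implemented in `streamco2`, the defaults
chosen where the published relationships leave parameters open, what the
synthetic-data generator does and does not emulate, and the numerical
conventions used throughout.

## Deterministic flux chain

Each stream segment is treated as an independent, well-mixed reach at
annual mean conditions. The chain is:

1. **Hydraulic geometry.** Width, depth and velocity are downstream
   power laws of annual mean discharge, fitted for steep mountain
   channels and valid up to Q = 2.26 m³ s⁻¹. Larger discharges raise a
   validity error unless extrapolation is explicitly requested (the
   retention filters exclude them anyway). Depth enters no downstream
   computation but is carried for the w·z·v ≈ Q consistency check: the
   three independent fits multiply to 1.414 Q^1.034, i.e. within a
   factor two of Q across the validity range.
2. **Energy dissipation and k600.** eD = g·v·S. The k600 relationship
   is a piecewise power law with a breakpoint at eD = 0.02 m² s⁻³. The
   published regimes are stated as strict inequalities on both sides;
   we assign equality to the low-energy branch (continuity of the
   low-energy regime) and note the branches disagree by ≈ 8.7% at the
   breakpoint (limits 6.134 vs 5.645 m d⁻¹). The eD ≤ 1.052 m² s⁻³
   calibration cap is enforced by the segment filters, not by the
   function, so the Monte Carlo can perturb velocity freely.
3. **Water temperature.** Tw = 3.941 + 0.818·Tair. The conversion can
   produce sub-zero water temperatures for Tair < −4.82 °C; because the
   Schmidt polynomial and the solubility fit are only valid for liquid
   water, Tw is clipped to [0, 30] °C by default and the number of
   clipped segments is logged. The clip is a modelling choice, not part
   of the published relationship, and can be disabled.
4. **Gas chemistry.** Barometric pressure follows the standard
   atmosphere (Tb = 292.15 K, λ = −0.0065 K m⁻¹) evaluated in Pa and
   converted to atm with the fixed factor 9.86923 × 10⁻⁶ — deliberately
   not 1/101325, to match the source arithmetic exactly (sea level then
   evaluates to 0.9999997 atm). Saturation uses an atmospheric CO2
   mixing ratio of 400.40 µatm (2017 annual mean); this is year-specific
   and lives with every other constant in one overridable
   `PhysicalConstants` object.
5. **Streamwater CO2.** The log-linear regression on ln E, ln Q and
   ln SOC with the published coefficients. The publication does not
   state the response unit; we fix µmol L⁻¹ because (a) the groundwater
   balance is formulated in µmol and (b) predictions at typical alpine
   covariates then convert to pCO2 in the few-hundred-µatm range, the
   magnitude reported for such streams. This inference is documented,
   not asserted as the source's intent.
6. **Fluxes.** ΔCO2 = (C − Csat) × 12.011 mg C m⁻³; areal flux
   F = kCO2·ΔCO2/1000 g C m⁻² d⁻¹; totals integrate over width × length
   and 365 days (the day count is configurable). Negative (invasion)
   fluxes are retained everywhere.

## Analysis population

Mountain terrain requires elevation ≥ 500 m a.s.l. plus relief roughness
(1000 × relief / half the cell length) above an elevation-banded
threshold. The cited terrain typology only brackets the thresholds at
20–40‰ without printing the schedule; our default is 40‰ below 1000 m,
30‰ for 1000–2500 m and 20‰ above 2500 m — stricter at low elevation,
where roughness must separate mountains from hills — and is fully
configurable. Further caps: Q ≤ 2.26 m³ s⁻¹ (hydraulic-geometry
validity), E ≤ 4938 m (upper training elevation of the CO2 regression,
applied to the segment mean elevation because that is the regression
covariate) and eD ≤ 1.052 m² s⁻³ (gas-exchange calibration range). The
exclusion report counts every violated criterion per segment.

Slopes computed from node elevations are floored at 10⁻⁴ m m⁻¹ rather
than dropped when DEM noise produces flat or inverted reaches; floored
segments are counted.

## Monte Carlo propagation

Each of the five fitted relationships is perturbed per segment per
iteration: ln-scale Gaussian noise for the multiplicative fits (width,
velocity, k600 applied after the piecewise law, CO2 concentration) and
additive °C noise for water temperature (clipped to [0, 30] °C). The
residual scales are not published; the defaults are

| channel | default | rationale |
|---|---|---|
| CO2 concentration | 0.605 (ln) | derived from R² = 0.39 (below) |
| k600 | 0.5 (ln) | widest channel: the gas-exchange model dominates the propagated uncertainty |
| width, velocity | 0.12 (ln) | tight at-site hydraulic fits |
| water temperature | 1.0 °C | scatter of an annual-mean air→water conversion |

All are `PerturbationSpec` fields and user-overridable. Coefficient
uncertainty of the regressions (the printed ± values) is deliberately
not resampled by default: the published procedure perturbs residual
distributions, not coefficients.

The CO2 residual default is derived in closed form rather than tuned:
with independent covariates log-uniform over the generator's default
ranges, each ln-covariate is uniform with variance (ln hi − ln lo)²/12,
the linear predictor variance follows from the coefficients, and
R² = 0.39 implies sd = √(var·(1−R²)/R²) ≈ 0.605.

Outlier handling follows the published rule: slope, CO2 concentration
and areal flux are each pooled across **all segments and iterations**,
and draws strictly above the pooled 99.5th percentile (linear
interpolation between order statistics, the common convention in
scientific software) of any variable are dropped — not replaced — from
all downstream statistics. Slope does not vary across iterations, so a
slope outlier removes its segment entirely, matching the intent of
discarding implausibly steep reaches. Trimming is applied after the
k600 → kCO2 conversion. With continuous draws the strictly-above rule
removes ≈ 0.5% per variable; with all values tied it removes nothing.

Totals are reported under two bracketing error models:

- **independent** — retained draws are summed over segments within each
  iteration, and the mean and 5th/95th percentiles are taken over the
  10,000 iteration totals; per-segment errors average out and the
  interval is narrow (width ∝ √n for i.i.d. segments);
- **dependent** — mean and percentiles are computed per segment from its
  own draws and then summed separately, so the interval width is the sum
  of per-segment widths (∝ n).

For 100 i.i.d. Normal(1, 0.2) segment fluxes the two interval widths are
6.58 and 65.8 — the √n ratio — which the test suite verifies against the
closed form. Both schemes estimate the same expectation.

Reproducibility: one master seed spawns a `SeedSequence` child per
segment and a grandchild per noise channel, so ensembles are bitwise
reproducible and invariant to segment evaluation order or subsetting.

## Groundwater CO2 mass balance

Assuming each downstream discharge increment Q_GW = Q_down − Q_up is
groundwater, the balance over the receiving reach's control volume gives
C_GW = (f + (CQ)_down − (CQ)_up)/Q_GW with C in µmol m⁻³ and f the
evasion flux (µmol s⁻¹) **of the receiving reach** — the printed
formula's subscript on f is ambiguous, and only this reading closes the
control-volume balance, which the forward-simulate-then-invert test
confirms to machine precision. At confluences the upstream discharge and
CO2 load are summed over tributaries. Reaches with Q_GW ≤ 0 are labelled
losing/degenerate and excluded from summaries (mirroring the published
analysis, which could solve the balance only on an eligible subset of
streams); the eligibility counts are reported per run. Internally all
concentrations are µmol m⁻³; conversion to µmol L⁻¹ and to pCO2 (C/K_H)
happens only at the reporting boundary, with the conversion temperature
exposed as a parameter.

## Synthetic data

`generate_network` grows a branching tree: headwater tips (lognormal
discharge, median 0.05 m³ s⁻¹, σ_ln = 0.8) merge pairwise level by level
with probability 0.7; unmerged tips extend downstream by a chain
segment; every non-headwater segment receives a 5% groundwater discharge
increment so networks are gaining throughout, and the water balance
(outlet Q = Σ increments) is exact by construction. Reach lengths are
uniform on 200–2000 m (sub-kilometre reaches typical of fine-resolution
network datasets); slopes are lognormal around 0.08 m m⁻¹ (σ_ln = 0.5,
spanning the 0.03–0.16 range of steep alpine study reaches, with eD then
almost always below the 1.052 m² s⁻³ cap); node elevations are built
upward from the outlet using slope × length drops, so elevations
strictly decrease downstream. SOC decreases linearly with elevation
(120 g kg⁻¹ at sea level, −0.02 g kg⁻¹ m⁻¹, floor 1 g kg⁻¹), air
temperature follows a −6.5 °C km⁻¹ lapse from 9.5 °C at sea level, and
relief roughness is lognormal around 80‰. Strahler orders are assigned
by the standard merge rule.

What the generator does **not** emulate: real channel sinuosity and
planform, spatial autocorrelation of covariates along the network,
seasonal and diel variability (everything is an annual mean), DEM error
structure, and the empirical joint distribution of slope and discharge
in real hydrography. Passing tests therefore demonstrate the
correctness and stability of the estimation chain under the assumed
statistical structure, not the accuracy of any regional flux estimate
for real networks.

`generate_calibration_set` draws covariates log-uniformly (elevation
500–4938 m, discharge 0.001–2.26 m³ s⁻¹, SOC 10–200 g kg⁻¹) and builds
the response from a known coefficient vector plus lognormal residuals,
supporting noiseless (exact recovery) and noisy (CI-coverage,
R²-calibration) refitting tests.

`simulate_groundwater_forward` walks the tree from the headwaters,
mixes groundwater at a known concentration into each reach (headwater
source water counts as groundwater), and removes CO2 via the evasion
law in a well-mixed steady reach: Q·c_out = Q·c_mix − kA(c_out − c_sat)
with kA = kCO2 · area / 86400, solved in closed form per reach. Carbon
mass then balances to machine precision, which is what makes the
mass-balance inversion testable exactly.

## Problem sizes and numerical conventions

Default test networks use 8–64 headwaters (≈ 20–150 segments) and the
standard 10,000 Monte Carlo iterations; statistical tests
(coefficient-recovery coverage over 200 replicate fits of n = 323,
closed-form interval checks at 100 × 10,000 draws) were sized so the
whole suite runs in a few seconds on one CPU. Percentiles everywhere use
linear interpolation between order statistics. Ties at the trim
threshold are kept (strictly-above removal). Degenerate inputs: empty
segment tables filter to empty with an empty report; an all-losing
network yields an empty groundwater summary; zero residual scales
collapse the ensemble onto the deterministic chain exactly.

## Known limitations

- The regression's response-unit inference (µmol L⁻¹) and the default
  roughness schedule are documented stand-ins for unpublished details.
- The two uncertainty schemes bracket, but do not estimate, the real
  spatial error correlation; no intermediate-correlation scheme is
  provided.
- No carbonate-system chemistry: alkalinity as a CO2 sink, calcite
  saturation and pH-based speciation are out of scope.
- The hydraulic geometry and k600 scaling are used strictly inside
  their calibration envelopes; the pipeline refuses (rather than
  extrapolates) beyond them unless explicitly overridden.
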