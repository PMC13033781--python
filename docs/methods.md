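# Methods

## The measurement problem

A sealed 100 mL vial holds 30 mL of nitrogen-free mineral medium (BG11₀)
and a headspace prepared volumetrically at 1 atm, spiked with 0.1 mL of
10% (v/v) doubly labeled ⁴⁶N₂O — 100 ppm on the nominal 100 mL gas basis.
Triplicate vials are incubated at 25 °C under a 12 h light:dark cycle and
sampled every few days for headspace ⁴⁶N₂O (GC-ECD), ³⁰N₂ (GC-MS), O₂, and
ethylene (GC-FID, acetylene assays); at the end the biomass is harvested
for dry mass, total nitrogen, and ¹⁵N atom% (IR-MS). The analysis must
turn these readings into biomass-specific uptake rates and a nitrogen
budget for the added tracer.

## Pool accounting

All vial arithmetic is ideal-gas: n = xPV/(RT) with the actual headspace
volume (70 mL). Mixing ratios quoted in ppm use the nominal introduced-gas
volume (100 mL): both conventions are carried by `VialConfig`, because the
0.1 mL spike reads "100 ppm" on the nominal basis (0.01/100.1 = 99.9 ppm,
rounding to 100) even though the equilibrated headspace is smaller.

Nitrogen masses use the **nominal-mass convention**: 14 g/mol per N atom
for every isotopologue, so 1 μmol of ³⁰N₂ and 1 μmol of ⁴⁶N₂O are both
28 μg-N. This matches how tracer studies report μg-N rates and keeps run
comparisons unit-consistent; the ≤7% mass error of treating ¹⁵N as 14 u is
irrelevant to ratios and is never mixed with gravimetric data.

Dissolved N₂O is included in every pool via instantaneous Henry's-law
equilibrium (the vials are shaken at 80 rpm): n_diss = pK₀V_liq with the
freshwater (salinity 0) solubility fit

    ln K₀ = a₁ + a₂(100/T) + a₃ ln(T/100),   K₀ in mol L⁻¹ atm⁻¹,

a₁ = −62.7062, a₂ = 97.3066, a₃ = 24.1406, valid 0–40 °C
(K₀(298.15 K) = 0.0248). Only N₂O is partitioned; N₂ and O₂ dissolution
are negligible at these signal sizes and are off by default.

## Isotope bookkeeping

Biomass enters as an `IsotopePool` (total N in μg, ¹⁵N atom fraction).
Natural abundance is b = 0.00366. Two excess measures are provided:

* `excess_15N_mass` = N·(a − b), the conventional atom%-excess mass;
* `tracer_derived_mass` = N·(a − b)/(1 − b), the two-end-member mixing
  inverse that counts *all* nitrogen atoms contributed by a pure-¹⁵N
  tracer, including those statistically sitting at the baseline share.

The budget uses the second form. The difference (a factor 1 − b ≈ 0.996)
is far below measurement error, but only the mixing inverse makes the
conservation identity exact: a sink-free, bias-free simulation closes its
budget at exactly 100%, which is the invariant the accountancy is tested
against. Negative excesses from biased readings are retained, never
clipped — they are what produces >100% closures.

Fixation flux drawn from the N₂ pool splits between isotopologues in
proportion to their partial pressures (no isotope discrimination).
Nitrogen fixed from the ambient ²⁸N₂ pool is booked at natural abundance —
the pool stands for ambient N₂, whose minor isotopologues (²⁹N₂) are not
tracked individually. ⁴⁴N₂O is carried as a species but is chemically
inert in the simulator; only the labeled tracer's kinetics are modeled.

## The forward model

State: two-phase ⁴⁶N₂O, headspace ³⁰N₂/²⁸N₂/O₂/C₂H₂/C₂H₄ (μmol), dry
biomass B (g), biomass ¹⁴N/¹⁵N (μg), and a cumulative unmeasured ¹⁵N sink.

    d[46N2O]/dt = −v_red·B/28
    d[30N2]/dt  = (1 − f_sink)·v_red·B/28 − f₃₀·v_fix·B/28
    d[28N2]/dt  = −(1 − f₃₀)·v_fix·B/28
    dB/dt       = μ·d_light·B,   dO2/dt = Y_O2·dB/dt

with v in μg-N g⁻¹ d⁻¹ and f₃₀ the ³⁰N₂ share of the N₂ pool. Rate laws:

* `empirical_first_order` (packaged default): v_red = k_red·p₄₆ with an
  effective constant per run. The paper-style linear fits are exactly the
  estimator for this law in the small-depletion regime.
* `competitive_MM` (exploratory): v_red = Vmax_red·p₄₆/(K_N₂O(1+p₂₈/Km)+p₄₆)
  and v_fix = Vmax_fix·p_N₂/(Km(1+p₄₆/K_N₂O)+p_N₂), Km = 0.04 atm. The
  nitrogenase half-saturation for N₂O, K_N₂O, has never been measured for
  this system and stays a free parameter (default 0.04 atm). This mode is
  *not* used for the packaged runs: with Km = 0.04 atm and a trace
  (10⁻⁴ atm) N₂O spike, pure competitive MM predicts ~96% suppression of
  v_red under 0.95 atm N₂, inconsistent with the observed ~62% slowdown,
  and no data exist to fit the MM parameters. The packaged runs therefore
  use honest effective first-order constants per run.

With acetylene present, ethylene is produced at
v = Vmax_ara·p_C₂H₂/(Ks + p_C₂H₂), Ks = 0.005 atm, and both N₂ fixation
and N₂O reduction are suppressed (acetylene occupies nitrogenase). The
ethylene Vmax is its own parameter — it is a different reaction from N₂O
reduction and shares no rate constant with it.

Optional O₂ inhibition multiplies v_red by 1/(1 + p_O₂/K_O₂); the O₂
series uses K_O₂ = 0.81 atm, the value implied by uptake at 10% O₂ being
89% of the anoxic rate. Light/dark is a duty-cycle multiplier on growth by
default (daily sampling cannot resolve diel structure); a square-wave
switching mode exists.

Integration: fixed-step classical RK4, step ≤ 0.01 day. RK4 propagates
linear functionals of the state exactly, so total ¹⁵N and ¹⁴N are
conserved to floating-point rounding; the test suite enforces 10⁻⁶
relative. All pools stay nonnegative in the smooth rate laws used.

## Measurement layer

`measure()` emits the configured number of replicate vials, adds
independent Gaussian noise per instrument channel (relative sd for GC and
balance channels — defaults 2–5%; additive sd 2×10⁻⁴ for the IR-MS atom
fraction), applies the scenario's additive bias to the biomass
atom-fraction channel, and drops the unmeasurable sink channel. Output is
deterministic given the scenario seed.

## Packaged scenarios and calibration

The packaged scenarios state the experimental world: 100/30 mL vial,
25 °C, 1 atm, 100 ppm spike, triplicates, daily sampling to day 17 (day 12
for the 12-day assays). Inocula follow the protocol: 1 mL of washed
suspension at OD₇₃₀ = 0.47 for runs A–C and 0.2 mL at OD₇₃₀ = 0.1 for the
assay scenarios, converted at 0.30 g dry weight L⁻¹ OD⁻¹ (a standard
cyanobacterial OD–dry-mass factor). Biomass nitrogen content is 0.10 g-N
per g dry mass; growth is slow (0.05 d⁻¹ nominal under the 0.5 light duty)
and — deliberately — equal between runs A and B: dry-mass growth is not
reported per run, and unequal growth would decouple the cumulative
retardation from the fitted-rate slowdown. O₂ yield is stoichiometric
photosynthesis (~1 mol O₂ per mol C, 4.17×10⁴ μmol O₂ per g biomass).

Four constants are calibrated at construction time, by deterministic 1-D
root finds through the very pipeline a user would run:

* Vmax_ara so the assay pipeline returns 2.46×10⁴ μg-N g⁻¹ d⁻¹
  (the nitrogenase Vmax on the N₂ basis follows via the 3:1 conversion);
* k_red for Run B → 1.27×10² and Run A → 4.87×10¹ μg-N g⁻¹ d⁻¹;
* Run B's sink fraction is 0.26, which fixes its closure at 74% by
  conservation alone; Run A's biomass-channel bias is computed so its
  closure is 127% (the minimal representation of the over-closure the
  N₂-based run shows, attributed to inaccurate dissolved-N measurements).

Everything else is emergent. In particular the day-17 cumulative
retardation of Run A vs Run B comes out at ≈61.6%, consistent with the
observed "60% by day 17" within its ±2-point tolerance, and the fitted-rate
slowdown is 61.7% (≈62%).

## What the generator does and does not emulate

It reproduces: trace-gas pool sizes (≈10 μg-N of N₂O-N per vial), two-phase
partitioning, the two-step transfer with an unmeasured sink, replicate
structure, instrument noise magnitudes, and seeded determinism. It does
not reproduce: absolute figure-level trajectories (the raw data are not
deposited), heterocyst/diel physiology, hydrogenase H₂ cycling, ATP
dynamics, or vial leakage. One known divergence: with the printed
Km_N₂ = 0.04 atm the ³⁰N₂ partial pressure reached in the He-based run
(~10⁻⁵ atm) supports re-fixation of only ~1% of the emitted ³⁰N₂, whereas
the study's budget figure shows roughly half of the consumed N₂O in
biomass; budget *closure* is invariant to this split, but per-term budget
bars should not be expected to match. A green round-trip test therefore
establishes that the pipeline inverts the stated generator — not that the
generator is a validated mechanistic model of the organism.

## Analysis conventions

* Rates are OLS slopes on **replicate means** per time point (matching the
  triplicate design and single reported rate per run), over days 0–17 by
  default, of the two-phase N₂O amount in μg-N; specific rate =
  |slope|/biomass with the window-mean dry biomass as the default
  normalizer (an average-catalyst convention; any explicit biomass can be
  passed instead).
* The acetylene conversion is keyed on **ethylene**: μmol N₂ = μmol
  C₂H₄ / 3, reported as μg-N (×28). Under complete reduction the
  acetylene- and ethylene-based phrasings of the 3:1 ratio coincide.
* Budget: consumed = two-phase N₂O drop between first and last sampled
  day; emitted = headspace ³⁰N₂ gain; fixed = tracer-derived biomass N
  from the end-point pool. No net consumption (blank runs) is flagged and
  closure left undefined rather than reported as a division artifact.
* ANOVA/Tukey: scipy's F test and studentized-range HSD; the compact
  letter display is a maximal-clique cover of the non-significant-pairs
  graph, with cliques ordered by group mean (alphabetical tie-break), so
  letters are deterministic. Fully degenerate input (all observations
  identical) returns p = 1 and one shared letter by contract.

## Numerical choices and degenerate inputs

Simplex states tolerate 10⁻⁹ in the sum of fractions. Fits require ≥2
points in the window and positive biomass. `isotopologue_split` raises on
an empty N₂ pool instead of guessing. Root finds use Brent's method on
brackets wide enough for any physiological rate (10⁴–10⁸ μg-N g⁻¹ d⁻¹
atm⁻¹); calibration is cached per process. Integration halts with a
diagnostic if the state leaves the finite range.

## Limitations

Effective first-order constants are per-run summaries, not transferable
kinetic parameters; the N₂O half-saturation remains unknown; pressure
changes from repeated sampling are ignored (no corrections were applied in
the underlying protocol); and the ¹⁵N budget treats IR-MS calibration as
upstream and perfect except for the single additive bias term.
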