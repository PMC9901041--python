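# Methods

## Energy currencies and conversions

All energy flows are tracked in grams of chemical oxygen demand (gCOD), the
mass of O₂ required to fully oxidize the organic matter. COD measures
electron equivalents, so the same number is meaningful for host absorption in
the small intestine and microbial fermentation in the colon, and conservation
can be checked as a strict balance. Conversions between kcal and gCOD use
theoretical oxygen demands per gram: 1.185 for carbohydrate of any kind
(C₆H₁₀O₅ monomer basis — applied equally to sugars, starch, resistant starch,
and fiber), 1.50 for mixed dietary protein, and 2.90 for triglyceride fat.
In the kilocalorie ledger the menu-software convention applies: fiber
contributes 0 kcal, resistant starch full carbohydrate kcal (4 kcal/g;
protein 4, fat 9). For a mixed ~2100 kcal/day diet these factors imply
~3.1 kcal/gCOD; 3.06 kcal/gCOD is the default scalar when no composition is
supplied, and the composition-weighted factor (kcal_total / total COD) is
used whenever a composition is available, which makes the kcal↔COD round
trip exact.

A day's intake is partitioned into five substrate classes (gCOD/day):
available sugar and starch (total carbohydrate − resistant starch − fiber),
resistant starch, non-starch polysaccharides (fiber), protein, and fat.

Methane energy uses the combustion enthalpy 212.8 kcal/mol with an ideal-gas
molar volume of 24,450 ml/mol (25 °C, 1 atm); 1 mol CH₄ ≡ 64 gCOD for
cross-checks between the gas-volume and COD ledgers.

## Marker normalization

Fecal measurements come from pooled multi-day composites, so a missed stool
would bias every derived daily rate. Because PEG 3350 (1.5 g/day, one 0.5-g
capsule per meal) is neither absorbed nor degraded, expected excretion equals
the administered dose, and recovery = (PEG in composite / window days) /
daily dose estimates the captured fraction of output. Every composite-derived
daily rate (COD, wet weight, SCFA, 16S copies) is divided by this recovery.
No washout/lag correction is applied across the 6-day window (steady-state
premise). Recoveries outside [0.5, 1.5] are logged as suspicious but
retained — the band is a logging policy, not a filter; a composite with zero
marker raises an explicit unusable-marker error rather than being dropped
silently.

## Biomass from 16S quantification

Plasmid standards: copies/µL = (ng/µL) · N_A / (length_bp · 10⁹ · 660).
Community biomass: copies/g × marker-normalized g feces/day → copies/day,
divided by 4 rRNA operons per genome (gut-community average), times
2.8×10⁻¹³ g dry mass per cell, times 1.42 gCOD per g dry weight (C₅H₇O₂N
biomass stoichiometry). All three conversion parameters are exposed; with the
defaults, a typical high-fiber-arm copy load of 2×10¹⁴ copies/day corresponds
to ~20 gCOD/day of biomass. This qPCR route is deliberately independent of
the gut model's biomass prediction so the two can be compared.

## The three-compartment gut model

Compartments: upper GI, colon, body.

1. **Upper GI.** Fixed absorbed fractions `d_ass`, `d_prot`, `d_fat` of
   available sugar/starch, protein, and fat; resistant starch and fiber pass
   to the colon intact.
2. **Colon.** Idealized as a single steady-state continuously stirred tank
   reactor (CSTR) whose residence time τ is the colonic transit time. A
   substrate with first-order rate constant `k` is fermented to extent
   `k·τ/(1+k·τ)`. This closed form was chosen over a transit discretization
   for analytic testability; a plug-flow variant (`1 − e^{−k·τ}`) is exposed
   as an option and both collapse to `k·τ` when `k·τ ≪ 1`. Residual available
   sugar/starch ferments at `k_rs` (rapidly fermentable, like resistant
   starch). An endogenous input `e0` (mucins, sloughed epithelium) enters the
   colon, ferments at `k_nsp` (polymer-like), and appears in feces but never
   in dietary intake — this is required for fecal COD to be able to exceed
   the dietary colonic influent on a highly digestible diet, mirroring how ME
   is measured. Fermented COD splits into biomass (`y_biomass`), methane
   (`f_ch4`), and SCFA (the remainder); the host absorbs `a_scfa` of SCFA
   COD, allocated over acetate/propionate/n-butyrate/iso-butyrate by a fixed
   0.60/0.20/0.15/0.05 split.
3. **Body.** ME (%) mirrors the measurement definition:
   `100·(intake − fecal)/intake`, with endogenous material in feces but not
   intake. The balance `intake + e0 = upper absorbed + SCFA absorbed + fecal
   + methane` holds to 10⁻⁹ relative in every evaluation and is enforced by
   tests.

### Parameters

| parameter | meaning | units | default (calibrated) |
|---|---|---|---|
| d_ass, d_prot, d_fat | upper-GI absorbed fractions | – | 0.900, 0.980, 0.942 |
| k_rs, k_nsp, k_prot, k_fat | colonic fermentation rates | 1/h | 0.064, 0.144, 0.023, 0.015 |
| y_biomass | biomass yield on fermented COD | – | 0.199 |
| f_ch4 | methane fraction of fermented COD | – | 0.01 (fixed) |
| a_scfa | host-absorbed fraction of SCFA COD | – | 0.95 (fixed) |
| e0 | endogenous colonic input | gCOD/day | 5.0 |

### Calibration

The reference outputs the model must reproduce are the per-diet modeled ME at
a fixed 48-h transit (95.2 % / 92.4 % for the Western and microbiome-fed mean
diets), and the per-diet host SCFA uptake (36.4 / 72.3 gCOD/day) and fecal
biomass (9.4 / 19.6 gCOD/day) at the measured mean transit times (39.2 h /
29.7 h). `calibrate` minimizes the sum of squared relative errors over these
six targets with bounded trust-region least squares from the documented
pre-calibration defaults; the run is deterministic and reaches an objective
of 5.9×10⁻⁴ — its structural floor, because the model forces a
diet-independent biomass/SCFA-uptake ratio `y/(a(1−y−f))` while the six
reference values imply slightly different ratios per diet (0.258 vs 0.271).
All six are nonetheless matched within ±0.14 ME points, ±0.9 gCOD/day SCFA,
and ±0.25 gCOD/day biomass.

Two parameters are held at literature values rather than fitted: `f_ch4` =
0.01 (methane is a directly measured, minor sink — freeing it drives it to
implausibly high values that would imply mean methane volumes above anything
observed) and `a_scfa` = 0.95 (the standard colonic SCFA absorption
efficiency — freeing it drives it to ~1, leaving feces nearly SCFA-free,
contradicting the measurable fecal SCFA concentrations such studies report).

A consequence of the CSTR kinetics worth noting: SCFA absorption, and hence
ME, is monotone increasing in transit time, so the modeled ME at a measured
transit shorter than 48 h is always below the fixed-48-h value.

## Synthetic cohort

The generator emulates a 17-participant randomized crossover: each
participant receives both diet templates (Western: 2126 kcal/day, 48/35/16 %
kcal from CHO/fat/protein, 6.4 g fiber and 1.2 g resistant starch per 1000
kcal; microbiome-fed: 2113.6 kcal/day, 49/34/17 %, 26.0 and 10.3 g/1000
kcal). Per participant-arm draws:

- energy intake ~ Normal(template, 150 kcal/day) — the between-participant
  spread is a stated assumption, not a reported quantity; day-to-day intake
  jitter (1.5 % CV) is renormalized so the participant mean is exact;
- energy expenditure = intake − balance, balance ~ Normal(5, 20) truncated
  to ±50 kcal/day (the study's energy-balance clamp);
- colonic transit ~ lognormal with arithmetic means 39.2 h (WD) / 29.7 h
  (MBD) and SDs of 6.2·√17 and 4.4·√17 (SEM→SD for n = 17), truncated below
  at 5 h (physiological floor);
- one lognormal mean-one multiplier per participant on all four fermentation
  rate constants, shared across arms — the single-knob representation of
  between-host microbiome efficiency. Its σ = 0.9 was set so the generated
  between-participant SD of MBD metabolizable energy is ≈3 percentage points,
  the measured spread (0.73 SEM × √17). The generated n=17 min–max ME range
  on the MBD comes out ≈9–10 points rather than the measured ≈12 because the
  model's ME saturates at high transit/efficiency, truncating the upper tail;
- PEG recovery ~ Normal(0.95, 0.08) truncated to [0.6, 1.3]; fecal COD
  concentration ~ Normal(0.30, 0.04) gCOD/g truncated to [0.15, 0.50].

True fluxes come from `gut_model.predict`; observables are the truths
re-expressed as assay readouts — composite totals scaled by collected days ×
recovery, concentrations per gram of feces — with multiplicative Gaussian
noise (CVs: COD 3 %, weight 2 %, PEG 2 %, SCFA 5 %, qPCR 10 %, methane 5 %).
With noise off, the pipeline recovers every per-participant truth to <10⁻⁶
relative; with default noise the pipeline's mean ME bias over 200 replicate
cohorts is below 0.2 percentage points (verified in tests).

What the generator does **not** emulate: taxa and sequencing readouts,
hormone/appetite series, within-window temporal structure of stools, diet
non-adherence, and any correlation between transit time and the efficiency
latent. Passing tests therefore validate the arithmetic and the estimator
chain, not the biology of any particular real cohort. A further known gap:
because truths come from the calibrated model and modeled ME at measured
transit cannot exceed the fixed-48-h value (monotonicity above), the
generated Western-arm cohort mean ME (~94.1–94.8 %) sits ~1 point below the
measured 95.4 % — the same direction of model-vs-measurement gap the
reference comparison itself shows.

## Statistics

- Paired crossover contrast: MBD − WD per participant, paired t-test with
  n−1 df. The reference analysis used a mixed model with diet, period, and
  sequence effects; in a balanced complete crossover the estimand is the
  same, and the report labels the substitution. Participants lacking either
  arm are excluded and logged.
- Bland–Altman: bias = mean(model − measured), limits of agreement = bias ±
  1.96·SD (sample SD, ddof = 1); proportional bias = OLS slope of difference
  on pairwise mean.
- Lin's CCC with population (1/n) moments — documented because n is small
  and the (n−1) variant differs visibly at n = 17.
- Net trapezoidal iAUC: baseline = mean of pre-meal (t < 0) samples;
  integral over post-meal samples of value − baseline, negative increments
  retained (the positive-only variant is not implemented; net iAUC is the
  stated choice).

## Numerical choices and degenerate inputs

- Zero fermentation rates, zero influent, zero noise, and single-point CTT
  grids are all well-defined; zero marker, non-positive recovery, negative
  masses, and infeasible partitions (`y + f_ch4 > 1`) raise typed errors.
- Tolerances: COD conservation 10⁻⁹ relative; kcal↔COD round trip 10⁻⁹;
  plasmid copy formula vs mole arithmetic 10⁻¹²; truncated draws use
  rejection sampling with a hard iteration cap.
- Problem sizes used by the shipped checks: cohorts of n = 17 (plus one
  n = 1000 noise-free mean check and 200 replicate n = 17 cohorts for the
  bias property), chosen to match the reference design while keeping the
  full suite under a minute of model time.
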