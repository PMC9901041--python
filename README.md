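# gutharvest

Quantitative bioenergetics of host–gut microbiome energy harvest in
controlled-feeding crossover studies.

When two diets deliver the same kilocalories and macronutrients but differ in
how much substrate (fiber, resistant starch) reaches the colon, the colonic
microbiome decides how much of the diet's energy the host actually keeps.
`gutharvest` implements the full analysis chain for such a study, for
researchers in nutrition, microbiome science, and environmental
biotechnology-style bioenergetics:

- **Electron-equivalent (COD) accounting** — diet and feces expressed in grams
  of chemical oxygen demand (gO₂ ≡ gCOD), the shared currency of host and
  microbial energy. Host metabolizable energy is
  `ME (%) = 100 · (intake_COD − fecal_COD) / intake_COD`.
- **PEG marker normalization** — multi-day composite fecal collections are
  converted to unbiased 24-h outputs via the recovery of a non-absorbable
  PEG 3350 marker dosed at 1.5 g/day.
- **16S biomass quantification** — plasmid-standard qPCR copy numbers →
  copies/day → microbial biomass in gCOD/day (C₅H₇O₂N stoichiometry).
- **A three-compartment gut model** — upper-GI digestion, colonic fermentation
  as a steady-state CSTR with residence time equal to the colonic transit time
  (substrate *i* fermented to extent `k_i·τ / (1 + k_i·τ)`), fermented COD
  partitioned into biomass (yield `y`), methane, and SCFA, of which the host
  absorbs a fraction `a`. COD is conserved exactly:
  `intake + endogenous = upper-GI absorbed + SCFA absorbed + fecal + methane`.
- **A synthetic crossover cohort generator** with sealed ground truth, so the
  whole pipeline and the model-validation loop are testable end to end.
- **Crossover and agreement statistics** — paired within-participant
  contrasts, Bland–Altman limits of agreement with proportional-bias slope,
  Lin's concordance correlation coefficient, R², and trapezoidal net iAUC.

## Worked example

Run the shipped calibrated model on the Western-diet mean day (2126 kcal/day;
48/35/16 % of kcal from carbohydrate/fat/protein; 6.4 g fiber and 1.2 g
resistant starch per 1000 kcal) at a fixed 48-h colonic transit time:

```python
from gutharvest.energy_accounting import WD_MEAN_DIET, partition_substrates
from gutharvest.gut_model import GutModelInput, CALIBRATED_PARAMS, predict

out = predict(GutModelInput(partition_substrates(WD_MEAN_DIET), ctt_h=48.0),
              CALIBRATED_PARAMS)
print(round(out.intake_cod, 1), round(out.me_pct, 1),
      round(out.scfa_absorbed_total, 1), round(out.biomass_fecal, 1))
# 685.8 95.3 37.9 10.0
```

The 2126 kcal day carries 685.8 gCOD of electron equivalents; the model
predicts the host keeps 95.3 % of them, absorbing 37.9 gCOD/day as
microbially produced SCFA while 10.0 gCOD/day leave as microbial biomass in
feces.

A complete synthetic study, analyzed from its CSV tables:

```sh
gutharvest generate --n 17 --seed 42 --out data/
gutharvest analyze --data data/ --out report/
```

prints (abridged):

```
           metric  wd_mean  wd_sem  mbd_mean  mbd_sem  diff_mbd_minus_wd  p_paired_t
        fecal_cod    41.19   2.812     77.65    4.356              36.46   1.311e-08
           me_pct    94.08  0.4017     89.54   0.5417             -4.539   1.187e-08
    nonmetab_kcal    127.7   8.719     222.3    12.47              94.62   5.538e-08

    ctt_mode  n  bias  proportional_slope    ccc     r2
   fixed_48h 34 1.989              -0.711 0.4608 0.5851
measured_ctt 34 1.015             -0.2904 0.6619 0.5377
```

The microbiome-fed arm (MBD) loses ~36 gCOD/day more energy to feces —
about 95 kcal/day of non-metabolizable energy — and feeding each
participant's measured transit time to the model roughly halves the bias and
raises concordance versus a one-size-fits-all 48-h transit.

Other CLI subcommands: `gutharvest model` (run the gut model over a cohort's
intake/CTT tables) and `gutharvest calibrate` (re-fit the shipped parameter
set from the documented reference outputs).

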