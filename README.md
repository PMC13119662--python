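# hgrisk

Tissue-specific mercury bioaccumulation statistics and dietary risk
assessment for freshwater fish surveys.

`hgrisk` is aimed at ecotoxicologists and risk assessors working with
multi-tissue total-mercury (THg) surveys of freshwater fish — here a
three-reservoir cascade system sampled for seven species and nine organs —
who need to turn a tidy specimen × organ concentration table into
species-specific, body-weight-aware consumption advisories. It covers the
full chain:

- **Survey model and I/O** — a validated tidy table (one row per specimen ×
  organ; THg in mg·kg⁻¹ wet weight), CSV round-trips, below-LOD handling,
  and median-TW size classes.
- **Biostatistics** — Shapiro–Wilk normality gate with log₁₀ fallback,
  one-way ANOVA + Tukey HSD (with a Levene homogeneity check), Pearson and
  Spearman size–Hg correlation matrices by species × organ, OLS size models
  with diagnostics, CV, and an exact Mann–Whitney size-class contrast.
- **Deterministic risk** — estimated daily intake, target hazard quotient,
  hazard index over diet baskets, safe weekly intake at the median and P95
  concentration, and traffic-light advisory categories.
- **Monte Carlo risk** — THQ/HI simulation with triangular weekly-intake
  sampling and species-specific empirical bootstrap of concentrations,
  summarised as P50 / P95 / P(THQ > 1), validated against closed-form
  triangular oracles.
- **Synthetic survey generator** — a lognormal effects model calibrated to
  the published summary structure, so every stage is testable without the
  original specimen data.

## The model

For fish concentration *C* (mg·kg⁻¹ ww), weekly intake *IR* (g·week⁻¹) and
body weight *BW* (kg; 70 / 60 / 15 for adults, pregnant women, children):

```
EDI = C · (IR / 7 / 1000) / BW          (mg·kg⁻¹·day⁻¹)
THQ = EDI / RfD                          RfD = 0.0001 mg·kg⁻¹·day⁻¹
HI  = Σᵢ THQᵢ                            (multi-species diet basket)
SWI = TWI · BW / C · 1000                TWI = 0.0013 mg·kg⁻¹·week⁻¹
```

THQ < 1 is read as no significant non-carcinogenic risk; SWI is the weekly
fish allowance (grams) at which the weekly dose equals the tolerable weekly
intake, categorised red (< 140 g·week⁻¹), yellow (140–299) or green
(≥ 300). The probabilistic engine draws IR ~ Tri(50, 140, 350) g·week⁻¹
and bootstraps *C* from the observed species sample, independently, with
BW fixed per group, and reports P50, P95 and P(THQ > 1) over 30,000
iterations.

## Worked example

```python
from hgrisk import (calibrate_defaults, generate_survey,
                    deterministic_risk_table, McConfig, mc_risk_table)

survey = generate_survey(calibrate_defaults(), seed=1)   # 49 specimens
det = deterministic_risk_table(survey)                   # THQ / SWI table
print(det[["species", "c_median", "thq_adults", "thq_children",
           "swi_med_adults", "category_children"]].to_string(index=False))
```

```
          species  c_median  thq_adults  thq_children  swi_med_adults category_children
  Cyprinus carpio  0.010455       0.030         0.139            8704             green
 Squalius orpheus  0.016639       0.048         0.222            5469             green
   Vimba melanops  0.039431       0.113         0.526            2308             green
   Silurus glanis  0.034519       0.099         0.460            2636             green
Perca fluviatilis  0.080243       0.229         1.070            1134            yellow
Carassius gibelio  0.016977       0.049         0.226            5360             green
  Rutilus rutilus  0.031084       0.089         0.414            2928             green
```

Each row is one species: `c_median` is its muscle THg median in this
survey; `thq_*` the hazard quotient at the 140 g·week⁻¹ national baseline
(perch exceeds 1 for children — elevated exposure); `swi_med_adults` the
adult weekly allowance in grams; and the traffic-light category translates
the children's allowance into advisory language.

```python
mc = mc_risk_table(survey, McConfig(n_iter=30_000, seed=1))
print(mc[mc.group == "children"].to_string(index=False))
```

```
          species    group   p50   p95  p_exceed_pct  n_iter       seed
  Cyprinus carpio children 0.191 0.519           0.0   30000  602120507
 Squalius orpheus children 0.303 0.716           0.0   30000  480482724
   Vimba melanops children 0.590 1.266          15.2   30000  396047450
   Silurus glanis children 0.539 0.938           2.8   30000 1780620601
Perca fluviatilis children 1.336 3.332          71.6   30000  944647869
Carassius gibelio children 0.297 0.845           2.1   30000 1634660384
  Rutilus rutilus children 0.426 0.998           5.0   30000  105208945
```

Exceedance risk concentrates in children consuming the predatory species
(perch: P(THQ > 1) ≈ 72% under intake variability), while adults stay
below 1 in all species — the pattern the advisory framework is built to
surface.

The same pipeline is available from the shell:

```sh
hgrisk --seed 1 --outdir out report --simulate     # full CSV bundle + log
hgrisk --seed 1 simulate --out survey.csv          # just the synthetic data
hgrisk risk-det --input survey.csv                 # deterministic table
hgrisk --seed 1 risk-mc --input survey.csv         # Monte Carlo table
```

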