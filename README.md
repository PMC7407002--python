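# basalsim

Virtual head-to-head trials of second-generation long-acting basal
insulins — glargine 300 U/mL (Gla-300) versus degludec 100 U/mL
(Deg-100) — in type 1 diabetes.

`basalsim` is aimed at pharmacometricians and trial designers who want a
transparent, fully scriptable bench for questions such as: *does a
once-daily basal analogue with a flatter PK profile improve CGM time in
range? does a tighter titration target pay off? will a difference that a
paired (crossover) analysis can see survive a parallel-group design?*
It combines:

* **Subcutaneous PK models.** Degludec free-active absorption is a
  three-compartment series chain — dose `D` enters the depot, converts
  through two molecular-complex stages with a common rate `kd`, and is
  absorbed to plasma with rate `ka`:

  ```
  dQ1/dt = -kd*Q1 + F*D      dQ2/dt = kd*(Q1 - Q2)
  dQ3/dt = kd*Q2 - ka*Q3     RaI    = ka*Q3
  ```

  Circulating degludec is almost entirely albumin-bound; a constant
  free-active fraction of 2.85% maps total assay concentrations to the
  receptor-available scale. Glargine uses a precipitate/dissolution
  two-compartment structure with configurable rates.

* **Plasma insulin kinetics.** A two-compartment (plasma + liver) model
  turns `RaI` into plasma concentration `I = Ip/VI`, reparameterised so
  that `m2, m3, m4` follow from `m1`, clearance `CL` and the fixed
  distribution volume `VI = 0.048 L/kg`, guaranteeing the steady-state
  identity `I_ss = RaI * BW / CL`.

* **MAP identification.** The five parameters `(F, kd, ka, m1, CL)` are
  estimated per subject from day-8 clamp concentration profiles by a
  maximum a posteriori fit in log space with lognormal priors on `m1`
  and `CL`, plus weighted-residual diagnostics, multivariate-lognormal
  population sampling, and a synthetic clamp fixture generator
  (8 once-daily doses at 0.4 or 0.6 U/kg, 14 samples over 0–30 h,
  multiplicative measurement error, LLOQ censoring).

* **A surrogate virtual patient** (minimal-model glucose core +
  two-compartment gut + circadian insulin-sensitivity modulation) with
  population variability, exact baseline calibration to a target fasting
  glucose (172.9 mg/dL at 0.3 U/kg glargine), and starting-dose matching
  between insulins.

* **A therapy engine and trial orchestrator**: three daily meals with
  carb-counting error, bolus calculator with insulin-on-board, weekly
  basal titration (rule A: 80–130 mg/dL target; rule B: 70–89 mg/dL)
  with a 7.5% hypoglycaemia stop condition, interoccasion
  bioavailability noise (CV 17% Gla-300 / 8.5% Deg-100), 12-week trials
  (8 weeks uptitration + 4 stable), CGM outcome metrics (time in
  ranges, LBGI/HBGI, 2-week CV), and crossover / 100-fold-split
  parallel statistics with a Lilliefors normality gate and a paired
  noninferiority test.

## Worked example

```python
import numpy as np
from basalsim.identification import PKParameters, day8_concentrations
from basalsim.virtual_patient import (generate_population, calibrate_baseline,
                                      match_starting_dose)
from basalsim.trial_engine import TrialScenario, run_arm, crossover_compare

# median-parameter degludec subject: day-8 profile at 0.4 U/kg
pk = PKParameters(F=0.69, kd=0.0056, ka=0.0007, m1=0.176, CL=1.10)
t = np.arange(0.0, 1801.0, 5.0)
conc = day8_concentrations(pk, 400.0, t)
print(f"day-8 Cmax = {conc.max():.1f} uU/mL at Tmax = {t[conc.argmax()]:.0f} min")

# a small calibrated population and a 12-week head-to-head trial
pop = calibrate_baseline(generate_population(20, seed=4), seed=4)
b0_deg = match_starting_dose(pop)
print(f"matched degludec starting dose: {b0_deg:.3f} U/kg")

arm_gla = run_arm(pop, TrialScenario(insulin="gla300", rule="A"))
arm_deg = run_arm(pop, TrialScenario(insulin="deg100", rule="A",
                                     b0_U_per_kg=b0_deg))
table = crossover_compare(arm_gla.outcomes, arm_deg.outcomes,
                          metrics=["t_t70_140", "mean"])
print(table[["metric", "mean_a", "mean_b", "test", "p_value"]].round(3))
```

prints

```
day-8 Cmax = 16.5 uU/mL at Tmax = 545 min
matched degludec starting dose: 0.386 U/kg
      metric   mean_a   mean_b      test  p_value
0  t_t70_140   29.913   24.731  wilcoxon    0.475
1       mean  158.900  163.975  paired_t    0.173
```

The median degludec subject peaks at 16.5 μU/mL about 9 h after the
day-8 dose. Degludec needs a slightly higher starting dose than
glargine (0.386 vs 0.3 U/kg) to reach the same baseline fasting
glucose, because only 2.85% of it circulates in free-active form and
the two depots differ in bioavailability. In this 20-subject trial the
paired comparison finds no significant difference between the insulins
in percent time in 70–140 mg/dL (the primary outcome) or in mean
glucose.

A command-line interface wraps the main workflows:

```bash
basalsim make-fixtures --n 48 --dose 0.4 --seed 7 --out clamp.csv
basalsim fit-pk --data clamp.csv --out fits.json
basalsim run-trial --config scenario.yaml --out results/
```

## Layout

| module | role |
| --- | --- |
| `basalsim.pk_absorption` | subcutaneous depot models, multidose RaI simulation |
| `basalsim.insulin_kinetics` | plasma/liver kinetics, reparameterisation, Cmax/Tmax |
| `basalsim.identification` | free-active rescaling, MAP fits, population sampling, fixtures |
| `basalsim.virtual_patient` | surrogate glucose model, population, calibration, dose matching |
| `basalsim.therapy_engine` | meals, boluses, IOB, titration rules, IOV |
| `basalsim.outcome_metrics` | CGM traces, time in ranges, LBGI/HBGI, CV |
| `basalsim.trial_engine` | closed-loop trial runs, crossover/parallel statistics |

See `docs/methods.md` for the modelling assumptions, parameter defaults
and known limitations.
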