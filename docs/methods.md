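# Methods

This note documents the models behind `basalsim`, the defaults and why
they were chosen, the numerical machinery, and what the synthetic data
and the passing tests do and do not establish about real data.

## Subcutaneous absorption

**Degludec (free-active).** The depot is a three-compartment series
chain `Q1 -> Q2 -> Q3 -> plasma` with a single molecular-complex
conversion rate `kd` for both transfer stages (the two stages are
indistinguishable in day-8 clamp profiles, so they are constrained
equal) and an absorption rate `ka` from the last compartment. Doses are
instantaneous mass additions of `F_inj * D` to `Q1` — subcutaneous pen
injections are boluses, not infusions. The chain topology is the unique
three-compartment series arrangement consistent with interpreting
`kd1`, `kd2` as complex-conversion rates and `ka` as the plasma
absorption rate. Identified population medians (with interquartile
ranges) used as sampling defaults:

| parameter | median | IQR | unit |
| --- | --- | --- | --- |
| F | 0.69 | 0.58–0.85 | – |
| kd | 0.0056 | 0.0041–0.0072 | 1/min |
| ka | 0.0007 | 0.0006–0.0009 | 1/min |
| m1 | 0.176 | 0.176–0.177 | 1/min |
| CL | 1.10 | 1.09–1.11 | L/min |

Degludec circulates 97–98% albumin-bound; the model works throughout on
the *free-active* scale via a constant fraction of 0.0285 (estimated as
the ratio of clamp potencies normalised by insulin exposure). The
total-insulin assay LLOQ of 12 μU/mL therefore maps to 0.342 μU/mL
free-active.

**Glargine.** A two-compartment precipitate/dissolution structure:
fraction `p_diss` of the dose dissolves directly, the rest precipitates
and redissolves at rate `kp`; dissolved insulin is absorbed at `ka_g`.
The exact Gla-300 rate values are not part of this package's
identification work; the shipped defaults (`F = 0.70`, `p_diss = 0.10`,
`kp = 0.0008 /min`, `ka_g = 0.0009 /min`) are **calibration constants**
chosen so the day-8 profile is flatter than degludec's with a broad
peak (day-8 peak/trough 1.26 vs 1.59 for degludec at matched exposure),
as expected for the higher-concentrated glargine formulation. All four
are configuration.

## Plasma insulin kinetics

Two compartments (plasma `Ip`, liver `Il`, masses in mU/kg) with
concentration `I = Ip/VI` in μU/mL. `VI` is fixed to the population
value 0.048 L/kg; `m2, m3, m4` are not separately identifiable from
plasma concentrations and are derived from `(m1, CL, VI, BW)`:

```
CLk = CL / (VI * BW)
m3  = m1 * HEb / (1 - HEb)          HEb = 0.6 (basal hepatic extraction)
m4  = (2/5) * CLk
m2  = (3/5) * CLk * (m1 + m3) / m3
```

The binding contract — and the tested invariant — is the clearance
identity `I_ss = RaI * BW / CL` together with basal hepatic extraction
`HEb`; the 3/5–2/5 hepatic/peripheral split is one admissible
completion of that contract and is exposed as a parameter. `BW`
defaults to 80 kg (adult male cohorts with BMI ≈ 26) and is sampled per
subject in the virtual population.

## MAP identification

Per subject, `(F, kd, ka, m1, CL)` are estimated from the 14-point
day-8 clamp grid (0–30 h) by minimising

```
sum_i (y_i - yhat_i)^2 / sigma_i^2
  + sum_{j in {m1, CL}} (log theta_j - log mu_j)^2 / omega_j^2
```

over log parameters. Choices:

* Prior means `m1 = 0.18 /min`, `CL = 1.11 L/min`; prior dispersions
  are not part of the identified dataset, so a weakly informative 50%
  log-SD is the default (configurable). `m1` and `CL` are individually
  poorly identified from concentration data (their product with the
  steady-state constraint is what the data see), which is exactly why
  they carry priors.
* Measurement SD `sigma_i = max(0.06 * y_i, 0.02 μU/mL)`: a 6% CV with
  an additive floor, standing in for the assay error model, which is
  known in form (independent, zero-mean Gaussian) but not in printed
  magnitude. Configurable.
* Optimiser: L-BFGS-B on log parameters (positivity by construction,
  `F <= 1.5`) from 10 jittered starts; best objective wins, ties by
  first found. A Nelder–Mead polish was evaluated during development
  and changed estimates by <1e-5 relative, so the quasi-Newton result
  is kept as is.
* Samples below the free-active LLOQ are excluded from the objective,
  not imputed.
* Precision: the objective is on the −2·log-posterior scale, so the
  log-parameter covariance is `2 H^{-1}` with `H` the central-difference
  Hessian at the optimum; the log-scale SD is reported as percent CV.
* The forward model (depot chain + kinetics) is linear, so day-8
  predictions use matrix-exponential propagation of the coupled 5-state
  system — exact, and fast enough for multi-start fitting.

**Estimator behaviour.** `kd` and `ka` trade off along a mean-residence
ridge; with 6% noise single-subject estimates wander along it (log-SD
of estimates ≈ 0.56 vs 0.42 true inter-subject spread). Across
replicate 48-subject cohorts the *median* recovery bias is about −5% on
`kd` and within ±3% on the other parameters, i.e. inside the ±10% band
the recovery checks use, but individual cohort draws can land one
standard error outside it.

**Population sampling** is multivariate lognormal with medians and
IQR-derived log-SDs (`(log q75 − log q25)/1.349`) from the table above.
The joint distribution of the original identification included
parameter correlations that are not printed; the default here is
**independence** (identity correlation, with a configuration hook).
This is a documented departure: it inflates the spread — and, through
Jensen-type effects on nonlinear summaries, slightly the mean — of
population Cmax (~+5%) and Tmax (~+4%, SD 125 vs 97 min) relative to
the correlated original. The day-8 population assessment inherits that
offset.

## Synthetic clamp fixtures

`generate_clamp_fixtures` emulates the clamp study design: 8 once-daily
doses at 0.4 or 0.6 U/kg, day-8 sampling at
{0,1,2,4,6,8,10,12,14,16,20,24,28,30} h, multiplicative zero-mean
Gaussian error (default CV 6%), LLOQ censoring. It reproduces the
*design*, not the assay: real clamp data add run-to-run analytical
drift, non-Gaussian tails and occasional missing draws that the
generator does not model, so parameter-recovery results bound the
estimator's behaviour under ideal noise only.

## Surrogate virtual patient

The glucose core is deliberately minimal (a full physiological
simulator is proprietary and out of scope): a one-compartment glucose
node with multiplicative insulin-dependent loss (minimal-model form), a
remote insulin-action state, a two-compartment gut, and a sinusoidal
circadian modulation of insulin sensitivity. The multiplicative loss
guarantees `G > 0` for all admissible inputs. Defaults (all
configuration, none of them literature estimates):

| parameter | default | unit | role |
| --- | --- | --- | --- |
| p1 | 0.0035 | 1/min | glucose effectiveness |
| p2 | 0.02 | 1/min | insulin-action decay |
| p3 | 8e-6 | 1/min² per μU/mL | insulin-action gain (SI = p3/p2 = 4e-4) |
| VG | 1.6 | dL/kg | glucose distribution volume |
| kempt, kabs | 0.018, 0.012 | 1/min | gastric emptying, absorption |
| f_bio | 0.9 | – | carbohydrate bioavailability |
| a_circ | 0.10 | – | circadian amplitude; phase uniform per subject |

Inter-subject variability is lognormal (CVs 10–30%) on `p1, p3, VG,
kempt, kabs, BW` and on glargine `F`; degludec PK vectors come from the
identified joint distribution. What the surrogate supports: meal
excursions, basal accumulation, dawn-type variation, monotone
dose–response, realistic population spread of CGM metrics. What it does
not: glucagon counter-regulation, hypoglycaemia symptoms and rescue
carbohydrates, exercise, renal glucose excretion — so absolute
hypoglycaemia rates and risk indices are qualitative, and trial-level
outcome tables should be read as *this population's* values, not as
predictions for any clinical cohort.

**Baseline calibration.** Each subject's non-insulin drive `Gb_drive`
is adjusted so that prebreakfast glucose (06:45, 15 min before the
scheduled breakfast) under steady once-daily dosing of 0.3 U/kg
glargine equals a per-subject target drawn lognormally (15% CV) around
172.9 mg/dL with the sample mean constrained exactly. How the original
trial distributed baseline FPG around its mean is not recorded; the
mean-constrained lognormal is this package's choice. For a fixed
insulin trajectory the fasting glucose is affine in `Gb_drive`, so two
simulations per subject give the exact root — calibration is exact and
idempotent. Therapy parameters follow clinical rules of thumb
`CR = 500/TDD`, `CF = 1700/TDD` with
`TDD = b0·BW / (1 − CHO_daily/500)` (self-consistent in the meal load).
The degludec starting dose is then found by a scalar Brent search so
the population mean fasting glucose matches the glargine baseline.

## Therapy engine

* Meals 07:00 / 13:00 / 20:00 with Gaussian timing jitter (SD 20 min),
  truncated-normal carbohydrates (40±10, 70±15, 80±15 g, 10 g floor),
  and unbiased multiplicative counting error (N(0, 0.2) truncated at
  ±0.5).
* Bolus `B = CHO/CR + (G − 160)/CF − IOB`, clamped at 0 and rounded to
  0.5 U; insulin-on-board decays as `(1 − τ/DIA)²` with DIA = 240 min —
  a simple monotone curvilinear form with the right endpoints.
* Titration every 7 days on the median of the last three prebreakfast
  readings. The published step tables for the two rules are in
  supplementary material that is not available; the defaults are
  reconstructions in the same style (rule A: ±3 U around the 80–130
  band; rule B: stepped −4…+6 U around 70–89) and are overridable.
  The hypoglycaemia stop (more than 7.5% of the last week below
  70 mg/dL) freezes increases only — whether it should also force a
  reduction is unspecified, and freezing is the conservative reading.
  Doses round to 1 U with a 2 U floor.
* Interoccasion variability multiplies each injection's bioavailability
  by `max(0.1, 1 + ε)`, `ε ~ N(0, cv)` with cv 0.17 (Gla-300) / 0.085
  (Deg-100); the floor guards a >5σ event.
* Basal timing: morning = at the realised breakfast, evening = at the
  realised dinner (basal and breakfast bolus co-timed).
* SMBG readings are noiseless plasma glucose; a sensor/meter noise hook
  exists but defaults off, as does CGM sensor error (the CGM trace is
  plasma glucose at 5-min sampling).

## Trial engine and statistics

Each arm runs 8 weeks of uptitration plus 4 weeks of stable dosing;
outcomes use the last 2 weeks. Meal, carb-error and IOV random streams
are keyed by (seed, subject index) but not by insulin, so both arms
apply an identical protocol to each subject — the requirement for the
crossover reading. Initial states are the exact periodic steady state
of the basal-insulin subsystem at the starting dose, so no burn-in is
needed.

Numerics: all insulin subsystems are linear and are advanced with a
precomputed 5-min matrix exponential (exact); gut states likewise. The
two nonlinear states (glucose, insulin action) use exponential-Euler
steps with coefficients frozen over each 5-min interval — unconditionally
positive and stable, with discretisation error far below the metric
resolution at the rate constants in use. Event times snap to the 5-min
grid.

Outcome metrics follow the consensus conventions: every metric except
the 2-week CV is computed per day and averaged over the 14-day window;
bands are closed-left/open-right (`[70,140)`, `[70,180)`) with strict
tails (<54, <70, >180, >250), which only matters for samples exactly on
a boundary; the daily SD is the within-day SD averaged across days (the
between/within ambiguity is resolved in favour of the daily-basis
convention). LBGI/HBGI use the standard symmetrising transform
`f(g) = 1.509((ln g)^1.084 − 5.381)` with glucose clamped to
[20, 600] mg/dL.

Comparisons: Lilliefors (statsmodels, table-based p-values at all
sample sizes) gates t-tests versus Wilcoxon signed-rank (paired) or
Mann–Whitney U (unpaired) at α = 0.05, per metric, with no multiplicity
correction (deliberately, matching per-metric reporting practice). The
parallel design repeats a without-replacement 50/50 split 100 times and
counts significant results. The noninferiority test is one-sided paired
at α = 0.025 with margin Δ = 0.5·SD of the comparator arm's primary
outcome by default (an explicit Δ, e.g. 8 percentage points, can be
passed instead).

## Problem sizes and determinism

The shipped analyses use the study's native sizes: 100-subject PK and
trial populations, 48-subject identification cohorts (24 per dose),
100-fold parallel splits. A full acceptance run takes about 1–2 min on
one CPU; the closed-loop simulator covers a 12-week subject in ~0.1 s.
Every stochastic step takes an explicit seed or Generator, and a trial
is reproducible bit-for-bit from its seed set.

## Known limitations

* Glargine PK parameter values are package calibration constants, so
  absolute glargine-arm doses and exposure are illustrative; degludec's
  are identified from the synthetic emulation of the clamp design.
* The independence default in PK population sampling (correlations not
  printed) widens population Cmax/Tmax spread and shifts their means a
  few percent upward.
* The surrogate patient omits counter-regulation and behavioural
  variability; virtual subjects adhere perfectly to titration and meal
  schedules, so between-arm differences are sharper than a clinical
  setting would show.
* Primary-outcome SDs of the surrogate population (~24 percentage
  points) exceed the 16 points of the reference adult population, so
  the default-margin noninferiority test is more conservative here.
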