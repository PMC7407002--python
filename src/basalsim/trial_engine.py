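"""Closed-loop virtual trial orchestration and comparison statistics.

A trial arm simulates every subject over 12 weeks (8 weeks of weekly
basal uptitration followed by 4 weeks of stable dosing) under a
basal/bolus regimen: three jittered meals a day with calculator boluses,
once-daily basal injections (morning = at breakfast, evening = at
dinner) with interoccasion bioavailability noise, weekly titration under
rule A or B with the hypoglycaemia stop condition, and 5-min CGM
recording.  The last two weeks feed the outcome metrics.

Common random numbers: meal schedules, carbohydrate-counting errors and
the IOV noise stream are keyed by (seed, subject index) only — not by
insulin — so the two treatment arms expose each subject to an identical
protocol except for the insulin itself.  This is what makes the paired
("crossover") comparison meaningful.

Statistics: per-metric comparisons use a normality gate (Lilliefors test
at 0.05) to choose between the t-test and its rank-based counterpart,
paired (Wilcoxon signed-rank) for the crossover design and unpaired
(Mann-Whitney U) for the parallel design.  The parallel design is
assessed by repeatedly (100-fold) splitting the population into two
halves and counting how often each metric reaches significance.  A
one-sided paired noninferiority test on the primary outcome supports
margin-based conclusions.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats
from scipy.linalg import expm

from ._linear import periodic_predose_state
from .insulin_kinetics import kinetics_matrix
from .outcome_metrics import (
    SAMPLES_PER_DAY,
    CGMTrace,
    OutcomeSet,
    summarize_outcomes,
)
from .pk_absorption import DegAbsorptionParams
from .therapy_engine import (
    RULES,
    BolusPolicy,
    IOVSpec,
    MealConfig,
    TitrationRule,
    compute_bolus,
    generate_meal_schedule,
    insulin_on_board,
    titrate,
)
from .virtual_patient import (
    BREAKFAST_MIN,
    FAST_BOLUS_PK,
    FPG_SAMPLE_MIN,
    MINUTES_PER_DAY,
    VirtualPatient,
)

__all__ = [
    "TrialScenario",
    "SubjectResult",
    "ArmResult",
    "run_arm",
    "select_test",
    "crossover_compare",
    "parallel_splits",
    "noninferiority_test",
    "NoninferiorityResult",
]

STEP_MIN = 5.0
STEPS_PER_DAY = SAMPLES_PER_DAY


@dataclass
class TrialScenario:
    """One cell of the trial design."""

    insulin: str = "gla300"          # gla300 | deg100
    schedule: str = "morning"        # morning | evening
    rule: str = "A"                  # titration rule id
    weeks_uptitration: int = 8
    weeks_stable: int = 4
    analysis_days: int = 14
    b0_U_per_kg: float | None = None  # default: population calibration dose
    titration_enabled: bool = True
    meal_seed: int = 100
    iov_seed: int = 200
    iov: IOVSpec = field(default_factory=IOVSpec)
    meal_config: MealConfig = field(default_factory=MealConfig)
    dia_min: float = 240.0

    def __post_init__(self) -> None:
        if self.insulin not in ("gla300", "deg100"):
            raise ValueError(f"unknown insulin {self.insulin!r}")
        if self.schedule not in ("morning", "evening"):
            raise ValueError(f"unknown schedule {self.schedule!r}")
        if self.rule not in RULES:
            raise ValueError(f"unknown titration rule {self.rule!r}")
        if self.analysis_days > 7 * self.weeks_stable:
            raise ValueError("analysis window must lie inside the stable period")

    @property
    def n_days(self) -> int:
        return 7 * (self.weeks_uptitration + self.weeks_stable)


@dataclass
class SubjectResult:
    subject_id: str
    trace: CGMTrace                 # last analysis window
    outcomes: OutcomeSet
    final_dose_U: float
    dose_history_U: list
    failed: bool = False


@dataclass
class ArmResult:
    scenario: TrialScenario
    subjects: list

    @property
    def outcomes(self) -> dict:
        return {s.subject_id: s.outcomes for s in self.subjects if not s.failed}

    def metric(self, name: str) -> np.ndarray:
        return np.array(
            [getattr(s.outcomes, name) for s in self.subjects if not s.failed]
        )


def _snap(t_min: float) -> int:
    """Nearest 5-min grid index of an event time."""
    return int(round(t_min / STEP_MIN))


def simulate_subject(
    patient: VirtualPatient,
    scenario: TrialScenario,
    subject_index: int,
) -> SubjectResult:
    """Closed-loop simulation of one subject through the full trial.

    The insulin subsystems (basal depot, rapid bolus chain, plasma/liver
    kinetics) form one constant linear system propagated exactly with a
    precomputed 5-min matrix exponential; the nonlinear glucose states
    use exponential-integrator steps with coefficients frozen over each
    5-min interval.
    """
    p = patient.params
    rule = RULES[scenario.rule]
    b0 = scenario.b0_U_per_kg if scenario.b0_U_per_kg is not None else patient.b0_U_per_kg
    dose_U = max(rule.dose_floor_U, round(b0 * p.BW))
    policy = BolusPolicy(CR=p.CR, CF=p.CF, DIA=scenario.dia_min)

    # --- random streams: keyed by subject, not by arm -------------------
    meal_rng = np.random.default_rng((scenario.meal_seed, subject_index))
    iov_rng = np.random.default_rng((scenario.iov_seed, subject_index))
    meals = generate_meal_schedule(scenario.n_days, meal_rng, scenario.meal_config)
    iov_z = iov_rng.normal(0.0, 1.0, size=scenario.n_days)
    iov_cv = scenario.iov.cv_for(scenario.insulin)

    # --- linear insulin block ------------------------------------------
    absorption = p.basal_absorption(scenario.insulin)
    kin = p.kinetics()
    k1 = absorption.n_compartments          # basal depot states
    nb = 3                                  # bolus chain states
    n = k1 + nb + 2
    A = np.zeros((n, n))
    A[:k1, :k1] = absorption.matrix()
    A[k1:k1 + nb, k1:k1 + nb] = FAST_BOLUS_PK.matrix()
    A[-2:, -2:] = kinetics_matrix(kin)
    basal_rate = absorption.ka if isinstance(absorption, DegAbsorptionParams) else absorption.ka_g
    A[n - 1, k1 - 1] = basal_rate           # basal RaI into plasma
    A[n - 1, k1 + nb - 1] = FAST_BOLUS_PK.ka  # bolus RaI into plasma
    M = expm(A * STEP_MIN)
    ip_idx = n - 1

    # gut propagator (2x2, exact)
    Ag = np.array([[-p.kempt, 0.0], [p.kempt, -p.kabs]])
    Mg = expm(Ag * STEP_MIN)

    # --- initial state: periodic steady basal dosing, no meals ---------
    inj_phase = (
        BREAKFAST_MIN if scenario.schedule == "morning"
        else scenario.meal_config.times_min[2]
    )
    A_basal = np.zeros((k1 + 2, k1 + 2))
    A_basal[:k1, :k1] = absorption.matrix()
    A_basal[k1:, k1:] = kinetics_matrix(kin)
    A_basal[k1 + 1, k1 - 1] = basal_rate
    d_basal = np.zeros(k1 + 2)
    d_basal[:k1] = absorption.dose_vector(dose_U * 1000.0 / p.BW, absorption.F)
    s_pre = periodic_predose_state(A_basal, d_basal, MINUTES_PER_DAY)
    x0 = expm(A_basal * (MINUTES_PER_DAY - inj_phase)) @ (s_pre + d_basal)
    u = np.zeros(n)
    u[:k1] = x0[:k1]
    u[-2:] = x0[-2:]
    I0 = max(u[ip_idx] / kin.VI, 0.0)
    X = p.p3 / p.p2 * I0
    G = patient.fpg_target
    qsto = qgut = 0.0

    # --- event tables ---------------------------------------------------
    meal_by_step: dict[int, tuple[float, float]] = {}
    basal_by_step: dict[int, int] = {}      # step -> day index (IOV draw)
    for day in range(scenario.n_days):
        day_meals = meals[3 * day: 3 * day + 3]
        for slot, ev in enumerate(day_meals):
            meal_by_step[_snap(ev.time_min)] = (ev.cho_true_g, ev.cho_est_g)
        anchor = day_meals[0] if scenario.schedule == "morning" else day_meals[2]
        basal_by_step[_snap(anchor.time_min)] = day

    total_steps = scenario.n_days * STEPS_PER_DAY
    fpg_offset = int(FPG_SAMPLE_MIN / STEP_MIN)
    decay_x = math.exp(-p.p2 * STEP_MIN)
    gain_x = p.p3 / p.p2 * (1.0 - decay_x)
    two_pi = 2.0 * math.pi / MINUTES_PER_DAY

    glucose = np.empty(total_steps)
    prebreakfast: list[float] = []
    bolus_history: list[tuple[float, float]] = []
    dose_history = [dose_U]
    n_titration_weeks = scenario.weeks_uptitration

    for j in range(total_steps):
        t = j * STEP_MIN
        # basal injection
        if j in basal_by_step:
            day = basal_by_step[j]
            f_inj = absorption.F * max(0.1, 1.0 + iov_cv * iov_z[day])
            u[:k1] += absorption.dose_vector(dose_U * 1000.0 / p.BW, f_inj)
        # meal + bolus
        if j in meal_by_step:
            cho_true, cho_est = meal_by_step[j]
            iob = insulin_on_board(bolus_history, t, scenario.dia_min)
            bolus_U = compute_bolus(G, cho_est, policy, iob)
            if bolus_U > 0:
                u[k1] += FAST_BOLUS_PK.F * bolus_U * 1000.0 / p.BW
                bolus_history.append((t, bolus_U))
                if len(bolus_history) > 12:
                    bolus_history = [
                        (tk, bk) for tk, bk in bolus_history
                        if t - tk < scenario.dia_min
                    ]
            qsto += cho_true * 1000.0 / p.BW
        # record CGM and prebreakfast SMBG
        glucose[j] = G
        if j % STEPS_PER_DAY == fpg_offset:
            prebreakfast.append(G)
        # weekly titration at the end of each uptitration week
        if (
            scenario.titration_enabled
            and j % (7 * STEPS_PER_DAY) == 7 * STEPS_PER_DAY - 1
            and (j + 1) // (7 * STEPS_PER_DAY) <= n_titration_weeks
        ):
            week_slice = glucose[j + 1 - 7 * STEPS_PER_DAY: j + 1]
            hypo_pct = 100.0 * float(np.mean(week_slice < 70.0))
            dose_U = titrate(rule, prebreakfast, dose_U, hypo_pct)
            dose_history.append(dose_U)
        # propagate one step
        I = max(u[ip_idx] / kin.VI, 0.0)
        s_circ = 1.0 + p.a_circ * math.sin(two_pi * (t - p.phi_circ))
        a = p.p1 + X * s_circ
        b = p.p1 * p.Gb_drive + p.f_bio * p.kabs * qgut / p.VG
        ea = math.exp(-a * STEP_MIN)
        G = G * ea + b / a * (1.0 - ea)
        X = X * decay_x + gain_x * I
        qsto, qgut = Mg @ (qsto, qgut)
        u = M @ u

    tail = scenario.analysis_days * STEPS_PER_DAY
    trace = CGMTrace(
        subject_id=patient.subject_id,
        glucose=glucose[-tail:],
        start_time_min=(total_steps - tail) * STEP_MIN,
    )
    return SubjectResult(
        subject_id=patient.subject_id,
        trace=trace,
        outcomes=summarize_outcomes(trace),
        final_dose_U=dose_U,
        dose_history_U=dose_history,
    )


def run_arm(
    population: Sequence[VirtualPatient],
    scenario: TrialScenario,
) -> ArmResult:
    """Simulate one trial arm over the whole population.

    A solver failure in one subject flags that subject and continues the
    arm rather than aborting the trial.
    """
    results = []
    for idx, patient in enumerate(population):
        try:
            results.append(simulate_subject(patient, scenario, idx))
        except Exception as exc:  # pragma: no cover - defensive
            warnings.warn(
                f"subject {patient.subject_id} failed: {exc}", stacklevel=2
            )
            results.append(
                SubjectResult(
                    subject_id=patient.subject_id,
                    trace=CGMTrace(patient.subject_id,
                                   np.full(SAMPLES_PER_DAY, 100.0)),
                    outcomes=None,
                    final_dose_U=float("nan"),
                    dose_history_U=[],
                    failed=True,
                )
            )
    return ArmResult(scenario=scenario, subjects=results)


# ---------------------------------------------------------------------------
# Statistics
# ---------------------------------------------------------------------------

def _lilliefors_normal(x: np.ndarray, alpha: float = 0.05) -> bool:
    """True when the Lilliefors test does not reject normality."""
    from statsmodels.stats.diagnostic import lilliefors

    x = np.asarray(x, dtype=float)
    if np.std(x, ddof=1) == 0:
        return False  # degenerate: route to the rank-based test
    _, pval = lilliefors(x, dist="norm", pvalmethod="table")
    return pval >= alpha


def select_test(values_a, values_b, paired: bool, alpha: float = 0.05) -> str:
    """Choose the comparison test via the Lilliefors normality gate.

    Paired designs test the within-subject differences; parallel designs
    require both groups to pass.  Returns one of ``paired_t``,
    ``wilcoxon``, ``unpaired_t``, ``mannwhitney``.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if min(a.size, b.size) < 4:
        raise ValueError("need at least 4 observations per group")
    if paired:
        if a.size != b.size:
            raise ValueError("paired comparison needs equal-length samples")
        return "paired_t" if _lilliefors_normal(a - b, alpha) else "wilcoxon"
    normal = _lilliefors_normal(a, alpha) and _lilliefors_normal(b, alpha)
    return "unpaired_t" if normal else "mannwhitney"


def _run_test(test: str, a: np.ndarray, b: np.ndarray) -> float:
    if test == "paired_t":
        return float(stats.ttest_rel(a, b).pvalue)
    if test == "wilcoxon":
        d = a - b
        if np.all(d == 0):
            return 1.0
        return float(stats.wilcoxon(a, b, zero_method="wilcox").pvalue)
    if test == "unpaired_t":
        return float(stats.ttest_ind(a, b).pvalue)
    if test == "mannwhitney":
        return float(stats.mannwhitneyu(a, b, method="asymptotic").pvalue)
    raise ValueError(f"unknown test {test!r}")


def crossover_compare(
    outcomes_a: Mapping[str, OutcomeSet],
    outcomes_b: Mapping[str, OutcomeSet],
    metrics: Sequence[str] | None = None,
    alpha: float = 0.05,
):
    """Paired per-metric comparison of two arms on the same subjects.

    Returns a DataFrame with per-arm mean and SD, the selected test, the
    p-value, and a significance flag at ``alpha``.
    """
    import pandas as pd

    if set(outcomes_a) != set(outcomes_b):
        raise ValueError("crossover comparison requires identical subject sets")
    sids = sorted(outcomes_a)
    metrics = list(metrics or OutcomeSet.metric_names())
    rows = []
    for m in metrics:
        a = np.array([getattr(outcomes_a[s], m) for s in sids])
        b = np.array([getattr(outcomes_b[s], m) for s in sids])
        if np.allclose(a, b):
            test, p = "wilcoxon", 1.0
        else:
            test = select_test(a, b, paired=True, alpha=alpha)
            p = _run_test(test, a, b)
        rows.append(
            {"metric": m, "mean_a": a.mean(), "sd_a": a.std(ddof=1),
             "mean_b": b.mean(), "sd_b": b.std(ddof=1),
             "test": test, "p_value": p, "significant": p < alpha}
        )
    return pd.DataFrame(rows)


def parallel_splits(
    outcomes_a: Mapping[str, OutcomeSet],
    outcomes_b: Mapping[str, OutcomeSet],
    n_splits: int = 100,
    seed: int = 0,
    metrics: Sequence[str] | None = None,
    alpha: float = 0.05,
):
    """Parallel-design robustness: repeated random 50/50 splits.

    For each split the population is divided without replacement into
    two equal subgroups; subgroup 1 contributes its arm-A outcomes and
    subgroup 2 its arm-B outcomes, compared unpaired.  Returns a
    DataFrame of significant counts per metric out of ``n_splits``.
    """
    import pandas as pd

    if set(outcomes_a) != set(outcomes_b):
        raise ValueError("parallel splits require identical subject sets")
    sids = np.array(sorted(outcomes_a))
    half = sids.size // 2
    if half < 2:
        raise ValueError("need at least 2 subjects per subgroup")
    metrics = list(metrics or OutcomeSet.metric_names())
    mat_a = {m: np.array([getattr(outcomes_a[s], m) for s in sids]) for m in metrics}
    mat_b = {m: np.array([getattr(outcomes_b[s], m) for s in sids]) for m in metrics}

    rng = np.random.default_rng(seed)
    counts = dict.fromkeys(metrics, 0)
    for _ in range(n_splits):
        perm = rng.permutation(sids.size)
        g1, g2 = perm[:half], perm[half: 2 * half]
        for m in metrics:
            a, b = mat_a[m][g1], mat_b[m][g2]
            if np.allclose(a.std(ddof=1), 0) and np.allclose(b.std(ddof=1), 0):
                continue
            test = select_test(a, b, paired=False, alpha=alpha)
            if _run_test(test, a, b) < alpha:
                counts[m] += 1
    return pd.DataFrame(
        {"metric": metrics, "significant_count": [counts[m] for m in metrics],
         "n_splits": n_splits}
    )


@dataclass(frozen=True)
class NoninferiorityResult:
    noninferior: bool
    mean_difference: float
    ci_lower: float
    delta: float
    alpha: float


def noninferiority_test(
    primary_a,
    primary_b,
    delta: float | None = None,
    alpha: float = 0.025,
) -> NoninferiorityResult:
    """One-sided paired noninferiority test on the primary outcome.

    Tests H0: mu_a - mu_b <= -delta.  Arm A is declared noninferior to
    arm B when the lower one-sided (1 - alpha) confidence bound of the
    paired difference exceeds -delta.  When ``delta`` is omitted it is
    set to half the standard deviation of the comparator arm's primary
    outcome (the margin convention used for percent-time-in-range).
    """
    a = np.asarray(primary_a, dtype=float)
    b = np.asarray(primary_b, dtype=float)
    if a.size != b.size:
        raise ValueError("paired samples required")
    if delta is None:
        delta = 0.5 * float(np.std(b, ddof=1))
    if delta <= 0:
        raise ValueError("noninferiority margin must be positive")
    d = a - b
    n = d.size
    mean = float(d.mean())
    se = float(d.std(ddof=1) / math.sqrt(n)) if n > 1 else 0.0
    tcrit = stats.t.ppf(1.0 - alpha, df=n - 1) if n > 1 else 0.0
    lower = mean - tcrit * se
    return NoninferiorityResult(
        noninferior=bool(lower > -delta),
        mean_difference=mean,
        ci_lower=float(lower),
        delta=float(delta),
        alpha=alpha,
    )
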