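"""Surrogate virtual patient: glucose-insulin dynamics and population tools.

The glucose core is a deliberately small, fully documented stand-in for a
full physiological simulator: a minimal-model glucose node with remote
insulin action, a two-compartment gut, and a circadian modulation of
insulin sensitivity.  It supports the phenomena the virtual trial needs
— meal excursions, basal insulin accumulation, dawn-type diurnal
variation, inter-subject variability — while staying transparent:

    dG/dt    = -(p1 + X * s(t)) * G + p1 * Gb_drive + f_bio * kabs * Qgut / VG
    dX/dt    = -p2 * X + p3 * max(I, 0)
    dQsto/dt = -kempt * Qsto + ingestion
    dQgut/dt =  kempt * Qsto - kabs * Qgut
    s(t)     = 1 + a_circ * sin(2*pi*(t - phi_circ) / 1440)

with G plasma glucose (mg/dL), X remote insulin action (1/min), I the
plasma free-insulin concentration (uU/mL) produced by the kinetics
module, and Qsto/Qgut carbohydrate masses (mg/kg).  The multiplicative
loss keeps G positive for all admissible inputs.  All surrogate
parameter values and dispersions are package calibration choices, not
literature estimates, and every one is configuration-exposed.

Baseline calibration exploits linearity: for a fixed insulin trajectory
the fasting glucose is affine in the drive parameter ``Gb_drive``, so the
per-subject calibration to a target fasting plasma glucose (FPG) is
exact (two simulations per subject) and idempotent.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.linalg import expm
from scipy.optimize import brentq

from ._linear import periodic_predose_state
from .identification import PKParameters, sample_population
from .insulin_kinetics import KineticsParams, kinetics_matrix
from .pk_absorption import DegAbsorptionParams, GlaAbsorptionParams

__all__ = [
    "PatientParams",
    "PatientState",
    "VirtualPatient",
    "PopulationConfig",
    "patient_rhs",
    "generate_population",
    "fasting_glucose",
    "population_fpg",
    "calibrate_baseline",
    "match_starting_dose",
    "derive_therapy_params",
    "FAST_BOLUS_PK",
]

MINUTES_PER_DAY = 1440
#: Prebreakfast FPG sampling time: 15 min before the scheduled 07:00 breakfast.
BREAKFAST_MIN = 7 * 60
FPG_SAMPLE_MIN = BREAKFAST_MIN - 15

#: Rapid-acting bolus analogue: same chain structure as the degludec depot
#: but with fast rates giving a plasma peak around an hour post-injection.
#: Plumbing constants, not subject-specific.
FAST_BOLUS_PK = DegAbsorptionParams(F=0.85, kd=0.04, ka=0.03)


@dataclass
class PatientParams:
    """Surrogate glucose-model, therapy and PK parameters for one subject."""

    p1: float = 0.0035          # glucose effectiveness, 1/min
    p2: float = 0.02            # insulin-action decay, 1/min
    p3: float = 8.0e-6          # insulin-action gain, 1/min^2 per uU/mL
    VG: float = 1.6             # glucose distribution volume, dL/kg
    Gb_drive: float = 300.0     # non-insulin glucose drive, mg/dL (calibrated)
    kempt: float = 0.018        # gastric emptying, 1/min
    kabs: float = 0.012         # intestinal absorption, 1/min
    f_bio: float = 0.90         # carbohydrate bioavailability
    a_circ: float = 0.10        # circadian insulin-sensitivity amplitude
    phi_circ: float = 0.0       # circadian phase, min
    BW: float = 80.0            # kg
    CR: float = 12.0            # carbohydrate ratio, g/U (set at calibration)
    CF: float = 42.0            # correction factor, mg/dL per U
    pk: PKParameters = None     # degludec PK vector
    gla: GlaAbsorptionParams = field(default_factory=GlaAbsorptionParams)

    def __post_init__(self) -> None:
        positives = (self.p1, self.p2, self.p3, self.VG, self.Gb_drive,
                     self.kempt, self.kabs, self.f_bio, self.BW,
                     self.CR, self.CF)
        if any(v <= 0 for v in positives):
            raise ValueError("patient parameters must be strictly positive")
        if not 0.0 <= self.a_circ < 0.5:
            raise ValueError("a_circ must lie in [0, 0.5)")
        if self.pk is None:
            self.pk = PKParameters(F=0.69, kd=0.0056, ka=0.0007,
                                   m1=0.176, CL=1.10, BW=self.BW)

    def circadian(self, t_min) -> np.ndarray:
        """Insulin-sensitivity modulation s(t), dimensionless."""
        return 1.0 + self.a_circ * np.sin(
            2.0 * np.pi * (np.asarray(t_min, dtype=float) - self.phi_circ)
            / MINUTES_PER_DAY
        )

    def kinetics(self) -> KineticsParams:
        return KineticsParams(m1=self.pk.m1, CL=self.pk.CL,
                              VI=self.pk.VI, BW=self.BW)

    def basal_absorption(self, insulin: str):
        if insulin == "deg100":
            return DegAbsorptionParams(F=min(self.pk.F, 1.5),
                                       kd=self.pk.kd, ka=self.pk.ka)
        if insulin == "gla300":
            return self.gla
        raise ValueError(f"unknown insulin {insulin!r}")


@dataclass
class PatientState:
    """Full dynamic state of the surrogate patient."""

    G: float                   # mg/dL
    X: float = 0.0             # 1/min
    Qsto: float = 0.0          # mg/kg
    Qgut: float = 0.0          # mg/kg
    Il: float = 0.0            # mU/kg
    Ip: float = 0.0            # mU/kg

    def __post_init__(self) -> None:
        if self.G <= 0:
            raise ValueError("glucose must be strictly positive")
        if min(self.Qsto, self.Qgut, self.Il, self.Ip) < 0:
            raise ValueError("masses must be nonnegative")


@dataclass
class VirtualPatient:
    """A subject: parameters plus trial bookkeeping."""

    subject_id: str
    params: PatientParams
    fpg_target: float = 172.9   # mg/dL, per-subject baseline target
    b0_U_per_kg: float = 0.3    # starting basal dose used at calibration


def patient_rhs(
    state: PatientState,
    t_min: float,
    params: PatientParams,
    ra_sc: float = 0.0,
    ingestion: float = 0.0,
) -> np.ndarray:
    """Time derivatives of (G, X, Qsto, Qgut, Il, Ip).

    ``ra_sc`` is the total subcutaneous insulin rate of appearance
    (basal + bolus, mU/kg/min); ``ingestion`` the carbohydrate ingestion
    rate (mg/kg/min).
    """
    kin = params.kinetics()
    I = state.Ip / kin.VI
    s = float(params.circadian(t_min))
    ra_meal = params.f_bio * params.kabs * state.Qgut / params.VG
    dG = -(params.p1 + state.X * s) * state.G + params.p1 * params.Gb_drive + ra_meal
    dX = -params.p2 * state.X + params.p3 * max(I, 0.0)
    dQsto = -params.kempt * state.Qsto + ingestion
    dQgut = params.kempt * state.Qsto - params.kabs * state.Qgut
    dIl = -(kin.m1 + kin.m3) * state.Il + kin.m2 * state.Ip
    dIp = -(kin.m2 + kin.m4) * state.Ip + kin.m1 * state.Il + ra_sc
    return np.array([dG, dX, dQsto, dQgut, dIl, dIp])


@dataclass(frozen=True)
class PopulationConfig:
    """Inter-subject variability of the surrogate population.

    Lognormal coefficients of variation on the metabolic parameters and
    body weight; the circadian phase is uniform over the day.  These are
    package calibration choices.
    """

    cv_p1: float = 0.20
    cv_p3: float = 0.30
    cv_VG: float = 0.10
    cv_kempt: float = 0.20
    cv_kabs: float = 0.20
    cv_BW: float = 0.12
    cv_gla_F: float = 0.15
    a_circ: float = 0.10
    fpg_cv: float = 0.15        # spread of per-subject baseline FPG targets
    base: PatientParams = field(default_factory=PatientParams)


def generate_population(
    n: int = 100,
    seed: int = 0,
    config: PopulationConfig | None = None,
) -> list[VirtualPatient]:
    """Generate ``n`` virtual subjects with inter-subject variability.

    Metabolic parameters vary lognormally around the surrogate defaults;
    degludec PK vectors are drawn from the identified joint parameter
    distribution; the circadian phase is uniform over the day.
    Deterministic given ``seed``.
    """
    if n < 2:
        raise ValueError("population needs at least 2 subjects")
    cfg = config or PopulationConfig()
    rng = np.random.default_rng(seed)
    pk_vectors = sample_population(n, seed=seed + 1)

    def lognorm(median, cv):
        return median * np.exp(rng.normal(0.0, cv, size=n))

    base = cfg.base
    p1 = lognorm(base.p1, cfg.cv_p1)
    p3 = lognorm(base.p3, cfg.cv_p3)
    vg = lognorm(base.VG, cfg.cv_VG)
    kempt = lognorm(base.kempt, cfg.cv_kempt)
    kabs = lognorm(base.kabs, cfg.cv_kabs)
    bw = lognorm(base.BW, cfg.cv_BW)
    gla_f = lognorm(base.gla.F, cfg.cv_gla_F)
    phi = rng.uniform(0.0, MINUTES_PER_DAY, size=n)

    out = []
    for i in range(n):
        pk = replace(pk_vectors[i], BW=float(bw[i]))
        params = PatientParams(
            p1=float(p1[i]), p2=base.p2, p3=float(p3[i]), VG=float(vg[i]),
            Gb_drive=base.Gb_drive, kempt=float(kempt[i]), kabs=float(kabs[i]),
            f_bio=base.f_bio, a_circ=cfg.a_circ, phi_circ=float(phi[i]),
            BW=float(bw[i]), CR=base.CR, CF=base.CF, pk=pk,
            gla=replace(base.gla, F=float(min(gla_f[i], 1.5))),
        )
        out.append(VirtualPatient(subject_id=f"P{i + 1:03d}", params=params))
    return out


# ---------------------------------------------------------------------------
# Fasting glucose under steady basal dosing (no meals)
# ---------------------------------------------------------------------------

def _basal_insulin_day(
    params: PatientParams, insulin: str, dose_mU_per_kg: float,
    injection_phase_min: float, step: float = 5.0,
) -> np.ndarray:
    """Periodic one-day plasma insulin profile (uU/mL) from midnight.

    The basal depot plus plasma/liver kinetics form one linear system;
    the day-periodic steady state under once-daily dosing is computed
    exactly, then sampled on a uniform grid over one day.
    """
    absorption = params.basal_absorption(insulin)
    kin = params.kinetics()
    k = absorption.n_compartments
    n = k + 2
    A = np.zeros((n, n))
    A[:k, :k] = absorption.matrix()
    A[k:, k:] = kinetics_matrix(kin)
    # plasma receives RaI from the last depot compartment
    rate = absorption.ka if isinstance(absorption, DegAbsorptionParams) else absorption.ka_g
    A[k + 1, k - 1] = rate

    d = np.zeros(n)
    d[:k] = absorption.dose_vector(dose_mU_per_kg, absorption.F)

    s_pre = periodic_predose_state(A, d, MINUTES_PER_DAY)
    # state at midnight: propagate from just after the dose
    x = expm(A * (MINUTES_PER_DAY - injection_phase_min)) @ (s_pre + d)
    M = expm(A * step)
    n_steps = int(MINUTES_PER_DAY / step)
    inj_idx = int(round(injection_phase_min / step))
    conc = np.empty(n_steps)
    for j in range(n_steps):
        if j == inj_idx:
            x = x + d
        conc[j] = x[k + 1] / kin.VI
        x = M @ x
    return np.maximum(conc, 0.0)


def fasting_glucose(
    patient: VirtualPatient,
    dose_U_per_kg: float,
    insulin: str = "gla300",
    injection_phase_min: float = BREAKFAST_MIN,
    step: float = 5.0,
    settle_days: int = 8,
    gb_override: float | None = None,
) -> float:
    """Prebreakfast glucose (mg/dL) at periodic steady basal dosing.

    Simulates the fasting patient (no meals) under once-daily injections
    of ``dose_U_per_kg`` and returns glucose 15 min before the scheduled
    breakfast once day-to-day dynamics have settled.
    """
    p = patient.params
    gb = p.Gb_drive if gb_override is None else gb_override
    dose_mU = dose_U_per_kg * 1000.0
    I_day = _basal_insulin_day(p, insulin, dose_mU, injection_phase_min, step)
    n_steps = I_day.size
    t_day = step * np.arange(n_steps)
    s_day = np.asarray(p.circadian(t_day))

    # remote insulin action: linear filter of I, iterated to periodicity
    decay = np.exp(-p.p2 * step)
    gain = p.p3 / p.p2 * (1.0 - decay)
    X = p.p3 / p.p2 * I_day[0]
    X_day = np.empty(n_steps)
    for _ in range(settle_days):
        for j in range(n_steps):
            X_day[j] = X
            X = X * decay + gain * I_day[j]

    # glucose: exponential integrator, affine in gb
    a = p.p1 + X_day * s_day
    ea = np.exp(-a * step)
    G = gb  # any positive start; periodic limit is independent of it
    for _ in range(settle_days):
        for j in range(n_steps):
            G = G * ea[j] + (p.p1 * gb / a[j]) * (1.0 - ea[j])
    # one extra day recording the prebreakfast sample
    sample_idx = int(round(FPG_SAMPLE_MIN / step))
    for j in range(n_steps):
        if j == sample_idx:
            return float(G)
        G = G * ea[j] + (p.p1 * gb / a[j]) * (1.0 - ea[j])
    raise RuntimeError("prebreakfast sample index out of range")


def population_fpg(
    population: Sequence[VirtualPatient],
    dose_U_per_kg: float,
    insulin: str = "gla300",
    **kwargs,
) -> np.ndarray:
    return np.array(
        [fasting_glucose(p, dose_U_per_kg, insulin, **kwargs) for p in population]
    )


def derive_therapy_params(b0_U_per_kg: float, BW: float,
                          daily_cho_g: float = 190.0) -> tuple[float, float]:
    """Carbohydrate ratio (g/U) and correction factor (mg/dL/U).

    Clinical rules of thumb CR = 500/TDD and CF = 1700/TDD, with the
    total daily dose estimated self-consistently from the starting basal
    dose and the mean daily carbohydrate load:
    TDD = b0*BW + CHO/CR  =>  TDD = b0*BW / (1 - CHO/500).
    """
    if daily_cho_g >= 500.0:
        raise ValueError("daily carbohydrate load must be below 500 g")
    tdd = b0_U_per_kg * BW / (1.0 - daily_cho_g / 500.0)
    return 500.0 / tdd, 1700.0 / tdd


def calibrate_baseline(
    population: Sequence[VirtualPatient],
    b0_U_per_kg: float = 0.3,
    fpg_mean: float = 172.9,
    insulin: str = "gla300",
    seed: int = 0,
    fpg_cv: float = 0.15,
) -> list[VirtualPatient]:
    """Calibrate each subject's glucose drive to a baseline FPG target.

    Per-subject targets are lognormal around ``fpg_mean`` (15% CV by
    default) with the sample mean constrained to ``fpg_mean`` exactly.
    Because fasting glucose is affine in ``Gb_drive`` for a fixed insulin
    input, the calibration is exact and idempotent.  Therapy parameters
    (CR, CF) are derived from the starting dose at the same time.

    Modifies the population in place and returns it.
    """
    population = list(population)
    rng = np.random.default_rng(seed)
    raw = np.exp(rng.normal(0.0, fpg_cv, size=len(population)))
    targets = fpg_mean * raw / raw.mean()

    for patient, target in zip(population, targets):
        g0 = fasting_glucose(patient, b0_U_per_kg, insulin, gb_override=100.0)
        g1 = fasting_glucose(patient, b0_U_per_kg, insulin, gb_override=500.0)
        beta = (g1 - g0) / 400.0
        alpha = g0 - beta * 100.0
        gb = (target - alpha) / beta
        if not np.isfinite(gb) or gb <= 0:
            raise RuntimeError(
                f"calibration failed for {patient.subject_id}: "
                f"alpha={alpha:.2f}, beta={beta:.4f}"
            )
        patient.params.Gb_drive = float(gb)
        patient.fpg_target = float(target)
        patient.b0_U_per_kg = b0_U_per_kg
        cr, cf = derive_therapy_params(b0_U_per_kg, patient.params.BW)
        patient.params.CR = cr
        patient.params.CF = cf
    return population


def match_starting_dose(
    population: Sequence[VirtualPatient],
    insulin: str = "deg100",
    fpg_ref: float | None = None,
    bracket: tuple[float, float] = (0.02, 1.5),
    tol_mg_dl: float = 0.5,
) -> float:
    """Starting dose (U/kg) of ``insulin`` matching the reference baseline FPG.

    Scalar search over the dose so that the population mean fasting
    glucose under ``insulin`` equals the mean obtained at calibration
    (by default, re-simulated under the calibration insulin and dose).
    """
    if fpg_ref is None:
        fpg_ref = float(
            np.mean(population_fpg(population, population[0].b0_U_per_kg, "gla300"))
        )

    def gap(dose):
        return float(np.mean(population_fpg(population, dose, insulin))) - fpg_ref

    lo, hi = bracket
    g_lo, g_hi = gap(lo), gap(hi)
    if g_lo * g_hi > 0:
        raise ValueError(
            f"dose bracket {bracket} does not span the reference FPG "
            f"(gap at ends: {g_lo:.1f}, {g_hi:.1f} mg/dL)"
        )
    dose = brentq(gap, lo, hi, xtol=1e-4)
    if abs(gap(dose)) > tol_mg_dl:
        raise RuntimeError("dose matching did not reach the FPG tolerance")
    return float(dose)
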