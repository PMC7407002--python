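"""Behavioural layer of the virtual trial: meals, boluses, titration, IOV.

This module generates everything the virtual patient *does* during the
trial:

* a stochastic three-meal-per-day schedule with realistic timing jitter
  and carbohydrate-counting error;
* the standard bolus calculator (carb ratio + correction factor with a
  160 mg/dL target, insulin-on-board subtraction, 0.5 U pen rounding);
* weekly basal titration under two rule sets — rule A targets a
  prebreakfast band of 80-130 mg/dL, rule B a tighter 70-89 mg/dL band
  with stepped adjustments — with a hypoglycaemia stop condition that
  freezes dose increases once more than 7.5% of the last week was spent
  below 70 mg/dL;
* interoccasion variability (IOV): each injection's realised
  bioavailability is the subject's nominal value modulated by zero-mean
  Gaussian noise (CV 17% for Gla-300, 8.5% for Deg-100).

The default titration tables are reconstructions in the style of the
published treat-to-target algorithms the rules derive from; both tables
are configuration-overridable.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "MealEvent",
    "MealConfig",
    "BolusPolicy",
    "TitrationRule",
    "IOVSpec",
    "RULE_A",
    "RULE_B",
    "generate_meal_schedule",
    "compute_bolus",
    "iob_weight",
    "insulin_on_board",
    "titrate",
    "apply_iov",
]

MINUTES_PER_DAY = 1440


@dataclass(frozen=True)
class MealEvent:
    """A single meal with true and (mis)counted carbohydrate content."""

    time_min: float       # since trial start
    cho_true_g: float
    cho_est_g: float

    def __post_init__(self) -> None:
        if self.cho_true_g <= 0 or self.cho_est_g <= 0:
            raise ValueError("carbohydrate amounts must be positive")


@dataclass(frozen=True)
class MealConfig:
    """Daily meal pattern: breakfast 07:00, lunch 13:00, dinner 20:00."""

    times_min: tuple = (7 * 60, 13 * 60, 20 * 60)
    time_jitter_sd_min: float = 20.0
    cho_mean_g: tuple = (40.0, 70.0, 80.0)
    cho_sd_g: tuple = (10.0, 15.0, 15.0)
    cho_floor_g: float = 10.0
    carb_error_sd: float = 0.20       # relative counting error
    carb_error_clip: float = 0.50


def generate_meal_schedule(
    days: int,
    seed: int | np.random.Generator = 0,
    config: MealConfig | None = None,
) -> list[MealEvent]:
    """Three meals per day with jittered timing and counted carbohydrates.

    Timing jitter is Gaussian (clipped so meals stay ordered within the
    day); carbohydrate amounts are truncated-normal with a 10 g floor;
    the estimated amount applies an unbiased multiplicative counting
    error ``1 + eps`` with ``eps ~ N(0, 0.2)`` truncated at +/-0.5.
    Deterministic given the seed.
    """
    if days < 1:
        raise ValueError("days must be >= 1")
    cfg = config or MealConfig()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    events: list[MealEvent] = []
    for day in range(days):
        base = day * MINUTES_PER_DAY
        prev = -np.inf
        for slot, nominal in enumerate(cfg.times_min):
            jitter = rng.normal(0.0, cfg.time_jitter_sd_min)
            t = base + nominal + float(np.clip(jitter, -120.0, 120.0))
            t = max(t, prev + 5.0)  # keep strictly increasing, >= one CGM step
            prev = t
            cho = max(
                rng.normal(cfg.cho_mean_g[slot], cfg.cho_sd_g[slot]),
                cfg.cho_floor_g,
            )
            eps = float(np.clip(rng.normal(0.0, cfg.carb_error_sd),
                                -cfg.carb_error_clip, cfg.carb_error_clip))
            events.append(MealEvent(t, cho, max(cho * (1.0 + eps), 1.0)))
    return events


@dataclass(frozen=True)
class BolusPolicy:
    """Prandial bolus calculator parameters for one subject."""

    CR: float                  # carbohydrate ratio, g/U
    CF: float                  # correction factor, mg/dL per U
    G_target: float = 160.0    # mg/dL
    DIA: float = 240.0         # insulin action duration for IOB, min

    def __post_init__(self) -> None:
        if self.CR <= 0 or self.CF <= 0 or self.G_target <= 0 or self.DIA <= 0:
            raise ValueError("bolus policy parameters must be positive")


def compute_bolus(
    g_pre: float, cho_est_g: float, policy: BolusPolicy, iob_U: float = 0.0
) -> float:
    """Optimal prandial bolus (U), clamped at zero and rounded to 0.5 U.

    B = CHO/CR + (G - G_target)/CF - IOB.
    """
    if g_pre < 0 or cho_est_g < 0 or iob_U < 0:
        raise ValueError("inputs must be nonnegative")
    raw = cho_est_g / policy.CR + (g_pre - policy.G_target) / policy.CF - iob_U
    return max(0.0, round(raw * 2.0) / 2.0)


def iob_weight(tau_min: float, dia_min: float = 240.0) -> float:
    """Fraction of a bolus still active ``tau`` minutes after injection.

    Monotone curvilinear decay ``(1 - tau/DIA)^2`` on [0, DIA], zero
    beyond: w(0) = 1, w(DIA) = 0.
    """
    if tau_min < 0:
        raise ValueError("tau must be nonnegative")
    x = 1.0 - tau_min / dia_min
    return x * x if x > 0 else 0.0


def insulin_on_board(
    bolus_history: Sequence[tuple[float, float]], t_min: float,
    dia_min: float = 240.0,
) -> float:
    """Residual bolus insulin (U) at time ``t`` from past boluses."""
    iob = 0.0
    for t_k, units in bolus_history:
        if t_k > t_min + 1e-9:
            raise ValueError("bolus history contains future events")
        iob += units * iob_weight(t_min - t_k, dia_min)
    return iob


@dataclass(frozen=True)
class TitrationRule:
    """Weekly basal-dose adjustment driven by prebreakfast SMBG.

    ``bands`` is a list of ``(lower, upper, adjustment_U)`` with
    closed-left/open-right intervals that partition (0, inf).  The
    aggregate SMBG statistic is the median of the last three prebreakfast
    readings; adjustments are applied every 7 days.
    """

    rule_id: str
    target_band: tuple[float, float]
    bands: tuple
    cadence_days: int = 7
    hypo_tolerance_pct: float = 7.5
    dose_floor_U: float = 2.0

    def __post_init__(self) -> None:
        edges = sorted(self.bands)
        lo = 0.0
        for lower, upper, _ in edges:
            if not math.isclose(lower, lo):
                raise ValueError("titration bands must partition (0, inf)")
            lo = upper
        if not math.isinf(lo):
            raise ValueError("titration bands must extend to infinity")

    def adjustment(self, smbg_median: float) -> float:
        for lower, upper, adj in self.bands:
            if lower <= smbg_median < upper:
                return adj
        raise ValueError(f"SMBG {smbg_median} outside all bands")


#: Rule A: treat-to-target 80-130 mg/dL with symmetric 3 U steps.
RULE_A = TitrationRule(
    rule_id="A",
    target_band=(80.0, 130.0),
    bands=((0.0, 80.0, -3.0), (80.0, 130.0, 0.0), (130.0, math.inf, +3.0)),
)

#: Rule B: tighter 70-89 mg/dL target with stepped adjustments.
RULE_B = TitrationRule(
    rule_id="B",
    target_band=(70.0, 89.0),
    bands=(
        (0.0, 56.0, -4.0),
        (56.0, 70.0, -2.0),
        (70.0, 90.0, 0.0),
        (90.0, 126.0, +2.0),
        (126.0, 162.0, +4.0),
        (162.0, math.inf, +6.0),
    ),
)

RULES = {"A": RULE_A, "B": RULE_B}


def titrate(
    rule: TitrationRule,
    smbg_readings: Sequence[float],
    current_dose_U: float,
    hypo_fraction_pct: float,
) -> float:
    """New basal dose (U) after one weekly titration step.

    Uses the median of the last three prebreakfast readings.  If the
    fraction of time below 70 mg/dL over the past week exceeds the
    tolerance, dose *increases* are suppressed (decreases still apply).
    The dose is rounded to 1 U with a 2 U floor.
    """
    if len(smbg_readings) < 3:
        warnings.warn("fewer than 3 prebreakfast readings: dose unchanged",
                      stacklevel=2)
        return current_dose_U
    aggregate = float(np.median(np.asarray(smbg_readings, dtype=float)[-3:]))
    adj = rule.adjustment(aggregate)
    if hypo_fraction_pct > rule.hypo_tolerance_pct and adj > 0:
        adj = 0.0
    return max(rule.dose_floor_U, round(current_dose_U + adj))


@dataclass(frozen=True)
class IOVSpec:
    """Interoccasion CV on bioavailability per insulin formulation."""

    cv: dict = field(default_factory=lambda: {"gla300": 0.17, "deg100": 0.085})

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.cv.values()):
            raise ValueError("IOV coefficients of variation must be >= 0")

    def cv_for(self, insulin: str) -> float:
        return self.cv[insulin]


def apply_iov(
    f_nominal: float, cv: float, rng: np.random.Generator,
    floor_factor: float = 0.1,
) -> float:
    """Realised bioavailability for one injection.

    ``F_inj = F_nominal * max(floor, 1 + eps)`` with ``eps ~ N(0, cv)``;
    the floor guards against nonphysical negative draws (negligible
    truncation at the CVs in use).
    """
    if cv < 0:
        raise ValueError("cv must be nonnegative")
    if cv == 0:
        return f_nominal
    return f_nominal * max(floor_factor, 1.0 + rng.normal(0.0, cv))
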