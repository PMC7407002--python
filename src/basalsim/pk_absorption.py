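"""Subcutaneous absorption models for long-acting basal insulins.

Two depot structures are provided:

* **Degludec 100 U/mL (Deg-100)** — a three-compartment series chain.  The
  injected dose enters the first compartment (multihexamer depot), converts
  through two molecular-complex stages with a common rate constant ``kd``
  (the two conversion rates are indistinguishable in clamp data and are
  constrained equal), and is absorbed to plasma from the third compartment
  with rate ``ka``.  The model describes the *free active* insulin, i.e.
  the small fraction not bound to albumin.

* **Glargine 300 U/mL (Gla-300)** — a precipitate/dissolution structure: a
  fraction ``p_diss`` of the dose enters a dissolved compartment directly,
  the rest precipitates at the injection site and redissolves with rate
  ``kp``; dissolved insulin is absorbed with rate ``ka_g``.  Rate values
  for Gla-300 are calibration constants of this package, exposed through
  configuration.

Both systems are linear, so multidose simulation uses exact
matrix-exponential propagation between bolus injections; doses are
instantaneous mass additions scaled by the per-injection realised
bioavailability.  Units: masses in mU/kg, rates in 1/min, plasma rate of
appearance RaI in mU/kg/min.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from ._linear import impulse_train_grid, periodic_predose_state, step_matrix

__all__ = [
    "DegAbsorptionParams",
    "GlaAbsorptionParams",
    "DoseSchedule",
    "RaSeries",
    "deg_sc_rates",
    "gla_sc_rates",
    "simulate_sc_multidose",
    "write_ra_series",
]


class ParameterError(ValueError):
    """Raised when a PK parameter violates its admissible range."""


@dataclass(frozen=True)
class DegAbsorptionParams:
    """Degludec subcutaneous absorption parameters.

    F
        Bioavailability fraction of the free-active dose (dimensionless).
        Values slightly above 1 can arise transiently under interoccasion
        perturbation; a hard cap of 1.5 is enforced.
    kd
        Molecular-complex conversion rate for both chain stages (1/min).
    ka
        Absorption rate from the last depot compartment to plasma (1/min).
    """

    F: float
    kd: float
    ka: float

    def __post_init__(self) -> None:
        if not (self.F > 0 and self.kd > 0 and self.ka > 0):
            raise ParameterError("F, kd, ka must all be strictly positive")
        if self.F > 1.5:
            raise ParameterError(f"bioavailability F={self.F} exceeds cap 1.5")

    def matrix(self) -> np.ndarray:
        """System matrix of the depot chain Q1 -> Q2 -> Q3 -> plasma."""
        kd, ka = self.kd, self.ka
        return np.array(
            [[-kd, 0.0, 0.0], [kd, -kd, 0.0], [0.0, kd, -ka]]
        )

    @property
    def n_compartments(self) -> int:
        return 3

    def dose_vector(self, dose: float, f_inj: float) -> np.ndarray:
        return np.array([f_inj * dose, 0.0, 0.0])

    def ra(self, state: np.ndarray) -> float | np.ndarray:
        return self.ka * np.asarray(state)[..., 2]


@dataclass(frozen=True)
class GlaAbsorptionParams:
    """Glargine precipitate/dissolution absorption parameters.

    A fraction ``p_diss`` of each dose bypasses the precipitate and enters
    the dissolved pool directly.  The shipped Gla-300 defaults give a
    day-8 profile flatter than degludec's with a broad peak; they are
    calibration constants of this simulator, not literature estimates.
    """

    F: float = 0.70
    p_diss: float = 0.10
    kp: float = 0.0008
    ka_g: float = 0.0009
    formulation: str = "Gla-300"

    def __post_init__(self) -> None:
        if not (self.F > 0 and self.kp > 0 and self.ka_g > 0):
            raise ParameterError("F, kp, ka_g must all be strictly positive")
        if not 0.0 <= self.p_diss <= 1.0:
            raise ParameterError("p_diss must lie in [0, 1]")
        if self.formulation not in ("Gla-100", "Gla-300"):
            raise ParameterError(f"unknown formulation {self.formulation!r}")

    def matrix(self) -> np.ndarray:
        """System matrix for [precipitate P, dissolved S]."""
        return np.array([[-self.kp, 0.0], [self.kp, -self.ka_g]])

    @property
    def n_compartments(self) -> int:
        return 2

    def dose_vector(self, dose: float, f_inj: float) -> np.ndarray:
        return np.array(
            [f_inj * (1.0 - self.p_diss) * dose, f_inj * self.p_diss * dose]
        )

    def ra(self, state: np.ndarray) -> float | np.ndarray:
        return self.ka_g * np.asarray(state)[..., 1]


@dataclass
class DoseSchedule:
    """Timed subcutaneous bolus injections.

    times_min
        Injection times since trial start (min), strictly increasing.
    doses
        Administered doses (mU/kg), nonnegative.
    f_inj
        Realised bioavailability per injection; defaults to the nominal
        parameter ``F`` when built through :meth:`daily`.
    """

    times_min: np.ndarray
    doses: np.ndarray
    f_inj: np.ndarray

    def __post_init__(self) -> None:
        self.times_min = np.asarray(self.times_min, dtype=float)
        self.doses = np.asarray(self.doses, dtype=float)
        self.f_inj = np.asarray(self.f_inj, dtype=float)
        if self.times_min.size:
            if np.any(np.diff(self.times_min) <= 0):
                raise ValueError("dose times must be strictly increasing")
            if np.any(self.doses < 0):
                raise ValueError("doses must be nonnegative")
        if not (self.times_min.size == self.doses.size == self.f_inj.size):
            raise ValueError("times, doses and f_inj must have equal length")

    @classmethod
    def daily(
        cls,
        n_days: int,
        dose: float,
        f_inj: float | Sequence[float],
        start: float = 0.0,
        interval: float = 1440.0,
    ) -> "DoseSchedule":
        """Once-daily dosing of ``dose`` mU/kg for ``n_days`` days."""
        times = start + interval * np.arange(n_days)
        doses = np.full(n_days, float(dose))
        f = np.broadcast_to(np.asarray(f_inj, dtype=float), (n_days,)).copy()
        return cls(times, doses, f)

    @classmethod
    def empty(cls) -> "DoseSchedule":
        return cls(np.array([]), np.array([]), np.array([]))


@dataclass
class RaSeries:
    """Plasma rate of appearance sampled on a uniform time grid."""

    times_min: np.ndarray
    ra: np.ndarray                 # mU/kg/min
    states: np.ndarray = field(repr=False)  # (n, k) depot masses, mU/kg
    injected_mass: float = 0.0     # sum of F_inj * D, mU/kg

    @property
    def step(self) -> float:
        return float(self.times_min[1] - self.times_min[0])

    def absorbed_mass(self) -> float:
        """Mass absorbed to plasma by the end of the grid (exact balance)."""
        return self.injected_mass - float(self.states[-1].sum())


def deg_sc_rates(
    state: np.ndarray, params: DegAbsorptionParams, dose_rate: float = 0.0,
    f_inj: float | None = None,
):
    """Right-hand side of the degludec depot chain.

    ``dose_rate`` is an optional continuous infusion (mU/kg/min) entering
    the first compartment scaled by the realised bioavailability ``f_inj``
    (defaults to the nominal ``F``).  Returns ``(derivatives, RaI)``.
    """
    q = np.asarray(state, dtype=float)
    if q.shape != (3,):
        raise ValueError("degludec depot state has three compartments")
    if dose_rate < 0:
        raise ValueError("dose_rate must be nonnegative")
    f = params.F if f_inj is None else f_inj
    dq = params.matrix() @ q
    dq[0] += f * dose_rate
    return dq, params.ka * q[2]


def gla_sc_rates(
    state: np.ndarray, params: GlaAbsorptionParams, dose_rate: float = 0.0,
    f_inj: float | None = None,
):
    """Right-hand side of the glargine precipitate/dissolution model."""
    x = np.asarray(state, dtype=float)
    if x.shape != (2,):
        raise ValueError("glargine depot state has two compartments")
    if dose_rate < 0:
        raise ValueError("dose_rate must be nonnegative")
    f = params.F if f_inj is None else f_inj
    dx = params.matrix() @ x
    dx[0] += f * (1.0 - params.p_diss) * dose_rate
    dx[1] += f * params.p_diss * dose_rate
    return dx, params.ka_g * x[1]


def simulate_sc_multidose(
    params: DegAbsorptionParams | GlaAbsorptionParams,
    schedule: DoseSchedule,
    horizon_min: float,
    step_min: float = 1.0,
    initial_state: np.ndarray | None = None,
) -> RaSeries:
    """Simulate RaI under a multidose schedule on a uniform grid.

    Doses are applied as instantaneous mass additions at the nearest grid
    point (injections must align with the grid to within half a step).
    Propagation between grid points is exact for the linear depot system.
    """
    if step_min <= 0 or step_min > 5.0:
        raise ValueError("step must be positive and at most 5 min")
    if horizon_min <= 0:
        raise ValueError("horizon must be positive")
    n_steps = int(round(horizon_min / step_min))
    times = step_min * np.arange(n_steps + 1)

    impulses: dict[int, np.ndarray] = {}
    injected = 0.0
    for t, d, f in zip(schedule.times_min, schedule.doses, schedule.f_inj):
        idx = int(round(t / step_min))
        if abs(idx * step_min - t) > step_min / 2 + 1e-9 or not (0 <= idx <= n_steps):
            raise ValueError(f"dose at t={t} min falls outside the simulation grid")
        vec = params.dose_vector(d, f)
        impulses[idx] = impulses.get(idx, 0.0) + vec
        injected += f * d

    k = params.n_compartments
    x0 = np.zeros(k) if initial_state is None else np.asarray(initial_state, float)
    states = impulse_train_grid(params.matrix(), x0, step_min, n_steps, impulses)
    ra = np.asarray(params.ra(states), dtype=float)
    return RaSeries(times, ra, states, injected)


def predose_steady_state(
    params: DegAbsorptionParams | GlaAbsorptionParams,
    dose: float,
    f_inj: float,
    interval: float = 1440.0,
) -> np.ndarray:
    """Depot state just before a dose under an infinite once-daily train."""
    return periodic_predose_state(
        params.matrix(), params.dose_vector(dose, f_inj), interval
    )


def write_ra_series(path, series: RaSeries, subject_id: str) -> None:
    """Write an RaI series as a delimited table."""
    import pandas as pd

    pd.DataFrame(
        {
            "subject_id": subject_id,
            "time_min": series.times_min,
            "ra_mU_per_kg_min": series.ra,
        }
    ).to_csv(path, index=False)


def check_default_ordering(params: DegAbsorptionParams) -> bool:
    """Soft sanity check kd > ka expected for the default population."""
    ok = params.kd > params.ka
    if not ok:
        import warnings

        warnings.warn(
            f"kd={params.kd} <= ka={params.ka}: outside the typical "
            "degludec ordering (absorption, not conversion, rate-limiting)",
            stacklevel=2,
        )
    return ok
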