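"""Two-compartment plasma/liver free-insulin kinetics.

The model receives the subcutaneous rate of appearance RaI (mU/kg/min)
into the plasma compartment and exchanges insulin with a liver
compartment:

    dIl/dt = -(m1 + m3) * Il + m2 * Ip
    dIp/dt = -(m2 + m4) * Ip + m1 * Il + RaI
    I      = Ip / VI          (uU/mL, since mU/kg / (L/kg) = mU/L)

The four rate parameters are not separately identifiable from plasma data
alone, so m2, m3, m4 are reparameterised in terms of m1, the whole-body
plasma insulin clearance CL (L/min) and the distribution volume VI
(fixed to the population value 0.048 L/kg):

    CLk = CL / (VI * BW)                       # 1/min, fractional clearance
    m3  = m1 * HEb / (1 - HEb)                 # hepatic extraction HEb = 0.6
    m4  = (2/5) * CLk                          # peripheral share of clearance
    m2  = (3/5) * CLk * (m1 + m3) / m3         # hepatic share of clearance

which guarantees the steady-state identity  I_ss = RaI * BW / CL  (the
binding contract, tested as an invariant) and a basal hepatic extraction
of HEb.  The hepatic/peripheral 3/5-2/5 split is configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._linear import foh_input_matrices, step_matrix

__all__ = [
    "KineticsParams",
    "InsulinState",
    "derive_rate_constants",
    "kinetics_matrix",
    "simulate_plasma_insulin",
    "day8_pk_summary",
]

VI_DEFAULT = 0.048   # L/kg, population insulin distribution volume
HE_B_DEFAULT = 0.6   # basal hepatic extraction fraction
HEPATIC_SHARE = 3.0 / 5.0  # fraction of clearance routed through the liver


class DegenerateParameterError(ValueError):
    """Raised when the reparameterisation degenerates (e.g. HEb -> 0 or 1)."""


def derive_rate_constants(
    m1: float,
    CL: float,
    VI: float = VI_DEFAULT,
    BW: float = 80.0,
    HE_b: float = HE_B_DEFAULT,
    hepatic_share: float = HEPATIC_SHARE,
) -> tuple[float, float, float]:
    """Express (m2, m3, m4) as functions of m1, CL, VI.

    Returns rates in 1/min.  Raises :class:`DegenerateParameterError` for
    HE_b outside the open interval (0, 1), where m3 -> 0 and m2 diverges.
    """
    if not (m1 > 0 and CL > 0 and VI > 0 and BW > 0):
        raise ValueError("m1, CL, VI, BW must be strictly positive")
    if not 0.0 < HE_b < 1.0:
        raise DegenerateParameterError("HE_b must lie strictly inside (0, 1)")
    if not 0.0 < hepatic_share < 1.0:
        raise ValueError("hepatic_share must lie in (0, 1)")
    clk = CL / (VI * BW)
    m3 = m1 * HE_b / (1.0 - HE_b)
    m4 = (1.0 - hepatic_share) * clk
    m2 = hepatic_share * clk * (m1 + m3) / m3
    return m2, m3, m4


@dataclass(frozen=True)
class KineticsParams:
    """Plasma/liver insulin kinetics parameters for one subject.

    ``m2``, ``m3``, ``m4`` are derived on construction from
    (m1, CL, VI, BW, HE_b) and should not be set directly.
    """

    m1: float
    CL: float
    VI: float = VI_DEFAULT
    BW: float = 80.0
    HE_b: float = HE_B_DEFAULT
    hepatic_share: float = HEPATIC_SHARE
    m2: float = field(init=False)
    m3: float = field(init=False)
    m4: float = field(init=False)

    def __post_init__(self) -> None:
        m2, m3, m4 = derive_rate_constants(
            self.m1, self.CL, self.VI, self.BW, self.HE_b, self.hepatic_share
        )
        object.__setattr__(self, "m2", m2)
        object.__setattr__(self, "m3", m3)
        object.__setattr__(self, "m4", m4)

    @property
    def clk(self) -> float:
        """Fractional plasma clearance CL / (VI * BW), 1/min."""
        return self.CL / (self.VI * self.BW)


@dataclass
class InsulinState:
    """Free-insulin masses (mU/kg) in liver and plasma."""

    Il: float = 0.0
    Ip: float = 0.0

    def as_array(self) -> np.ndarray:
        return np.array([self.Il, self.Ip])


def kinetics_matrix(params: KineticsParams) -> np.ndarray:
    """System matrix for the state [Il, Ip]."""
    return np.array(
        [
            [-(params.m1 + params.m3), params.m2],
            [params.m1, -(params.m2 + params.m4)],
        ]
    )


def simulate_plasma_insulin(
    ra: np.ndarray,
    step_min: float,
    params: KineticsParams,
    initial: InsulinState | None = None,
    method: str = "exact",
) -> np.ndarray:
    """Plasma free-insulin concentration I(t) (uU/mL) from an RaI grid.

    ``ra`` is the rate of appearance (mU/kg/min) sampled on a uniform grid
    of spacing ``step_min``; the input is treated as piecewise linear
    between grid points.  ``method='exact'`` uses first-order-hold
    matrix-exponential propagation (the reference); ``method='ivp'`` uses
    an adaptive ODE solver on the same interpolated input and exists as an
    independent cross-check.
    """
    ra = np.asarray(ra, dtype=float)
    if ra.ndim != 1 or ra.size < 2:
        raise ValueError("ra must be a 1-D series with at least two samples")
    A = kinetics_matrix(params)
    b = np.array([0.0, 1.0])
    x = np.zeros(2) if initial is None else initial.as_array()

    if method == "exact":
        phi, B0, B1 = foh_input_matrices(A, b, step_min)
        out = np.empty((ra.size, 2))
        out[0] = x
        for k in range(ra.size - 1):
            x = phi @ x + B0 * ra[k] + B1 * ra[k + 1]
            out[k + 1] = x
        return out[:, 1] / params.VI
    if method == "ivp":
        from scipy.integrate import solve_ivp

        t = step_min * np.arange(ra.size)

        def rhs(ti, xi):
            rai = np.interp(ti, t, ra)
            return A @ xi + b * rai

        sol = solve_ivp(
            rhs, (t[0], t[-1]), x, t_eval=t, method="LSODA",
            rtol=1e-9, atol=1e-12,
        )
        if not sol.success:
            raise RuntimeError(f"ODE solver failed: {sol.message}")
        return sol.y[1] / params.VI
    raise ValueError(f"unknown method {method!r}")


def day8_pk_summary(
    times_min: np.ndarray,
    concentration: np.ndarray,
    dose_time_min: float,
    window_min: float = 30.0 * 60.0,
) -> tuple[float, float]:
    """Cmax (uU/mL) and Tmax (min after dose) over a post-dose window.

    The window defaults to the 30 h clamp observation period after the
    day-8 dose.  Ties in the maximum are broken by the earliest time.
    """
    times_min = np.asarray(times_min, dtype=float)
    concentration = np.asarray(concentration, dtype=float)
    if times_min[-1] + 1e-9 < dose_time_min + window_min:
        raise ValueError("series does not cover the post-dose window")
    mask = (times_min >= dose_time_min - 1e-9) & (
        times_min <= dose_time_min + window_min + 1e-9
    )
    t_win = times_min[mask]
    c_win = concentration[mask]
    idx = int(np.argmax(c_win))  # argmax returns the first maximum: earliest tie
    return float(c_win[idx]), float(t_win[idx] - dose_time_min)
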