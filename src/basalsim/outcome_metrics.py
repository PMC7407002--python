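"""CGM outcome metrics: time-in-range bands, variability, and risk indices.

All metrics operate on a uniform 5-min continuous glucose monitoring
trace covering the analysis window (the last 2 weeks of a trial).
Following the consensus convention, every metric except the 2-week
coefficient of variation is computed per day and averaged across the 14
days; CV_2weeks is a single number over the full window.

Band boundaries use a closed-left / open-right convention ([70, 140),
[70, 180)), with the hypoglycaemia and hyperglycaemia tails strict
(< 54, < 70, > 180, > 250).  This only affects samples landing exactly
on a boundary.

The low/high blood-glucose risk indices (LBGI/HBGI) use the standard
symmetrising transform of the glucose scale,

    f(g) = 1.509 * ((ln g)^1.084 - 5.381)

with risk 10*f(g)^2 attributed to the low branch when f < 0 and to the
high branch when f > 0; glucose is clamped to the validated 20-600 mg/dL
domain of the transform.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from typing import Sequence

import numpy as np

__all__ = [
    "CGMTrace",
    "OutcomeSet",
    "time_in_ranges",
    "bg_risk_indices",
    "cv_2weeks",
    "summarize_outcomes",
    "fraction_cv_below",
    "write_cgm_trace",
    "read_cgm_traces",
    "write_outcome_table",
]

SAMPLES_PER_DAY = 288  # 5-min sampling


@dataclass
class CGMTrace:
    """Uniform 5-min glucose series for one subject over whole days."""

    subject_id: str
    glucose: np.ndarray            # mg/dL
    start_time_min: float = 0.0
    step_min: float = 5.0

    def __post_init__(self) -> None:
        self.glucose = np.asarray(self.glucose, dtype=float)
        if self.glucose.size == 0:
            raise ValueError("empty CGM trace")
        if np.any(~np.isfinite(self.glucose)) or np.any(self.glucose <= 0):
            raise ValueError("CGM trace must be finite and strictly positive")
        if self.glucose.size % SAMPLES_PER_DAY != 0:
            raise ValueError(
                f"trace length {self.glucose.size} is not a whole number of "
                f"days at 5-min sampling"
            )

    @property
    def n_days(self) -> int:
        return self.glucose.size // SAMPLES_PER_DAY

    def daily(self) -> np.ndarray:
        """Glucose reshaped to (n_days, 288)."""
        return self.glucose.reshape(self.n_days, SAMPLES_PER_DAY)


@dataclass
class OutcomeSet:
    """Per-subject glycaemic outcome metrics over the analysis window."""

    mean: float          # mg/dL, daily means averaged
    sd: float            # mg/dL, within-day SD averaged across days
    cv_2weeks: float     # %, single full-window number
    t_b54: float         # % time < 54 mg/dL
    t_b70: float         # % time < 70 mg/dL
    t_t70_140: float     # % time in [70, 140)  (primary outcome)
    t_t70_180: float     # % time in [70, 180)
    t_a180: float        # % time > 180 mg/dL
    t_a250: float        # % time > 250 mg/dL
    lbgi: float
    hbgi: float

    def as_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    @staticmethod
    def metric_names() -> list[str]:
        return [f.name for f in fields(OutcomeSet)]


def time_in_ranges(trace: CGMTrace) -> dict:
    """Percent time per glucose band, daily values averaged across days."""
    g = trace.daily()
    pct = lambda mask: float(np.mean(mask.mean(axis=1)) * 100.0)
    return {
        "t_b54": pct(g < 54.0),
        "t_b70": pct(g < 70.0),
        "t_t70_140": pct((g >= 70.0) & (g < 140.0)),
        "t_t70_180": pct((g >= 70.0) & (g < 180.0)),
        "t_a180": pct(g > 180.0),
        "t_a250": pct(g > 250.0),
    }


def _risk_transform(g: np.ndarray) -> np.ndarray:
    g = np.clip(g, 20.0, 600.0)
    return 1.509 * (np.log(g) ** 1.084 - 5.381)


def bg_risk_indices(trace: CGMTrace) -> tuple[float, float]:
    """(LBGI, HBGI): daily risk means averaged across the window."""
    if np.any(trace.glucose <= 0):
        raise ValueError("glucose must be strictly positive")
    f = _risk_transform(trace.daily())
    rl = np.where(f < 0, 10.0 * f**2, 0.0)
    rh = np.where(f > 0, 10.0 * f**2, 0.0)
    return float(rl.mean(axis=1).mean()), float(rh.mean(axis=1).mean())


def cv_2weeks(trace: CGMTrace) -> float:
    """Full-window coefficient of variation of glucose, percent."""
    g = trace.glucose
    return float(100.0 * g.std(ddof=0) / g.mean())


def summarize_outcomes(trace: CGMTrace) -> OutcomeSet:
    g = trace.daily()
    bands = time_in_ranges(trace)
    lbgi, hbgi = bg_risk_indices(trace)
    return OutcomeSet(
        mean=float(g.mean(axis=1).mean()),
        sd=float(g.std(axis=1, ddof=0).mean()),
        cv_2weeks=cv_2weeks(trace),
        lbgi=lbgi,
        hbgi=hbgi,
        **bands,
    )


def fraction_cv_below(outcomes: Sequence[OutcomeSet], threshold: float = 36.0) -> float:
    """Percent of subjects whose CV_2weeks lies below ``threshold``."""
    if len(outcomes) == 0:
        raise ValueError("need at least one subject")
    below = sum(1 for o in outcomes if o.cv_2weeks < threshold)
    return 100.0 * below / len(outcomes)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def write_cgm_trace(path, trace: CGMTrace) -> None:
    import pandas as pd

    t = trace.start_time_min + trace.step_min * np.arange(trace.glucose.size)
    pd.DataFrame(
        {"subject_id": trace.subject_id, "time_min": t,
         "glucose_mg_dl": trace.glucose}
    ).to_csv(path, index=False)


def read_cgm_traces(path) -> list[CGMTrace]:
    import pandas as pd

    df = pd.read_csv(path)
    out = []
    for sid, grp in df.groupby("subject_id", sort=False):
        out.append(
            CGMTrace(
                subject_id=str(sid),
                glucose=grp["glucose_mg_dl"].to_numpy(),
                start_time_min=float(grp["time_min"].iloc[0]),
            )
        )
    return out


def write_outcome_table(path, outcomes: dict[str, OutcomeSet], arm: str = "") -> None:
    """One row per subject; columns named after the reported metrics."""
    import pandas as pd

    rows = []
    for sid, o in outcomes.items():
        row = {"subject_id": sid}
        if arm:
            row["arm"] = arm
        row.update(o.as_dict())
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)
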