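"""Per-stratum annual cardiovascular-risk paths.

The 10-year risk score observed in the trial (year 0 baseline, year 1 the
12-month follow-up score adjusted for baseline) is extrapolated over age
with male risk growth rates (used for both sexes, which keeps female risk
below male risk at all ages and keeps paths below 100%), switching beyond
age 84 — where the risk score is not validated — to a fixed +1 percentage
point per year on the 10-year score.  Each year's 10-year risk is converted
to an annual any-event probability under a constant-hazard assumption and
split into event-specific probabilities with age/sex incidence shares.

The duration-of-effect scenario decides for how many model years the
intervention arm keeps its own (lower) risk path before reverting to the
control path, with a one-year averaging step to avoid a jump in risk.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .synthetic_data import CohortStratum, ParameterSet

#: duration-of-effect scenarios: model years of retained benefit
SCENARIOS: dict[str, Optional[int]] = {"1y": 1, "2y": 2, "5y": 5, "lifetime": None}


@dataclass(frozen=True)
class EffectScenario:
    """Duration of intervention effect: 1, 2 or 5 model years, or lifetime
    (``duration=None``)."""

    duration: Optional[int]

    def __post_init__(self) -> None:
        if self.duration not in (1, 2, 5, None):
            raise ValueError(f"duration must be 1, 2, 5 or None, got {self.duration}")

    @property
    def label(self) -> str:
        return "lifetime" if self.duration is None else f"{self.duration}y"

    @classmethod
    def from_label(cls, label: str) -> "EffectScenario":
        if label not in SCENARIOS:
            raise ValueError(f"unknown scenario {label!r}; expected one of {list(SCENARIOS)}")
        return cls(SCENARIOS[label])


@dataclass(eq=False)
class RiskTrajectory:
    """One stratum's risk path under one scenario: per model year the
    attained age, the 10-year risk and the annual any-event probability."""

    stratum: CohortStratum
    scenario: str
    years: np.ndarray
    ages: np.ndarray
    r10: np.ndarray
    p_annual: np.ndarray


def extrapolate_r10(
    stratum: CohortStratum, params: ParameterSet, horizon: int
) -> np.ndarray:
    """10-year risk for model years 0..horizon.

    Year 0 is the baseline score and year 1 the adjusted 12-month score;
    thereafter risk grows multiplicatively by the male growth rate at the
    attained age while under 85, and by +0.01 (one percentage point on the
    10-year score) per year from 85 on.  Risk is capped at 1.
    """
    if horizon <= 0:
        raise ValueError(f"horizon must be positive, got {horizon}")
    r10 = np.empty(horizon + 1)
    r10[0] = stratum.baseline_r10
    if horizon >= 1:
        r10[1] = stratum.followup_r10
    for t in range(2, horizon + 1):
        age = stratum.age0 + t
        if age < 85:
            r10[t] = min(1.0, r10[t - 1] * (1.0 + params.growth(age)))
        else:
            r10[t] = min(1.0, r10[t - 1] + 0.01)
    return r10


def apply_effect_scenario(
    intv_path: Sequence[float],
    ctrl_path: Sequence[float],
    scenario: EffectScenario,
) -> np.ndarray:
    """Intervention-arm risk path under a duration-of-effect scenario.

    For a finite duration D: model years 1..D keep the intervention path;
    year D+1 is the average of the two paths (smoothing the reversion);
    later years follow the control path.  Year 0 is never touched (year-0
    outcomes are trial-observed, not simulated).  A lifetime duration
    returns the intervention path unchanged.
    """
    intv = np.asarray(intv_path, dtype=float)
    ctrl = np.asarray(ctrl_path, dtype=float)
    if intv.shape != ctrl.shape:
        raise ValueError(f"path length mismatch: {intv.shape} vs {ctrl.shape}")
    if scenario.duration is None:
        return intv.copy()
    d = scenario.duration
    out = ctrl.copy()
    out[0] = intv[0]
    out[1 : d + 1] = intv[1 : d + 1]
    if d + 1 < len(out):
        out[d + 1] = 0.5 * (intv[d + 1] + ctrl[d + 1])
    return out


def annualize(r10):
    """Annual any-event probability from 10-year risk under a constant
    hazard: ``1 - (1 - r10)**(1/10)``; monotone and order-preserving."""
    r = np.asarray(r10, dtype=float)
    if np.any(r < 0) or np.any(r > 1):
        raise ValueError("10-year risk must lie in [0, 1]")
    out = 1.0 - (1.0 - r) ** 0.1
    return float(out) if np.isscalar(r10) else out


def split_events(
    p_annual: float, age: float, sex: str, params: ParameterSet
) -> dict[str, float]:
    """Split an annual any-event probability into event-specific
    probabilities using the incidence shares for the age band and sex; the
    outputs sum to ``p_annual``."""
    if not (0.0 <= p_annual <= 1.0):
        raise ValueError(f"annual probability must lie in [0, 1], got {p_annual}")
    shares = params.incidence(sex, age)
    return {event: p_annual * share for event, share in shares.items()}


def build_trajectory(
    stratum: CohortStratum,
    params: ParameterSet,
    scenario: EffectScenario,
    ctrl_stratum: Optional[CohortStratum] = None,
    horizon: Optional[int] = None,
) -> RiskTrajectory:
    """Full risk path for one stratum.

    For an intervention stratum the matching control stratum (same sex)
    must be supplied so the duration-of-effect reversion has a control path
    to revert to.  Horizon defaults to age 100.
    """
    t_max = horizon if horizon is not None else 100 - stratum.age0
    r10 = extrapolate_r10(stratum, params, t_max)
    if stratum.arm == "intervention":
        if ctrl_stratum is None:
            raise ValueError("intervention stratum needs its matching control stratum")
        ctrl = extrapolate_r10(ctrl_stratum, params, t_max)
        r10 = apply_effect_scenario(r10, ctrl, scenario)
    years = np.arange(t_max + 1)
    return RiskTrajectory(
        stratum=stratum,
        scenario=scenario.label,
        years=years,
        ages=stratum.age0 + years,
        r10=r10,
        p_annual=annualize(r10),
    )
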