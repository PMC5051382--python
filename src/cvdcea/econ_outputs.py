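"""Decision metrics from PSA output: ICER, NMB, CEACs, CE-plane quadrants.

Conventions: the ICER is reported from mean increments (ratio of means,
the convention consistent with per-patient average tables), with dominance
labels replacing the ratio when its sign would mislead.  The CEAC at a
threshold λ is the fraction of PSA iterations with positive net monetary
benefit λ·ΔQ − ΔC.  Both percentile (2.5/97.5) and SE-of-the-mean 95%
intervals are reported, percentile as the headline.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence, Union

import numpy as np
import pandas as pd

from .psa import PSAResult

ICERValue = Union[float, str]

DOMINANT = "dominant"
DOMINATED = "dominated"
INDIFFERENT = "indifferent"

HEADLINE_THRESHOLDS = (20000.0, 30000.0)


def icer(delta_cost: float, delta_qaly: float) -> ICERValue:
    """Incremental cost-effectiveness ratio, or a dominance label.

    ``dominant`` (cheaper and more effective) and ``dominated`` (dearer
    and less effective) replace ratios whose sign would mislead; a zero
    QALY difference yields ``indifferent`` or a signed-infinity label.
    """
    if delta_qaly == 0.0:
        if delta_cost == 0.0:
            return INDIFFERENT
        return "+inf" if delta_cost > 0 else "-inf"
    if delta_cost <= 0.0 and delta_qaly > 0.0:
        return DOMINANT if delta_cost < 0.0 else 0.0
    if delta_cost > 0.0 and delta_qaly < 0.0:
        return DOMINATED
    return delta_cost / delta_qaly


def nmb(threshold: float, delta_cost: float, delta_qaly: float) -> float:
    """Net monetary benefit at willingness-to-pay ``threshold``."""
    if threshold < 0:
        raise ValueError(f"threshold must be >= 0, got {threshold}")
    return threshold * delta_qaly - delta_cost


def ceac(result: PSAResult, thresholds: Sequence[float]) -> pd.DataFrame:
    """Probability of cost-effectiveness per threshold: the fraction of
    iterations with strictly positive net monetary benefit."""
    grid = np.asarray(thresholds, dtype=float)
    if grid.size == 0:
        raise ValueError("empty threshold grid")
    dc = result.delta_cost
    dq = result.delta_qaly
    prob = [(t * dq - dc > 0).mean() for t in grid]
    return pd.DataFrame({"threshold": grid, "prob_ce": prob})


def plane_quadrants(result: PSAResult) -> dict[str, float]:
    """Shares of (ΔQALY, ΔCost) pairs per cost-effectiveness-plane
    quadrant.  Axis-exact points go to the costlier / less-effective side
    (ΔQ = 0 counts as not more effective; ΔC = 0 counts as costlier)."""
    dq = result.delta_qaly
    dc = result.delta_cost
    q_pos = dq > 0
    c_pos = dc >= 0
    n = len(dq)
    return {
        "NE": float((q_pos & c_pos).sum()) / n,
        "SE": float((q_pos & ~c_pos).sum()) / n,
        "NW": float((~q_pos & c_pos).sum()) / n,
        "SW": float((~q_pos & ~c_pos).sum()) / n,
    }


def _intervals(x: np.ndarray) -> dict[str, tuple[float, float]]:
    lo, hi = np.percentile(x, [2.5, 97.5])
    se = x.std(ddof=1) / np.sqrt(len(x)) if len(x) > 1 else 0.0
    m = x.mean()
    return {
        "percentile": (float(lo), float(hi)),
        "se": (float(m - 1.96 * se), float(m + 1.96 * se)),
    }


@dataclass(eq=False)
class EconSummary:
    """Decision summary for one duration-of-effect scenario."""

    scenario: str
    n_iter: int
    mean_control_cost: float
    mean_intervention_cost: float
    mean_control_qaly: float
    mean_intervention_qaly: float
    delta_cost: float
    delta_qaly: float
    icer: ICERValue
    nmb: dict[float, float]                 # threshold -> NMB of the means
    prob_ce: dict[float, float]             # threshold -> P(NMB_i > 0)
    ci_delta_cost: dict[str, tuple[float, float]]
    ci_delta_qaly: dict[str, tuple[float, float]]
    ci_nmb: dict[float, dict[str, tuple[float, float]]]
    quadrants: dict[str, float]
    ceac: pd.DataFrame = field(repr=False, default=None)


def summarize(
    result: PSAResult, thresholds: Sequence[float] | None = None
) -> EconSummary:
    """Means, increments, ICER, NMB, intervals, CEAC and quadrant shares
    for one PSA run."""
    if thresholds is None:
        thresholds = np.arange(0, 50001, 500, dtype=float)
    grid = np.asarray(thresholds, dtype=float)
    d = result.data
    dc = result.delta_cost
    dq = result.delta_qaly
    mdc, mdq = float(dc.mean()), float(dq.mean())
    curve = ceac(result, grid)
    prob = dict(zip(curve["threshold"], curve["prob_ce"]))
    return EconSummary(
        scenario=result.scenario,
        n_iter=result.n_iter,
        mean_control_cost=float(d["control_cost"].mean()),
        mean_intervention_cost=float(d["intervention_cost"].mean()),
        mean_control_qaly=float(d["control_qaly"].mean()),
        mean_intervention_qaly=float(d["intervention_qaly"].mean()),
        delta_cost=mdc,
        delta_qaly=mdq,
        icer=icer(mdc, mdq),
        nmb={t: nmb(t, mdc, mdq) for t in HEADLINE_THRESHOLDS},
        prob_ce={
            t: float(prob[t]) if t in prob else float((t * dq - dc > 0).mean())
            for t in HEADLINE_THRESHOLDS
        },
        ci_delta_cost=_intervals(dc),
        ci_delta_qaly=_intervals(dq),
        ci_nmb={t: _intervals(t * dq - dc) for t in HEADLINE_THRESHOLDS},
        quadrants=plane_quadrants(result),
        ceac=curve,
    )


def _fmt_ci(ci: tuple[float, float], digits: int = 0) -> str:
    return f"({ci[0]:.{digits}f} to {ci[1]:.{digits}f})"


def summary_table(summaries: Sequence[EconSummary]) -> pd.DataFrame:
    """Per-patient average costs and effects by scenario, one column per
    duration of effect, mirroring the standard base-case layout."""
    rows = {
        "Control arm NHS costs": lambda s: f"£{s.mean_control_cost:.0f}",
        "Intervention arm NHS costs": lambda s: f"£{s.mean_intervention_cost:.0f}",
        "Control arm QALYs": lambda s: f"{s.mean_control_qaly:.3f}",
        "Intervention arm QALYs": lambda s: f"{s.mean_intervention_qaly:.3f}",
        "Incremental costs (95% CI)": lambda s: (
            f"£{s.delta_cost:.0f} {_fmt_ci(s.ci_delta_cost['percentile'])}"
        ),
        "Incremental QALYs (95% CI)": lambda s: (
            f"{s.delta_qaly:.3f} ({s.ci_delta_qaly['percentile'][0]:.3f} to "
            f"{s.ci_delta_qaly['percentile'][1]:.3f})"
        ),
        "ICER": lambda s: s.icer if isinstance(s.icer, str) else f"£{s.icer:.0f}",
        "Probability cost-effective at £20000": lambda s: f"{s.prob_ce[20000.0]:.2f}",
        "Probability cost-effective at £30000": lambda s: f"{s.prob_ce[30000.0]:.2f}",
        "NMB at £20000 (95% CI)": lambda s: (
            f"£{s.nmb[20000.0]:.0f} {_fmt_ci(s.ci_nmb[20000.0]['percentile'])}"
        ),
    }
    out = {s.scenario: {label: f(s) for label, f in rows.items()} for s in summaries}
    return pd.DataFrame(out)


def plane_frame(result: PSAResult) -> pd.DataFrame:
    """Plot-ready CE-plane points (scenario, iteration, delta_qaly,
    delta_cost)."""
    return pd.DataFrame(
        {
            "scenario": result.scenario,
            "iteration": result.data["iteration"],
            "delta_qaly": result.delta_qaly,
            "delta_cost": result.delta_cost,
        }
    )
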