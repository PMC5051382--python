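"""Deterministic cohort trace, half-cycle correction, discounting.

A cohort (default 1000 patients) starts event-free and is propagated
through the per-cycle transition tables until age 100.  Costs and QALYs
are accrued per cycle on the trapezoidal average of the occupancy at the
cycle's start and end (the standard half-cycle correction) and discounted
at 3.5% per year with cycle ``t`` weighted ``(1 + rate)**-t``.  Cycle 0 is
special: its cost and QALY accruals are replaced by the trial-observed
year-0 values of the stratum (which already include the intervention
cost), undiscounted; simulated dynamics take over from cycle 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .state_space import ExpandedSpace
from .synthetic_data import CohortStratum
from .transition_model import TransitionTable

CONSERVATION_TOL = 1e-8


@dataclass(eq=False)
class CohortTrace:
    """Occupancy of every expanded state at every cycle 0..T."""

    occupancy: np.ndarray  # (T+1, n_states)
    space: Optional[ExpandedSpace] = None

    @property
    def n_cycles(self) -> int:
        return self.occupancy.shape[0] - 1

    @property
    def cohort_size(self) -> float:
        return float(self.occupancy[0].sum())


@dataclass(eq=False)
class ArmResult:
    """Per-person lifetime outcomes for one stratum under one draw."""

    discounted_cost: float
    discounted_qalys: float
    undiscounted_cost: float
    undiscounted_qalys: float
    cycles: pd.DataFrame  # cycle, cost, qaly, discount_factor (cohort totals)
    cohort_size: float


def _table_matrix(t) -> np.ndarray:
    return t.matrix if isinstance(t, TransitionTable) else np.asarray(t, dtype=float)


def run_trace(
    initial: np.ndarray,
    tables: Sequence,
    T: Optional[int] = None,
    space: Optional[ExpandedSpace] = None,
) -> CohortTrace:
    """Propagate an initial occupancy vector through T per-cycle tables.

    ``tables`` may hold :class:`TransitionTable` objects or raw matrices;
    conservation of cohort mass is asserted at every cycle.
    """
    initial = np.asarray(initial, dtype=float)
    n_cycles = len(tables) if T is None else T
    if n_cycles > len(tables):
        raise ValueError(f"{n_cycles} cycles requested but only {len(tables)} tables")
    total = initial.sum()
    occ = np.empty((n_cycles + 1, initial.size))
    occ[0] = initial
    for t in range(n_cycles):
        occ[t + 1] = occ[t] @ _table_matrix(tables[t])
        if abs(occ[t + 1].sum() - total) > CONSERVATION_TOL * max(1.0, total):
            raise ValueError(
                f"cohort mass not conserved at cycle {t + 1}: "
                f"{occ[t + 1].sum()!r} vs {total!r}"
            )
    return CohortTrace(occupancy=occ, space=space)


def _per_cycle_values(values, n_cycles: int, n_states: int) -> np.ndarray:
    """Broadcast a static state-value vector or accept a (T, n) array."""
    arr = np.asarray(values, dtype=float)
    if arr.ndim == 1:
        if arr.size != n_states:
            raise ValueError(f"value vector length {arr.size} != {n_states} states")
        return np.broadcast_to(arr, (n_cycles, n_states))
    if arr.shape != (n_cycles, n_states):
        raise ValueError(f"value array shape {arr.shape} != ({n_cycles}, {n_states})")
    return arr


def accumulate(
    trace: CohortTrace,
    costs,
    utilities,
    stratum: Optional[CohortStratum] = None,
    discount_rate: float = 0.035,
    year0_override: bool = True,
) -> ArmResult:
    """Lifetime discounted costs and QALYs from a cohort trace.

    ``costs`` is a per-state cost vector (GBP per cycle); ``utilities`` is
    either a per-state utility vector or a (T, n_states) array when
    utilities vary with attained age.  With a ``stratum`` and
    ``year0_override`` the cycle-0 accruals are replaced by the stratum's
    trial-observed year-0 cost and QALYs.
    """
    occ = trace.occupancy
    n_cycles, n_states = occ.shape[0] - 1, occ.shape[1]
    cost_cy = _per_cycle_values(costs, n_cycles, n_states)
    util_cy = _per_cycle_values(utilities, n_cycles, n_states)
    if np.any(cost_cy < 0):
        raise ValueError("negative state cost")
    if np.any(util_cy < 0) or np.any(util_cy > 1):
        raise ValueError("state utility outside [0, 1]")

    eff = 0.5 * (occ[:-1] + occ[1:])  # half-cycle (trapezoidal) occupancy
    cost_t = np.einsum("tn,tn->t", eff, cost_cy)
    qaly_t = np.einsum("tn,tn->t", eff, util_cy)
    size = trace.cohort_size

    if stratum is not None and year0_override and n_cycles >= 1:
        cost_t[0] = stratum.year0_cost * size
        qaly_t[0] = stratum.year0_qaly * size

    df = (1.0 + discount_rate) ** (-np.arange(n_cycles, dtype=float))
    cycles = pd.DataFrame(
        {
            "cycle": np.arange(n_cycles),
            "cost": cost_t,
            "qaly": qaly_t,
            "discount_factor": df,
        }
    )
    return ArmResult(
        discounted_cost=float(cost_t @ df) / size,
        discounted_qalys=float(qaly_t @ df) / size,
        undiscounted_cost=float(cost_t.sum()) / size,
        undiscounted_qalys=float(qaly_t.sum()) / size,
        cycles=cycles,
        cohort_size=size,
    )
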