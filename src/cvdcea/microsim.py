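"""Individual-level brute-force simulator over the same transition tables.

Each simulated person walks the per-cycle transition matrix by categorical
sampling.  Costs and QALYs are accrued with exactly the cohort engine's
conventions — trapezoidal half-cycle weights on the states occupied at the
start and end of each cycle, discounting by cycle index, and the year-0
override — so the two estimators share an estimand and the microsimulation
mean converges to the cohort-trace expectation at the usual 1/sqrt(n)
Monte-Carlo rate.  Used only to validate the cohort engine; the analysis
path always runs on the cohort trace.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .cohort_engine import _per_cycle_values, _table_matrix
from .state_space import ExpandedSpace
from .synthetic_data import CohortStratum


@dataclass(eq=False)
class MicrosimResult:
    """Per-person means with Monte-Carlo standard errors."""

    n: int
    mean_cost: float
    se_cost: float
    mean_qaly: float
    se_qaly: float
    event_counts: dict[int, float]  # final lifetime event count -> share
    event_log: Optional[pd.DataFrame] = None


def run_microsim(
    tables: Sequence,
    costs,
    utilities,
    n: int,
    seed: int,
    stratum: Optional[CohortStratum] = None,
    discount_rate: float = 0.035,
    space: Optional[ExpandedSpace] = None,
    initial_state: int = 0,
    year0_override: bool = True,
    keep_event_log: bool = False,
) -> MicrosimResult:
    """Simulate ``n`` individuals through the per-cycle tables.

    ``costs``/``utilities`` follow the cohort engine's interface (a static
    per-state vector, or a (T, n_states) array for age-varying utilities).
    With ``stratum`` the cycle-0 accruals are replaced by its trial-observed
    year-0 values, as in the cohort engine.
    """
    if n <= 0:
        raise ValueError(f"n must be positive, got {n}")
    mats = [_table_matrix(t) for t in tables]
    n_cycles = len(mats)
    n_states = mats[0].shape[0]
    cost_cy = _per_cycle_values(costs, n_cycles, n_states)
    util_cy = _per_cycle_values(utilities, n_cycles, n_states)
    if space is None:
        initial = initial_state
    else:
        initial = space.event_free_idx if initial_state == 0 else initial_state

    rng = np.random.default_rng(seed)
    states = np.full(n, initial, dtype=np.intp)
    cost_acc = np.zeros(n)
    qaly_acc = np.zeros(n)
    log_rows = []
    for t in range(n_cycles):
        cum = np.cumsum(mats[t], axis=1)
        u = rng.random(n)
        nxt = (cum[states] < u[:, None]).sum(axis=1)
        np.clip(nxt, 0, n_states - 1, out=nxt)
        df = (1.0 + discount_rate) ** (-t)
        if t == 0 and stratum is not None and year0_override:
            cost_acc += stratum.year0_cost
            qaly_acc += stratum.year0_qaly
        else:
            cost_acc += 0.5 * (cost_cy[t][states] + cost_cy[t][nxt]) * df
            qaly_acc += 0.5 * (util_cy[t][states] + util_cy[t][nxt]) * df
        if keep_event_log:
            log_rows.append(
                pd.DataFrame({"individual": np.arange(n), "cycle": t + 1, "state": nxt})
            )
        states = nxt

    if space is not None:
        counts = np.asarray(space.counts)[states]
    else:
        counts = np.zeros(n, dtype=int)
    uniq, freq = np.unique(counts, return_counts=True)
    event_counts = {int(c): float(f) / n for c, f in zip(uniq, freq)}

    return MicrosimResult(
        n=n,
        mean_cost=float(cost_acc.mean()),
        se_cost=float(cost_acc.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0,
        mean_qaly=float(qaly_acc.mean()),
        se_qaly=float(qaly_acc.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0,
        event_counts=event_counts,
        event_log=pd.concat(log_rows, ignore_index=True) if keep_event_log else None,
    )
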