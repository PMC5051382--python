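"""Per-cycle transition tables over the expanded state space.

Competing risks are ordered: other-cause (non-CVD) death is applied first;
conditional on surviving it, CVD dynamics apply.  From the event-free
state these are the primary-event probabilities, each split by case
fatality into a flow to CVD death and a flow into the acute state (count
+1).  Acute states settle deterministically into their post-event state
after one cycle (anginas, which are their own post states, receive the
chronic secondary-event dynamics from the year of onset).  Chronic states
face the secondary-event table, again split by case fatality, with the
residual mass persisting.  Once the lifetime event count reaches its cap
only persistence and death remain.  At the transition into age 100 all
surviving mass is sent to other-cause death.

Event probabilities within a cycle are exclusive: if their sum exceeds 1
the construction fails loudly rather than silently rescaling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .state_space import ACUTE, EVENT_FREE, ExpandedSpace, StateRegistry, expand
from .synthetic_data import CohortStratum, ParameterSet

ROW_SUM_TOL = 1e-8
FORCED_DEATH_AGE = 100


class TransitionConstructionError(ValueError):
    """A transition row could not be assembled as a probability row."""


@dataclass(eq=False)
class TransitionTable:
    """Row-stochastic annual transition matrix for one stratum and cycle."""

    cycle: int
    age: int
    space: ExpandedSpace
    matrix: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        """Sparse (from_state, to_state, prob) audit export."""
        rows = []
        labels = self.space.labels
        for i, j in zip(*np.nonzero(self.matrix)):
            rows.append((labels[i], labels[j], self.matrix[i, j]))
        return pd.DataFrame(rows, columns=["from_state", "to_state", "prob"])


def noncvd_death_prob(
    age: float, sex: str, params: ParameterSet, smr_draw: float
) -> float:
    """Annual other-cause death probability: the life-table all-cause rate
    scaled by the (CVD-excluded) standardised mortality ratio, capped at 1."""
    if smr_draw < 0:
        raise ValueError(f"standardised mortality ratio must be >= 0, got {smr_draw}")
    return min(1.0, params.qx(sex, age) * smr_draw)


def as_space(reg_or_space: StateRegistry | ExpandedSpace) -> ExpandedSpace:
    if isinstance(reg_or_space, ExpandedSpace):
        return reg_or_space
    return expand(reg_or_space)


def cvd_dynamics_matrix(
    space: ExpandedSpace,
    age: int,
    sex: str,
    event_probs: dict[str, float],
    params: ParameterSet,
    *,
    repeat_from_acute: bool = False,
) -> np.ndarray:
    """CVD transition matrix conditional on surviving other-cause death.

    Death rows are identity so the matrix composes with the mortality
    layer via :func:`combine_mortality`.  ``repeat_from_acute`` optionally
    allows a further event directly from an acute state within its first
    year (default: repeat events arise from post-event states only).
    """
    reg = space.registry
    n = space.n
    m = np.zeros((n, n))
    cvd_idx = space.cvd_death_idx
    non_idx = space.noncvd_death_idx
    m[cvd_idx, cvd_idx] = 1.0
    m[non_idx, non_idx] = 1.0

    if age + 1 >= FORCED_DEATH_AGE:
        # the cycle that would take survivors to age 100: forced death
        for i in space.living_idx:
            m[i, non_idx] = 1.0
        return m

    for i in space.living_idx:
        name = space.state_names[i]
        count = space.counts[i]
        state = reg.by_name[name]

        if state.category == EVENT_FREE:
            total = 0.0
            for event, p in event_probs.items():
                if p == 0.0:
                    continue
                f = params.fatality(event, sex, age)
                m[i, cvd_idx] += p * f
                m[i, space.idx(event, 1)] += p * (1.0 - f)
                total += p
            if total > 1.0 + 1e-12:
                raise TransitionConstructionError(
                    f"primary event probabilities sum to {total} > 1 at age {age}"
                )
            m[i, i] += 1.0 - total
            continue

        is_chronic = name in reg.chronic_states
        if state.category == ACUTE and not is_chronic and not repeat_from_acute:
            # acute states last exactly one cycle, then settle
            m[i, space.idx(reg.post_of[name], count)] = 1.0
            continue

        # chronic dynamics (also used for acute states when repeats from
        # the acute year are enabled); the non-event residual settles into
        # the state's post-event destination
        settle = space.idx(reg.post_of.get(name, name), count)
        if count >= reg.max_events:
            m[i, settle] = 1.0
            continue
        sec = params.secondary(sex, age, name if is_chronic else reg.post_of[name])
        total = 0.0
        for event, p in sec.items():
            if p == 0.0:
                continue
            f = params.fatality(event, sex, age)
            m[i, cvd_idx] += p * f
            m[i, space.idx(event, count + 1)] += p * (1.0 - f)
            total += p
        if total > 1.0 + 1e-12:
            raise TransitionConstructionError(
                f"secondary event probabilities from {name!r} sum to {total} > 1 "
                f"at age {age}"
            )
        m[i, settle] += 1.0 - total
    return m


def combine_mortality(
    m_cvd: np.ndarray, q_noncvd: float, space: ExpandedSpace
) -> np.ndarray:
    """Compose the survival-conditional CVD matrix with other-cause death
    applied first: living rows become ``(1-q)*row`` plus ``q`` into the
    other-cause death state."""
    p = m_cvd.copy()
    living = space.living_idx
    p[living] *= 1.0 - q_noncvd
    p[living, space.noncvd_death_idx] += q_noncvd
    return p


def build_cycle_table(
    stratum: CohortStratum,
    cycle: int,
    event_probs: dict[str, float],
    params: ParameterSet,
    smr_draw: float,
    reg: StateRegistry | ExpandedSpace,
    *,
    repeat_from_acute: bool = False,
) -> TransitionTable:
    """Assemble the full row-stochastic table for one stratum and cycle.

    ``event_probs`` are this cycle's primary-event probabilities (from
    ``split_events``); ``smr_draw`` is the realized standardised mortality
    ratio of the current parameter draw.
    """
    space = as_space(reg)
    age = stratum.age0 + cycle
    q = noncvd_death_prob(age, stratum.sex, params, smr_draw)
    m = cvd_dynamics_matrix(
        space, age, stratum.sex, event_probs, params,
        repeat_from_acute=repeat_from_acute,
    )
    p = combine_mortality(m, q, space)
    sums = p.sum(axis=1)
    bad = np.flatnonzero(np.abs(sums - 1.0) > ROW_SUM_TOL)
    if bad.size:
        i = int(bad[0])
        raise TransitionConstructionError(
            f"row {space.labels[i]!r} sums to {sums[i]!r} at cycle {cycle}"
        )
    return TransitionTable(cycle=cycle, age=age, space=space, matrix=p)
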