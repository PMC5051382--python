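"""Health-state topology for a cardiovascular cohort state-transition model.

The model distinguishes an event-free state, acute first-year event states
(acute myocardial infarction, stable and unstable angina, transient
ischaemic attack, stroke), chronic post-event states, and two absorbing
death states (cardiovascular death and other-cause death).  Angina carries
no separate post-event state: it is treated as a chronic condition, so an
angina state acts as its own post-event state and persists from the year of
onset onwards.

For computation every living state is expanded by a lifetime event count
(1..``max_events``; the event-free state carries count 0).  Entering any
acute-event state increments the count; settling from an acute state into
its post-event state does not.  Once the count reaches ``max_events`` only
post-event persistence and death transitions remain.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass
from functools import cached_property
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

EVENT_FREE = "event-free"
ACUTE = "acute-event"
POST = "post-event"
DEAD = "dead"
CATEGORIES = (EVENT_FREE, ACUTE, POST, DEAD)


@dataclass(frozen=True)
class HealthState:
    """One discrete clinical state.

    ``linked_acute`` names, for a post-event state, the acute event it
    follows.  ``fatal`` marks, among the death states, the one attributable
    to the modelled disease (cardiovascular death).
    """

    name: str
    category: str
    linked_acute: Optional[str] = None
    fatal: bool = False


@dataclass(eq=False)
class StateRegistry:
    """A set of health states plus the permitted transition pairs.

    The registry is plain data: alternative topologies are expressed by
    constructing a different registry, not by changing code.
    """

    states: tuple[HealthState, ...]
    permitted: frozenset[tuple[str, str]]
    max_events: int = 3

    # -- lookups -------------------------------------------------------

    @cached_property
    def by_name(self) -> dict[str, HealthState]:
        return {s.name: s for s in self.states}

    @cached_property
    def event_free(self) -> str:
        names = [s.name for s in self.states if s.category == EVENT_FREE]
        if len(names) != 1:
            raise ValueError(f"expected exactly one event-free state, got {names}")
        return names[0]

    @cached_property
    def acute_events(self) -> tuple[str, ...]:
        return tuple(s.name for s in self.states if s.category == ACUTE)

    @cached_property
    def post_events(self) -> tuple[str, ...]:
        return tuple(s.name for s in self.states if s.category == POST)

    @cached_property
    def death_states(self) -> tuple[str, ...]:
        return tuple(s.name for s in self.states if s.category == DEAD)

    @cached_property
    def cvd_death(self) -> str:
        names = [s.name for s in self.states if s.category == DEAD and s.fatal]
        if len(names) != 1:
            raise ValueError("registry needs exactly one disease-attributable death state")
        return names[0]

    @cached_property
    def noncvd_death(self) -> str:
        names = [s.name for s in self.states if s.category == DEAD and not s.fatal]
        if len(names) != 1:
            raise ValueError("registry needs exactly one other-cause death state")
        return names[0]

    @cached_property
    def post_of(self) -> dict[str, str]:
        """Acute state -> the state it settles into after its first year.

        Acute states with no referencing post-event state (the anginas)
        settle into themselves.
        """
        mapping = {a: a for a in self.acute_events}
        for s in self.states:
            if s.category == POST and s.linked_acute is not None:
                mapping[s.linked_acute] = s.name
        return mapping

    @cached_property
    def chronic_states(self) -> tuple[str, ...]:
        """States subject to secondary-event dynamics: post-event states
        plus acute states that are their own post state."""
        self_post = tuple(a for a in self.acute_events if self.post_of[a] == a)
        return self.post_events + self_post


def default_registry() -> StateRegistry:
    """The default topology: event-free; AMI, stable/unstable angina, TIA,
    stroke as acute events; post-AMI/-TIA/-stroke chronic states; two
    absorbing death states.

    Permitted transitions: the event-free state can move to any acute event
    or either death state (a fatal first event flows directly to CVD
    death); each acute event can settle into its post-event state, suffer
    any further acute event (count + 1), or die; each chronic state can
    persist, suffer any acute event (count + 1), or die.
    """
    acute = ("ami", "stable_angina", "unstable_angina", "tia", "stroke")
    states = [HealthState("event_free", EVENT_FREE)]
    states += [HealthState(a, ACUTE) for a in acute]
    states += [
        HealthState("post_ami", POST, linked_acute="ami"),
        HealthState("post_tia", POST, linked_acute="tia"),
        HealthState("post_stroke", POST, linked_acute="stroke"),
    ]
    states += [
        HealthState("cvd_death", DEAD, fatal=True),
        HealthState("noncvd_death", DEAD),
    ]
    reg = StateRegistry(states=tuple(states), permitted=frozenset())

    deaths = ("cvd_death", "noncvd_death")
    pairs: set[tuple[str, str]] = set()
    for d in deaths:
        pairs.add(("event_free", d))
    for a in acute:
        pairs.add(("event_free", a))
    post_of = {a: a for a in acute}
    post_of.update({"ami": "post_ami", "tia": "post_tia", "stroke": "post_stroke"})
    for a in acute:
        pairs.add((a, post_of[a]))
        for a2 in acute:
            pairs.add((a, a2))
        for d in deaths:
            pairs.add((a, d))
    for p in ("post_ami", "post_tia", "post_stroke", "stable_angina", "unstable_angina"):
        pairs.add((p, p))
        for a2 in acute:
            pairs.add((p, a2))
        for d in deaths:
            pairs.add((p, d))
    return StateRegistry(states=tuple(states), permitted=frozenset(pairs))


def validate_registry(reg: StateRegistry) -> list[str]:
    """Check registry invariants; return one message per breach.

    Violations are data, not exceptions: an empty list means the registry
    is valid.
    """
    violations: list[str] = []
    names = [s.name for s in reg.states]
    if len(set(names)) != len(names):
        violations.append("duplicate state names")
    by_name = {s.name: s for s in reg.states}

    for s in reg.states:
        if s.category not in CATEGORIES:
            violations.append(f"state {s.name!r}: unknown category {s.category!r}")

    n_free = sum(1 for s in reg.states if s.category == EVENT_FREE)
    if n_free != 1:
        violations.append(f"expected exactly one event-free state, found {n_free}")
    deaths = [s for s in reg.states if s.category == DEAD]
    if len(deaths) < 2:
        violations.append(f"expected at least two death states, found {len(deaths)}")

    for s in reg.states:
        if s.category == POST:
            if s.linked_acute is None:
                violations.append(f"post-event state {s.name!r} has no linked acute state")
            elif s.linked_acute not in by_name or by_name[s.linked_acute].category != ACUTE:
                violations.append(
                    f"post-event state {s.name!r} links to {s.linked_acute!r}, "
                    "which is not a registered acute-event state"
                )

    death_names = {s.name for s in deaths}
    for pair in sorted(reg.permitted):
        frm, to = pair
        if frm not in by_name or to not in by_name:
            violations.append(f"permitted pair {pair} references unregistered state(s)")
            continue
        if frm in death_names:
            violations.append(f"transition out of absorbing death state: {pair}")

    for s in reg.states:
        if s.category == DEAD:
            continue
        for d in death_names:
            if (s.name, d) not in reg.permitted:
                violations.append(f"living state {s.name!r} has no permitted transition to {d!r}")

    if reg.max_events != 3:
        violations.append(f"max_events must be 3, got {reg.max_events}")
    return violations


# ---------------------------------------------------------------------------
# Expanded (state x event-count) space
# ---------------------------------------------------------------------------


@dataclass(eq=False)
class ExpandedSpace:
    """The reachable (state, event-count) pairs, in a fixed order.

    Death states carry no meaningful count and are stored with count 0.
    """

    registry: StateRegistry
    labels: tuple[str, ...]
    state_names: tuple[str, ...]
    counts: tuple[int, ...]

    @cached_property
    def index(self) -> dict[tuple[str, int], int]:
        return {
            (name, c): i for i, (name, c) in enumerate(zip(self.state_names, self.counts))
        }

    @cached_property
    def n(self) -> int:
        return len(self.labels)

    @cached_property
    def dead_mask(self) -> np.ndarray:
        by = self.registry.by_name
        return np.array([by[s].category == DEAD for s in self.state_names])

    @cached_property
    def living_idx(self) -> np.ndarray:
        return np.flatnonzero(~self.dead_mask)

    @cached_property
    def event_free_idx(self) -> int:
        return self.index[(self.registry.event_free, 0)]

    @cached_property
    def cvd_death_idx(self) -> int:
        return self.index[(self.registry.cvd_death, 0)]

    @cached_property
    def noncvd_death_idx(self) -> int:
        return self.index[(self.registry.noncvd_death, 0)]

    def idx(self, name: str, count: int = 0) -> int:
        return self.index[(name, count)]


def _expanded_successors(
    reg: StateRegistry, name: str, count: int
) -> list[tuple[str, int]]:
    """Successors of one expanded node under the permitted pairs, applying
    the event-count bookkeeping rules."""
    by = reg.by_name
    out: set[tuple[str, int]] = set()
    for frm, to in reg.permitted:
        if frm != name:
            continue
        target = by[to]
        if target.category == DEAD:
            out.add((to, 0))
        elif to == reg.post_of.get(name, name):
            # settling into the post-event state (or chronic persistence,
            # for states that are their own post state): count unchanged
            out.add((to, count))
        elif target.category == ACUTE:
            if count < reg.max_events:
                out.add((to, count + 1))
    return sorted(out)


def expand(reg: StateRegistry) -> ExpandedSpace:
    """Enumerate the reachable expanded space by graph search from the
    event-free state at count 0, then order it: event-free first, living
    states in registry order by ascending count, deaths last."""
    start = (reg.event_free, 0)
    seen = {start}
    queue = deque([start])
    while queue:
        name, count = queue.popleft()
        for nxt in _expanded_successors(reg, name, count):
            if nxt not in seen:
                seen.add(nxt)
                queue.append(nxt)

    order: list[tuple[str, int]] = [start]
    for s in reg.states:
        if s.category in (EVENT_FREE, DEAD):
            continue
        for c in range(0, reg.max_events + 1):
            if (s.name, c) in seen and (s.name, c) != start:
                order.append((s.name, c))
    for d in reg.death_states:
        if (d, 0) in seen:
            order.append((d, 0))

    by = reg.by_name
    labels = tuple(
        name if by[name].category in (DEAD, EVENT_FREE) else f"{name}#{c}"
        for name, c in order
    )
    return ExpandedSpace(
        registry=reg,
        labels=labels,
        state_names=tuple(name for name, _ in order),
        counts=tuple(c for _, c in order),
    )


# ---------------------------------------------------------------------------
# Serialization (CSV state table + edge list)
# ---------------------------------------------------------------------------


def registry_to_frames(reg: StateRegistry) -> tuple[pd.DataFrame, pd.DataFrame]:
    states = pd.DataFrame(
        {
            "name": [s.name for s in reg.states],
            "category": [s.category for s in reg.states],
            "linked_acute": [s.linked_acute or "" for s in reg.states],
            "fatal": [s.fatal for s in reg.states],
        }
    )
    edges = pd.DataFrame(sorted(reg.permitted), columns=["from", "to"])
    return states, edges


def registry_from_frames(
    states: pd.DataFrame, edges: pd.DataFrame, max_events: int = 3
) -> StateRegistry:
    hs = tuple(
        HealthState(
            name=row["name"],
            category=row["category"],
            linked_acute=row["linked_acute"] or None,
            fatal=bool(row["fatal"]),
        )
        for _, row in states.iterrows()
    )
    permitted = frozenset((r["from"], r["to"]) for _, r in edges.iterrows())
    return StateRegistry(states=hs, permitted=permitted, max_events=max_events)


def save_registry(reg: StateRegistry, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    states, edges = registry_to_frames(reg)
    states.to_csv(outdir / "states.csv", index=False)
    edges.to_csv(outdir / "transitions.csv", index=False)


def load_registry(indir: str | Path, max_events: int = 3) -> StateRegistry:
    indir = Path(indir)
    states = pd.read_csv(indir / "states.csv", keep_default_na=False)
    edges = pd.read_csv(indir / "transitions.csv")
    return registry_from_frames(states, edges, max_events=max_events)
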