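"""Transition-table assembly: competing-risk ordering, stochasticity,
mass conservation."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from cvdcea import build_cycle_table, noncvd_death_prob
from cvdcea.synthetic_data import CohortStratum, EVENTS
from cvdcea.transition_model import (
    TransitionConstructionError,
    combine_mortality,
    cvd_dynamics_matrix,
)


def _stratum(age0=67, sex="male"):
    return CohortStratum(
        arm="control", sex=sex, age0=age0, weight=1.0, baseline_r10=0.3,
        followup_r10=0.3, year0_cost=0.0, year0_qaly=0.0,
    )


class TestNonCvdDeath:
    def test_identity_ratio(self, params):
        assert noncvd_death_prob(67, "male", params, 1.0) == params.qx("male", 67)

    def test_scaling_and_cap(self, params):
        q = params.qx("male", 99)
        assert noncvd_death_prob(99, "male", params, 0.8) == pytest.approx(0.8 * q)
        huge = 2.0 / q
        assert noncvd_death_prob(99, "male", params, huge) == 1.0

    def test_negative_smr_rejected(self, params):
        with pytest.raises(ValueError):
            noncvd_death_prob(67, "male", params, -0.1)


class TestBuildCycleTable:
    def test_null_dynamics_identity_on_living_states(self, params, space):
        """No events and no mortality: every state maps to its settled
        self (acute states settle into their post state; all other living
        states persist)."""
        zero_sec = params.secondary_transitions.copy()
        zero_sec["prob"] = 0.0
        from dataclasses import replace

        lt = params.life_table.copy()
        lt["qx"] = 0.0
        quiet = replace(params, secondary_transitions=zero_sec, life_table=lt)
        probs = {e: 0.0 for e in EVENTS}
        table = build_cycle_table(_stratum(), 0, probs, quiet, 0.0, space)
        m = table.matrix
        reg = space.registry
        for i in range(space.n):
            name, c = space.state_names[i], space.counts[i]
            settled = space.idx(reg.post_of.get(name, name), c)
            assert m[i, settled] == pytest.approx(1.0)

    def test_hand_product_event_free_row(self, params, space):
        """Non-CVD death first (q=0.01), then a primary AMI of 0.02 with
        case fatality 0.3: P(CVD death) = 0.99*0.02*0.3, P(AMI) =
        0.99*0.02*0.7."""
        from dataclasses import replace

        cf = params.case_fatality.copy()
        cf["prob"] = 0.3
        lt = params.life_table.copy()
        lt["qx"] = 0.01
        fixed = replace(params, case_fatality=cf, life_table=lt)
        probs = {e: 0.0 for e in EVENTS}
        probs["ami"] = 0.02
        table = build_cycle_table(_stratum(), 0, probs, fixed, 1.0, space)
        row = table.matrix[space.event_free_idx]
        assert row[space.cvd_death_idx] == pytest.approx(0.99 * 0.02 * 0.3)
        assert row[space.idx("ami", 1)] == pytest.approx(0.99 * 0.02 * 0.7)
        assert row[space.event_free_idx] == pytest.approx(0.99 * 0.98)
        assert row[space.noncvd_death_idx] == pytest.approx(0.01)

    @given(
        p_any=st.floats(min_value=0.0, max_value=1.0),
        smr=st.floats(min_value=0.0, max_value=3.0),
        cycle=st.integers(min_value=0, max_value=32),
    )
    def test_rows_always_stochastic(self, params, space, p_any, smr, cycle):
        from cvdcea import split_events

        s = _stratum()
        probs = split_events(p_any, s.age0 + cycle, s.sex, params)
        table = build_cycle_table(s, cycle, probs, params, smr, space)
        np.testing.assert_allclose(table.matrix.sum(axis=1), 1.0, atol=1e-10)
        assert np.all(table.matrix >= 0) and np.all(table.matrix <= 1)

    def test_mass_conservation_under_any_occupancy(self, params, space, rng):
        from cvdcea import split_events

        s = _stratum()
        probs = split_events(0.05, 67, "male", params)
        table = build_cycle_table(s, 0, probs, params, 0.9, space)
        occ = rng.uniform(0, 100, space.n)
        after = occ @ table.matrix
        assert after.sum() == pytest.approx(occ.sum(), rel=1e-12)

    def test_no_death_flow_without_mortality_or_fatality(self, params, space):
        from dataclasses import replace

        from cvdcea import split_events

        cf = params.case_fatality.copy()
        cf["prob"] = 0.0
        no_cf = replace(params, case_fatality=cf)
        s = _stratum()
        probs = split_events(0.10, 67, "male", no_cf)
        table = build_cycle_table(s, 0, probs, no_cf, 0.0, space)
        assert table.matrix[:, space.cvd_death_idx].sum() == pytest.approx(1.0)
        assert table.matrix[:, space.noncvd_death_idx].sum() == pytest.approx(1.0)
        # (only the absorbing self-loops remain)

    def test_forced_death_at_age_100(self, params, space):
        s = _stratum(age0=67)
        probs = {e: 0.0 for e in EVENTS}
        table = build_cycle_table(s, 32, probs, params, 1.0, space)  # age 99
        for i in space.living_idx:
            assert table.matrix[i, space.noncvd_death_idx] == 1.0

    def test_capped_event_count_only_persists(self, params, space):
        from cvdcea import split_events

        probs = split_events(0.05, 67, "male", params)
        table = build_cycle_table(_stratum(), 0, probs, params, 1.0, space)
        i = space.idx("post_stroke", 3)
        nonzero = {space.labels[j] for j in np.nonzero(table.matrix[i])[0]}
        assert nonzero <= {"post_stroke#3", "cvd_death", "noncvd_death"}

    def test_excessive_event_probabilities_fail_loudly(self, params, space):
        probs = {e: 0.3 for e in EVENTS}  # sums to 1.5
        with pytest.raises(TransitionConstructionError, match="> 1"):
            build_cycle_table(_stratum(), 0, probs, params, 1.0, space)

    def test_more_event_probability_more_event_flow(self, params, space):
        """Raising one primary-event probability raises flow into that
        event's state from event-free."""
        probs_lo = {e: 0.0 for e in EVENTS}
        probs_lo["stroke"] = 0.01
        probs_hi = dict(probs_lo, stroke=0.05)
        lo = build_cycle_table(_stratum(), 0, probs_lo, params, 1.0, space)
        hi = build_cycle_table(_stratum(), 0, probs_hi, params, 1.0, space)
        j = space.idx("stroke", 1)
        assert hi.matrix[space.event_free_idx, j] > lo.matrix[space.event_free_idx, j]


def test_combine_mortality_layers_death_first(params, space):
    m = cvd_dynamics_matrix(space, 67, "male", {e: 0.0 for e in EVENTS}, params)
    p = combine_mortality(m, 0.25, space)
    i = space.event_free_idx
    assert p[i, space.noncvd_death_idx] == pytest.approx(0.25)
    assert p[i, i] == pytest.approx(0.75)
    # death rows untouched
    assert p[space.cvd_death_idx, space.cvd_death_idx] == 1.0


def test_table_audit_frame(params, space):
    from cvdcea import split_events

    probs = split_events(0.05, 67, "male", params)
    table = build_cycle_table(_stratum(), 0, probs, params, 1.0, space)
    df = table.to_frame()
    assert set(df.columns) == {"from_state", "to_state", "prob"}
    total = df.groupby("from_state")["prob"].sum()
    np.testing.assert_allclose(total, 1.0, atol=1e-10)
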