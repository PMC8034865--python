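from datetime import datetime, timedelta

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from smstailor.engine import (
    FOLLOWUP_DELAY,
    Followup,
    GroupWeights,
    SelectionError,
    SelectionState,
    apply_feedback,
    select_next_message,
    selection_probabilities,
    state_from_dict,
    state_to_dict,
)

from conftest import make_tiny_library


def run_selections(lib, n, rng, state=None, weights=None, now=None):
    state = state or SelectionState()
    weights = weights or GroupWeights.uniform(lib)
    out = []
    for _ in range(n):
        msg, state = select_next_message(lib, state, weights, rng, now=now)
        out.append(msg)
    return out, state


class TestSelection:
    def test_forced_choice_returns_the_single_unsent_message(self, rng):
        lib = make_tiny_library(n_groups=1, per_group=2, q=5)
        state = SelectionState(sent_ids={"g1-m1"})
        msg, state = select_next_message(lib, state, GroupWeights.uniform(lib), rng)
        assert msg.message_id == "g1-m2"
        assert "g1-m2" in state.sent_ids

    def test_lifestyle_sent_when_bct_run_reaches_q(self, tiny_lib, rng):
        state = SelectionState(consecutive_bct_count=tiny_lib.interleave_q)
        msg, state = select_next_message(tiny_lib, state, GroupWeights.uniform(tiny_lib), rng)
        assert msg.kind == "lifestyle"
        assert state.consecutive_bct_count == 0

    def test_interleave_pattern_one_lifestyle_per_q_bct(self, rng):
        # q=2: selections follow B,B,G,B,B,G,...
        lib = make_tiny_library(n_groups=5, per_group=4, n_lifestyle=10, q=2)
        msgs, _ = run_selections(lib, 12, rng)
        kinds = [m.kind for m in msgs]
        assert kinds == ["bct", "bct", "lifestyle"] * 4

    def test_no_repeat_and_no_consecutive_group_until_exhaustion(self, rng):
        lib = make_tiny_library(n_groups=4, per_group=3, n_lifestyle=6, q=2)
        # 12 bct + 6 lifestyle = 18 messages without exhaustion
        msgs, _ = run_selections(lib, 18, rng)
        ids = [m.message_id for m in msgs]
        assert len(set(ids)) == len(ids)
        bct_groups = [m.group_id for m in msgs if m.kind == "bct"]
        assert all(a != b for a, b in zip(bct_groups, bct_groups[1:]))

    def test_exhausted_pool_resets_history_and_keeps_exclusion(self, rng):
        lib = make_tiny_library(n_groups=3, per_group=1, n_lifestyle=1, q=50)
        msgs, state = run_selections(lib, 9, rng)  # 3 unique, then repeats allowed
        assert all(m.kind == "bct" for m in msgs)
        groups = [m.group_id for m in msgs]
        assert all(a != b for a, b in zip(groups, groups[1:]))

    def test_rng_is_required(self, tiny_lib):
        with pytest.raises(SelectionError):
            select_next_message(tiny_lib, SelectionState(), GroupWeights.uniform(tiny_lib), None)

    def test_input_state_is_not_mutated(self, tiny_lib, rng):
        state = SelectionState()
        select_next_message(tiny_lib, state, GroupWeights.uniform(tiny_lib), rng)
        assert state.sent_ids == set() and state.consecutive_bct_count == 0


class TestFollowups:
    def test_due_followup_consumes_next_bct_slot(self, rng):
        lib = make_tiny_library(n_groups=3, per_group=2, q=5)
        now = datetime(2024, 1, 1)
        state = SelectionState(pending_followups=[Followup("g2", now - timedelta(days=1))])
        msg, state = select_next_message(lib, state, GroupWeights.uniform(lib), rng, now=now)
        assert msg.group_id == "g2"
        assert state.pending_followups == []

    def test_unripe_followup_waits(self, rng):
        lib = make_tiny_library(n_groups=2, per_group=2, q=5)
        now = datetime(2024, 1, 1)
        fu = Followup("g2", now + timedelta(days=13))
        state = SelectionState(pending_followups=[fu], last_bct_group="g2")
        msg, state = select_next_message(lib, state, GroupWeights.uniform(lib), rng, now=now)
        assert msg.group_id == "g1"  # g2 excluded as most recent; follow-up not due
        assert state.pending_followups == [fu]

    def test_followup_for_just_used_group_is_deferred(self, rng):
        lib = make_tiny_library(n_groups=2, per_group=3, q=5)
        now = datetime(2024, 1, 1)
        fu = Followup("g2", now - timedelta(days=1))
        state = SelectionState(pending_followups=[fu], last_bct_group="g2")
        msg, state = select_next_message(lib, state, GroupWeights.uniform(lib), rng, now=now)
        assert msg.group_id == "g1"
        assert state.pending_followups == [fu]  # kept for the next slot
        msg2, state = select_next_message(lib, state, GroupWeights.uniform(lib), rng, now=now)
        assert msg2.group_id == "g2" and state.pending_followups == []

    def test_followup_for_exhausted_group_is_dropped(self, rng):
        lib = make_tiny_library(n_groups=3, per_group=1, q=5)
        now = datetime(2024, 1, 1)
        state = SelectionState(
            sent_ids={"g2-m1"},
            pending_followups=[Followup("g2", now - timedelta(days=1))],
        )
        msg, state = select_next_message(lib, state, GroupWeights.uniform(lib), rng, now=now)
        assert msg.group_id != "g2"
        assert state.pending_followups == []


class TestFeedback:
    def test_positive_feedback_doubles_weight_and_schedules_followup(self, tiny_lib):
        w = GroupWeights.uniform(tiny_lib)
        now = datetime(2024, 3, 1, 10, 0)
        w2, state2 = apply_feedback(w, SelectionState(), "increase", "g1", now=now)
        assert w2["g1"] == 2.0
        assert state2.pending_followups == [Followup("g1", now + FOLLOWUP_DELAY)]
        assert (now + FOLLOWUP_DELAY) - now == timedelta(days=14)

    def test_negative_feedback_halves_weight_no_followup(self, tiny_lib):
        w2, state2 = apply_feedback(
            GroupWeights.uniform(tiny_lib), SelectionState(), "decrease", "g1"
        )
        assert w2["g1"] == 0.5
        assert state2.pending_followups == []

    def test_feedback_compounds_multiplicatively(self, tiny_lib):
        w, s = GroupWeights.uniform(tiny_lib), SelectionState()
        for _ in range(2):
            w, s = apply_feedback(w, s, "increase", "g2")
        assert w["g2"] == 4.0
        assert len(s.pending_followups) == 2

    def test_other_weights_untouched_and_inputs_unmutated(self, tiny_lib):
        w = GroupWeights.uniform(tiny_lib)
        w2, _ = apply_feedback(w, SelectionState(), "increase", "g1")
        assert w["g1"] == 1.0
        assert all(w2[g] == 1.0 for g in ("g2", "g3"))

    def test_unknown_group_rejected(self, tiny_lib):
        with pytest.raises(KeyError):
            apply_feedback(GroupWeights.uniform(tiny_lib), SelectionState(), "increase", "nope")

    @given(hst.lists(hst.sampled_from(["increase", "decrease"]), max_size=8))
    @settings(deadline=None)
    def test_odds_double_or_halve_exactly_per_feedback(self, seq):
        lib = make_tiny_library(n_groups=4, per_group=2)
        w, s = GroupWeights.uniform(lib), SelectionState()
        for fb in seq:
            others_before = sum(w[g] for g in ("g2", "g3", "g4"))
            odds_before = w["g1"] / others_before
            w, s = apply_feedback(w, s, fb, "g1")
            odds_after = w["g1"] / sum(w[g] for g in ("g2", "g3", "g4"))
            factor = 2.0 if fb == "increase" else 0.5
            assert odds_after == odds_before * factor


class TestProbabilities:
    def test_equal_weights_symmetric(self, rng):
        lib = make_tiny_library(n_groups=4, per_group=2)
        probs = selection_probabilities(lib, SelectionState(), GroupWeights.uniform(lib))
        assert all(p == pytest.approx(0.25) for p in probs.values())

    def test_weighted_normalization(self):
        lib = make_tiny_library(n_groups=3, per_group=2)
        w = GroupWeights({"g1": 2.0, "g2": 1.0, "g3": 1.0})
        probs = selection_probabilities(lib, SelectionState(), w)
        assert probs == pytest.approx({"g1": 0.5, "g2": 0.25, "g3": 0.25})

    def test_recent_group_excluded(self):
        lib = make_tiny_library(n_groups=3, per_group=2)
        probs = selection_probabilities(
            lib, SelectionState(last_bct_group="g2"), GroupWeights.uniform(lib)
        )
        assert probs["g2"] == 0.0
        assert sum(probs.values()) == pytest.approx(1.0)

    def test_no_eligible_group_is_an_error(self):
        lib = make_tiny_library(n_groups=1, per_group=1)
        with pytest.raises(SelectionError):
            selection_probabilities(
                lib, SelectionState(last_bct_group="g1"), GroupWeights.uniform(lib)
            )

    def test_monte_carlo_matches_analytic(self, rng):
        lib = make_tiny_library(n_groups=4, per_group=3)
        w = GroupWeights({"g1": 2.0, "g2": 1.0, "g3": 0.5, "g4": 0.5})
        state = SelectionState(last_bct_group="g4")
        probs = selection_probabilities(lib, state, w)
        counts = {g: 0 for g in probs}
        n = 4000
        for _ in range(n):
            msg, _ = select_next_message(lib, state, w, rng)
            counts[msg.group_id] += 1
        for g, p in probs.items():
            assert counts[g] / n == pytest.approx(p, abs=0.03)


def test_state_serialization_round_trip(tiny_lib, rng):
    state = SelectionState(
        sent_ids={"g1-m1"},
        last_bct_group="g1",
        consecutive_bct_count=1,
        pending_followups=[Followup("g2", datetime(2024, 5, 1, 12, 0))],
    )
    w = GroupWeights({"g1": 2.0, "g2": 0.5, "g3": 1.0})
    state2, w2 = state_from_dict(state_to_dict(state, w))
    assert state2 == state and w2.weights == w.weights


def test_fixed_seed_reproduces_full_trace(feas_lib):
    traces = []
    for _ in range(2):
        rng = np.random.default_rng(77)
        msgs, _ = run_selections(feas_lib, 78, rng)
        traces.append([m.message_id for m in msgs])
    assert traces[0] == traces[1]
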