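from datetime import datetime, timedelta

import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from smstailor.interaction import (
    HANDSHAKE_REPLY,
    CommandRejected,
    ParsedCommand,
    ParticipantState,
    Role,
    Unrecognized,
    admin_restart,
    apply_command,
    attribute_rating,
    authorize,
    handle_unrecognized,
    parse_inbound,
    resume_if_due,
)
from smstailor.metrics import Event

NOW = datetime(2024, 2, 1, 10, 0)


class TestParsing:
    @pytest.mark.parametrize(
        "raw,mode,verb",
        [
            ("DIA LIKE", "keyword", "like"),
            ("dia dislike", "keyword", "dislike"),
            ("Start", "virtual_number", "start"),
            ("STOP", "virtual_number", "stop"),
            ("  am ", "virtual_number", "am"),
            ("PM", "virtual_number", "pm"),
            ("Useful", "virtual_number", "useful"),
            ("not useful", "virtual_number", "not_useful"),
            ("MORE", "virtual_number", "more"),
        ],
    )
    def test_verbs_parse_case_insensitively(self, raw, mode, verb):
        cmd = parse_inbound(raw, mode=mode)
        assert isinstance(cmd, ParsedCommand) and cmd.verb == verb

    def test_register_captures_trailing_names(self):
        cmd = parse_inbound("register Jane Doe", mode="virtual_number")
        assert cmd.verb == "register" and cmd.names == "Jane Doe"

    def test_pause_captures_weeks(self):
        cmd = parse_inbound("  pause 2 ", mode="virtual_number")
        assert cmd.verb == "pause" and cmd.weeks == 2

    def test_help_levels(self):
        assert parse_inbound("help", mode="virtual_number").help_level == 1
        assert parse_inbound("DIA Help 3", mode="keyword").help_level == 3

    def test_missing_keyword_is_structured_unrecognized(self):
        out = parse_inbound("LIKE", mode="keyword")
        assert isinstance(out, Unrecognized) and out.reason == "missing keyword"

    @pytest.mark.parametrize("raw", ["", "   ", "banana", "pause", "pause x", "help 9"])
    def test_unparseable_texts_become_values_not_exceptions(self, raw):
        assert isinstance(parse_inbound(raw, mode="virtual_number"), Unrecognized)

    @given(hst.text(max_size=50))
    @settings(deadline=None, max_examples=200)
    def test_parser_is_total(self, raw):
        for mode in ("keyword", "virtual_number"):
            out = parse_inbound(raw, mode=mode)
            assert isinstance(out, (ParsedCommand, Unrecognized))


class TestStateMachine:
    def test_register_emits_handshake_exactly_once(self):
        st = ParticipantState("p1", "feasibility", status="pending")
        st, replies = apply_command(st, ParsedCommand("register", names="A B"), NOW)
        assert replies == [HANDSHAKE_REPLY]
        assert st.status == "pending"

    def test_stop_is_absorbing_without_admin_restart(self, active_participant):
        st, replies = apply_command(active_participant, ParsedCommand("stop"), NOW)
        assert st.status == "stopped" and replies == []
        with pytest.raises(CommandRejected, match="study team"):
            apply_command(st, ParsedCommand("start"), NOW)
        assert admin_restart(st).status == "active"

    def test_pause_then_auto_resume(self, active_participant):
        st, _ = apply_command(active_participant, ParsedCommand("pause", weeks=4), NOW)
        assert st.status == "paused"
        assert st.pause_until == NOW + timedelta(weeks=4)
        assert resume_if_due(st, NOW + timedelta(weeks=3)).status == "paused"
        resumed = resume_if_due(st, NOW + timedelta(weeks=4))
        assert resumed.status == "active" and resumed.pause_until is None

    def test_start_resumes_from_paused(self, active_participant):
        st, _ = apply_command(active_participant, ParsedCommand("pause", weeks=2), NOW)
        st, replies = apply_command(st, ParsedCommand("start"), NOW)
        assert st.status == "active" and replies

    def test_window_commands_update_delivery_window(self, active_participant):
        st, _ = apply_command(active_participant, ParsedCommand("pm"), NOW)
        assert st.delivery_window == "PM"
        st, _ = apply_command(st, ParsedCommand("am"), NOW)
        assert st.delivery_window == "AM"

    def test_rating_verbs_do_not_change_state(self, active_participant):
        st, replies = apply_command(active_participant, ParsedCommand("like"), NOW)
        assert st == active_participant and replies == []

    def test_pilot_only_verbs_rejected_in_feasibility(self, active_participant):
        with pytest.raises(CommandRejected, match="feasibility"):
            apply_command(active_participant, ParsedCommand("easy"), NOW)

    def test_unrecognized_reply_policy(self, active_participant):
        assert handle_unrecognized(active_participant, Unrecognized("xx", "unknown command"))
        pending = ParticipantState("p2", "pilot", status="pending")
        assert handle_unrecognized(pending, Unrecognized("xx", "unknown command")) == []


class TestAttribution:
    def delivered(self, t, mid):
        return Event(t, "p1", "outbound", "regular", message_id=mid,
                     kind="bct", status="Delivered")

    def test_most_recent_delivery_wins(self):
        t1, t2 = NOW, NOW + timedelta(hours=2)
        log = [self.delivered(t1, "m1"), self.delivered(t2, "m2")]
        assert attribute_rating(log, "p1", at=t2 + timedelta(hours=1)) == "m2"

    def test_rating_between_two_deliveries_hits_the_first(self):
        t1, t2 = NOW, NOW + timedelta(hours=2)
        log = [self.delivered(t1, "m1"), self.delivered(t2, "m2")]
        assert attribute_rating(log, "p1", at=t1 + timedelta(hours=1)) == "m1"

    def test_rating_before_any_delivery_is_none(self):
        log = [self.delivered(NOW, "m1")]
        assert attribute_rating(log, "p1", at=NOW - timedelta(hours=1)) is None

    def test_failed_and_prompt_sends_are_not_attributable(self):
        log = [
            Event(NOW, "p1", "outbound", "regular", message_id="m1",
                  kind="bct", status="Failed"),
            Event(NOW, "p1", "outbound", "weekly_prompt", status="Delivered"),
        ]
        assert attribute_rating(log, "p1", at=NOW + timedelta(hours=1)) is None


class TestAccess:
    @pytest.mark.parametrize(
        "level,action,allowed",
        [
            ("admin", "add system users", True),
            ("researcher", "add system users", False),
            ("user", "add system users", False),
            ("admin", "add participants", True),
            ("researcher", "add participants", True),
            ("user", "add participants", False),
            ("researcher", "view sms", True),
            ("user", "view sms", False),
            ("admin", "list of participants".replace("of ", ""), True),
            ("researcher", "list participants", True),
            ("user", "list participants", True),
            ("user", "view own details", True),
        ],
    )
    def test_privilege_matrix(self, level, action, allowed):
        assert authorize(Role(level), action) is allowed

    def test_unknown_action_denied_for_everyone(self):
        for level in ("admin", "researcher", "user"):
            assert not authorize(Role(level), "drop all tables")

    def test_privileges_strictly_nested(self):
        from smstailor.interaction import PERMISSIONS

        assert PERMISSIONS["user"] < PERMISSIONS["researcher"] < PERMISSIONS["admin"]
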