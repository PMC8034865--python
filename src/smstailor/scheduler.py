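"""Outbound message timeline: weekly cadence, reminders, control-arm sends.

Intervention participants receive 3 messages per week at an even nominal
spacing of 56 hours (7×24/3), each snapped to the midpoint of the
participant's chosen delivery window on that calendar day — so sends fall
on days 0, 2 and 4 of each study week, at 10:30 for the AM window
(09:00–12:00) and 15:00 for the PM window (12:00–18:00).

Scheduled reminders per study variant:

* pilot — a weekly prompt asking the participant to rate received
  messages (sent 24 h after the week's last regular send, i.e. day 5),
  plus a week-4 reminder on the rating commands;
* feasibility (intervention arm) — the week-4 rating-command reminder
  only (no weekly prompt);
* both — a Help-commands reminder at the start and at the study midpoint,
  a birthday text on the participant's date-of-birth anniversary, and a
  World Diabetes Day text on 14 November, when those dates fall inside
  the study window.

Control-arm participants (feasibility only) instead receive one control
message every 28 days, cycling through the six control texts in fixed
order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from datetime import date, datetime, time, timedelta

from .interaction import ParticipantState
from .library import MessageLibrary

#: delivery windows, local study time: label -> (start, end, send time)
WINDOWS = {
    "AM": (time(9, 0), time(12, 0), time(10, 30)),
    "PM": (time(12, 0), time(18, 0), time(15, 0)),
}

NOMINAL_OFFSETS_H = (0, 56, 112)  # even gaps: 7*24/3 hours
CONTROL_PERIOD_DAYS = 28  # "approximately once a month"
WDD_MONTH_DAY = (11, 14)  # World Diabetes Day

ORIGINS = (
    "regular",
    "followup",
    "weekly_prompt",
    "command_reminder",
    "help_reminder",
    "birthday",
    "wdd",
    "control",
)


@dataclass(frozen=True)
class ScheduledSend:
    participant_id: str
    due_time: datetime
    origin: str
    message_id: str | None = None  # resolved at dispatch for regular/followup


@dataclass(frozen=True)
class StudyCalendar:
    """Per-participant study dates: pilot runs 13 weeks (extendable to 26),
    feasibility 26 weeks."""

    start: datetime
    weeks: int
    dob: date | None = None

    @property
    def end(self) -> datetime:
        return self.start + timedelta(weeks=self.weeks)

    @property
    def midpoint_week(self) -> int:
        return math.ceil(self.weeks / 2)


def window_send_time(state: ParticipantState, day: date) -> datetime:
    """The send instant on a given day: the midpoint of the participant's window."""
    return datetime.combine(day, WINDOWS[state.delivery_window][2])


def in_window(state: ParticipantState, t: datetime) -> bool:
    start, end, _ = WINDOWS[state.delivery_window]
    return start <= t.time() < end


def build_week_schedule(
    state: ParticipantState, week_index: int, start: datetime | None = None
) -> list[ScheduledSend]:
    """The 3 regular intervention sends for one study week.

    Nominal offsets of 0/56/112 h from the week start are snapped to the
    window midpoint of their calendar day, landing on days 0, 2 and 4.
    Paused or stopped participants (and control-arm participants) get an
    empty list.
    """
    if state.status != "active" or state.arm == "control":
        return []
    start = start or state.started_at
    if start is None:
        raise ValueError("participant has no start time")
    week_start = start + timedelta(weeks=week_index)
    sends = []
    for off in NOMINAL_OFFSETS_H:
        # snap the nominal offset to its whole day, then to the window midpoint
        day = week_start.date() + timedelta(days=off // 24)
        sends.append(
            ScheduledSend(
                participant_id=state.participant_id,
                due_time=window_send_time(state, day),
                origin="regular",
            )
        )
    return sends


def reminder_plan(state: ParticipantState, calendar: StudyCalendar) -> list[ScheduledSend]:
    """All scheduled reminders for one participant over the study window."""
    if state.status not in ("active", "pending"):
        return []
    sends: list[ScheduledSend] = []
    pid = state.participant_id

    def at_week(week: int, day_offset: int = 0) -> datetime:
        day = (calendar.start + timedelta(weeks=week, days=day_offset)).date()
        return window_send_time(state, day)

    intervention = state.arm != "control"

    if state.study == "pilot":
        # weekly rating prompt, 24 h after the week's last regular send (day 4)
        for wk in range(calendar.weeks):
            sends.append(ScheduledSend(pid, at_week(wk, day_offset=5), "weekly_prompt"))
    if intervention and calendar.weeks > 4:
        sends.append(ScheduledSend(pid, at_week(4), "command_reminder"))

    sends.append(ScheduledSend(pid, at_week(0), "help_reminder"))
    if calendar.midpoint_week < calendar.weeks:
        sends.append(ScheduledSend(pid, at_week(calendar.midpoint_week), "help_reminder"))

    if calendar.dob is not None:
        for year in range(calendar.start.year, calendar.end.year + 1):
            try:
                bday = calendar.dob.replace(year=year)
            except ValueError:  # Feb 29
                bday = date(year, 3, 1)
            t = window_send_time(state, bday)
            if calendar.start <= t < calendar.end:
                sends.append(ScheduledSend(pid, t, "birthday"))

    for year in range(calendar.start.year, calendar.end.year + 1):
        wdd = date(year, *WDD_MONTH_DAY)
        t = window_send_time(state, wdd)
        if calendar.start <= t < calendar.end:
            sends.append(ScheduledSend(pid, t, "wdd"))

    sends.sort(key=lambda s: s.due_time)
    return sends


def control_arm_schedule(
    state: ParticipantState, lib: MessageLibrary, calendar: StudyCalendar | None = None
) -> list[ScheduledSend]:
    """Monthly control sends cycling through the control messages in order."""
    if state.study == "pilot":
        raise ValueError("the pilot study has no control arm")
    if state.arm != "control":
        raise ValueError("control schedule requested for a non-control participant")
    if state.status != "active":
        return []
    if not lib.control:
        raise ValueError("library has no control messages")
    calendar = calendar or StudyCalendar(start=state.started_at, weeks=26)
    sends = []
    # one send per complete 28-day period: 26 weeks (182 days) -> 6 sends
    n_sends = (calendar.weeks * 7) // CONTROL_PERIOD_DAYS
    for i in range(n_sends):
        day = (calendar.start + timedelta(days=i * CONTROL_PERIOD_DAYS)).date()
        sends.append(
            ScheduledSend(
                participant_id=state.participant_id,
                due_time=window_send_time(state, day),
                origin="control",
                message_id=lib.control[i % len(lib.control)].message_id,
            )
        )
    return sends


def full_timeline(
    state: ParticipantState, lib: MessageLibrary, calendar: StudyCalendar
) -> list[ScheduledSend]:
    """Regular + reminder (+ control) sends for one participant, time-ordered."""
    sends: list[ScheduledSend] = []
    if state.arm == "control":
        sends.extend(control_arm_schedule(state, lib, calendar))
    else:
        for wk in range(calendar.weeks):
            sends.extend(build_week_schedule(state, wk, start=calendar.start))
    sends.extend(reminder_plan(state, calendar))
    # at a shared instant, prompts/reminders go out ahead of content sends
    content = ("regular", "followup", "control")
    sends.sort(key=lambda s: (s.due_time, 1 if s.origin in content else 0))
    return sends
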