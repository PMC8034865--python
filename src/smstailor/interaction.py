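"""Two-way SMS command handling: parsing, participant lifecycle, registry, roles.

Participants steer the intervention by texting short commands: register,
start/stop/pause, AM/PM delivery-window choice, help requests, and message
ratings (Like/Dislike in both study variants; Easy/Hard, Useful/Not
Useful, More/Less in the pilot only).

Inbound routing has two modes.  With a shared toll-free number every text
must begin with a routing keyword (default ``DIA``) or it never reaches
the system; with a dedicated virtual number no keyword is needed.
``parse_inbound`` is total: any string maps to a :class:`ParsedCommand`
or a structured :class:`Unrecognized` value, never an exception.

The participant lifecycle is pending → active with paused/stopped
excursions; ``stopped`` is absorbing except via an explicit study-team
(admin) restart.
"""

from __future__ import annotations

import csv
import json
import re
from dataclasses import dataclass, replace
from datetime import datetime, timedelta
from pathlib import Path
from typing import Iterable

DEFAULT_KEYWORD = "DIA"

RATING_VERBS_PILOT = frozenset(
    {"like", "dislike", "easy", "hard", "useful", "not_useful", "more", "less"}
)
RATING_VERBS_FEASIBILITY = frozenset({"like", "dislike"})
RATING_VERBS = {"pilot": RATING_VERBS_PILOT, "feasibility": RATING_VERBS_FEASIBILITY}

#: ratings that adapt selection weights: positive doubles, negative halves
POSITIVE_RATINGS = frozenset({"like", "more"})
NEGATIVE_RATINGS = frozenset({"dislike", "less"})

COMMON_VERBS = frozenset({"register", "start", "stop", "pause", "am", "pm", "help"})
COMMANDS_BY_STUDY = {
    "pilot": COMMON_VERBS | RATING_VERBS_PILOT,
    "feasibility": COMMON_VERBS | RATING_VERBS_FEASIBILITY,
}
HELP_LEVELS = {"pilot": (1, 2, 3), "feasibility": (1, 2)}

HANDSHAKE_REPLY = (
    "Thank you for registering your interest. Your mobile number has been "
    "confirmed and the study team will be in touch."
)
HELP_TEXTS = {
    1: "Help 1: text STOP to stop, PAUSE <weeks> to pause, START to resume, AM or PM to choose your delivery time.",
    2: "Help 2: rate the last message by texting LIKE or DISLIKE.",
    3: "Help 3: you can also rate messages with EASY/HARD, USEFUL/NOT USEFUL, and ask for MORE or LESS similar messages.",
}
HELP_HINT = "Sorry, that was not recognised. Text HELP for the list of commands."


@dataclass(frozen=True)
class ParsedCommand:
    verb: str
    names: str | None = None  # register
    weeks: int | None = None  # pause
    help_level: int = 1  # help


@dataclass(frozen=True)
class Unrecognized:
    raw: str
    reason: str


@dataclass(frozen=True)
class RegistryRecord:
    """Personal details shared at recruitment; the mobile number is the matching key."""

    first_name: str
    last_name: str
    mobile: str
    gp_practice: str
    dob: str  # ISO date
    preferred_name: str
    gender: str
    nhs_number: str
    smartphone: bool
    study_id: str
    arm: str  # intervention | control | none


@dataclass
class ParticipantState:
    participant_id: str
    study: str  # pilot | feasibility
    arm: str = "none"  # intervention | control | none (pilot)
    status: str = "pending"  # pending | active | paused | stopped | finished
    delivery_window: str = "AM"  # AM | PM
    pause_until: datetime | None = None
    registered_at: datetime | None = None
    started_at: datetime | None = None
    profile: RegistryRecord | None = None


class CommandRejected(Exception):
    """An otherwise-valid command that the state machine refuses."""


# ---------------------------------------------------------------------------
# Parsing
# ---------------------------------------------------------------------------

_PAUSE_RE = re.compile(r"^pause\s+(\d+)$", re.IGNORECASE)
_HELP_RE = re.compile(r"^help(?:\s+([123]))?$", re.IGNORECASE)

_SINGLE_WORD = {
    "start": "start",
    "stop": "stop",
    "am": "am",
    "pm": "pm",
    "like": "like",
    "dislike": "dislike",
    "more": "more",
    "less": "less",
    "easy": "easy",
    "hard": "hard",
    "useful": "useful",
}


def parse_inbound(
    raw: str, mode: str = "virtual_number", keyword: str = DEFAULT_KEYWORD
) -> ParsedCommand | Unrecognized:
    """Parse one inbound text into a command; total over all strings.

    ``mode='keyword'`` models the shared toll-free number: texts that do
    not start with the routing keyword are returned as
    ``Unrecognized(reason='missing keyword')``, mirroring the real failure
    mode in which such texts never reach the system at all.  Matching is
    case-insensitive and whitespace-tolerant.
    """
    text = (raw or "").strip()
    if mode == "keyword":
        parts = text.split(None, 1)
        if not parts or parts[0].upper() != keyword.upper():
            return Unrecognized(raw=raw, reason="missing keyword")
        text = parts[1].strip() if len(parts) > 1 else ""
    if not text:
        return Unrecognized(raw=raw, reason="empty")

    lowered = " ".join(text.lower().split())
    if lowered in _SINGLE_WORD:
        return ParsedCommand(verb=_SINGLE_WORD[lowered])
    if lowered in ("not useful", "not_useful", "notuseful"):
        return ParsedCommand(verb="not_useful")
    if m := _HELP_RE.match(lowered):
        return ParsedCommand(verb="help", help_level=int(m.group(1) or 1))
    if m := _PAUSE_RE.match(lowered):
        weeks = int(m.group(1))
        if weeks < 1:
            return Unrecognized(raw=raw, reason="pause weeks must be positive")
        return ParsedCommand(verb="pause", weeks=weeks)
    if lowered.startswith("register"):
        names = text[len("register"):].strip()
        return ParsedCommand(verb="register", names=names or None)
    return Unrecognized(raw=raw, reason="unknown command")


# ---------------------------------------------------------------------------
# Participant state machine
# ---------------------------------------------------------------------------

def apply_command(
    state: ParticipantState, cmd: ParsedCommand, now: datetime
) -> tuple[ParticipantState, list[str]]:
    """Apply one parsed command; return the new state and any reply texts.

    Rating verbs leave the state untouched (the caller routes them to
    rating attribution and weight adaptation).  ``start`` on a stopped
    participant is rejected: leaving ``stopped`` requires the study team
    (:func:`admin_restart`).
    """
    if cmd.verb not in COMMANDS_BY_STUDY[state.study]:
        raise CommandRejected(f"command {cmd.verb!r} is not available in the {state.study} study")

    if cmd.verb == "register":
        new = replace(state, status="pending", registered_at=now)
        return new, [HANDSHAKE_REPLY]
    if cmd.verb == "stop":
        # absorbing: no further replies or sends until an admin restart
        return replace(state, status="stopped", pause_until=None), []
    if cmd.verb == "start":
        if state.status == "stopped":
            raise CommandRejected("restart after STOP requires the study team")
        return replace(state, status="active", pause_until=None), [
            "Messages restarted. Welcome back."
        ]
    if cmd.verb == "pause":
        until = now + timedelta(weeks=cmd.weeks or 1)
        return replace(state, status="paused", pause_until=until), [
            f"Messages paused for {cmd.weeks} week(s)."
        ]
    if cmd.verb in ("am", "pm"):
        window = cmd.verb.upper()
        return replace(state, delivery_window=window), [
            f"You will now receive messages in the {window} window."
        ]
    if cmd.verb == "help":
        level = cmd.help_level if cmd.help_level in HELP_LEVELS[state.study] else 1
        return state, [HELP_TEXTS[level]]
    # rating verbs: no state change here
    return state, []


def admin_restart(state: ParticipantState) -> ParticipantState:
    """Study-team restart: the only way out of ``stopped``."""
    return replace(state, status="active", pause_until=None)


def resume_if_due(state: ParticipantState, now: datetime) -> ParticipantState:
    """Auto-resume a paused participant once ``pause_until`` has passed."""
    if state.status == "paused" and state.pause_until is not None and now >= state.pause_until:
        return replace(state, status="active", pause_until=None)
    return state


def handle_unrecognized(state: ParticipantState, unrec: Unrecognized) -> list[str]:
    """Reply policy for unparseable texts: hint registered active senders, ignore others."""
    if state.status in ("active", "paused") and unrec.reason != "missing keyword":
        return [HELP_HINT]
    return []


# ---------------------------------------------------------------------------
# Rating attribution
# ---------------------------------------------------------------------------

def attribute_rating(event_log: Iterable, participant_id: str, at: datetime) -> str | None:
    """Return the message a rating refers to: the most recent intervention
    message (BCT or lifestyle) delivered to the participant strictly
    before ``at``; ``None`` if there was no prior delivery.

    ``event_log`` is any iterable of event records with ``participant_id``,
    ``direction``, ``etype``, ``status``, ``kind``, ``message_id`` and ``t``
    attributes (see :mod:`smstailor.metrics`).
    """
    best_t, best_id = None, None
    for ev in event_log:
        if (
            ev.participant_id == participant_id
            and ev.direction == "outbound"
            and ev.etype in ("regular", "followup")
            and ev.status == "Delivered"
            and ev.kind in ("bct", "lifestyle")
            and ev.t < at
            and (best_t is None or ev.t >= best_t)
        ):
            best_t, best_id = ev.t, ev.message_id
    return best_id


# ---------------------------------------------------------------------------
# Role-based access (three nested privilege levels)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Role:
    level: str  # admin | researcher | user


_ADMIN_ONLY = frozenset(
    {"add_system_users", "list_system_users", "edit_system_users"}
)
_RESEARCHER_UP = frozenset(
    {
        "add_participants",
        "add_gp_practices",
        "edit_participants",
        "edit_gp_practices",
        "list_sms",
        "view_sms",
    }
)
_ALL_LEVELS = frozenset(
    {
        "list_participants",
        "search_participants",
        "list_gp_practices",
        "view_participants",
        "view_gp_practices",
        "view_own_details",
    }
)

PERMISSIONS = {
    "admin": _ADMIN_ONLY | _RESEARCHER_UP | _ALL_LEVELS,
    "researcher": _RESEARCHER_UP | _ALL_LEVELS,
    "user": _ALL_LEVELS,
}


def authorize(role: Role, action: str) -> bool:
    """Allow/deny an action for a privilege level; unknown actions are denied.

    Admins manage system users on top of everything below; researchers
    additionally add/edit participants and GP practices and see SMS
    traffic; plain users get read-only participant and practice views.
    """
    key = action.strip().lower().replace(" ", "_")
    return key in PERMISSIONS.get(role.level, frozenset())


# ---------------------------------------------------------------------------
# Roster I/O
# ---------------------------------------------------------------------------

_ROSTER_FIELDS = [
    "participant_id",
    "study",
    "arm",
    "first_name",
    "last_name",
    "mobile",
    "gp_practice",
    "dob",
    "preferred_name",
    "gender",
    "nhs_number",
    "smartphone",
    "study_id",
    "delivery_window",
]


def write_roster(
    roster: list[tuple[RegistryRecord, ParticipantState]], path: str | Path
) -> None:
    path = Path(path)
    rows = []
    for rec, st in roster:
        rows.append(
            {
                "participant_id": st.participant_id,
                "study": st.study,
                "arm": st.arm,
                "first_name": rec.first_name,
                "last_name": rec.last_name,
                "mobile": rec.mobile,
                "gp_practice": rec.gp_practice,
                "dob": rec.dob,
                "preferred_name": rec.preferred_name,
                "gender": rec.gender,
                "nhs_number": rec.nhs_number,
                "smartphone": rec.smartphone,
                "study_id": rec.study_id,
                "delivery_window": st.delivery_window,
            }
        )
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(rows, indent=1) + "\n")
    else:
        with path.open("w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=_ROSTER_FIELDS)
            writer.writeheader()
            writer.writerows(rows)


def read_roster(path: str | Path) -> list[tuple[RegistryRecord, ParticipantState]]:
    path = Path(path)
    if path.suffix.lower() == ".json":
        rows = json.loads(path.read_text())
    else:
        with path.open(newline="") as fh:
            rows = list(csv.DictReader(fh))
    out = []
    mobiles: set[str] = set()
    for row in rows:
        if row["mobile"] in mobiles:
            raise ValueError(f"duplicate mobile number {row['mobile']!r} in roster")
        mobiles.add(row["mobile"])
        rec = RegistryRecord(
            first_name=row["first_name"],
            last_name=row["last_name"],
            mobile=row["mobile"],
            gp_practice=row["gp_practice"],
            dob=row["dob"],
            preferred_name=row["preferred_name"],
            gender=row["gender"],
            nhs_number=row["nhs_number"],
            smartphone=str(row["smartphone"]).lower() in ("true", "1", "yes"),
            study_id=row["study_id"],
            arm=row["arm"],
        )
        st = ParticipantState(
            participant_id=row["participant_id"],
            study=row["study"],
            arm=row["arm"],
            delivery_window=row.get("delivery_window", "AM"),
            profile=rec,
        )
        out.append((rec, st))
    return out
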