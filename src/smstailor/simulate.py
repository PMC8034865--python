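"""Synthetic cohort simulation: the stand-in for a human study population.

``simulate_cohort`` wires every component together — roster generation,
registration handshakes, the weekly schedule, message selection, the mock
delivery gateway with retries, inbound command parsing, rating
attribution and weight adaptation — and emits the event log the metrics
module consumes.  Participant behaviour is a simple memoryless model: on
each delivered intervention message the participant sends one rating with
probability ``rating_prob`` (positive with probability ``like_fraction``),
prefixes the routing keyword with probability ``keyword_compliance`` when
one is requested, and each week may pause or stop with small hazards.

The one departure from memorylessness is the reminder boost: for the 4
weeks after the week-4 rating-command reminder, ``rating_prob`` is
multiplied by a factor that starts at ``reminder_boost`` and decays
linearly back to 1 over the window — producing a rating peak in week 5
that returns to baseline by week 9, the qualitative signature of the
reminder effect this simulator is meant to reproduce.

Two canned scenarios mirror the study designs at their real sizes:
``pilot_default`` (48 participants, 13 weeks, weekly prompts, q=5, a
requested routing keyword) and ``feasibility_default`` (209 participants,
26 weeks, q=2, 1:1 control/intervention arms, no keyword).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from datetime import date, datetime, timedelta

import numpy as np

from . import engine, gateway, interaction, metrics, scheduler
from .interaction import ParticipantState, RegistryRecord
from .library import MessageLibrary, generate_fixture_library
from .metrics import Event, EventLog

DEFAULT_START = datetime(2024, 1, 8, 9, 0)  # a Monday, local study time

FIRST_NAMES = [
    "Alex", "Sam", "Chris", "Jo", "Pat", "Morgan", "Jamie", "Robin",
    "Charlie", "Frankie", "Ash", "Dana", "Eli", "Gene", "Kim", "Lee",
]
LAST_NAMES = [
    "Smith", "Jones", "Taylor", "Brown", "Williams", "Wilson", "Johnson",
    "Davies", "Patel", "Robinson", "Wright", "Thompson", "Evans", "Walker",
    "White", "Green",
]


@dataclass(frozen=True)
class BehaviorProfile:
    """Stochastic participant behaviour parameters (all probabilities per event)."""

    rating_prob: float = 0.25  # per delivered intervention message
    like_fraction: float = 0.8  # share of ratings that are positive
    keyword_compliance: float = 0.93  # P(inbound correctly keyworded)
    reminder_boost: float = 3.0  # rating_prob multiplier right after the reminder
    boost_weeks: int = 4  # fixed decay window of the reminder effect
    weekly_stop_hazard: float = 0.002
    pause_prob: float = 0.002  # per week; pause length 1-4 weeks
    response_delay_hours: float = 4.0  # mean of an exponential delay
    delivery_failure_rate: float = 0.01
    malformed_rate: float = 0.01  # inbound texts that parse to nothing


@dataclass(frozen=True)
class CohortConfig:
    n: int
    study: str  # pilot | feasibility
    weeks: int
    seed: int
    keyword: str | None = None  # requested routing keyword, or None
    median_age: float = 65.0
    age_spread: float = 8.0
    am_fraction: float = 0.5
    start: datetime = DEFAULT_START


# ---------------------------------------------------------------------------
# Roster generation
# ---------------------------------------------------------------------------

def generate_roster(cfg: CohortConfig) -> list[tuple[RegistryRecord, ParticipantState]]:
    """Synthetic participants; feasibility uses alternating-block 1:1 arms."""
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 11]))
    arms: list[str] = []
    if cfg.study == "feasibility":
        # randomised permuted blocks of 2: exact 1:1 split for even n
        while len(arms) < cfg.n:
            block = ["intervention", "control"]
            if rng.random() < 0.5:
                block.reverse()
            arms.extend(block)
        arms = arms[: cfg.n]
    else:
        arms = ["none"] * cfg.n

    roster = []
    for i in range(cfg.n):
        pid = f"p{i + 1:04d}"
        age = max(30.0, rng.normal(cfg.median_age, cfg.age_spread))
        dob = cfg.start.date() - timedelta(days=int(age * 365.25))
        rec = RegistryRecord(
            first_name=FIRST_NAMES[int(rng.integers(len(FIRST_NAMES)))],
            last_name=LAST_NAMES[int(rng.integers(len(LAST_NAMES)))],
            mobile=f"+4477{i + 1:07d}",
            gp_practice=f"Practice {int(rng.integers(1, 21)):02d}",
            dob=dob.isoformat(),
            preferred_name=FIRST_NAMES[int(rng.integers(len(FIRST_NAMES)))],
            gender=("female" if rng.random() < 0.41 else "male"),
            nhs_number=f"{rng.integers(10**9, 10**10 - 1)}",
            smartphone=bool(rng.random() < 0.8),
            study_id=f"S{i + 1:04d}",
            arm=arms[i],
        )
        st = ParticipantState(
            participant_id=pid,
            study=cfg.study,
            arm=arms[i],
            status="active",
            delivery_window="AM" if rng.random() < cfg.am_fraction else "PM",
            registered_at=cfg.start - timedelta(days=7),
            started_at=cfg.start,
            profile=rec,
        )
        roster.append((rec, st))
    return roster


# ---------------------------------------------------------------------------
# Cohort simulation
# ---------------------------------------------------------------------------

def _boost_factor(profile: BehaviorProfile, reminder_at: datetime | None, t: datetime) -> float:
    """Linearly decaying rating-probability multiplier after the command reminder."""
    if reminder_at is None or t < reminder_at:
        return 1.0
    window = timedelta(weeks=profile.boost_weeks)
    age = t - reminder_at
    if age >= window:
        return 1.0
    frac = 1.0 - age / window
    return 1.0 + (profile.reminder_boost - 1.0) * frac


def _rating_verb(study: str, positive: bool, rng: np.random.Generator) -> str:
    if study == "feasibility":
        return "like" if positive else "dislike"
    pair = ("like", "dislike"), ("useful", "not_useful"), ("easy", "hard"), ("more", "less")
    pos, neg = pair[int(rng.integers(len(pair)))]
    return pos if positive else neg


def _parse_tolerant(raw: str, keyword: str | None):
    """Parse an inbound text, stripping the requested keyword when present.

    Models arrival over a dedicated virtual number with a *requested*
    routing keyword: keyworded and unkeyworded texts both reach the
    system, and a leading keyword is stripped before verb parsing.
    """
    if keyword:
        parsed = interaction.parse_inbound(raw, mode="keyword", keyword=keyword)
        if not (
            isinstance(parsed, interaction.Unrecognized)
            and parsed.reason == "missing keyword"
        ):
            return parsed
    return interaction.parse_inbound(raw, mode="virtual_number")


def _simulate_participant(
    state: ParticipantState,
    rec: RegistryRecord,
    lib: MessageLibrary,
    profile: BehaviorProfile,
    cfg: CohortConfig,
    rng: np.random.Generator,
) -> list[Event]:
    events: list[Event] = []
    pid = state.participant_id
    mode = "keyword" if cfg.keyword else "virtual_number"

    # registration handshake one week before the first scheduled message
    reg_t = state.registered_at or cfg.start - timedelta(days=7)
    reg_raw = f"Register {rec.first_name} {rec.last_name}"
    if cfg.keyword:
        reg_raw = f"{cfg.keyword} {reg_raw}"
    cmd = interaction.parse_inbound(reg_raw, mode=mode, keyword=cfg.keyword or "DIA")
    events.append(Event(reg_t, pid, "inbound", cmd.verb, raw=reg_raw))
    state, replies = interaction.apply_command(state, cmd, reg_t)
    for reply in replies:
        events.append(
            Event(reg_t, pid, "outbound", "handshake", raw=reply, status="Delivered")
        )
    state = replace(state, status="active")

    calendar = scheduler.StudyCalendar(
        start=cfg.start, weeks=cfg.weeks, dob=date.fromisoformat(rec.dob)
    )
    timeline = scheduler.full_timeline(state, lib, calendar)

    # pre-sample weekly lifecycle events (stop is absorbing, pause is transient)
    stop_at: datetime | None = None
    pauses: list[tuple[datetime, datetime]] = []
    for wk in range(1, cfg.weeks):
        boundary = cfg.start + timedelta(weeks=wk)
        u = rng.random()
        if u < profile.weekly_stop_hazard:
            stop_at = boundary
            break
        if u < profile.weekly_stop_hazard + profile.pause_prob:
            length = int(rng.integers(1, 5))
            pauses.append((boundary, boundary + timedelta(weeks=length)))

    transport = gateway.MockTransport(
        failure_rate=profile.delivery_failure_rate,
        rng=np.random.default_rng(rng.integers(2**31)),
    )
    sel_state = engine.SelectionState()
    weights = engine.GroupWeights.uniform(lib)
    reminder_at: datetime | None = None
    stop_logged = False

    for send in timeline:
        t = send.due_time
        if stop_at is not None and t >= stop_at:
            if not stop_logged:
                raw = f"{cfg.keyword} STOP" if cfg.keyword else "STOP"
                events.append(Event(stop_at, pid, "inbound", "stop", raw=raw))
                state, _ = interaction.apply_command(
                    state, interaction.ParsedCommand(verb="stop"), stop_at
                )
                stop_logged = True
            break
        paused = next((p for p in pauses if p[0] <= t < p[1]), None)
        if paused is not None:
            continue  # paused: the send is skipped, not back-filled

        # resolve the message for this slot
        body, message_id, kind, group_id = None, send.message_id, None, None
        origin = send.origin
        if send.origin in ("regular", "followup"):
            before = {(fu.group_id, fu.due_time) for fu in sel_state.pending_followups}
            msg, sel_state = engine.select_next_message(
                lib, sel_state, weights, rng, now=t
            )
            after = {(fu.group_id, fu.due_time) for fu in sel_state.pending_followups}
            consumed = {g for g, _ in before - after}
            if msg.group_id is not None and msg.group_id in consumed:
                origin = "followup"  # this slot satisfied a 2-week follow-up
            message_id, kind, group_id, body = (
                msg.message_id, msg.kind, msg.group_id, msg.body,
            )
        elif send.origin == "control":
            msg = lib.message(send.message_id)
            kind, body = msg.kind, msg.body
        else:
            body = f"[{send.origin}] scheduled study text"
        if send.origin == "command_reminder":
            reminder_at = t

        record, alert = gateway.deliver(pid, rec.mobile, body, transport, t)
        events.append(
            Event(
                t, pid, "outbound", origin,
                message_id=message_id, kind=kind, group_id=group_id,
                raw=body, status=record.status,
            )
        )
        if alert is not None:
            events.append(Event(alert.at, pid, "system", "alert", raw=alert.text))
        if record.status != "Delivered":
            continue

        # stochastic rating response to delivered intervention messages
        if send.origin in ("regular", "followup") and kind in ("bct", "lifestyle"):
            p = min(1.0, profile.rating_prob * _boost_factor(profile, reminder_at, t))
            if rng.random() < p:
                delay = timedelta(hours=float(rng.exponential(profile.response_delay_hours)))
                at = t + delay
                positive = rng.random() < profile.like_fraction
                verb = _rating_verb(cfg.study, positive, rng)
                if rng.random() < profile.malformed_rate:
                    raw = "??" + verb
                elif cfg.keyword and rng.random() < profile.keyword_compliance:
                    raw = f"{cfg.keyword} {verb.replace('_', ' ').upper()}"
                else:
                    raw = verb.replace("_", " ").capitalize()
                parsed = _parse_tolerant(raw, cfg.keyword)
                etype = (
                    parsed.verb
                    if isinstance(parsed, interaction.ParsedCommand)
                    else "unrecognized"
                )
                events.append(Event(at, pid, "inbound", etype, raw=raw))
                if etype in interaction.RATING_VERBS[cfg.study]:
                    target = interaction.attribute_rating(events, pid, at)
                    if target is not None:
                        rated = lib.message(target)
                        if rated.kind == "bct":
                            direction = (
                                "increase"
                                if etype in interaction.POSITIVE_RATINGS
                                else "decrease"
                            )
                            weights, sel_state = engine.apply_feedback(
                                weights, sel_state, direction, rated.group_id, now=at
                            )
                            events.append(
                                Event(
                                    at, pid, "system", "weight_update",
                                    group_id=rated.group_id,
                                    raw=f"{direction}:{weights[rated.group_id]:g}",
                                )
                            )

    events.sort(key=lambda ev: (ev.t, ev.direction))
    return events


def simulate_cohort(
    cfg: CohortConfig, profile: BehaviorProfile, lib: MessageLibrary
) -> EventLog:
    """Run the full pipeline for a synthetic cohort; return the event log.

    Deterministic for a fixed ``cfg.seed``: each participant gets an
    independent child RNG stream, so per-participant traces are stable
    under cohort-size changes.
    """
    roster = generate_roster(cfg)
    log = EventLog()
    master = np.random.SeedSequence([cfg.seed, 23])
    children = master.spawn(len(roster))
    for (rec, st), seq in zip(roster, children):
        log.extend(
            _simulate_participant(st, rec, lib, profile, cfg, np.random.default_rng(seq))
        )
    log.sort(key=lambda ev: (ev.t, ev.participant_id, ev.direction))
    return log


# ---------------------------------------------------------------------------
# Canned scenarios
# ---------------------------------------------------------------------------

SCENARIOS = {
    "pilot_default": dict(n=48, study="pilot", weeks=13, keyword="DIA"),
    "feasibility_default": dict(n=209, study="feasibility", weeks=26, keyword=None),
}


def run_scenario(
    name: str, seed: int, profile: BehaviorProfile | None = None
) -> tuple[EventLog, dict]:
    """One-command study-shaped run; returns the event log and a metrics summary."""
    if name not in SCENARIOS:
        raise ValueError(f"unknown scenario {name!r}; choose from {sorted(SCENARIOS)}")
    params = SCENARIOS[name]
    cfg = CohortConfig(seed=seed, **params)
    profile = profile or BehaviorProfile()
    lib = generate_fixture_library(cfg.study, seed)
    log = simulate_cohort(cfg, profile, lib)

    table = metrics.participant_metrics(log, cfg.study, keyword=cfg.keyword or "DIA")
    summary = {
        "scenario": name,
        "n_participants": cfg.n,
        "weeks": cfg.weeks,
        "n_events": len(log),
        "response_rate": metrics.cohort_summary(table["response_rate"]),
    }
    if cfg.study == "pilot":
        summary["keyword_percentage"] = metrics.cohort_summary(table["keyword_percentage"])
        summary["rate_vs_prompt"] = metrics.cohort_summary(table["rate_vs_prompt"])
    return log, summary
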