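"""Engagement metrics computed from the event log.

Three per-participant metrics summarise engagement with the messaging
system:

* **response rate** — rating commands received divided by intervention
  messages (BCT + lifestyle) delivered, as a percentage.  One message can
  attract several ratings in the pilot (Like *and* Useful, say), so the
  rate can exceed 100%.  The pilot numerator counts all eight rating
  verbs; the feasibility numerator counts Like/Dislike only.
* **keyword percentage** — the share of a participant's inbound texts
  that begin with the routing keyword (default ``DIA``), in [0, 100].
* **rate versus prompt** — ratings divided by weekly prompt messages
  delivered (pilot only), as a percentage.

The weekly Like/Dislike series (total commands per week and distinct
participants sending them, counted from each participant's first study
week) expose the effect of the week-4 rating-command reminder.

The exact numerator/denominator conventions — which reminder sends are
excluded from the response-rate denominator, in particular — are this
package's reconstruction from the study descriptions, documented in
docs/methods.md.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from datetime import datetime, timedelta
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .interaction import RATING_VERBS

INTERVENTION_ORIGINS = frozenset({"regular", "followup"})


@dataclass(frozen=True)
class Event:
    """One record in the append-only event log.

    ``etype`` carries the scheduling origin for outbound records
    (regular, followup, weekly_prompt, command_reminder, help_reminder,
    birthday, wdd, control, handshake, reply, alert) and the parsed verb
    (or ``unrecognized``) for inbound records.
    """

    t: datetime
    participant_id: str
    direction: str  # outbound | inbound | system
    etype: str
    message_id: str | None = None
    kind: str | None = None  # bct | lifestyle | control
    group_id: str | None = None
    raw: str | None = None
    status: str | None = None  # delivery status for outbound


class EventLog(list):
    """An append-only, time-ordered list of :class:`Event` records."""

    def for_participant(self, participant_id: str) -> "EventLog":
        return EventLog(ev for ev in self if ev.participant_id == participant_id)

    @property
    def participant_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for ev in self:
            seen.setdefault(ev.participant_id, None)
        return list(seen)

    def to_jsonl(self, path: str | Path) -> None:
        with Path(path).open("w") as fh:
            for ev in self:
                row = asdict(ev)
                row["t"] = ev.t.isoformat()
                fh.write(json.dumps(row) + "\n")

    @classmethod
    def from_jsonl(cls, path: str | Path) -> "EventLog":
        log = cls()
        with Path(path).open() as fh:
            for line in fh:
                if not line.strip():
                    continue
                row = json.loads(line)
                row["t"] = datetime.fromisoformat(row["t"])
                log.append(Event(**row))
        return log

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame([asdict(ev) for ev in self])


def _delivered_intervention(log: Iterable[Event], pid: str) -> int:
    return sum(
        1
        for ev in log
        if ev.participant_id == pid
        and ev.direction == "outbound"
        and ev.etype in INTERVENTION_ORIGINS
        and ev.status == "Delivered"
    )


def _rating_count(log: Iterable[Event], pid: str, study: str) -> int:
    verbs = RATING_VERBS[study]
    return sum(
        1
        for ev in log
        if ev.participant_id == pid and ev.direction == "inbound" and ev.etype in verbs
    )


def response_rate(log: Iterable[Event], participant_id: str, study: str) -> float | None:
    """Rating responses per delivered intervention message, as a percent.

    Returns ``None`` (missing) when no intervention message was
    delivered.  May exceed 100 when single messages attract multiple
    ratings.
    """
    delivered = _delivered_intervention(log, participant_id)
    if delivered == 0:
        return None
    return 100.0 * _rating_count(log, participant_id, study) / delivered


def keyword_percentage(
    log: Iterable[Event], participant_id: str, keyword: str = "DIA"
) -> float | None:
    """Share of the participant's inbound texts starting with the routing keyword."""
    inbound = [
        ev.raw
        for ev in log
        if ev.participant_id == participant_id
        and ev.direction == "inbound"
        and ev.raw is not None
    ]
    if not inbound:
        return None
    kw = keyword.upper()
    hits = sum(1 for raw in inbound if raw.strip().upper().startswith(kw))
    return 100.0 * hits / len(inbound)


def rate_vs_prompt(log: Iterable[Event], participant_id: str) -> float | None:
    """Pilot ratings per delivered weekly prompt, as a percent."""
    prompts = sum(
        1
        for ev in log
        if ev.participant_id == participant_id
        and ev.direction == "outbound"
        and ev.etype == "weekly_prompt"
        and ev.status == "Delivered"
    )
    if prompts == 0:
        return None
    return 100.0 * _rating_count(log, participant_id, "pilot") / prompts


def weekly_feedback_counts(
    log: Iterable[Event], starts: dict[str, datetime], weeks: int | None = None
) -> pd.DataFrame:
    """Weekly Like/Dislike totals and distinct senders, week 1 onward.

    ``starts`` maps participant id to their randomization/start time;
    week ``k`` covers days ``[7(k-1), 7k)`` after that participant's
    start.  Returns a DataFrame indexed by week with ``total_commands``
    and ``participants`` columns (distinct senders, pointwise <= totals).
    """
    rows = []
    for ev in log:
        if ev.direction != "inbound" or ev.etype not in ("like", "dislike"):
            continue
        start = starts.get(ev.participant_id)
        if start is None or ev.t < start:
            continue
        week = int((ev.t - start) // timedelta(weeks=1)) + 1
        rows.append((week, ev.participant_id))
    if weeks is None:
        weeks = max((w for w, _ in rows), default=0)
    index = pd.RangeIndex(1, weeks + 1, name="week")
    total = pd.Series(0, index=index, dtype=int)
    distinct = pd.Series(0, index=index, dtype=int)
    by_week: dict[int, set[str]] = {}
    for week, pid in rows:
        if week in total.index:
            total[week] += 1
            by_week.setdefault(week, set()).add(pid)
    for week, pids in by_week.items():
        distinct[week] = len(pids)
    return pd.DataFrame({"total_commands": total, "participants": distinct})


def cohort_summary(values: Iterable[float | None]) -> dict[str, float]:
    """Median and quartiles over a cohort, ignoring missing values."""
    arr = np.array([v for v in values if v is not None and not math.isnan(v)], dtype=float)
    if arr.size == 0:
        return {"n": 0, "median": math.nan, "q1": math.nan, "q3": math.nan}
    q1, med, q3 = np.percentile(arr, [25, 50, 75])
    return {"n": int(arr.size), "median": float(med), "q1": float(q1), "q3": float(q3)}


def participant_metrics(
    log: EventLog, study: str, keyword: str = "DIA"
) -> pd.DataFrame:
    """Per-participant metric table (one row per participant in the log)."""
    rows = []
    for pid in log.participant_ids:
        rows.append(
            {
                "participant_id": pid,
                "response_rate": response_rate(log, pid, study),
                "keyword_percentage": keyword_percentage(log, pid, keyword),
                "rate_vs_prompt": rate_vs_prompt(log, pid) if study == "pilot" else None,
            }
        )
    return pd.DataFrame(rows)


def quadratic_fit(x: Iterable[float], y: Iterable[float]) -> np.ndarray:
    """Ordinary-least-squares quadratic fit (rated-vs-prompted helper).

    Returns the polynomial coefficients, highest degree first.
    """
    return np.polyfit(np.asarray(list(x), float), np.asarray(list(y), float), deg=2)
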