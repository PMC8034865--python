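"""Feedback-adaptive random message selection.

Selection of the next message for a participant follows four rules:

1. **Interleaving** — after ``q`` consecutive BCT messages, one general
   lifestyle message is sent (``q = 5`` pilot, ``q = 2`` feasibility), then
   the BCT counter resets.
2. **History exclusion** — a message is never repeated before its pool is
   exhausted, and the most recently used BCT group is excluded from the
   next BCT draw (so two consecutive BCT messages never share a group).
3. **Weight-proportional group choice** — an eligible BCT group is drawn
   with probability proportional to its weight (all weights start at 1),
   then a message is drawn uniformly among that group's unsent texts.
4. **Feedback adaptation** — a positive rating (Like / More) on a BCT
   message doubles its group's weight (+100% selection odds against the
   rest) and schedules a follow-up message from the same group two weeks
   later; a negative rating (Dislike / Less) halves the weight (−50%).
   Updates compound multiplicatively and leave other groups untouched, so
   the liked group's odds against the field exactly double or halve.

"Doubling the chance" is interpreted as multiplying the group's
unnormalised sampling weight — equivalently its selection odds — rather
than its normalised probability, which would be ill-defined above 0.5 and
would not compose.

Pool exhaustion: a 26-week run delivers 78 messages, which exceeds the
35-text lifestyle pool at ``q = 2``; when every message of the required
kind has been sent, the sent-history for that kind is cleared (with a
logged warning) and repeats are allowed, still honouring the
most-recent-group exclusion.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timedelta
from pathlib import Path

import numpy as np

from .library import Message, MessageLibrary

logger = logging.getLogger(__name__)

FOLLOWUP_DELAY = timedelta(days=14)
POSITIVE_FACTOR = 2.0  # Like / More: +100% selection odds
NEGATIVE_FACTOR = 0.5  # Dislike / Less: -50% selection odds


@dataclass
class GroupWeights:
    """Multiplicative per-group sampling weights, all 1.0 at enrolment."""

    weights: dict[str, float]

    @classmethod
    def uniform(cls, lib: MessageLibrary) -> "GroupWeights":
        return cls({gid: 1.0 for gid in lib.group_ids})

    def copy(self) -> "GroupWeights":
        return GroupWeights(dict(self.weights))

    def __getitem__(self, group_id: str) -> float:
        return self.weights[group_id]


@dataclass(frozen=True)
class Followup:
    """A scheduled same-group follow-up created by a positive rating."""

    group_id: str
    due_time: datetime | None  # None = due immediately


@dataclass
class SelectionState:
    """Per-participant selection memory.

    ``sent_ids`` is the no-repeat history; ``last_bct_group`` is the
    group excluded from the next BCT draw; ``consecutive_bct_count``
    triggers the lifestyle interleave when it reaches ``q``.
    """

    sent_ids: set[str] = field(default_factory=set)
    last_bct_group: str | None = None
    consecutive_bct_count: int = 0
    pending_followups: list[Followup] = field(default_factory=list)

    def copy(self) -> "SelectionState":
        return SelectionState(
            sent_ids=set(self.sent_ids),
            last_bct_group=self.last_bct_group,
            consecutive_bct_count=self.consecutive_bct_count,
            pending_followups=list(self.pending_followups),
        )


class SelectionError(ValueError):
    """Raised when no message can be selected (empty library, missing RNG)."""


def _unsent(messages: list[Message], sent: set[str]) -> list[Message]:
    return [m for m in messages if m.message_id not in sent]


def _eligible_groups(lib: MessageLibrary, state: SelectionState) -> list[str]:
    return [
        g.group_id
        for g in lib.groups
        if g.group_id != state.last_bct_group and _unsent(g.members, state.sent_ids)
    ]


def selection_probabilities(
    lib: MessageLibrary, state: SelectionState, weights: GroupWeights
) -> dict[str, float]:
    """Analytic group-selection distribution for the next regular BCT draw.

    Eligible groups (at least one unsent message, not the most recent
    group) get probability proportional to their weight; ineligible
    groups get 0.  This mirrors the sampling in
    :func:`select_next_message` and exists so Monte-Carlo behaviour can be
    checked against a closed form.
    """
    eligible = _eligible_groups(lib, state)
    if not eligible:
        raise SelectionError("no eligible BCT group")
    total = sum(weights[g] for g in eligible)
    probs = {gid: 0.0 for gid in lib.group_ids}
    for g in eligible:
        probs[g] = weights[g] / total
    return probs


def _draw_uniform(rng: np.random.Generator, items: list[Message]) -> Message:
    return items[int(rng.integers(len(items)))]


def select_next_message(
    lib: MessageLibrary,
    state: SelectionState,
    weights: GroupWeights,
    rng: np.random.Generator,
    now: datetime | None = None,
) -> tuple[Message, SelectionState]:
    """Select the next intervention message for one participant.

    Order of precedence: lifestyle interleave (when ``q`` consecutive BCT
    messages have gone out), then a due follow-up, then a regular
    weight-proportional BCT draw.  ``now`` gates follow-up dueness
    (``due_time <= now``); with ``now=None`` every pending follow-up
    counts as due.  The input state is not mutated; the updated copy is
    returned alongside the message.
    """
    if rng is None:
        raise SelectionError("a seeded random generator is required")
    if not lib.groups and not lib.lifestyle:
        raise SelectionError("empty message library")

    state = state.copy()

    # 1. lifestyle interleave
    if state.consecutive_bct_count >= lib.interleave_q:
        pool = _unsent(lib.lifestyle, state.sent_ids)
        if not pool:
            logger.warning("lifestyle pool exhausted; clearing lifestyle history")
            state.sent_ids -= {m.message_id for m in lib.lifestyle}
            pool = list(lib.lifestyle)
        if not pool:
            raise SelectionError("library has no lifestyle messages")
        msg = _draw_uniform(rng, pool)
        state.sent_ids.add(msg.message_id)
        state.consecutive_bct_count = 0
        # a lifestyle send does not reset the most-recent-group exclusion
        return msg, state

    # 2. due follow-up (consumes the regular BCT slot)
    for fu in list(state.pending_followups):
        due = now is None or fu.due_time is None or fu.due_time <= now
        if not due:
            continue
        if fu.group_id == state.last_bct_group:
            continue  # deferred: would repeat the group just used
        pool = _unsent(lib.group(fu.group_id).members, state.sent_ids)
        state.pending_followups.remove(fu)
        if not pool:
            logger.info("follow-up for exhausted group %s dropped", fu.group_id)
            continue
        msg = _draw_uniform(rng, pool)
        state.sent_ids.add(msg.message_id)
        state.last_bct_group = fu.group_id
        state.consecutive_bct_count += 1
        return msg, state

    # 3. regular weighted BCT draw
    if not lib.groups:
        raise SelectionError("library has no BCT groups")
    eligible = _eligible_groups(lib, state)
    if not eligible:
        logger.warning("BCT pool exhausted; clearing BCT history")
        all_bct = {m.message_id for g in lib.groups for m in g.members}
        state.sent_ids -= all_bct
        eligible = _eligible_groups(lib, state)
    if not eligible:
        # single-group library whose group was just used: allow the repeat
        eligible = [g.group_id for g in lib.groups if _unsent(g.members, state.sent_ids)]
    if not eligible:
        raise SelectionError("no BCT message available")
    w = np.array([weights[g] for g in eligible], dtype=float)
    gid = eligible[int(rng.choice(len(eligible), p=w / w.sum()))]
    msg = _draw_uniform(rng, _unsent(lib.group(gid).members, state.sent_ids))
    state.sent_ids.add(msg.message_id)
    state.last_bct_group = gid
    state.consecutive_bct_count += 1
    return msg, state


def apply_feedback(
    weights: GroupWeights,
    state: SelectionState,
    feedback: str,
    target_group: str,
    now: datetime | None = None,
) -> tuple[GroupWeights, SelectionState]:
    """Adapt a group's weight after a rating of one of its messages.

    ``increase`` (Like / More) doubles the group's weight and schedules a
    same-group follow-up two weeks from ``now``; ``decrease`` (Dislike /
    Less) halves the weight with no follow-up.  All other weights are
    unchanged.  Inputs are not mutated.
    """
    if target_group not in weights.weights:
        raise KeyError(f"unknown BCT group {target_group!r}")
    weights = weights.copy()
    state = state.copy()
    if feedback == "increase":
        weights.weights[target_group] *= POSITIVE_FACTOR
        due = None if now is None else now + FOLLOWUP_DELAY
        state.pending_followups.append(Followup(target_group, due))
    elif feedback == "decrease":
        weights.weights[target_group] *= NEGATIVE_FACTOR
    else:
        raise ValueError(f"feedback must be 'increase' or 'decrease', got {feedback!r}")
    logger.debug("weight[%s] -> %s", target_group, weights[target_group])
    return weights, state


# ---------------------------------------------------------------------------
# Checkpointing
# ---------------------------------------------------------------------------

def state_to_dict(state: SelectionState, weights: GroupWeights) -> dict:
    return {
        "sent_ids": sorted(state.sent_ids),
        "last_bct_group": state.last_bct_group,
        "consecutive_bct_count": state.consecutive_bct_count,
        "pending_followups": [
            {
                "group_id": fu.group_id,
                "due_time": fu.due_time.isoformat() if fu.due_time else None,
            }
            for fu in state.pending_followups
        ],
        "weights": dict(weights.weights),
    }


def state_from_dict(data: dict) -> tuple[SelectionState, GroupWeights]:
    state = SelectionState(
        sent_ids=set(data["sent_ids"]),
        last_bct_group=data["last_bct_group"],
        consecutive_bct_count=data["consecutive_bct_count"],
        pending_followups=[
            Followup(
                fu["group_id"],
                datetime.fromisoformat(fu["due_time"]) if fu["due_time"] else None,
            )
            for fu in data["pending_followups"]
        ],
    )
    return state, GroupWeights(dict(data["weights"]))


def save_state(state: SelectionState, weights: GroupWeights, path: str | Path) -> None:
    Path(path).write_text(json.dumps(state_to_dict(state, weights), indent=1))


def load_state(path: str | Path) -> tuple[SelectionState, GroupWeights]:
    return state_from_dict(json.loads(Path(path).read_text()))
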