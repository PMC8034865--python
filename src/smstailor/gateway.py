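"""SMS transport abstraction with delivery tracking, retries and alerts.

Every outbound message is handed to a transport (the real system used a
commercial SMS provider; this package ships an in-memory mock) which
returns a provider message ID.  Five hours after dispatch the record's
delivery status is checked against the transport; the provider vocabulary
is ``Delivered``, ``Sent``, ``Failed``, ``Expired``, ``Cancelled`` and
``PartiallyDelivered`` (plus a local ``Pending`` before the first check).

Failure handling: on any failure status one redelivery attempt is made
immediately; after 2 further failed redelivery attempts (4 attempts in
all) an alert event — the analogue of the automatic email to study staff —
is emitted exactly once, suggesting the participant may have changed
their mobile number.  ``Sent`` is treated as non-terminal: re-polled at
the next tick (default 30 s), not retried.

All timing is driven by an injected clock value; nothing here sleeps.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from datetime import datetime, timedelta
from typing import Callable, Iterator

import numpy as np

logger = logging.getLogger(__name__)

STATUS_CHECK_DELAY = timedelta(hours=5)
POLL_TICK = timedelta(seconds=30)
MAX_ATTEMPTS = 4  # 1 original + 1 immediate retry + 2 further retries

TERMINAL_SUCCESS = "Delivered"
FAILURE_STATUSES = frozenset({"Failed", "Expired", "Cancelled", "PartiallyDelivered"})
ALL_STATUSES = FAILURE_STATUSES | {TERMINAL_SUCCESS, "Sent", "Pending"}


class TransportRefused(Exception):
    """The transport would not accept the message at all."""


@dataclass
class DeliveryRecord:
    """The delivery lifecycle of one outbound message."""

    participant_id: str
    mobile: str
    body: str
    provider_id: str
    dispatch_time: datetime
    status: str = "Pending"
    attempt_count: int = 1
    alert_raised: bool = False
    alert_text: str | None = None
    last_status_check: datetime | None = None
    next_check_at: datetime | None = None


@dataclass
class AlertEvent:
    """Email-analogue notification of a terminally failed delivery."""

    participant_id: str
    mobile: str
    at: datetime
    text: str


class MockTransport:
    """Scriptable in-memory transport.

    The eventual status of each send is taken, in order of precedence,
    from ``script`` (an iterable of status strings consumed one per
    send), from ``outcome_fn(mobile, body, attempt)``, or by Bernoulli
    sampling with ``failure_rate`` using ``rng`` (failures are reported
    as ``Failed``).  ``refuse=True`` makes ``send`` raise
    :class:`TransportRefused`.
    """

    def __init__(
        self,
        script: Iterator[str] | list[str] | None = None,
        outcome_fn: Callable[[str, str, int], str] | None = None,
        failure_rate: float = 0.0,
        rng: np.random.Generator | None = None,
        refuse: bool = False,
    ) -> None:
        self._script = iter(script) if script is not None else None
        self._outcome_fn = outcome_fn
        self._failure_rate = failure_rate
        self._rng = rng or np.random.default_rng(0)
        self.refuse = refuse
        self._ids = itertools.count(1)
        self._statuses: dict[str, str] = {}
        self._sends_per_mobile: dict[str, int] = {}
        self.sent: list[tuple[str, str, str]] = []  # (provider_id, mobile, body)

    def send(self, mobile: str, body: str) -> str:
        if self.refuse:
            raise TransportRefused("transport refused the message")
        provider_id = f"prov-{next(self._ids):06d}"
        attempt = self._sends_per_mobile.get(mobile, 0) + 1
        self._sends_per_mobile[mobile] = attempt
        if self._script is not None:
            try:
                status = next(self._script)
            except StopIteration:
                status = TERMINAL_SUCCESS
        elif self._outcome_fn is not None:
            status = self._outcome_fn(mobile, body, attempt)
        else:
            status = (
                "Failed" if self._rng.random() < self._failure_rate else TERMINAL_SUCCESS
            )
        self._statuses[provider_id] = status
        self.sent.append((provider_id, mobile, body))
        return provider_id

    def query_status(self, provider_id: str) -> str:
        if provider_id not in self._statuses:
            logger.warning("unknown provider message id %s", provider_id)
            return "Failed"
        return self._statuses[provider_id]


class SimClock:
    """A manually advanced clock so polling contracts can be tested without sleeping."""

    def __init__(self, start: datetime) -> None:
        self._now = start

    def now(self) -> datetime:
        return self._now

    def advance(self, delta: timedelta) -> datetime:
        self._now += delta
        return self._now


# ---------------------------------------------------------------------------
# Lifecycle operations
# ---------------------------------------------------------------------------

def dispatch(
    participant_id: str,
    mobile: str,
    body: str,
    transport: MockTransport,
    now: datetime,
) -> DeliveryRecord:
    """Hand a message to the transport; schedule the 5-hour status check."""
    if not body:
        raise ValueError("cannot dispatch an empty message body")
    try:
        provider_id = transport.send(mobile, body)
    except TransportRefused:
        logger.warning("transport refused message to %s", mobile)
        return DeliveryRecord(
            participant_id=participant_id,
            mobile=mobile,
            body=body,
            provider_id="",
            dispatch_time=now,
            status="Failed",
        )
    return DeliveryRecord(
        participant_id=participant_id,
        mobile=mobile,
        body=body,
        provider_id=provider_id,
        dispatch_time=now,
        status="Pending",
        next_check_at=now + STATUS_CHECK_DELAY,
    )


def poll_status(
    record: DeliveryRecord, transport: MockTransport, now: datetime
) -> tuple[DeliveryRecord, AlertEvent | None]:
    """Check the provider status once the 5-hour mark has passed.

    A poll before ``next_check_at`` is a no-op.  ``Sent`` stays pending
    and is re-polled at the next 30-second tick; failure statuses route
    to :func:`handle_failure`.
    """
    if record.next_check_at is not None and now < record.next_check_at:
        return record, None
    record.status = transport.query_status(record.provider_id)
    record.last_status_check = now
    if record.status == TERMINAL_SUCCESS:
        record.next_check_at = None
        return record, None
    if record.status == "Sent":
        record.next_check_at = now + POLL_TICK
        return record, None
    if record.status in FAILURE_STATUSES:
        return handle_failure(record, transport, now)
    return record, None


def handle_failure(
    record: DeliveryRecord, transport: MockTransport, now: datetime
) -> tuple[DeliveryRecord, AlertEvent | None]:
    """Retry a failed delivery; raise one alert if the retry budget runs out.

    One redelivery attempt is made immediately, then up to 2 further
    attempts (4 in all, counting the original).  Each retry reuses the
    original body under a fresh provider message ID.  On terminal failure
    an alert naming the participant's mobile number is emitted exactly
    once.
    """
    if record.status not in FAILURE_STATUSES:
        raise ValueError(f"handle_failure called on status {record.status!r}")
    while record.status in FAILURE_STATUSES and record.attempt_count < MAX_ATTEMPTS:
        record.attempt_count += 1
        try:
            record.provider_id = transport.send(record.mobile, record.body)
        except TransportRefused:
            record.status = "Failed"
            record.last_status_check = now
            continue
        record.status = transport.query_status(record.provider_id)
        record.last_status_check = now
        logger.info(
            "redelivery attempt %d for %s: %s",
            record.attempt_count,
            record.mobile,
            record.status,
        )
    if record.status == TERMINAL_SUCCESS:
        record.next_check_at = None
        return record, None
    if record.status in FAILURE_STATUSES and not record.alert_raised:
        record.alert_raised = True
        record.alert_text = (
            f"Delivery to {record.mobile} failed after {record.attempt_count} attempts; "
            "the participant may have changed this mobile number."
        )
        alert = AlertEvent(
            participant_id=record.participant_id,
            mobile=record.mobile,
            at=now,
            text=record.alert_text,
        )
        logger.warning(alert.text)
        return record, alert
    return record, None


def deliver(
    participant_id: str,
    mobile: str,
    body: str,
    transport: MockTransport,
    now: datetime,
) -> tuple[DeliveryRecord, AlertEvent | None]:
    """Dispatch and drive one message to a terminal state (simulation helper).

    Runs the 5-hour status check and any retries against the scripted
    transport; returns the final record and the alert, if any.
    """
    record = dispatch(participant_id, mobile, body, transport, now)
    if record.status in FAILURE_STATUSES:  # refused outright
        return handle_failure(record, transport, now)
    return poll_status(record, transport, now + STATUS_CHECK_DELAY)
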