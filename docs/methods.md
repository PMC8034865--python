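# Methods

This note documents the model implemented by `smstailor`, the choices made
where the design was genuinely open, and what the synthetic cohort does and
does not show about real participants.

## Message pool and study variants

Two study designs are built in. The *pilot* design is single-arm: 157 BCT
messages in 30 groups plus 35 lifestyle messages, interleave parameter
q = 5, a weekly rating prompt, and a requested routing keyword (`DIA`).
The *feasibility* design is a two-arm randomised design: 170 BCT messages
in 30 groups, 35 lifestyle messages, 6 control messages, q = 2, no weekly
prompt, and a dedicated virtual number (no keyword). Fixture libraries
reproduce these compositions with synthetic placeholder bodies (the real
intervention texts are copyrighted and not reproduced here); group sizes
are distributed as evenly as possible (170 over 30 → twenty groups of 6
and ten of 5), and group labels follow the BCT taxonomy naming convention.
Fixture generation is a pure function of `(study, seed)`.

## Selection model

Selection for one participant keeps: the set of already-sent message ids,
the most recently used BCT group, a consecutive-BCT counter, and a queue of
pending follow-ups. Precedence at each slot:

1. **Lifestyle interleave.** If q consecutive BCT messages have gone out,
   the slot is a lifestyle message, drawn uniformly from unsent lifestyle
   texts; the counter resets. A lifestyle send does *not* reset the
   most-recent-group exclusion — that exclusion tracks BCT usage only.
2. **Follow-up.** A positive rating schedules a same-group follow-up due
   14 days later. A due follow-up consumes the next regular BCT slot (the
   weekly cadence stays at 3; no fourth message is added). If the
   follow-up's group is the most recently used group, it is deferred one
   slot so that two consecutive BCT messages never share a group; if its
   group has no unsent texts, it is dropped with a log note.
3. **Regular draw.** An eligible group (≥ 1 unsent text, not the most
   recent group) is drawn with probability proportional to its weight,
   then a text uniformly within it.

**Weight semantics.** "Double / halve the chance" is implemented as
multiplying the group's *unnormalised sampling weight* — equivalently its
selection odds against all other groups — not its normalised probability.
Probability-doubling is ill-defined once p > 0.5 and does not compose;
odds-doubling is exact, composable, and reduces to probability-doubling
when p is small. Updates compound without a cap; weight changes are
logged so drift is observable.

**Pool exhaustion.** A 26-week run delivers 78 messages; at q = 2 that
means 26 lifestyle slots against a 35-text pool, and long runs or
follow-up-heavy histories can exhaust a kind entirely. When every message
of the required kind has been sent, the sent-history for that kind is
cleared (logged warning) and repeats are allowed; the most-recent-group
exclusion still applies. A single-group library is the one degenerate case
where the exclusion itself is relaxed rather than deadlocking.

## Scheduling

"Even time gap" for 3 messages/week is a nominal 56-hour spacing
(7×24/3) anchored at the participant's start; each nominal instant is
snapped to the midpoint of the participant's delivery window on that
calendar day, yielding days {0, 2, 4} at 10:30 (AM window, 09:00–12:00)
or 15:00 (PM window, 12:00–18:00). Midpoint snapping keeps every send
strictly inside the window and makes timelines deterministic.

Reminders: the pilot's weekly prompt goes out 24 h after the week's last
regular send (day 5), keeping the prompt adjacent to the content it asks
about; the rating-command reminder goes out at week 4; help reminders at
week 0 and at ceil(weeks/2); birthday and World Diabetes Day (14 Nov)
texts are emitted when those dates fall inside the study window. At a
shared instant, prompts and reminders dispatch ahead of content sends —
so the week-4 reminder precedes that day's regular message, which matters
for the reminder-boost behaviour below.

Control-arm participants receive one control message per complete 28-day
period ("approximately once a month"): 6 sends over 26 weeks, days
0, 28, …, 140, cycling through the 6 control texts in fixed order.

Pausing removes sends inside the pause window without back-filling
(cadence is defined per week, not per backlog); auto-resume happens at
the first tick after `pause_until`. `stopped` is absorbing except via an
explicit admin restart.

## Delivery gateway

Dispatch hands the body to the transport and schedules a status check
5 hours later. Status vocabulary: `Delivered` (terminal success), `Sent`
(non-terminal: re-polled at the next 30-second tick, not retried),
`Failed` / `Expired` / `Cancelled` / `PartiallyDelivered` (failures). On
failure, one redelivery is attempted immediately, then up to 2 further
attempts — 4 in all — each with a fresh provider message ID and the
original body; terminal failure raises exactly one alert event naming the
participant's mobile number (the analogue of the automatic email to study
staff). All timing is injected; nothing sleeps.

## Metrics

The metric formulas are this package's reconstruction from prose
descriptions of the originals (the primary-source equations are not
reproducible verbatim), and that interpretation should be kept in mind:

* **response rate** = 100 × ratings / delivered intervention messages.
  The denominator counts `regular` + `followup` sends with status
  `Delivered`; prompts and reminders are excluded (the metric targets
  intervention content). The pilot numerator counts all eight rating
  verbs, so one message rated twice (Like + Useful) contributes 2 — which
  is how per-participant rates above 100% arise; the feasibility
  numerator counts Like/Dislike only.
* **keyword percentage** = 100 × keyword-prefixed inbound / all inbound,
  case-insensitive, always in [0, 100].
* **rate versus prompt** = 100 × ratings (pilot numerator) / delivered
  weekly prompts.

All three are missing (None) when their denominator is zero. Weekly
Like/Dislike series are indexed from each participant's first study week
(week 1 = days 0–6 after start).

## Cohort simulator

The simulator is the stand-in for a human cohort. Behaviour is
memoryless per delivered message: a rating is sent with probability
`rating_prob` (default 0.25), positive with probability `like_fraction`
(0.8 — most observed feedback in this kind of programme is positive),
keyword-prefixed with probability `keyword_compliance` (0.93) when a
keyword is requested, after an exponential delay (mean 4 h). Weekly stop
and pause hazards are small (0.002 each, matching the low withdrawal
rates such programmes report); delivery failures are rare (0.01).
Feasibility arms are assigned 1:1 in randomised blocks of two. Ages are
drawn around a median of 65 for roster realism.

The one departure from memorylessness is the **reminder boost**: after
the week-4 command reminder, `rating_prob` is multiplied by a factor that
starts at `reminder_boost` (default 3) and decays linearly to 1 over 4
weeks. A decaying boost, rather than a constant one, is what produces a
rating peak in the week right after the reminder followed by a return to
baseline four weeks later; a constant boost would produce a plateau, not
a peak.

The pilot scenario models a *requested* keyword over a dedicated virtual
number: every inbound text reaches the system regardless of prefix, and
keyword compliance is measured on the raw text — texts would be lost only
under true shared-number (`keyword` mode) routing.

**What passing tests show — and don't.** The simulator demonstrates that
the machinery is correct (selection invariants, cadence, window
containment, retry ceilings, metric arithmetic, qualitative reminder
response) and that metrics converge to the behaviour model's parameters.
It does not model real human engagement: observed cohort statistics
(response-rate medians, withdrawal timing, admission durations) depend on
real participants and are not targets of this package.

## Problem sizes and determinism

Canned scenarios run at the real study sizes (48 participants × 13 weeks;
209 × 26 weeks) in about a second each; statistical test checks use
20,000 Monte-Carlo draws for selection frequencies, 200 independent
26-week selection runs for the no-repeat/no-consecutive invariants, and
500-participant cohorts for metric convergence — sizes at which binomial
noise is comfortably inside the asserted bands. Every stochastic
component takes a seeded `numpy` generator; cohorts spawn one child
stream per participant, so per-participant traces are reproducible and
independent of cohort size. Fixed seed ⇒ byte-identical event logs and
CLI outputs.

## Known limitations

* Pilot "Less" is mapped to the −50% weight update symmetrically with
  "More" → +100%; the original description is explicit only about the
  positive direction in the pilot. Easy/Hard and Useful/Not Useful are
  rating-only and never affect weights.
* Rating attribution is "most recent delivered intervention message
  strictly before the rating", with no time limit; a very delayed rating
  that crosses the next delivery is attributed to the newer message, as
  it would be in the live system.
* One study-wide timezone; per-participant timezone handling is out of
  scope.
* The transport is an in-memory mock with provider-style semantics; no
  real SMS API integration is included.
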