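# smstailor

A toolkit for delivering **tailored SMS brief-message interventions** — the
kind of two-way text-messaging programme used to support medication
adherence in long-term conditions such as type 2 diabetes — and for testing
every part of such a system without real participants or a commercial SMS
provider.

It is aimed at digital-health engineers and trial methodologists who need a
faithful, fully observable desk model of an intervention delivery system:
the message-selection algorithm, the participant command set, the messaging
cadence, the delivery-status retry logic, the engagement metrics, and a
stochastic cohort simulator that drives all of it end to end.

## The core algorithm

The message pool is a set of *t* behaviour change technique (BCT) groups
{B₁, …, B_t}, group *i* holding *nᵢ* interchangeable texts, plus *m*
general lifestyle texts and (in the two-arm design) a handful of control
texts. Each participant receives 3 messages per week at an even time gap
inside their chosen delivery window (AM 09:00–12:00 or PM 12:00–18:00),
with one lifestyle message after every *q* consecutive BCT messages
(*q* = 5 in the single-arm pilot design, *q* = 2 in the two-arm
feasibility design).

The next BCT message is chosen by **weighted random selection with history
exclusion**: all previously sent messages and the most recently used BCT
group are excluded; an eligible group is drawn with probability
proportional to its weight *wᵢ* (all 1 at enrolment), then a text is drawn
uniformly from that group's unsent members. Feedback adapts the weights
multiplicatively:

* a positive rating (Like / More) sets *wᵢ ← 2 wᵢ* — the group's selection
  odds against the field exactly double (+100%) — and schedules a
  follow-up message from the same group 2 weeks later;
* a negative rating (Dislike / Less) sets *wᵢ ← wᵢ / 2* (−50%).

Around the selection engine sit the participant command state machine
(Register/Start/Stop/Pause X/AM/PM/Help plus the rating verbs), a
reminder scheduler (weekly rating prompts in the pilot design, a week-4
rating-command reminder, help reminders at start and midpoint, birthday
and World Diabetes Day texts), a delivery gateway with the provider status
lifecycle (5-hour status check, one immediate redelivery plus 2 further
retries, then a single staff alert), and the engagement metrics
(response rate, keyword percentage, rate versus prompt).

## Worked example

Generate a message library with the feasibility-design composition and run
the canned pilot-shaped scenario (48 synthetic participants, 13 weeks,
weekly prompts, a requested `DIA` routing keyword):

```bash
$ smstailor library make-fixture --study feasibility --seed 1 -o lib.json
wrote feasibility library: 170 bct in 30 groups, 35 lifestyle, 6 control, q=2

$ smstailor simulate --scenario pilot_default --seed 7 -o events.jsonl
{
 "scenario": "pilot_default",
 "n_participants": 48,
 "weeks": 13,
 "n_events": 3833,
 "response_rate": {"n": 48, "median": 33.3, "q1": 30.8, "q3": 38.5},
 "keyword_percentage": {"n": 48, "median": 93.8, "q1": 89.7, "q3": 100.0},
 "rate_vs_prompt": {"n": 48, "median": 100.0, "q1": 92.3, "q3": 115.4}
}
```

Reading the summary: each synthetic participant rated about a third of the
messages delivered to them (`response_rate`, ratings per delivered
intervention message), prefixed ~94% of their inbound texts with the
routing keyword (`keyword_percentage`, matching the behaviour profile's
93% compliance), and sent about one rating per weekly prompt
(`rate_vs_prompt` ≈ 3 × response rate, since 3 ratable messages go out per
prompt). The event log (`events.jsonl`) holds every outbound send with its
delivery status and every inbound command, and can be re-analysed with
`smstailor metrics --log events.jsonl --study pilot`.

The same numbers are reproduced by the library API:

```python
from smstailor import run_scenario
log, summary = run_scenario("pilot_default", seed=7)
```

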