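# Methods

## The intervention model

The engine models a tailored SMS program as three layers.

**Static tailoring.** Content is parsed into 24 message classes. Six are
*universal* (enabled for everyone at account creation): the weekly Sunday
adherence question (class 1), Wednesday wellness (11), Sunday social
support (12), Monday patient involvement (13), the eight satisfaction
questions on days 38–61 (14), and the early social-support burst on days
9–12 (18). The rest are enabled by deterministic rules over the enrollment
record: any sex partner in the past 3 months → Saturday sexual-risk
messages (7); drinking ≥2–3 times/month, any monthly binge drinking, or any
illicit drug use → Friday substance-risk messages (8); any substance use
before or during sex → the combined Saturday stream (9); smoking (or
refusing the question) → smoking cessation every other Thursday from the
second (10); age, race, ethnicity, and diagnosis recency select among six
single-shot social-support classes on days 13–19 (19–24); risk
reassessment questions on days 36 and 64 (15–17) go to everyone.
Medication-reminder classes (4 daily / 5 morning / 6 evening, chosen by the
participant's dosing schedule) are enabled at enrollment only for
participants reporting a missed dose in the prior week (or "don't know" /
"refused", read conservatively as nonadherence) or an ART start within the
past 6 months (`rx_recency_window_months`, configurable). Opt-outs
recorded on the preference form are removed last and therefore dominate
qualification; universal classes cannot be opted out at enrollment.

**Scheduling.** Each participant is anchored at his own intervention day 1
(the date of his first study message); study week *k* covers days
7(k−1)+1 … 7k. Weekday-cadence classes fire on calendar weekdays, so the
first occurrence depends on the start weekday; day-of-study classes fire on
the intervention-day index regardless of weekday. The default horizon is
91 days — 13 complete weeks, making weekly counts well-defined (every
weekday occurs exactly 13 times) — and can be set to 90 for a strict
90-day reading of the program. All texts carry the `<HB>` prefix.
Appointment reminders are a pseudo-class (id 0) sent once at a uniformly
random minute within the 72 hours before each appointment.

**Dynamic tailoring.** A per-participant state machine consumes classified
replies. Missed-dose reports queue class-2/3 feedback for the next Monday
at 16:00 (`feedback_weekday` configurable; the narrative operating schedule
is followed rather than the content plan's Tuesday note) and switch the
dosing-schedule reminder classes on permanently from the following day
(`activation_lag_days = 1`, chosen to match weekly roster-batch semantics).
"Yes" and "don't remember" answers to the reassessment items activate the
mapped risk class (condomless sex → 7, binge or drugs → 8, substances with
sex → 9). Stop requests are permanent, dominate any later trigger, and are
logged individually even when idempotent. All transitions are pure in the
event sequence, so replaying a logged archive reproduces final state
exactly.

## Response classification

Every inbound text maps to exactly one of five categories. Normalization
case-folds and strips whitespace/punctuation; zero-for-O substitution is
applied only when it turns the whole token into a pure word (`0K` → `ok`),
never inside the numeric part of a code, so a bare `0` remains the
adherence answer "no missed doses". A number+letter code (satisfaction
A–H, risk i/J/K/L, option ranges per item) is recognized only as the whole
normalized token and only when the corresponding question window is open;
a bare 0–7 is an adherence answer only inside an open weekly window.
Because printed reply instructions sometimes omit the letter, a bare 1–3
is accepted as a risk answer when exactly one risk item is open and no
adherence window is — the letter form wins on any ambiguity. Windows stay
open for 7 days (configurable), with the newest adherence question closing
its predecessor. Acknowledgment and stop vocabularies are open config
lists. Aggregation to final answers is last-response-wins per
(participant, question instance).

The four reassessment items map onto three question classes: the substance
question (15) alternates the binge item (i, day 36) and the drug item
(J, day 64); the sex (16) and combined (17) questions repeat their items
both days. This is the arrangement consistent with the binge item being
asked only at the first reassessment.

## The UserList roster

Enrollment is exchanged as a 24-position roster row (id, cell number,
inclusion flags for the tailorable classes, three reminder clock times, a
literal `*` for the universally received early social-support stream, and
six tailored social-support flags). The XML dialect — one `<user>` element
with 24 ordered `<field index="k">` children — is this artifact's own,
since only positions are standardized; serialization is deterministic and
byte-stable under read/write round trips. Custom reminder messages are
encoded as `flag/text` with `/` escaped. Weekly batches cut at Saturday
22:00: a batch holds exactly the participants enrolled in
(previous posting, this posting], so consecutive batches partition the
roster.

## The cohort simulator

The simulator generates the study conditions, not a fitted behavioral
model. Cohort defaults use reported structure where it exists — 52
enrollees, 51/52 on ART, near-universal baseline qualification for the
risk streams, enrollment on consecutive Fridays — and placeholder rates
where it does not (smoking 0.30, baseline-week nonadherence 0.30,
demographic mix, per-class opt-out rates around 0.45–0.55 chosen so that
roughly a third to a half of the cohort receives each risk stream).
Delivery failure is Bernoulli at 0.045 per send; acknowledgment (0.045)
and stop (0.0004) probabilities per delivered message mirror the observed
volumes of unprompted traffic; reply probabilities (0.55 adherence, 0.50
satisfaction, 0.35 risk) sit in the observed non-response band. Weekly
adherence follows a two-state chain (miss probability 0.025 from an
adherent week, 0.50 persistence from a missing week), which yields
mid-study stream changes at a realistic rate. A fraction of replies is
rendered in noisy dialect (case, spacing, bare numbers) and a small rate
of unsolicited unparseable texts exercises the "other" category.

Replies are queued with their arrival timestamps and dispatched to the
engine **through the classifier, in timestamp order interleaved with
sends**, so the context a reply is classified against contains exactly the
questions delivered before it — making simulation identical to replaying
the saved archive. Failed deliveries suppress the reply opportunity;
batched deliveries (probability 0.02, delay up to 8 h) arrive late but
intact. The archive is fully determined by the cohort and behavior seeds.

What the simulator does **not** emulate: real human response styles beyond
the dialect lexicon, attrition, carrier-level behavior, number changes, or
any correlation between baseline risk and reply behavior. Passing tests
therefore demonstrate the correctness and calibration of the *engine*, not
cohort-level behavioral findings.

## Analytics conventions

Weekly intensity uses the sample (n−1) SD; single-participant weeks report
SD 0 with a flag. "Received" counts delivered messages only, with a
`count_attempted` switch since sent-versus-received is ambiguous in common
reporting. Percentages are over all participants (options plus
no-response sum to n) and are rounded half-away-from-zero for
presentation. The stream-change fraction counts on-ART participants whose
daily reminders were activated mid-study; reply fractions use the on-ART
denominator.

## Numerical and design choices

* Ties among simultaneous sends break by ascending class id, giving
  deterministic logs.
* The smoking stream defaults to a biweekly-from-second-Thursday cadence;
  `default_registry(smoking_cadence="weekly")` selects the weekly variant,
  as both appear in descriptions of such programs.
* A participant may map to several reminder classes at once (e.g. morning
  + lunch doses → classes 5 and 4); `rx_mode` labels the common cases
  (`am`, `pm`, `am+pm`, `daily`) and reports `mixed` otherwise.
* An absent diagnosis date enables neither diagnosis-recency class; a
  reported date ≤ 6 months selects the newly-diagnosed stream, else the
  long-time-positive stream (boundary inclusive).
* Custom reminder times replace (not supplement) the class default slot.
* Zero or negative horizons yield empty schedules rather than errors in
  the library API; the CLI validates configuration separately.
* Problem sizes in the test suite: oracle equivalence over 200 random
  tailoring decisions across all seven start weekdays; exhaustive
  state-machine enumeration to sequence length 3; 100-roster round trips;
  one 52-participant simulated trial (~7,000 sends) shared across
  statistical checks, with binomial concentration asserted at 3 SE.

## Known limitations

* The engine holds all timestamps as naive local clock times; a multi-site
  deployment would need timezone-aware scheduling.
* Risk-class activation from a day-64 reply leaves at most 27 days of
  exposure; the engine activates the next day rather than waiting for a
  weekly roster batch, which is one of several defensible readings.
* Content is fixture text plus a handful of genuine example messages; the
  library enforces the 160-character SMS limit but no content policy.
* The bare-number risk dialect cannot be disambiguated when several risk
  questions are open simultaneously (as on day 36 mornings); such replies
  fall to "other", which matches a conservative manual-review posture.
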