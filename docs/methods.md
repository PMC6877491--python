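# Methods

`aaproto` treats an ambulatory-assessment (AA) protocol — the materials and
procedures of an experience-sampling or ecological-momentary-assessment
study — as a single HTML document written with `aa-*` custom elements.
The document is simultaneously the human-readable description of the study
and the program the engine executes.  This note records the semantics the
engine implements, the parameters that matter, and the choices made where
the element vocabulary leaves behaviour open.

## Document model

The parser (stdlib `html.parser`, lenient HTML5 tokenizer) builds a typed
tree: input-collecting widgets (`aa-textfield`, `aa-likert`, `aa-boxgrid`,
`aa-multiple-choice`/`aa-choice-item`), value-producing widgets
(`aa-variable`, `aa-function-random`, `aa-geolocation`), grouping
(`aa-screen`), and procedural structure (`aa-sequence`,
`aa-choose`/`aa-when`/`aa-otherwise`, `aa-session`).  Standard HTML is
never interpreted: every run of non-`aa` markup (text, tags, comments,
entity references) is kept verbatim in a raw node, so it survives
round-trips byte-identically.  Strictness is asymmetric on purpose:
standard HTML may be sloppy (unclosed `<p>` is fine), but `aa-*` elements
must be closed and well nested — `aa-when` outside `aa-choose`, a second
`aa-otherwise`, or a non-branch child of `aa-choose` is a parse error with
a source position.  Unknown `aa-*` tags parse into a generic node and are
reported by the linter instead; a misspelled tag should not make the
document unreadable.

Serialization emits one canonical text form — lowercase tags, a fixed
documented attribute order (`name`, `label`, `value`, `min`, `max`,
`vboxes`, `hboxes`, `width`, `height`, the four side labels, `multi`,
`five`, `seven`, `test`, `dates`, `times`, `submit-label`; unrecognised
attributes after these, alphabetically), boolean flags as bare attributes,
raw HTML verbatim — so two labs can diff their protocols textually.
`parse(serialize(t)) = t` on canonical trees and serialization is
idempotent; both are enforced by property tests over generated protocols.

Attribute typing: `min`, `max`, `vboxes`, `hboxes`, `width`, `height` are
integers (a non-integer value is a parse error); `five`, `seven`, `multi`
are presence flags; everything else is text.

## Widget semantics

* **Likert** options are `"1"`..`"k"` left to right; `k` is 7 with the
  `seven` flag and 5 otherwise (both worked snippets in circulation are
  five-point, so five is the default when no flag is given; both flags at
  once is a lint error and the engine then uses five).
* **Multiple choice** takes its categorical options from its
  `aa-choice-item` children, in document order; the `multi` flag allows
  multi-select.  Each selected option becomes its own data record; the
  variable store keeps the selection joined with `;`.
* **Boxgrid** responses are 0-based `"row,col"` cells with row 0 at the
  top, `vboxes` rows by `hboxes` columns.  The vocabulary only names the
  axis labels, so the coordinate convention is fixed here.
* **Random generator** draws integers uniformly from the *inclusive*
  range `[min, max]` from the injected seeded stream; `min > max` is a
  configuration error.  `aa-variable` and `aa-geolocation` never consume
  randomness, so adding or removing them cannot perturb later draws.
* **Geolocation** is a provider contract (`get_fix(now) -> LocationFix`);
  the headless default returns a configured fixed position and serializes
  as `"lat,lon"` in decimal degrees.  No hardware is ever touched.
* **Adaptive text** (re-using earlier answers inside later item text)
  replaces `{{name}}` placeholders anywhere in rendered content.  An
  unknown name stays verbatim and records one warning — rendering never
  raises.

## Test expressions

`aa-when` conditions use a small expression language: identifiers,
single-quoted strings, decimal numbers, `== != < <= > >=`, `&& || !`,
parentheses; precedence `!` > comparison > `&&` > `||`.  The deployed
protocols in this idiom only ever use `==` on strings; the comparison and
logical operators are a deliberate superset so protocols can branch on
numeric answers.  Two semantic choices were open and are fixed as follows:

* comparison is numeric when *both* operands parse as numbers, and
  lexicographic text comparison otherwise;
* `!` applies to the comparison or parenthesised group that follows it
  (`!a=='x'` reads as `!(a=='x')`), and a bare variable or literal in
  boolean position is truthy unless its text is empty, `0` or `false`.

Evaluation is total.  A variable missing from the store makes the
enclosing comparison false — including `!=` — and records a warning; an
unparseable test is false with a warning.  A faulty protocol therefore
keeps running exactly as it does in the field, silently; the linter exists
to catch these faults before any participant is enrolled.  The evaluator
is cross-checked against an independent brute-force tree evaluator on
randomly generated expressions.

## Execution semantics

Top-level nodes and sequence children run strictly one at a time in
document order; each starts only after the previous signals completion.
A screen instantiates all of its children simultaneously (content renders
and non-interactive child widgets write the store in child order), then
waits for a single submit: the responder returns answers for named input
widgets, each answer is checked against its widget's response domain, the
store is updated, and one record per answered widget is emitted.
Unanswered named widgets yield a record with the empty-string marker and
an explicit `missing` flag — submit is a single event, not per-item
validation (a `required` attribute would be an extension).  Widgets
without a `name` capture nothing.

`aa-choose` evaluates its branch tests in document order and instantiates
the first branch that holds, the `otherwise` branch when none do, or
nothing at all.  Branch children execute as an implicit sequence.
Instantiation is lazy: content in unselected branches never executes,
never consumes randomness and never appears in the trace — checked by
exhaustive enumeration of forced outcomes on a branching fixture.

Non-interactive widgets write the store but do *not* emit data records;
only screen submissions produce records.  This keeps the long-format
completeness identity exact (records per session = answered input
widgets); computed values remain observable through the store write-log
and the execution trace.

The variable store lives per participant for the whole study, across
sessions, so later sessions can re-use earlier input; records carry the
session index so per-session analysis can ignore carry-over.  A bare
input widget outside any screen runs as its own one-widget screen.  An
`aa-session` nested inside running content is not executed inline
(sessions run only from the trigger scheduler) and records a warning.

Every run is driven by an injected simulated clock (response latencies
advance it), an injected responder, and an injected random stream — a
run is a pure function of (protocol, seed, responder, clock plan), and
repeated runs are byte-identical.

## Scheduling

`aa-session` declares `dates="DD/MM/YYYY;DD/MM/YYYY-DD/MM/YYYY;..."`
(single days and inclusive ranges) and `times="HH:MM;..."`.  Both lists
are sorted and deduplicated; the trigger list is the Cartesian product,
chronologically ordered, so the trigger count is exactly
`|dates| x |times|`.  Dates default to the day-first dialect with a
`MM/DD/YYYY` switch (`01/08/2018` is ambiguous between the two; the
dialect used is recorded in run metadata).  Times are naive study-local;
no timezone or DST modelling.

Each trigger carries an expiry window, default 60 minutes: EMA practice
needs a cutoff for missed-signal accounting even though the vocabulary
does not define one.  A session is **missed** when the participant
declines the trigger, when a screen would be submitted after the window,
or when the trigger fires while the previous session is still open
(policy `miss`, the default; `queue` runs it late instead).  Missed
sessions contribute nothing: their records are dropped and their store
writes are rolled back.  `session_index` is the participant's
chronological trigger ordinal including missed triggers, so indices are
stable across compliance levels.  Session content never runs untriggered.

## Linting

All diagnostics are computed statically, in deterministic order
(document position, then code).  Severity policy: whatever silently
corrupts data is an error — duplicate variable names
(`DUPLICATE_VARIABLE`), reads not dominated by a write
(`DANGLING_REFERENCE`), unparseable tests (`BAD_EXPRESSION`), malformed
schedules (`BAD_SCHEDULE`), `five`+`seven` together
(`CONFLICTING_FLAGS`), inconsistent widget configuration (`BAD_WIDGET`);
recoverable issues are warnings (`UNKNOWN_ELEMENT`, `NESTED_SCREEN`,
`MISSING_NAME` — an unnamed input widget is legal display-only content).

Reference analysis is a conservative must-write dataflow: a test or
placeholder read is flagged unless a write dominates it on every path
that can reach it.  Screen text renders at instantiation, so it may only
read variables written before that moment; participant answers become
readable after the screen, auto-widget writes immediately.  A choose
without an otherwise contributes a nothing-selected path, so writes on
some branches never dominate.  Unknown-element subtrees are excluded
entirely (they never run).  On protocols whose conditions are opaque the
analysis may over-warn about dynamically impossible branches — acceptable
for a pre-registration linter.  On a step-model family of small protocols
the verdict is tested to coincide exactly with exhaustive enumeration of
all execution paths, and a mutation harness checks that every injected
duplicate-name or broken-reference fault is flagged.  Intentional
overwriting (adaptive-text workflows) is supported via an explicit
`--allow-rewrite NAME` suppression.

The `run` command refuses protocols with lint errors unless `--force`:
the engine inverts the silent-misbehaviour failure mode by default.

## Simulated cohorts

A participant profile is (id, seed, per-trigger compliance probability,
latency model, answering policy).  Compliance is an independent Bernoulli
draw per trigger — the simplest defensible model; time-varying compliance
is an extension hook.  Latency is `fixed(s)` or `exponential(mean s)`,
default exponential with mean 30 s, a typical prompt-to-completion delay
for short mobile questionnaires.  The random policy answers uniformly
over each widget's response domain (free text from a small fixed
vocabulary); the scripted policy plays back an explicit
(session, variable, value) table and leaves everything else unanswered.

Per-participant seeds derive from one master seed as
`seed_i = (master XOR 0x9E3779B9*(i+1)) mod 2^31`; each participant gets
two independent substreams (responder behaviour, in-protocol randomness),
so changing one participant's seed provably touches only that
participant's records.

The fixture generator emits random *valid* protocols — screens of random
widgets inside a session sequence, conditionals reading
previously-written variables, adaptive text, random date/time schedules —
lint-clean by construction, covering every widget kind and both
conditional outcomes with positive probability.  What the simulation does
**not** emulate: psychometrically realistic answer distributions,
answer–answer correlations, dropout and fatigue, real sensor noise, or
device/network failures.  Passing tests therefore demonstrate that the
engine executes protocols correctly and reproducibly, not that simulated
data resemble any particular human population.

## Problem sizes and tolerances

The property suites run at 500 generated protocols (round-trip), 1,000
random expressions against the brute-force evaluator, 200 random schedule
specs, 300 step-model protocols against the path-enumeration oracle, and
~190 mutants; the whole suite completes in a few seconds on one CPU.
Calibration uses 10,000 random-generator draws (chi-square against
uniform over 11 outcomes, plus a 5-sigma per-outcome frequency bound) and
2,000 Bernoulli triggers at p=0.7 checked against the exact binomial 99%
interval.  The acceptance script re-runs all of the above from scratch
plus a 4-participant, 12-trigger-per-participant diary study, twice, and
verifies byte-identical output.

## Known limitations

* No concurrent sessions for one participant, and no pause/resume of a
  half-finished screen across process restarts.
* Server communication, data upload and notification delivery are out of
  scope; the engine is headless by design.
* No arithmetic, function calls or date algebra in test expressions.
* Wide-format pivoting keeps the last value when a variable is captured
  twice in one session, and a session whose only records are missing
  markers contributes no wide row.
* The date dialects cover day-first and month-first only; ISO dates in
  `dates=` attributes are not accepted.
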