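# aaproto

A headless engine for ambulatory-assessment (AA) protocols written as
HTML documents.

Experience-sampling and ecological-momentary-assessment studies (ESM/EMA)
prompt participants several times a day, in daily life, through their
phones.  The *protocol* of such a study has two halves: the **materials**
(the questions and interfaces participants see) and the **procedures**
(when sessions trigger, in what order items appear, which items are shown
conditionally on earlier answers).  Protocols shared in prose are
ambiguous and re-implemented by hand; protocols locked inside a vendor's
GUI cannot be inspected or moved.  Writing the protocol as one HTML
document with a small vocabulary of `aa-*` custom elements makes it both
human-readable and machine-executable — the same file is the
documentation and the program.

`aaproto` is for researchers and tool builders who want to work with such
documents *without a browser*: parse and canonicalize them, lint them for
the faults that silently corrupt data, expand their sampling schedules,
dry-run them against simulated participants, and get tidy long-format
records out.

## The vocabulary and its semantics

Materials: `aa-textfield`, `aa-likert` (`five`/`seven` flag),
`aa-multiple-choice` with `aa-choice-item` children (optionally `multi`),
`aa-boxgrid` (a `vboxes` x `hboxes` two-dimensional rating), plus
value-producing widgets that run without interaction: `aa-variable`,
`aa-function-random` (uniform integer on the inclusive `[min, max]`),
`aa-geolocation`.  `aa-screen` groups content behind a single submit.

Procedures: `aa-sequence` instantiates its children strictly one at a
time, each starting on the previous child's completion signal.
`aa-choose`/`aa-when test="..."`/`aa-otherwise` instantiates the first
branch whose test holds — tests like `company=='others'` or
`random_choice==2` read named variables that earlier widgets wrote into
the participant's store.  Instantiation is lazy: unselected branches
never execute.  `aa-session dates="01/08/2018;03/08/2018-05/08/2018"
times="10:00;15:00;20:00"` expands to the Cartesian product of its days
and times — here 4 x 3 = 12 concrete triggers.  Item text can re-use
earlier answers via `{{name}}` placeholders.

Execution never halts on a protocol fault: a missing variable makes a
test false and leaves a placeholder verbatim, with a warning — exactly
the silent misbehaviour seen in the field.  The linter exists to catch
those faults statically (duplicate variable names, references not
written on every path that reaches them, unparseable tests, malformed
schedules), and `aaproto run` refuses protocols with lint errors unless
forced.

## Worked example

`src/aaproto/examples.py` ships a complete daily-diary protocol
(`DIARY_PROTOCOL`): three prompts a day over four days, a mood likert and
a company question, and a follow-up screen shown only when the
participant is with others.

```python
import aaproto as A
from aaproto import examples as E

doc = A.parse_protocol(E.DIARY_PROTOCOL, source_name="diary.html")
print([(w.kind, w.name) for w in A.collect_widgets(doc)])
print(A.lint(doc))
print(len(A.expand_all_schedules(doc)[0].triggers))

rs, res = A.simulate_study(doc, A.make_profiles(2, compliance_p=0.8),
                           master_seed=7)
print(res.summary)
```

prints

```
[('likert', 'mood'), ('multiple_choice', 'company'), ('likert', 'social_pleasant'), ('textfield', 'activity')]
[]
12
RunSummary(participants=2, triggers=24, responses=17, missed=7)
```

— the document is lint-clean, its session expands to 12 triggers, and
two simulated participants at 80% compliance answered 17 of their 24
prompts (the other 7 are missed and contribute no records).  The
resulting `RecordSet` is tidy long format, one row per captured value:

```
participant_id session_index        trigger_time              response_time     widget_kind variable value missing
          p000             1 2018-08-01T15:00:00 2018-08-01T15:00:09.101189          likert     mood     5   false
          p000             1 2018-08-01T15:00:00 2018-08-01T15:00:09.101189 multiple_choice  company alone   false
          p000             1 2018-08-01T15:00:00 2018-08-01T15:00:52.705938       textfield activity tired   false
```

The same run from the shell:

```sh
$ aaproto validate diary.html
diary.html: clean
$ aaproto schedule diary.html | head -3
date,time
2018-08-01,10:00
2018-08-01,15:00
$ aaproto run diary.html --participants 2 --seed 7 --out records.csv
participants=2 triggers=24 responses=24 missed=0 records=72
```

(`run` defaults to full compliance; records land in `records.csv` with a
`records.csv.meta.json` sidecar carrying the protocol checksum, seeds and
configuration, so the run is reproducible bit-for-bit.)  `aaproto
roundtrip` rewrites a document in its canonical serialization —
lowercase tags, fixed attribute order, bare boolean flags — so protocols
can be diffed across labs.

## Layout

```
src/aaproto/document_model.py  parse/serialize the typed protocol tree
src/aaproto/widgets.py         response domains, auto values, {{pipping}}
src/aaproto/expression.py      aa-when test language
src/aaproto/runtime.py         lazy sequential/conditional execution
src/aaproto/scheduler.py       dates/times expansion, simulated study clock
src/aaproto/linter.py          static diagnostics
src/aaproto/cohort_sim.py      synthetic participants, protocol generator
src/aaproto/records_io.py      tidy records, CSV/JSONL, wide pivot
src/aaproto/cli.py             validate / schedule / run / roundtrip
src/aaproto/examples.py        worked-example protocol fragments
docs/methods.md                full semantics and design rationale
```
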