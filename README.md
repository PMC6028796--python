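# mcid — low-tech casualty identification codes for mass-casualty incidents

When a disaster produces more casualties than local resources can absorb,
first responders must triage and *identify* people fast, often with no
working electronics and no way to get a name, age or birth date from a
semi-conscious patient, a small child, or a foreigner. `mcid` implements a
16-character alphanumeric identification code a responder can write on a
triage tag by hand, together with the analytics needed to reason about its
central failure mode: two responders producing the identical code for
different casualties.

It is written for disaster-medicine and health-information researchers who
want to study or extend pen-and-paper identifier schemes, and for exercise
designers who need to generate and audit ID sets from simulated triage
drills.

## The code

```
D K S 3 5 0 1 - 0 1 0 1 0 1 0 M K
└─────┬──────┘  └───────┬───────┘
 responder (7)    casualty (9)
```

| positions | field | rule |
|---|---|---|
| 1 | job category | D(octor), N(urse), P(aramedic), V(olunteer) |
| 2–3 | responder initials | family then given, A–Z |
| 4–5 | responder age | years mod 100, zero-padded |
| 6–7 | serial triage number | case *n* written as *n* mod 100 — case 1 → `01`, case 100 → `00`, case 101 → `01` again |
| 8–9 | day of month | `01`–`31` |
| 10–11 | hour | `00`–`23` |
| 12–13 | minute | `00`–`59` |
| 14 | casualty age group | ⌊age/10⌋ capped at 9 (under 10 → `0`, 65 → `6`, 90+ → `9`), or the estimated decade |
| 15 | casualty gender | `M` / `F` |
| 16 | casualty name initial | A–Z |

Casualty information that cannot be obtained is written as a lowercase `u`,
which never collides with the uppercase real letters. Canonical storage is
the bare 16 characters; the hyphen is display-only.

## Duplication analytics

Treating the identifying fields as independent categorical draws, two
responders match on a field set *F* with probability
∏<sub>f∈F</sub> Σ<sub>i</sub> p²<sub>f,i</sub>, and among *n* responders the
expected number of matching pairs is C(n,2) times that — a structured
birthday problem. `mcid.dupstats` computes these closed forms plus empirical
duplication reports (items and patterns duplicated, with half-up one-decimal
percentages); `mcid.simulate` replicates the duplication-prone desk-study
design — a one-cohort roster with skewed name-initial frequencies, every
responder encoding the same ten printed casualties with shared printed
serials — and estimates duplication rates by seeded Monte Carlo.

## Worked example

Encode the canonical example — a 35-year-old doctor K.S. on their first
case, triaging a 5-year-old boy with initial K at 01:01 on the 1st:

```
$ mcid encode --job D --family-initial K --given-initial S --responder-age 35 \
      --serial 1 --day 1 --hour 1 --minute 1 --age 5 --gender M --initial K
DKS3501-0101010MK
```

Run the packaged reconstruction of the 89-responder desk study (exact job
allocation D29/N15/P19/V26, one pair of paramedics sharing the full
7-character responder prefix, their clocks coinciding on exactly one
casualty):

```python
>>> from mcid import reconstruct_desk_study
>>> res = reconstruct_desk_study(seed=0)
>>> len(res.ids), res.id_stats.n_complete_duplicates, res.id_stats.percent_unique
(890, 2, 99.8)
>>> for k, v in res.roster_reports.items():
...     print(k, f"{v.n_items_in_duplicated}/{v.n_items}", v.percent_items_in_duplicated)
initials 28/89 31.5
initials_age 6/89 6.7
initials_age_job 2/89 2.2
```

Reading: 28 of the 89 responders share their two-letter initials with
someone else (31.5%); adding responder age cuts that to 6.7% and adding job
category to 2.2% — yet only one pair of the 890 full IDs collides (0.2%),
because the casualty half of the code (minute of triage, casualty initials)
separates almost every residual clash.

The `mcid` CLI also provides `decode`, `validate`, `stats` (duplication
reports over an ID list file) and `simulate` (seeded Monte-Carlo replicates
from a YAML scenario).

## Acceptance script

`scripts/acceptance.py` re-derives the scheme's printed rule values by
running the codec — the serial field written for a responder's 100th case
and the age-group digits for casualties aged 65 and 93 — and writes them as
JSON:

```
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```
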