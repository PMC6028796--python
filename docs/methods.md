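# Methods

## The identifier and its grammar

The code is a fixed-width concatenation of a 7-character responder block
and a 9-character casualty block. The grammar is purely positional — every
field is checkable in isolation — so validation is a total function
returning one violation record per failed position, and `decode` succeeds
exactly when the violation list is empty. Design choices behind the
grammar:

- **Unknown marker.** Unknowns are the lowercase `u` and only casualty
  fields may be unknown; responder fields are always known (a responder can
  pre-fill their own block before deployment). Because real letters are
  uppercase, `u` is unambiguous even for a casualty whose initial is U.
- **Wrapping fields.** The serial number and the responder age are encoded
  modulo 100 with `%02d` formatting. Case 100 reads `00` and case 101 reads
  `01` again; a 104-year-old responder encodes as `04`. Decoding therefore
  recovers these fields only modulo 100 — the round-trip contract is
  `decode ∘ encode = identity` on *encodable* fields.
- **Age-group digit.** An exact casualty age wins and maps to
  `min(age // 10, 9)`; otherwise an estimated decade digit is used;
  otherwise `u`. The cap makes 90+ indistinguishable from 90–99 by design.
- **Date.** Day-of-month only, no month or year. Cross-month collisions
  (the 5th of two different months) are inherent to the printed format and
  accepted; the scheme targets the hours-to-days scale of one incident.
- **Hyphen.** Display-only. Canonical storage, comparison and file formats
  use the bare 16 characters; both forms are accepted on input.
- **Initials order.** Family-name initial first, given-name initial second
  for responders; the single casualty initial is the family-name initial,
  falling back to the given name when only that is known. The convention is
  ours (the scheme's home setting lists family names first); nothing
  downstream depends on it beyond consistency.

## Duplication statistics

A *pattern* is a value of the chosen key (initials; initials+age;
initials+age+job; or the full 16 characters). An item counts as
*duplicated* when its key occurs at least twice. Reports carry the item
count, pattern count, duplicated-pattern count and duplicated-item count,
and two accounting identities are asserted on construction:
`singletons + duplicated_items = items` and
`singletons + duplicated_patterns = patterns`.

Percentages are rounded **half-up** to one decimal using exact decimal
arithmetic. Half-up (rather than Python's default banker's rounding) is the
rule consistent with all the printed fraction/percentage pairs this package
reproduces (43/89 → 48.3, 17/89 → 19.1, 2/89 → 2.2, 2/890 → 0.2,
888/890 → 99.8).

The analytic collision model treats identifying fields as mutually
independent categoricals. Two independent draws agree on field *f* with
probability Σᵢ p²ᵢ (the Simpson concentration of that field's
distribution), so they agree on a field set F with probability
∏_{f∈F} Σᵢ p²_{f,i}, and the expected number of agreeing pairs among *n*
draws is C(n,2) · ∏ Σ p² — a structured birthday problem. Independence is
an explicit assumption: correlated structures (e.g. job category predicting
age) belong to the Monte-Carlo simulator, not this closed form. Adding a
field can only shrink the match probability, which is the analytic
counterpart of the empirical observation that refining the key never adds
duplicated items.

## The desk-study simulator

The generator states the verification-study world and emulates nothing
more:

- **Roster.** 89 responders by default. Job mix D/N/P/V in proportions
  29/15/19/26 of 89, allocated by largest remainder in `exact` mode
  (deterministic histogram, random ordering) or sampled i.i.d. in `iid`
  mode. Ages uniform on {22, 23, 24} — a single-cohort student roster with
  median 23 and interquartile range 22–24. Initial frequencies default to a
  documented skewed categorical (family initials concentrated on S, K, T,
  M, …; given initials on T, K, S, M, …) standing in for the heavy
  concentration of common family names (Sato, Suzuki, Saito, …) and popular
  given names in a single-country cohort; both distributions are plain
  dictionaries and fully overridable.
- **Casualties.** The ten packaged printed casualties: five dated the 31st
  and five the 1st, triage numbers 1–123 spanning the 100/101 serial wrap,
  two casualties identical in initial/age/gender, three with unknown names
  and one with unknown gender. Triage class labels (O/I/II/III, the
  Black/Red/Yellow/Green categories of the START method) are carried as
  data, never computed — triage logic is out of scope.
- **Serials.** `printed` mode copies each casualty's printed triage number,
  identical across responders — the deliberately duplication-prone study
  design. `free` mode runs each responder's own counter, as on a real
  scene.
- **Clock.** All responders start together at a configurable wall-clock
  hour (default 10:00, arbitrary) and work down the list with positive
  per-casualty minute increments drawn from a pacing distribution (default
  1 or 2 minutes, equiprobable), so each finishes within the 20-minute
  completion window. Stamps are strictly increasing per responder; the day
  field always comes from the casualty's printed date.
- **Transcription errors.** An optional per-ID error hook flips the gender
  letter or replaces the day with a different valid day — the simple
  clerical mistakes seen on real forms — leaving the code grammar-valid.
  The default rate is 0 and no human-accuracy figure is claimed or
  targeted.
- **Randomness.** One root seed. Replicate *r* uses
  `numpy.random.default_rng([seed, r, k])` with sub-stream k = 0 (roster),
  1 (time stamps), 2 (errors); a single-shot run is replicate 0. Identical
  configuration including seed gives bit-identical results.

`reconstruct_desk_study` builds the one scenario the study design pins
down: exact job allocation, exactly one pair of responders (two paramedics)
sharing the full 7-character prefix, everyone else's prefix de-collided by
resampling, and the pair's stamps forced to coincide on exactly the first
casualty. This yields 890 IDs with exactly 2 complete duplicates (0.2%) by
construction. The realized single-study roster behind the published
duplication pattern was never printed, so its specific initials breakdown
is *not* reproducible; what a green reconstruction establishes is that the
codec, the study arithmetic and the collision mechanics compose to the
documented outcome, not that the generator recreates one historical
classroom.

What the generator does **not** emulate: real multi-agency rosters (wide
age ranges, country-specific name distributions), dependent fields
(initials correlated with age or job), clock estimation error when a
responder has no watch, and free-text transcription behaviour beyond the
two clerical error kinds above.

## Numerical and testing choices

- Distribution sanity uses an absolute tolerance of 1e-9 on the sum; probed
  probabilities are renormalised exactly before sampling.
- The analytic-vs-simulation cross-check accepts the closed form when it
  lands within three Monte-Carlo standard errors of a 10⁵-replicate direct
  simulation on a small model (n = 6) — an error-rate choice (~0.3%
  false alarm), not a fitted tolerance.
- Property suites run 10⁴ seeded random codec round trips and
  single-character mutations; the mutation check asserts that `validate`
  accepts exactly the strings `decode` accepts.
- Degenerate inputs: empty key lists, empty files, rosters of size 0 and
  `n < 2` in the birthday formula are errors, not silent zeros; a
  point-mass roster with shared pacing is the forced-collision limit and
  returns a 100% duplication rate.

## Known limitations

- Two-digit ages and a day-of-month date make cross-century and
  cross-month collisions possible by construction; the format accepts this
  in exchange for hand-writability.
- The collision closed form assumes field independence; use the simulator
  when that is implausible.
- The transcription-error hook models only gender/date slips, the kinds
  that leave the grammar intact; it does not model illegible handwriting or
  dropped characters.
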