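# Methods

## The instrument and its data model

The instrument is a 44-indicator checklist for assessing ICU quality of care
during a single one-hour visit, restricted to structure and process measures
(the two Donabedian arms that are collectable on the spot and robust to
case-mix variation). Indicators are organized by collection method —
observation (codes A01–A19), chart review (B01–B12), interview (C01–C14) —
and tagged with one of six domains. `icuqa` treats the instrument as *data*:
a versioned YAML registry (`icuqa/data/registry_v1.yaml`) holds every
indicator definition and every scoring rule, so a future revision of the
instrument is a new registry file, not a code change. `validate_registry`
checks the structural invariants (unique codes, method-letter prefixes,
comparator/response-type compatibility, each scored indicator in exactly one
item) and, for the shipped instrument, the published counts: 44 indicators,
33 scored, 26 items, 4 groups covering 11 indicators, domain maxima
3/5/2/12/2/2.

**Code-mapping convention.** The published indicator table prints codes only
in the scoring protocol, so codes are assigned positionally within each
method section. The interview section has 13 rows while the scoring protocol
cites codes up to C14; we keep the two-part rows (thromboembolism, C10;
pneumothorax, C11) as single indicators with compound `yes: <how>` / `no`
text payloads, and leave **C12 intentionally unassigned** so that the
protocol's citations of C13 (M&M conference) and C14 (specialist diploma)
resolve verbatim. This is the only assignment consistent with both the
44-indicator total and the printed scoring codes.

## Scoring

Each of the 26 items is worth one point; a grouped item requires *all*
member indicators to pass their dichotomization rule. Boundary inclusivity
follows the protocol exactly: `>= 0.5` passes at 0.5, `<= 15` passes at 15,
`> 12` fails at 12. The total is the sum of item points minus the
missing-data penalty, floored at zero; the percentage is reported to one
decimal against the fixed 26-point maximum.

Two behaviours the protocol leaves open are explicit, defaulted, and
configurable (`ScoringConfig`):

* **Penalty granularity** (`penalty`, default `per_item`). "One point is
  subtracted" when data are missing is applied once per *item* containing at
  least one missing member, because points exist at item level and
  per-indicator deductions could exceed an item's worth (a fully missing
  4-indicator group would otherwise cost 5 points). `per_indicator` is
  available for sensitivity analysis.
* **Not-applicable responses** (`na`, default `vacuous`). A unit with no
  intubated patients cannot demonstrate substandard head-of-bed elevation,
  so a not-applicable member counts as vacuously passing and is flagged in
  the verdict map. The alternative `exclude` drops an all-NA item from the
  denominator, reducing the maximum.

**Percentage denominator.** The field report of the three pilot hospitals
prints 13 → "52%", 21 → "84%", 23 → "90%", which is inconsistent with the
26-point maximum it also states (50.0 / 80.8 / 88.5). The engine always
computes from first principles against the stated maximum and makes no
attempt to reproduce the printed percentages; with the `exclude` NA mode a
reduced denominator (e.g. 25) is computable, which is one possible origin of
the discrepancy, but we do not guess.

## Agreement

Duplicate collections of the same visit are compared at the *classification*
level: scored indicators on their dichotomized verdict (14 vs 15 minutes of
blood-gas turnaround agree — both pass), descriptive indicators on their raw
value. Indicators not answered by both collectors are excluded from the
comparison and listed. The report exposes three framings — all 44
indicators, scored-only, and item-level over the 26 items — because the
published concordance test does not state which set it counted. Cohen's
kappa over the dichotomized verdicts is a supplementary, clearly labelled
extension (the field test reported only raw discordance); it is computed
closed-form, with the degenerate case of two identical constant raters
defined as kappa = 1.0 (chance agreement equals 1 only when observed
agreement does).

## Synthetic visits

No real checklist responses are published, so the generator emulates them.
Per indicator, a profile gives the probability the response is missing, not
applicable, or (for scored indicators) *passes its rule*; numeric values are
then drawn from fixed intervals on the chosen side of the threshold (e.g. a
passing nurse/patient ratio from U[0.5, 1.0], a failing one from U[0.2,
0.5); a passing blood-gas turnaround from U[5, 15] minutes, a failing one
from U[16, 60]). Dichotomizing a generated value therefore reproduces the
Bernoulli draw exactly. Descriptive indicators draw from plausible fixed
ranges. All draws come from one `numpy` generator seeded per call, so output
is byte-identical given (profile, seed).

The shipped archetypes were calibrated analytically, once, to the spread the
instrument is meant to resolve: with uniform per-indicator pass probability
*p*, the expected total is `22p + p³ + p⁴ + 2p²`, giving ≈ 13.0/26 at
*p* = 0.55 (`low_resource`, plus 2% per-indicator missingness to exercise
the penalty, expected total ≈ 12) and ≈ 22.8/26 ≈ 88% at *p* = 0.90
(`high_resource`). These sit near the low hospital's half-of-maximum score
and the high hospitals' 85–90% band. Calibration lives in the profile YAML
files, not in code.

Rater noise for duplicate-collector pairs flips each answered indicator's
classification independently with `rater_flip_prob` — scored indicators are
resampled on the other side of their threshold, descriptive ones get a
guaranteed-different raw value (both collectors see the same missing/NA
statuses). Flips apply to all 44 indicators so that a flip probability of
1/44 on a complete visit yields a binomial mean of exactly one discordant
indicator, the discordance level observed in the instrument's field test.
What the generator does **not** model: correlation between indicators
(a hospital failing staffing ratios likely also fails protocols), day-to-day
drift between duplicate collections, within-class disagreement on raw
values, or any real Lebanese case-mix — so passing tests demonstrate the
engine's arithmetic and the instrument's structure, not field validity.

## Numerical and design choices

* Ratios are decimals (0.5 = one nurse per two patients), durations integer
  minutes, percentages in [0, 100], dates ISO 8601; booleans accept
  yes/no/true/false/y/n/1/0 on input and normalize to yes/no on write.
* An absent CSV row is `missing`; the explicit token `NA` is
  `not_applicable`. The distinction is load-bearing: missing is penalized,
  NA is not.
* A visit with every item missing scores 0, not −26: the floor keeps the
  percentage in [0, 100]. With an empty denominator (`exclude` mode and all
  items NA) the percentage is defined as 0.0.
* Ranking ties in comparison tables break lexicographically by ICU id;
  trend deltas are against the immediately preceding visit.
* Problem sizes used by the reproduction script: 500 simulated visits per
  archetype for the discrimination gap and 2000 collector pairs for the
  rater-noise mean, which bound the Monte-Carlo standard error of both means
  well below the decision margins while keeping a run in seconds.

## Known limitations

The engine validates the instrument's internal logic, not its clinical
validity: the 13 vs 21/23-point field comparison cannot be reproduced because
the underlying responses are unpublished (and its printed percentages are
internally inconsistent, as above). Kappa on 33 near-balanced binary
verdicts from a single visit is a weak statistic and is reported only as a
supplement. Multi-rater (> 2) agreement and any weighting beyond equal
one-point items are out of scope.
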