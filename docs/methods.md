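# Methods

## The coding model

`helmetcoder` treats helmet-status extraction as dictionary-based
indicator construction followed by deterministic conflict resolution.
For a narrative *t* and term library *L* with category lists
*L_W* (wearing), *L_N* (not wearing), *L_U* (explicit unknown), define
three indicators

    I_c(t) = 1  iff  some phrase s ∈ L_c is a substring of normalize(t)

and code the record by the precedence table in the README: any fired
negation wins, otherwise any fired unknown marker wins, otherwise a
fired affirmation codes wearing, and no indicator at all codes
unknown.

Assumptions this encodes:

* **Raw substrings, no word boundaries.** The library deliberately
  contains sub-word and symbol surfaces (`",helmet,"`, `"whelmet"`,
  `"+ helmemt"`, `"- helmet"`) that only match as raw substrings.
  The cost is systematic nesting collisions — every `"unhelmeted"`
  also matches `"helmeted"`, every `"not wearing helmet"` also matches
  `"wearing helmet"` — which is exactly what the negation-first
  precedence rule absorbs. The full match set (phrase, category,
  offset) is preserved in the audit table so every resolution is
  inspectable.
* **Normalization is minimal by design**: lower-casing and whitespace
  collapsing only. No spelling correction, stop-word removal,
  lemmatization or negation-scope parsing — the approach is the
  preprocessing-free baseline that NLP pipelines are measured against,
  and its known failure mode (out-of-library variants such as
  `"was not wearig a helmet"`) is part of what the synthetic benchmark
  measures.
* **All-three-fired codes not wearing.** Only the three pairwise rules
  are externally specified; the triple case is the composition of the
  two rules that both favor the negation, and is logged as a conflict
  event.

The default library ships 111 phrases (58 wearing / 36 not-wearing /
17 unknown) in `data/default_terms.yaml`; editorial notes in that file
document retained misspellings and two typographic artifacts in the
curated source list. Custom libraries use the same three-key YAML
schema. A phrase under two categories is rejected at load time:
cross-category ambiguity is the resolver's job, never the library's.

## Agreement statistics

* **Cohen κ** from the 3×3 contingency table, κ = (p₀−pₑ)/(1−pₑ).
  The 95% CI uses the asymptotic variance of Fleiss, Cohen & Everitt
  (1969) — the default of mainstream agreement packages — with the
  classical sqrt(p₀(1−p₀))/((1−pₑ)√n) approximation available behind
  `se_method="simple"`. The CI method behind published intervals for
  this kind of analysis is rarely stated, so printed CIs are treated
  as indicative, not as reproduction targets. A table in which both
  raters are constant on the same category has pₑ = 1; κ is undefined
  and the package raises rather than returning a silent 0 or 1.
* **Fleiss κ** for m ≥ 2 complete sessions, with the large-sample
  null SE of Fleiss (1971) giving a z statistic and two-sided normal
  p-value (reported as "<.001" below that threshold in text reports).
  With m = 2 this is *not* algebraically Cohen's κ; tests check it
  against a direct transcription of the published formula instead.
* **Bands**: almost perfect (>0.90), strong (0.80–0.90), moderate
  (0.60–0.79), weak (0.40–0.59), minimal (0.21–0.39), none (0–0.20);
  exactly 0.90 is "strong"; negative values map to "none" with a
  logged flag.
* **Per-class precision/recall/F1** are one-vs-rest
  (scikit-learn backend); zero-denominator categories return 0 and are
  flagged. Category order is fixed everywhere as (wearing,
  not wearing, unknown).
* **Criterion-standard sampling** is stratified by assigned label,
  uniform without replacement within strata, seeded. The default
  strata (100 wearing / 100 not-wearing / 200 unknown) deliberately
  oversample the unknown stratum, where both automated coders are most
  likely to have missed information.

## Synthetic data

The generator emulates the *shape* of ED surveillance narratives, not
their content: `<AGE><SEX> <ACTION> <PRODUCT> [<PHRASE>] DX:
<DIAGNOSIS>`, upper-case, with the helmet phrase drawn uniformly from
the library list of the drawn truth stratum. Default truth mixture
(9.3% wearing, 11.0% not wearing, 1.8% explicit-unknown marker, 77.9%
unmentioned) follows the marginal composition of a 54,569-record
micromobility corpus coded by string search, with the explicit-unknown
share set from the ≈1,000 unknown-marker disagreements observed there;
both are documented approximations, since the true phrasing
distribution of real narratives is unknowable from published
aggregates. Misspelling corruption is a single random character
substitution/deletion/transposition inside the phrase — the edit
distance of observed real-world misses ("wearig", "helmemt") — and
flags the record `corrupted`.

What passing the synthetic round trip shows: the matcher, resolver and
I/O plumbing are exact on in-library phrasing, and degrade only on
corrupted records. What it does not show: performance on real
narratives, whose phrase inventory is open (out-of-library phrasings
like "helmet was cracked" exist) and whose distractor text may collide
with library surfaces in ways the template vocabulary — chosen to
contain no library surface — cannot.

The rater error model applies at most one transition per record, in
fixed order: negation flip (true not-wearing labeled wearing, the
dominant observed LLM failure), unknown-marker miss (explicit-unknown
record labeled wearing), then symmetric noise (uniform over the other
two categories). `expected_kappa` builds the implied truth×label joint
in closed form, so simulation correctness is testable as parameter
recovery: empirical κ at n = 50,000 must sit within 3 bootstrap SE of
the analytic value.

## Numerical and design choices

* All randomness flows through explicit integer seeds into
  `numpy.random.default_rng`; no global state. Re-running any CLI
  command with the same configuration and seeds produces byte-identical
  machine-readable outputs (no timestamps in outputs; atomic writes via
  rename).
* Problem sizes in the test suite and acceptance script — 10,000
  records for the round trip, 50,000 for parameter recovery, 200
  bootstrap resamples — were chosen as the smallest sizes at which the
  binomial/bootstrap error bands are meaningfully tight.
* The five-session test-retest reconstruction used in the acceptance
  surface is the unique block pattern consistent with every published
  session marginal (unanimous blocks of 5,110 / 3,079 / 43,477, a
  2,901-record negation-flip block, and two single-record
  spelling-error flips). The accompanying prose disagreement counts
  (2,902 and 2,900) are mutually inconsistent with those marginals by
  one record; the marginals win and the discrepancy is documented here
  rather than resolved.
* Micromobility inclusion filtering is config-driven (a YAML map of
  product code → mode); a record whose codes map to more than one
  distinct mode is excluded. The pipeline order is filter → duplicate
  check → classify.

## Limitations

* No fuzzy matching: single-character variants of library phrases are
  misses by construction. This is the method's defining trade-off, not
  an oversight.
* The Cohen κ CI is asymptotic; for very small n a bootstrap or exact
  method would be preferable (not implemented; weighted κ and
  Krippendorff's α likewise out of scope).
* The synthetic narratives are templated and cannot measure recall
  against phrasings absent from the library; estimating that requires
  a human-coded criterion standard, which the `validate` workflow
  supports but cannot replace.
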