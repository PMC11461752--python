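# Methods

## The scoring model

An observation's confidence is the sum of three ordinal step scores —
species identifiability, media quality, georeference quality — banded into
low (4–8), medium (9–13) and high (14–18), with four stop conditions that
make a record unscorable outright (molecular-only taxa, unusable media,
features not shown, missing coordinates). The model is deliberately
deterministic: media assessment is an input annotation supplied by a human
or an upstream tool, not computed from pixels, so the same inputs always
yield the same band and the protocol is auditable record by record.

Default point tables: species 1/3/5/7 over (diagnostic visibility ×
similar-species presence); media 1–7 over a full 3 × 3 clarity × features
grid, filled monotonically along both axes around the anchor cells
(clear/all = 7, clear/most = 5, moderate/most = moderate/some = 3,
poor/some = 1); georeference 4/3/2 over accuracy bins [0, 1 km),
[1 km, 10 km), [10 km, ∞). These values satisfy every structural constraint
of the protocol — minimum attainable total 4, maximum 18, species and media
point ranges wider than the georeference range, bands disjoint, contiguous
and covering [4, 18] — and the YAML configuration allows substituting any
other table that passes the same validation. Accuracy bins are half-open
and lower-inclusive because "less than 1 km" reads as strict; band edges
are integer-inclusive, and totals are always integers so rounding never
arises.

Two deliberate edge-case policies:

* A record with coordinates but no positional-accuracy radius receives the
  *lowest* georeference points with a warning rather than stopping; missing
  radii are common in exports and should degrade confidence, not void it.
  `strict_missing_accuracy` (CLI `--strict-geo`) switches to stop behaviour.
* When several steps stop at once, the reported reason follows step order
  (species, media, georeference), matching the protocol's sequence.

Habitat plausibility (e.g. "a marine species photographed on land is
wrong") is a pluggable `(lat, lon) -> bool` predicate applied before
scoring; the package ships only a rectangular toy mask because no
authoritative land/sea source belongs in a scoring library. Records without
coordinates bypass the filter and stop at the georeference step instead.

## Validation statistics

Confidence band, expert accuracy label and platform quality grade are
ordinal with massive ties, so association is measured with Kendall's τ_b,
implemented over the contingency table of the two codings so the
concordant/discordant counts and tie terms n₁, n₂ are exact and exposed on
the result. τ_a would be degenerate under this tie structure. The default
coding ranks unscorable below low — an unscorable record conveys less
support than any scored one — with `include_unscorable=False` available to
drop such records pairwise. A constant sequence raises an error rather than
returning NaN.

p-values use the large-sample normal approximation
z = 3(C − D)/√(n(n−1)(2n+5)/2), adequate at the hundreds-to-thousands of
records this tool targets; the test suite checks it against an exhaustive
permutation distribution at small n, where the approximation is loose but
unbiased. No tie-corrected variance or continuity correction is applied.
Strength labels band |τ| lower-inclusively at 0.10/0.40/0.70/0.90.

Percentages in summaries are computed from unrounded ratios and rounded
half-up to one decimal only at formatting time.

## The synthetic generator

`generate_dataset` emulates the joint structure a validation study sees: a
single uniform latent quality u per record drives every rubric input
monotonically (species level and media level by quartile of u, accuracy
radius by third), with cut points aligned so the three confidence bands
occupy equal thirds of u among scorable records. The expert label follows
the band-aligned class (low → incorrect, medium → uncertain, high →
correct) with probability |association|, otherwise it is uniform noise;
negative association reverses the alignment. Records forced into a stop
condition (rate `stop_rate`, mix dominated by molecular-only taxa) are,
when aligned, labelled incorrect for u < 1/3 and uncertain otherwise —
an observation that cannot be scored cannot be verified correct either.
The quality grade follows the accuracy label only with probability
1 − `grade_noise`, otherwise it is drawn from a fixed marginal heavy on
research grade; this makes the grade a weak accuracy proxy by
construction. All draws come from one seeded generator, so identical
parameters and seed give byte-identical CSV output.

Defaults (n = 957, association = 0.85, stop_rate = 0.374,
grade_noise = 0.85) mirror the case study's marginal structure: roughly a
third of records unscorable and a grade–accuracy association an order of
magnitude weaker than the confidence–accuracy one. Because stops are
injected independently of u and ties are heavy, the confidence–accuracy τ
at these defaults sits in the moderate range (≈ 0.46) rather than at the
no-stop coupling (≈ 0.82 at association 0.85 with stop_rate 0); the
comonotone fixture below shows the upper end (≈ 0.77) that a maximally
aligned joint distribution yields at the same marginals.

What the generator does *not* emulate: real spatial/temporal sampling
patterns, per-species observation frequencies, observer behaviour, or any
correlation between stop causes and season/place. Passing tests therefore
demonstrate that the pipeline recovers planted ordinal structure, not that
any particular real export will show a given τ.

## The case-study fixture

`case_study_fixture` rebuilds a 957-record scored set whose marginal counts
equal the published case-study marginals exactly: confidence 226/341/32/358
(high/medium/low/unscorable), accuracy 498/126/333
(correct/incorrect/uncertain), grade 543/407/7 (research grade/needs
ID/casual), with the 358 unscorable records split 197 molecular-required
and 161 unusable-media per the reported share of molecular-only taxa. The
joint distribution is a documented deterministic fill — the three marginals
zipped in ascending rank order (the comonotonic coupling) — and carries no
claim about the real joint counts; only the marginals are asserted
anywhere. Rubric inputs per band come from fixed templates and the
fixture's results are produced by actually scoring them, so the fixture
also exercises the scoring path end to end. Registry rows use real marine
alien/cryptogenic species names as examples; their trait values beyond the
molecular flag are illustrative.

Two published percentages are internally inconsistent with their own
counts (32/957 = 3.3%, printed as 3.4%; 543/957 = 56.7%, printed as 56.8%);
the package reports the values computed from the counts.

## Problem sizes

The test suite and the acceptance script use the full 36-cell rubric
lattice exhaustively, 500 random instances (n ≤ 30) for the τ oracle
check, and n = 2000 with five seeds per association level for generator
recovery; the whole suite runs in a few seconds.

## Known limitations

* The per-level point values are constraint-satisfying defaults; a team
  applying the published protocol verbatim should transcribe its exact
  step values into the YAML config.
* The species step depends entirely on the curated trait registry; the
  package validates but cannot author it.
* No confidence intervals on τ, no ordinal regression, and no
  multiple-testing correction are provided.
* Media grading from images, platform API access and Darwin-Core export
  are out of scope.
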