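# obsconf

Confidence scoring and validation statistics for citizen-science species
observations.

## The problem

Platforms such as iNaturalist deliver species-occurrence records at a scale
traditional monitoring cannot match, but every record carries three
intrinsic sources of uncertainty: how identifiable the species is from
photographs, how good the uploaded media are, and how trustworthy the
georeference is. The platform's own quality tier ("research grade") is a
weak proxy for identification accuracy, so researchers — for example teams
monitoring marine alien and cryptogenic species from opportunistic records
— need a transparent, repeatable way to decide which observations to trust
before analysis.

`obsconf` implements a three-step confidence rubric for that decision, plus
the ordinal-association statistics used to validate it against
expert-verified accuracy labels.

## The rubric

Each observation is scored in three steps:

1. **Species** — does the species have easy-to-see diagnostic features, and
   do very similar species occur in the region? (default points 1/3/5/7)
2. **Media** — are the images clear, and do they show the diagnostic
   features? (default points 1–7 over a clarity × features grid)
3. **Georeference** — positional accuracy radius under 1 km scores
   highest, 1–10 km intermediate, beyond 10 km lowest (default 4/3/2).

Step scores are summed to a total *T* ∈ [4, 18], banded as **low** (4–8),
**medium** (9–13) or **high** (14–18). Four *stop points* make an
observation **unscorable** instead: the species requires dissection or
molecular evidence, the media are unusable, the media show none of the
required features, or the record has no coordinates. All point tables, bin
edges and band edges are configurable via YAML and validated structurally
(attainable totals must equal the band range; species and media ranges must
be wider than the georeference range).

Validation uses Kendall's tie-corrected rank correlation

τ_b = (C − D) / √((n₀ − n₁)(n₀ − n₂)),  n₀ = n(n−1)/2,

between confidence band, expert accuracy label (incorrect < uncertain <
correct) and platform quality grade (casual < needs ID < research grade),
with two-sided p-values from the normal approximation
z = 3(C − D)/√(n(n−1)(2n+5)/2) and conventional strength labels
(|τ| < 0.10 negligible, < 0.40 weak, < 0.70 moderate, < 0.90 strong,
otherwise very strong).

## Worked example

Simulate a labelled dataset, score it, and validate confidence against the
ground-truth labels:

```sh
obsconf simulate --n 500 --seed 1 --out-dir sim
obsconf score --observations sim/observations.csv --registry sim/registry.csv --out-dir scored
obsconf validate --observations sim/observations.csv --registry sim/registry.csv \
    --truth sim/truth.csv --out-dir val
```

The validate command prints (this exact output for seed 1):

```
read 500 rows: 500 records, 0 rejected
tau(confidence, accuracy) = 0.454 (n=500, p=5.2e-25, moderate)
tau(confidence, quality_grade) = 0.068 (n=500, p=0.15, negligible)
tau(accuracy, quality_grade) = 0.187 (n=500, p=0.0002, weak)
observations: 500
confidence band:
  unscorable          195  (39.0%)
  low                 100  (20.0%)
  medium              109  (21.8%)
  high                 96  (19.2%)
...
retained at medium-or-high confidence: 41.0%
```

Reading: the rubric's confidence band tracks the true accuracy labels far
more closely (τ = 0.45) than the platform quality grade does (τ = 0.19
against accuracy), which is the qualitative pattern the rubric exists to
exploit; 41% of this simulated set would survive the recommended
keep-medium-and-high retention rule. Scored output, crosstabs, the summary
and a rejection report are written as CSV in the `--out-dir`.

The same pipeline runs on real exports: point `--observations` at a CSV
with the expected columns (a `--column-map` is configurable for other
dialects) and `--registry` at a researcher-curated species-trait table.

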