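# lexirt

IRT-based construction and validation of short lexical-decision reading
tests.

A two-alternative forced-choice lexical decision task (LDT) — "is this
letter string a real word?" — can be self-administered in a browser and
scored automatically, which makes it a practical proxy for
clinician-administered measures of single-word reading ability. Turning a
long experimental item list into a short, reliable instrument is a
psychometric problem: calibrate the items, discard the ones that measure
nothing, and split the survivors into interchangeable short forms.
`lexirt` implements that whole workflow as a tested Python library, together
with a synthetic-data generator so every stage can be exercised and
validated without human data.

## The model

Because the task is 2AFC, chance performance fixes the lower asymptote at
c = 0.5. Responses are modelled with guess-floored logistic item response
functions

```
P(correct | θ) = c + (1 − c) / (1 + exp(−a (θ − b))),   c = 0.5
```

in two variants: a Rasch-style model (one common slope `a`, per-item
difficulty `b`) and a 2PL (per-item `a` and `b`). Both are estimated by
marginal maximum likelihood with an EM algorithm over a fixed quadrature
grid under a standard-normal latent prior; abilities are scored by EAP.
Item quality is judged by infit/outfit mean-square statistics
(expectation 1 under the model) and by the 2PL slope.

The item-optimization pipeline mirrors the published four-step procedure:

1. **Correlation screen** — drop items whose responses correlate at
   r ≤ 0.10 with overall accuracy or with the external criterion score.
2. **Rasch fit pruning** — iteratively refit and drop items with infit or
   outfit outside [0.6, 1.4] until all survive.
3. **Discrimination pruning** — fit the 2PL and drop items with a < 0.7.
4. **Assembly** — partition the survivors into class-balanced lists equated
   on difficulty (and length), with overlapping test-information curves.

Response-time analyses replicate the standard screening rules (one-sided
3-SD participant rule on median RT; a 0.2–5 s window; per-person 3×IQR
fences) and estimate the classic log-RT effects (lexicality, frequency,
bigram frequency, length, length × ability) with a two-stage
per-person-regression estimator. Validation statistics include criterion
correlations with disattenuation, Williams' test for dependent correlations,
two-way consistency ICC across forms, Spearman-Brown composite reliability,
and rank-based comparisons of retained vs. rejected item properties.

## Worked example

`examples/build_short_forms.py` generates a 300-item bank with 5% planted
bad items, simulates 300 examinees, runs the pipeline and assembles three
forms:

```
step1_correlation      removed  37, retained 263
step2_rasch_fit        removed   3, retained 260
step3_discrimination   removed  19, retained 241

list composition:
   pseudo  real
A      39    39
B      39    39
C      39    39

difficulty summary (Rasch b):
    mean     sd    min    max     n
A -0.034  1.084 -2.118  1.910  78.0
B -0.032  1.091 -2.160  2.011  78.0
C -0.036  1.104 -1.992  2.252  78.0

pairwise information ratio range: [0.959, 1.012]
between-form score ICC (single): 0.822
```

The screen removes uninformative items (including the planted ones), the
fit and slope prunes catch the remainder, and the assembled lists are
balanced (39 real + 39 pseudo each), matched in mean difficulty to three
decimals, and carry test-information curves within ±5% of each other —
i.e., the three short forms are interchangeable measures.

The other examples cover simulation (`simulate_session.py`), calibration
and scoring (`calibrate_and_score.py`), response-time analyses
(`rt_effects.py`), and the one-command reproducible run
(`end_to_end_run.py`). A thin CLI wraps the same entry points:

```bash
lexirt simulate --seed 1 --out run/
lexirt fit --responses run/responses.csv --out run/model.json
lexirt end-to-end --seed 1 --out run/
```

Every run directory is self-describing: resolved config, per-stage event
log, and a SHA-256 manifest — identical configurations produce
byte-identical artifacts.

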