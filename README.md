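# synkit

Analysis of synesthesia consistency-test data in Python: color-space
consistency scoring, automated validity classification of participants via
density clustering, screening arithmetic, seeded synthetic respondents and
per-participant diagnostic plots.

## Who this is for

In a grapheme-color consistency test, inducers (letters, digits, vowels,
sounds, …) are each presented several times — typically three — and the
participant picks a color for every presentation. Genuine synesthetes choose
very similar colors for the same inducer across repetitions; most other
people cannot. `synkit` is for researchers who run such tests and need to
(a) score response consistency, (b) weed out participants whose data are
uninterpretable before scoring (all-black clickers, single-color responders,
"very light but hue-varying" responders), and (c) reason about what a
positive screen means at population prevalence.

## The methods

**Consistency score.** For a grapheme with trial responses
*x₁, …, x_t* in a working color space, the score is the sum of pairwise
distances, Σ_{i<j} d(x_i, x_j) (for 3 trials: d₁₂ + d₁₃ + d₂₃); a
participant's score is the mean over their graphemes. Lower = more
consistent. Two (space, metric) pairs carry published synesthesia cutoffs
for three-trial tests, applied strictly below: Euclidean distance in CIELUV
with cutoff **135**, and taxicab distance in unit-normalized sRGB with
cutoff **1**. Supported working spaces: sRGB, CIE XYZ (D65, white Y = 100),
CIELAB, CIELUV.

**Validity classification.** A participant's pooled response colors are
clustered with DBSCAN (inclusive radius `eps`, density threshold
`min_pts`); points joining no cluster form a noise set. Within-cluster
spread is summarized by the total within-cluster variance,

TWCV = Σ_c (1/n_c) Σ_{x∈c} ‖x − μ_c‖²,

summed over non-noise clusters c with centroid μ_c. Data are invalid when
(in order): too few fully answered inducers; one cluster holds at least
`max_prop_single_cluster` of all responses; or fewer than
`min_num_clusters` clusters formed while TWCV stays below `safe_twcv`.
Defaults encode "at least 4 complete inducers, at least 3 clearly different
colors, no color covering 80 %+ of responses" (a stricter `rater_strict`
preset uses 60 %).

**Screening arithmetic.** For sensitivity *se*, specificity *sp* and
prevalence *π*, PPV = se·π / (se·π + (1−sp)(1−π)); the complement is the
expected false-positive share among positive screens.

## Worked example

```python
from synkit import (ArchetypeParams, ScoringConfig, ValidationSpec,
                    gen_group, group_scores, validate_group)

group, truth = gen_group(
    [(ArchetypeParams("synesthete"), 3),
     (ArchetypeParams("random"), 2),
     (ArchetypeParams("single_color"), 2)],
    seed=7,
)
print(group_scores(group, ScoringConfig(metric="euclidean", color_space="Luv")))
print(validate_group(group, ValidationSpec()))
```

```
    participant_id      score  n_graphemes_used  synesthetic
  p0000_synesthete  17.970097                16         True
  p0001_synesthete  15.374649                16         True
  p0002_synesthete  19.799893                16         True
      p0003_random 304.241403                16        False
      p0004_random 310.814972                16        False
p0005_single_color  10.169464                16         True
p0006_single_color  27.201295                16         True

    participant_id  valid                 reason  ... num_clusters  prop_largest_cluster
  p0000_synesthete   True                     ok  ...            8              0.125000
  p0001_synesthete   True                     ok  ...            8              0.125000
  p0002_synesthete   True                     ok  ...            8              0.125000
      p0003_random   True                     ok  ...            2              0.083333
      p0004_random   True                     ok  ...            2              0.083333
p0005_single_color  False dominant_color_cluster ...            1              1.000000
p0006_single_color  False dominant_color_cluster ...            1              1.000000
```

The synesthete-like participants score far below the CIELUV cutoff of 135
and random responders far above it — but so do the single-color clickers
(scores 10.2 and 27.2, "synesthetic" by cutoff alone). The validity table
is what catches them: all their responses fall into one DBSCAN cluster
(`prop_largest_cluster = 1.0`), so they are flagged
`dominant_color_cluster` and should be excluded before scoring is
interpreted.

The same pipeline is available from the shell:

```bash
synkit simulate --mix synesthete:3 --mix random:2 --seed 7 --out trials.csv --truth-out truth.csv
synkit score    --input trials.csv --color-space Luv --metric euclidean --out scores.csv
synkit validate --input trials.csv --out validity.csv
synkit plot     --input trials.csv --participant-id p0000_synesthete --out p0.png
synkit ppv      --sensitivity 0.9 --specificity 0.94 --prevalence 0.011
# PPV: 0.143 (14.3%)
# Expected false positives among positives: 0.857 (85.7%)
```

That last command is the screening lesson in one line: a test with 90 %
sensitivity and 94 % specificity, applied where only 1.1 % of people have
the trait, yields positives of whom ~85.7 % are expected to be false —
which is why validity filtering (and any other boost to effective
specificity) matters.

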