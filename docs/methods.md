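# Methods

This note documents the models and procedures `synkit` implements, the
parameter defaults and why they were chosen, the numerical conventions,
and what the synthetic-data tests do and do not establish about real data.

## Data model

Input is a tidy long-format trial table: one row per trial with a
participant ID, an inducer symbol and a response color as `#RRGGBB` hex.
"No color" responses and absent rows are both MISSING (`None`); MISSING is
distinct from every color, including pure black. Each grapheme holds
exactly `trials_per_symbol` response slots (default 3, the standard test
geometry); symbols with fewer rows are padded with MISSING, because
aborted tests are common and completeness is the validation step's
concern, while more rows than configured is a hard error. Trial order
within a symbol is file order unless a trial-index column is configured —
pairwise scoring is order-invariant, so order only affects plotting.

Researchers who want to discard a particular clicked color regardless of
count (commonly pure black, since inducers are usually displayed in
black) can recode it to MISSING (`recode_to_missing`) before analysis;
the package deliberately takes no stance on what counts as "black".

## Color spaces

Four working spaces are supported: nonlinear sRGB on [0, 1]³, CIE XYZ,
CIELAB and CIELUV. Conversion conventions:

* sRGB → linear RGB via the IEC 61966-2-1 piecewise transfer function
  (threshold 0.04045, divisor 12.92, offset 0.055, exponent 2.4);
* linear RGB → XYZ via the standard sRGB/D65 matrix, scaled so the sRGB
  white point has Y = 100. The CIELUV cutoff of 135 presumes standard
  CIELUV units, which this scaling produces.
* XYZ → Lab/Luv via the CIE formulas with exact rational constants
  (ε = 216/24389, κ = 24389/27). The reference white is the image of
  sRGB (1, 1, 1) under the matrix — not a separately tabulated white —
  so white maps to exactly L\* = 100 with zero chroma and the gray axis is
  chroma-free to machine precision.
* At zero luminance the CIELUV chromaticities u′, v′ are undefined
  (denominator 0); u\* and v\* are defined as 0 there so pure-black
  responses remain representable and conversion is continuous.

sRGB channels are kept in [0, 1] because the published taxicab cutoff of
1 presumes unit-normalized RGB. Hex parsing accepts upper/lower case with
optional `#`; 8-digit (alpha) hex is rejected since consistency tests emit
opaque colors. HSL appears only inside the synthetic-data generator, never
as an analysis space.

## Consistency scoring

The grapheme score is the **sum** of pairwise distances over the usable
trial responses; the participant score is the **mean** over grapheme
scores. This reproduces the three-trial scores to which the published
cutoffs apply (135 for CIELUV/Euclidean, 1.0 for sRGB/taxicab; both
strict "score < cutoff"). With trial counts other than three, the sum
grows with the number of pairs and the published cutoffs no longer apply;
no re-normalization is attempted, and users must supply their own cutoff
for any other (space, metric) pair. By default (`complete_only=True`)
graphemes with any MISSING response are excluded from scoring, matching
the framing that only fully answered inducers are interpretable; with
`complete_only=False`, graphemes with exactly two usable responses yield
a single-pair score that is deliberately left on that raw scale.

## Validity classification

Response colors (from complete graphemes only, by default) are pooled and
clustered with DBSCAN in the working space using Euclidean neighborhoods.
Determinism conventions: the eps-ball is closed (d ≤ eps), a point's own
membership counts toward `min_pts`, points are processed in input order,
border points join the first cluster that reaches them, and cluster ids
follow discovery order. The implementation delegates to
scikit-learn's DBSCAN, which satisfies all of these; an exhaustive
density-connectivity oracle in the test suite checks the resulting core
partition and noise set on randomized instances.

Total within-cluster variance is defined here as

    TWCV = Σ_c (1/n_c) Σ_{x∈c} ‖x − μ_c‖²,

the sum over non-noise clusters of the population-variance-style mean
squared distance to the centroid, and 0 when no cluster exists. Noise
points contribute nothing to TWCV but do count in the denominator of the
dominant-cluster proportion, since that criterion concerns "proportion of
all responses".

The ordered decision procedure: (1) fewer than `min_complete_graphemes`
complete inducers → invalid; (2) a cluster holding ≥
`max_prop_single_cluster` of all points → invalid; (3) fewer than
`min_num_clusters` clusters **and** TWCV < `safe_twcv` → invalid;
(4) otherwise valid. The TWCV conjunct in (3) exists because a
participant whose colors are so scattered that *no* cluster forms has
k = 0 and TWCV = 0; their large spread is then evidenced only by the
noise count, and the conjunction prevents flagging them as "too few
distinct colors" only when TWCV is genuinely high — with all-noise data
both conditions hold and the verdict is invalid, a documented edge (such
data are anyway uninterpretable under any reasonable criteria).

Defaults: `min_complete_graphemes=4`, `eps=20` (CIELUV units),
`min_pts=4`, `min_num_clusters=3`, `max_prop_single_cluster=0.8`,
`safe_twcv=250`, `complete_graphemes_only=True`. The structural values
mirror widely used manual criteria (at least 4 complete inducers, at
least 3 clearly different colors, no single color covering 80 % or more
of responses); the numeric clustering parameters are this package's own
calibration, validated by the synthetic-recovery properties below, and
are expressed in CIELUV units — they should be re-chosen if another
working space is used. A `rater_strict` preset sets the dominant-cluster
bound to 0.6, mirroring manual rating schemes in which using one color
for 60 % or more of responses invalidates the data. Degenerate input with
`min_pts` above the point count yields all-noise (k = 0) and is decided
by rule (3), not treated as an error.

## Screening arithmetic

PPV = se·π / (se·π + (1−sp)(1−π)) for sensitivity se, specificity sp and
prevalence π, all strictly as proportions in [0, 1] — percentage-style
inputs (1.1 for 1.1 %) are rejected by range checks to avoid silent
hundred-fold errors. The expected false-positive share among positive
screens is 1 − PPV. With se = 0.90, sp = 0.94, π = 0.011 this gives
PPV ≈ 14.3 % and ≈ 85.7 % expected false positives, the standard
rare-trait screening caveat.

## Synthetic respondents

`synthdata` generates seeded participants of five archetypes chosen to
span the response styles that matter for scoring and validation:

* **synesthete** — a personal palette of well-separated colors (pairwise
  sRGB Euclidean separation ≥ 0.5, rejection-sampled; an impossible
  request raises), assigned to inducers cyclically so every palette color
  backs several inducers, plus per-trial Gaussian jitter;
* **random** — uniform draws on the sRGB cube;
* **single_color** — one base color plus jitter for every trial;
* **light_varying** — hue uniform, lightness in [0.85, 0.97] and
  saturation in [0, 0.4] drawn in HSL and converted to sRGB;
* **few_colors** — every trial drawn from a small separated palette.

Defaults emulate a 16-inducer, three-trial test. Jitter SD is 0.02 sRGB
units per channel — small relative to palette separation (0.5) but
non-zero, standing in for color-picker motor noise. Each response is
independently MISSING with `missing_rate` (default 0). Randomness flows
from `numpy.random.default_rng` with per-participant sub-seeds
`seed + index`, so groups are reproducible and any participant can be
regenerated in isolation.

What the generator does *not* emulate: per-inducer category structure
(letters vs digits sharing hues), inducer-specific missingness, response
drift over a session, palette-widget quantization biases, or mixtures
within one participant. Passing recovery tests therefore show that the
criteria separate clearly degenerate from clearly well-formed response
styles — not that the default thresholds are optimal for any particular
real dataset; thresholds should be sanity-checked on a held-out subset of
real data, and the criteria actually used should be reported alongside
results.

## Verification and problem sizes

The test suite checks, among others: conversion round trips (sRGB → XYZ →
sRGB within 1e-6 on an 11³ grid), agreement of Lab/Luv with scikit-image's
independent conversions, the frozen reference values for pure red, DBSCAN
and TWCV against exhaustive brute-force oracles on 200 random instances of
up to 50 points, and archetype recovery on a seeded mixture of 100
synesthete-like, 100 single-color and 100 uniform-random participants
(≥ 95 % of single-color flagged invalid, ≥ 95 % of synesthete-like valid,
mean CIELUV scores straddling 135). The light-color artifact — that very
light, hue-varying responses receive *lower* CIELUV consistency scores
than saturated random responses, because light colors crowd together near
white — is reproduced by simulation at 60 participants per archetype.
These sizes keep the full suite under a minute while leaving the
statistical margins comfortable.

## Known limitations

* Published cutoffs apply only to three-trial tests and the two anchored
  (space, metric) pairs; everything else needs a user-supplied cutoff.
* TWCV as defined here (population denominator, noise excluded, summed
  over clusters) is this package's definition; other implementations of
  cluster-spread statistics may differ in normalization, and the
  `safe_twcv` default is calibrated against *this* definition.
* The validation defaults are CIELUV-scaled; no automatic eps selection
  (e.g. k-distance elbow) is provided.
* Only D65 is supported; no ICC profiles or chromatic adaptation.
* Wide-format ingestion is out of scope — reshape to tidy long format
  first.
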