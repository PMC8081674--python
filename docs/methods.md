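# Methods

This note documents the models and procedures implemented in `objectnorms`,
the defaults they use, the design choices that were genuinely open, and what
the synthetic benchmarks do and do not establish.

## Norm preprocessing

Raw feature-listing responses are cleaned by declarative rules applied in a
fixed order: token-level spelling correction, adverb deletion, and plural
stripping, then full-label synonym/morphological collapsing, then feature
splitting ("has a round face" → "has a round face" + "has a face"). The
chain is iterated to a fixed point (capped at 8 passes) so normalization is
idempotent; responses emptied by cleaning are logged and discarded, never
fatal. Relation words ("is", "has", "does", "is made of") are part of
feature identity and are never altered by cleaning. Curation that is
traditionally done by hand is expressed entirely as rule files (CSV), which
makes preprocessing reproducible and unit-testable; the cost is that only
supplied rules are applied — there is no automatic synonym discovery or
spell checking.

Production frequency is a head-count: a participant listing the same
canonical feature twice for one concept counts once, so `pf[c, f]` can never
exceed the concept's rater count (validated at construction). The matrix
stores raw integer counts; a per-concept normalized view (`pf / raters`) is
a derived transform, keeping the core lossless.

Filtering order: (1) cells with `pf < cell_cutoff` (default 3) are zeroed;
(2) taxonomic features are dropped (category-membership statements are not
treated as true semantic features); (3) features left with no surviving cell
or occurring in fewer than `min_concepts` (default 2) concepts are dropped;
(4) concepts retaining fewer than 3 features are flagged but kept, so
callers decide exclusion. The cell-level and feature-level thresholds are
deliberately separate parameters because published norming pipelines state
both kinds of cut-off without fixing their combination; the defaults apply
both.

## Conceptual-structure statistics

* `d_f = 1/n_f` exactly, with `n_f` the post-cutoff concept count.
* MD is the unweighted mean of member `d_f`; concepts with no members report
  missing values, never zeros, to avoid silently biasing regressions.
* Feature correlations are Pearson correlations between production-frequency
  vectors across all concepts (not binarized occurrence). `cs_f` averages a
  feature's correlations with all *other* features (self-correlation
  excluded); zero-variance features yield undefined correlations and are
  masked. The default inclusion policy ("all") admits every defined pair; a
  "shared" policy masking pairs that never co-occur in any concept is
  available, since parts of the norms literature threshold pairs this way.
  Unweighted means are used throughout (production-frequency weighting of
  the CS average is a known variant, not implemented as the default).
* CSxD is the unstandardized least-squares slope `cov(d, cs) / var(d)`
  within the concept's feature set, undefined (flagged) when fewer than two
  members have defined statistics or the members' `d_f` are identical.

**Known limitation of naive CS on sparse matrices.** Features appearing in
only one or two concepts have near-degenerate pf vectors, so their pairwise
correlations with concept-mates approach 1 regardless of any real
co-occurrence structure. On small synthetic matrices this inflates
concept-level CS for concepts built from rare features, to the point that a
category of heavily feature-sharing concepts can show *lower* naive CS than
disjoint-pool controls even though its features are genuinely more
co-occurring. The package therefore validates the co-occurrence construction
at the feature-pair level (within-pool pairs correlate far higher than
cross-category pairs), and users comparing CS across very differently sized
support sets should prefer the "shared" policy or interpret CS jointly with
`n_f`.

Naming agreement is the modal-name share of all responses; "don't know"
counts in the denominator but can only be modal when it is the sole
response type; ties break lexicographically and are logged.

## Image statistics

Pinned conventions (recorded in each output's JSON sidecar):

* white threshold 250/255 per channel — a pixel is background white when all
  three channels reach it;
* hue is averaged circularly (mean resultant angle), since hue is an angle;
  saturation and value are plain means on [0, 1];
* grayscale uses ITU-R BT.601 luma weights (0.299, 0.587, 0.114);
* spectral energy is the mean squared non-DC Fourier magnitude per pixel,
  which by Parseval's theorem equals the grayscale variance — a constant
  image has energy exactly 0 and a sinusoidal grating of amplitude A has
  energy A²/2 (used as the analytic test);
* JPEG complexity is the byte length at quality 75, baseline encoding,
  4:2:0 chroma subsampling, no metadata. It is deterministic for a fixed
  encoder build but not across libjpeg versions, so tests assert
  determinism and ordering (noise > flat), not frozen byte counts.

Layer-activation entropy is the Shannon entropy, in bits, of the
L1-normalized rectified activation vector: negatives are clipped, `p_i =
v_i / Σv`, `H = −Σ p_i log2 p_i`. This estimator is scale-invariant and has
no binning hyper-parameter; a histogram-binned variant is available behind
`method="histogram"` for comparison. The early/middle/late layer labels are
data, not code — any three labeled vectors per image are accepted. A
pretrained-network adapter hook exists but requires torch/torchvision;
everything in this package runs on synthetic or externally supplied
activation files.

## Memory scoring

Scores are item-level: HR from old-status trials, FAR from new-status
trials, each across the raters who saw the item in that status; items
missing a status report a missing rate. Extreme rates are corrected before
the quantile transform with the 1/(2N) rule by default (0 → 1/(2N),
1 → 1 − 1/(2N)); an additive (count + 0.5)/(N + 1) policy is selectable.
`d' = Z_HR − Z_FAR` and `c = −0.5 (Z_HR + Z_FAR)` are exact linear
identities of the transformed rates and are asserted to 1e−12. Response
times are averaged per outcome class (hit/miss/correct rejection/false
alarm) with no trimming by default. Test-level summary SDs are across items;
participant-level spread is not recoverable from item scores and is labeled
accordingly. Category summaries drop categories with fewer than 5 items;
most/least-remembered rankings break ties by item id.

## Modeling

Predictor normalization is skew-driven: columns with |sample skew| > 1.0 get
log10 (with a recorded offset when non-positive values are present: the
smallest positive value added beyond the minimum); hue, saturation, and
value always get a maximum-likelihood Box–Cox transform, as bounded
non-Gaussian pixel statistics. The skew threshold of 1.0 is a declared
convention. Fitted `TransformSpec`s (transform, λ, offset) persist so
transforms re-apply reproducibly.

Regression is OLS with intercept via statsmodels: unstandardized β with
t = β/SE reported by default (standardized β behind a flag), adjusted R²,
and per-predictor VIF = 1/(1 − R²_j). Rank-deficient designs raise an error
naming the dependent columns; missing rows are removed listwise per model
with counts exposed. p-values are descriptive; Bonferroni/FDR adjustment
exists but defaults off. The d′ outcome runs through the identical code
path as the rate outcomes.

Mediation uses OLS path estimates (a from m~x; b, c′ from y~x+m; c from
y~x), for which c = c′ + ab holds exactly on a common sample, and a
percentile bootstrap over items (default 5,000 resamples, fixed seed,
95% CI on ab) — the most common convention where no method is otherwise
specified. The bootstrap is vectorized and bit-reproducible under a fixed
seed. A mediator (near-)collinear with the predictor is rejected as
unidentifiable. Proportion mediated ab/c is reported missing when the total
effect is numerically zero.

## Synthetic data: what it emulates, and what it does not

The norming generator plants category structure: members of a category
sample five features per rater (the feature-listing task format) from a
category-shared pool and from "distinctive" features shared by a small
number of adjacent members (default 2, so they survive the ≥2-concepts
cutoff while keeping d_f = 1/2). Default 20 raters per concept; the
shared-pool sampling weight is jittered per category so conceptual
statistics vary between items. Taxonomic statements are emitted at a
configurable rate to exercise the taxonomic filter.

The memory generator produces per-item response probabilities
`link(intercept + β'x + noise)` with binomial rater sampling (defaults 43
old / 31 new raters per item, the scale of crowd-sourced recognition tests)
and per-test baselines (hit ~0.56/0.55, false alarm 0.27 visual vs 0.44
lexical). Visual and lexical tests share the predictor signal and a
configurable fraction of item noise; that fraction can be solved in closed
form to hit a target cross-test hit-rate correlation (default 0.33) given
the binomial attenuation. The logistic link is the default because it keeps
rates in [0, 1]; the linear link exists for parameter-recovery experiments,
where the analysis model (linear regression on rates) must coincide with
the generative model for "recovered β equals planted β" to be well-posed —
under a logistic link the OLS estimand is a link-dependent rescaling, not
the planted coefficient.

Recovery benchmarks are scored with z-statistics, `(β̂ − β_true)/SE`. For an
unbiased estimator these are approximately standard normal, so any single
coefficient exceeds 2 SE about 5% of the time by chance; across 15
predictors, two tests, and several seeds, "every coefficient within 2 SE"
would fail for a *correct* implementation most of the time. The recovery
tests therefore bound the ensemble: max |z| ≤ 3.5 and mean |z| ≤ 1.2
(expected mean |z| ≈ 0.8 under normality), with adjusted R² required within
±0.05 of the generator's closed-form value. The end-to-end pipeline also
checks the mediation machinery against closed-form population paths derived
from the generator's moments.

Passing these benchmarks shows the pipeline's statistics and estimators are
correct and unbiased under the generative assumptions; it does not show
that real feature norms satisfy those assumptions. In particular the
synthetic feature vocabulary is structural, not linguistic; the images are
geometric shapes whose statistics are more mutually collinear than real
object photographs (pipeline mean VIF ≈ 4–5, driven by area-related
predictors); and Dirichlet activation vectors do not mimic real
convolutional-network activation distributions — only the entropy ordering
is controlled.

## Problem sizes and runtime

Defaults emulate a realistic large norming study while staying desk-scale:
1,000 concepts (50 categories × 20 members) through the full pipeline, 1,000
items for regression and mediation recovery, 5,000 bootstrap resamples. The
full pipeline runs in well under a minute on one CPU; the complete test
suite in about one minute.
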