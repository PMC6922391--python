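# Methods

## Episode model and time conventions

An episode is four boundaries on one timeline: onset ≤ plateau onset ≤
plateau offset ≤ offset, with offset > onset. A zero-length plateau is
legal. The three phases (opening, plateau, closing) partition the
episode, so total = opening + plateau + closing; with float boundaries
the identity holds to ≤ 1e-9 s and tests assert it at that tolerance.

Frame-by-frame video coding marks the first and last *visible* frame of
an extent (inclusive). We convert to seconds with a half-open convention:
a span from frame f0 to frame f1 occupies [f0/fps, (f1+1)/fps). This
makes a single-frame event 1/fps long and guarantees the phases tile the
episode exactly in frame arithmetic — the alternative (last-frame/fps as
the end) leaves a one-frame hole between phases and breaks the duration
identity. Default fps is 24, the frame rate of the recordings the
analysis models.

File formats: a canonical CSV schema (`episode_id, subject_id, onset_s,
plateau_onset_s, plateau_offset_s, offset_s, label_ref[, coder_id]`, with
a `*_frame` + fps variant) and read-only ELAN EAF. EAF intervals come
from two independent tiers — episode extents and plateau extents — paired
by containment; an episode must contain exactly one plateau interval.
CSV floats are written with `repr`, so a seconds-dialect round trip is
bit-exact.

## Timing rule

Yawn iff opening + plateau > closing, strictly; the plateau counts toward
the opening phase. Ties classify as non-yawn: the rule demands a *longer*
time to maximum opening, and because inputs are frame-quantized an exact
tie is a meaningful event, not float noise, so no epsilon is applied. The
signed margin (opening + plateau − closing) is returned for diagnostics.
The decision is invariant under rescaling time units.

## Agreement statistics

Cohen's κ, sensitivity, specificity and percent agreement are computed
from 2×2 counts with yawn as the positive class; κ uses chance agreement
from the table margins. Statistics whose margin is empty are NaN, the
rest are still returned. All values are kept at full precision
internally; report methods round to two decimals (percent agreement to
the nearest integer), matching conventional presentation. Note that
42/115 = 0.3652 specificity rounds to 0.37 at two decimals although such
values are often printed truncated (0.36); we never truncate.

Event-level reliability between two coders has no natural true-negative
count, so the primary statistic is percent matched: greedy one-to-one
matching by nearest onset (A processed in onset order — a deterministic
tie-break), a pair being eligible when onset *and* offset each agree
within the tolerance (default 1 s), divided by the larger coder's event
count. Optimal bipartite matching was considered and rejected: at
realistic event densities (events are seconds long, minutes apart) greedy
and optimal matching coincide, and greedy is reproducible and simple. A
frame-binned κ (bin = 1/fps, a bin positive when its centre lies inside
an event) is provided for comparability with κ-based reliability
reporting whose exact convention is unknown; we deliberately do not guess
which convention produced any particular published κ.

Phase-duration agreement is the fraction of aligned duration pairs with
|ΔA − ΔB| ≤ tolerance (default 0.5 s), plus the median absolute
difference.

## SVM models

Feature sets: Model A = {total, plateau, opening, asymmetry,
opening/closing ratio}; Model B = {total, plateau, asymmetry}. A
feature-set description phrased in terms of "interactions" is not literal
in a kernel classifier, so the default mode feeds raw feature vectors and
lets the RBF kernel capture interactions implicitly; an
`add_product_term` mode appends the literal product of the listed
features (e.g. total·plateau·asymmetry for Model B) for users who want
the three-way-interaction reading. Both are exposed; raw features are the
default because the kernel subsumes the product term.

Features are z-scaled with mean/SD fitted on training data only
(sample SD, n−1); constant columns are dropped with a warning. Scaling
can be disabled. Training solves the standard soft-margin dual via the
libsvm solver (scikit-learn `SVC`, tol 1e-7); the fitted model stores
support vectors, dual coefficients αᵢyᵢ, bias, (C, γ) and the scaling, and
recomputes decisions and the dual objective from those stored parameters
alone — tests verify the dual objective against an independent SLSQP
quadratic-programming oracle on small instances (≤ 8 points, 1e-4
relative) and check dual feasibility (0 < αᵢ ≤ C, Σαᵢyᵢ = 0) on every
fit. Episodes with a zero-length closing phase have an undefined
opening/closing ratio and are rejected by Model A's feature matrix by
episode id (Model B does not use the ratio).

Grid search: 7×7 powers of ten over [10⁻³, 10³] for C and γ, stratified
k-fold CV (default 10) with seeded shuffling; stratification is chosen so
every fold contains positives at a 15:115 imbalance. If the minority
class has fewer members than the fold count, folds reduce to that count
with a warning. Ties on CV error break toward the smallest C, then the
smallest γ — a preference for the least complex model among equals. No
class weights are applied; imbalance is handled by reporting
sensitivity/specificity separately in validation.

## Hold-out validation

Each iteration draws a simple (non-stratified) random split — 2/3 train,
1/3 test; 87/43 at n = 130 — fits scaling and the SVM on the training
rows only, and scores the test rows through the agreement module.
Summaries are mean and SD over iterations (default 200, enough to
stabilise the mean well inside the reported SDs). The split sequence is a
pure function of (seed, n, train fraction, iterations), so model
comparisons reuse identical splits per candidate and rank by mean κ with
mean sensitivity as tie-break.

Degenerate splits are kept, not resampled: a test split without positives
records NaN sensitivity (counted and reported); a training split without
positives — possible in principle with few positives — is scored with the
constant classifier, the only one consistent with such training data.
Tuning modes: `fixed` (C, γ supplied), `tune_once_full_data` (one grid
search on the full sample before the loop; mirrors protocols that report
a single optimum per model, at the cost of tuning having seen future test
episodes — the report records the mode used) and `tune_per_split`
(leakage-free, slower).

`group_compare` fits each temporal variable on the class indicator by
OLS; the standardized slope of the unadjusted model equals the
point-biserial correlation and the t statistic equals the pooled
two-sample t with df = n − 2. Published headline comparisons of this kind
report df implying additional unnamed covariates; we implement the simple
model and expose a covariate hook rather than guess a hierarchy, so
printed t/β values of the original analyses are not reproduction targets.

## Synthetic generator

Per class and phase, durations are drawn from normal distributions
truncated to the published min/max, with the published mean/SD as the
parent-normal parameters — the simplest family consistent with all four
printed summaries (the published medians serve as a soft plausibility
check only). Truncation shifts the realised moments slightly away from
the parent parameters; tests therefore compare sample means against the
*truncated*-normal closed forms (within 3 SE at n = 10⁵), and the
generated yawn mean total duration (~5.0 s) sits near, not exactly at,
the sum of the parent means. Sampling uses exact inverse-CDF truncated
normals; parameter sets whose bounds leave < 1e-6 probability mass are
rejected as errors.

Phases are independent within an episode — no within-episode correlations
are published, and we flag rather than assume them. Durations are
quantized to the 24-fps frame grid by default (nearest frame, minimum one
frame per nonzero phase), mirroring the measurement process; fps = 0
keeps continuous durations for analytic tests. Episodes start at onset 0
by default; an optional `gap` lays them sequentially on a shared timeline
for event-matching fixtures. A jittered "second coder" copy perturbs each
boundary with independent normal noise, resampling ordering violations.

What passing tests on generated data do and do not show: the generator
reproduces class-conditional *marginal* phase-duration structure, class
imbalance and frame quantization, but not subject-level clustering (17
neonates; no per-subject parameters are published), within-episode
correlations, or coder biases. End-to-end SVM results on generated data
therefore validate the pipeline's mechanics and the qualitative
separability of the classes (mean hold-out κ well above 0.5; in practice
≈ 0.87–0.99 depending on seed), not the exact accuracy printed for the
real dataset. One structural property does transfer exactly: the timing
rule's sensitivity is 1.0 on generated yawns because the yawn bounds
force opening + plateau ≥ 2.16 s > 2.01 s ≥ closing.

## Problem sizes and determinism

Defaults: 130-episode samples (15/115), 200 hold-out iterations, 7×7
grids with 10-fold CV, 10⁵ draws for moment checks — the full suite and
the acceptance script each run in seconds on one CPU. Every stochastic
component takes an explicit seed (numpy `default_rng`); identical seeds
give bit-identical datasets, split sequences, grid-search surfaces and
reports.

## Known limitations

- The SVM hyperparameter optima and hold-out statistics printed for the
  original coded dataset can only be reproduced from that dataset; on
  synthetic data they are sanity-checked, not matched.
- Event-level κ conventions for unsegmented streams vary; the package
  offers matching-percent (primary) and frame-binned κ rather than
  claiming any one published convention.
- No probability calibration, alternative kernels, multi-rater κ,
  weighted κ, nested CV or bootstrap intervals.
- EAF support is read-only and limited to two alignable interval tiers
  paired by containment.
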