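# Methods

`sprbench` implements the evaluation machinery of a surgeons-versus-AI
benchmark for surgical phase recognition (SPR) in robot-assisted partial
nephrectomy (RAPN): how survey questions are drawn from annotated procedure
videos, how answers are scored, and how the two question modalities (single
frames vs 10-second video snippets) are compared statistically. Because the
underlying video corpus is private, the package ships generators that emulate
the study's procedures, respondents and frame-level predictors; every
quantity below is computed, never hard-coded.

## Timeline model

A procedure is an ordered list of labelled segments on a 0-based seconds
axis, half-open `[start, end)`. Two schemas are built in: 15 RAPN phases and
7 laparoscopic-cholecystectomy (Cholec80-style) phases, each with a published
per-phase duration table (mean ± sd, minutes). Gaps between segments are
legal and represent discarded footage (out-of-body sequences, ambiguous
transitions); the sampler never draws from a gap. RAPN workflows are highly
nonlinear, so a phase may recur as several segments; its duration is the sum
over segments, and phase-relative time is accumulated across recurrences by
walking the segments in order. Per-frame annotation files (one label per
frame at a declared FPS) are converted to segments by maximal-run grouping,
so segment durations always sum to `n_frames / fps` exactly.

## Survey sampler

For one procedure the sampler emits `n_samples = 17` timestamps, each
yielding a frame item and a snippet item:

* **Allocation.** Every phase present gets one sample. The
  `n_samples − n_phases` extras (2 for RAPN) go one each to the phases longer
  than 10 minutes, in descending duration order with schema-order
  tie-breaks, wrapping to the longest remaining phases if there are not
  enough long ones. With all phases at their mean durations the two extras
  land on kidney mobilisation (23.8 min) and tumour identification
  (16.9 min).
* **Within-phase draw.** In phase-relative time the timestamp is
  `Normal(0.5·D, 0.1·D)` for phase duration `D`, truncated by rejection (not
  clipping, which would pile mass at the edges and distort the sd) to the
  central `[0.05·D, 0.95·D]` band, keeping draws away from phase
  transitions.
* **Snippet admissibility.** Each snippet is the 10 s preceding its
  timestamp. By default the window must stay inside the timestamp's own
  segment (`allow_crossing=False`); if that starves a short phase, the
  constraint relaxes to "inside annotated footage" before erroring. Windows
  never span gaps.
* **Spacing.** All timestamps of a procedure must be ≥ 30 s apart. Draws are
  accepted jointly: violating pairs are detected on the sorted sequence and
  *both* members of each pair are redrawn, up to `max_retries` rounds.
  Redrawing only one side can deadlock when the other sits at the extreme of
  its truncated band in a short phase. If rounds are exhausted, the most
  crowded phase is fully resampled once; failure after that raises a
  `SamplingError` naming the procedure.

All draws flow through a caller-supplied `numpy` `Generator`, so item lists
are bit-reproducible from a seed.

## Metrics

Let `C` be the k×k confusion matrix (rows = true phase, columns = answer).

* **Accuracy** = trace(C) / total.
* **Weighted F1** = Σ_c (support_c / total) · F1_c, with F1_c the harmonic
  mean of precision and recall and defined as 0 when precision + recall = 0.
* **L½ spread.** For a row normalized to probabilities `p`, the row
  statistic is `(Σ_i √p_i)²`, which is 1 for a one-hot row and k for a
  uniform row and is Schur-concave (any mass transfer from a larger to a
  smaller entry increases it). Rows with positive support are averaged and
  the mean is rescaled to `[0, 1]` via `(mean − 1)/(k − 1)`. Zero-support
  rows are excluded from the average (imputing one-hot or uniform would bias
  the spread in opposite directions) and logged.

Scoring of a survey supports two modes. The default scores each
participant's own 17-answer matrix and averages metrics within
(group, modality). Note that a 17-answer matrix over 15 phases has roughly
one answer per row, so the per-participant L½ spread is nearly 0 for
everyone regardless of skill; the `pooled` mode, which pools a group's
answers into one matrix first, is the mode whose spread values are
informative (and the one that reproduces the magnitude of published group
spreads). Accuracy and weighted F1 are unaffected by this distinction in
expectation.

## Statistical comparison

Frames vs snippets are compared per group by a two-sided Wilcoxon
signed-rank test on per-participant accuracy pairs: zero differences are
discarded (classical rule), |differences| ranked with average ranks, the
statistic is `min(W+, W−)`. The null distribution is exact (full
enumeration-equivalent) when the effective n ≤ 25 with no ties, else a
normal approximation with tie and continuity correction; p-values come from
`scipy.stats.wilcoxon` and are verified in the test suite against an
independent brute-force sign-enumeration oracle. The per-group p-values are
held to a Bonferroni threshold `α/m` with strict inequality, `m` taken from
the data (number of groups present), never hard-coded. Spearman rank
correlation (tie-aware, t-approximation p) is exposed for
accuracy-vs-confidence and accuracy-vs-difficulty analyses.

## Generators

* **Timelines.** One segment per phase in canonical schema order
  (recurrence statistics are unpublished, so none are invented). Durations
  are drawn per phase from a family moment-matched to the published mean ±
  sd: `lognormal` (default), `truncated-normal` (N(mean, sd) with
  non-positive draws rejected; if the expected rejection fraction exceeds
  50% it falls back to lognormal with a warning), or `degenerate` (means
  exactly). Lognormal is the default because several phases have sd > mean
  (hilar clamping 2.0 ± 4.7 min), which a positive normal cannot represent
  without severe truncation bias. A floor of `min_phase_s = 30 s` is applied
  by clipping: real annotated phases are never a few seconds long, and a
  sub-30-s phase cannot host a spaced survey timestamp at all. Clipping
  shifts the shortest phase's mean by ≈ 5% (well inside the 3-SE
  moment-recovery band); rejection-truncation at the floor would inflate it
  by ~50% and was therefore not used. The RAPN phase means sum to 147.9 min
  while the study reports a 122.3-min mean procedure length (phase absence
  or annotation overlap in the source data, unstated); the generator does
  not rescale to reconcile the two.
* **Respondents.** Three expertise groups with defaults matching the
  published group results: frame accuracy 0.303 / 0.415 / 0.412 and snippet
  boost 0.133 / 0.114 / 0.120 for medical students / surgical trainees /
  consultants. An answer is correct with probability
  `p_correct_frame (+ snippet_boost)`; errors fall on other phases with
  weight `adjacency_spread^(distance−1)` in schema order — 0 confines errors
  to the two adjacent phases, 1 spreads them uniformly — standing in for
  temporal-adjacency confusion, for which no kernel is published.
  Confidence 1–5 comes from a Gaussian latent cut at fixed thresholds with
  configurable correlation to correctness (default 0.3; setting 0 reproduces
  a no-correlation finding); response times are lognormal (median 12 s,
  σ=0.6 — roughly a 30-minute survey of 34 questions). Respondents are
  exchangeable within group: no participant random effects, fatigue or
  anchoring are modelled, so passing tests show pipeline correctness, not
  cognitive realism.
* **Surveys.** Each participant is assigned a distinct procedure (assignment
  without replacement; more participants than procedures is an error) and
  answers its 17 frame items, then its 17 snippet items — 34 responses.
* **Predictors.** Per-second emitters over annotated footage with a
  per-phase correct probability (errors uniform over the other labels) and a
  trailing majority vote over `smoothing_window_s` seconds (1 = off; vote
  ties go to the earliest schema label), a desk-scale stand-in for
  frame-only vs temporally-smoothed recognition models.

## Calibration and power under the default conditions

With no snippet effect, the pipeline's per-group rejection rate over 200
simulated 90-participant surveys stays at the Bonferroni level α/m (checked
within 2 binomial SEs). Detection power, however, is modest at the study's
scale: a participant's accuracy over 17 questions has binomial sd ≈ 0.16 at
baseline accuracies near 0.3–0.4, so a +0.10 snippet boost yields a paired z
of ≈ 3.2 at n = 30 per group — per-group power ≈ 0.75 at the α/3 threshold
and all-three-groups power ≈ 0.4. The corresponding power check in the
acceptance suite documents this honestly rather than relaxing the
conditions; detecting a 0.10 boost reliably in all groups simultaneously
would need either more participants/questions or baseline accuracies far
from one half.

## Problem sizes and numerics

Simulation-backed tests use 10,000 draws for distribution recovery, 1,000
procedures for moment recovery, and 200 surveys per arm for
calibration/power; the whole suite runs in a couple of minutes on one CPU.
Probability-vector validation tolerates 1e-9 in the simplex sum; metric
identities are asserted to float precision. All randomness flows through
explicit `numpy.random.Generator` objects seeded at entry points, and every
pipeline artifact (items, responses, reports, comparison JSON, manifest) is
byte-stable under a fixed (config, seed).

## Known limitations

* Phase recurrence is supported by the model but not generated by default;
  μ/σ of the within-phase draw treat recurrences as concatenated.
* The respondent model is behavioural shorthand — fixed per-group
  accuracies, no item difficulty, no participant heterogeneity. Real paired
  scores would show extra between-participant variance in levels (which
  cancels in the paired difference) and item effects (which do not).
* No visual-quality filtering of sampled frames (blur, bleeding, fog) is
  modelled; no computable criterion exists for it.
* The exact per-long-phase oversampling arithmetic beyond "one extra each,
  then wrap" is a design choice; only the totals are published.
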