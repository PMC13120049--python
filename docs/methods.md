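# Methods

## Degradation operators

**Clipping.** `clip_signal(x, τ)` implements y = sign(x)·min(|x|, τ)
pointwise (computed as a single-pass clamp to [−τ, τ], which is identical for
real inputs).  Clipping is applied to *z-score-normalized* signals, so τ is in
z-units and the sweep τ ∈ {10⁻⁶ … 10⁻¹} spans "sign structure only" to
"essentially clean".  The operator's algebra — idempotence, identity for
τ ≥ max|x|, sign preservation, 1-Lipschitz contraction (which implies the
waveform-length inequality), RMS contraction, RMS monotone in τ — is enforced
by property tests rather than assumed.

By default the degradation transforms every partition of a split (train,
validation, and test see the same clipped world); a `test-only` scope is
available for the asymmetric scenario where only deployment data is degraded.

**Saturation model.** For x ~ N(0, σ²), P_sat = Pr(|x| > τ) = 2Q(τ/σ).  Tests
compare the closed form (derived independently through the Gaussian CDF/erf)
with the empirical clipped fraction of 10⁵ standard-normal draws, inside a
3-standard-error binomial envelope.

**Dropout.** Electrode disconnection is flat-lined zeros (`zero-signal`,
default) applied before normalization/feature extraction; a zero channel then
has σ = 0 and the δ-stabilized z-score maps it to exactly zero features.  The
alternative `drop-columns` mode removes the channel's feature columns after
extraction.  Intermittent/bursty loss is exposed only as an explicit
`NotImplementedError` placeholder.  Note that spectral features (MNF/MDF) are
undefined on a flat-lined channel — such conditions fail loudly and are
recorded by the sweep driver rather than silently imputed.

## Pipeline and its fixed order

Filtering always precedes segmentation; normalization statistics are fitted
on the training partition of each split only, then applied to
validation/test; clipping follows normalization; features follow clipping.
The API encodes this order (windowing consumes filtered `Recording`s;
`evaluate_split` owns the normalize→degrade→extract sequence), and a leakage
canary test verifies that permuting test labels leaves normalization
statistics and tuned hyperparameters bit-identical.

Filter choices (the filter families are standard; the parameters are this
package's): zero-phase (forward–backward) application to avoid group delay
misaligning labels; Butterworth band-pass 20–450 Hz of order 4; notch cascade
at the mains frequency and its first 3 harmonics with Q = 30.  Window length
and hop are rounded from milliseconds (250 ms → 481 samples, 50 ms → 96
samples at fs = 1925.9259 Hz).  Windows that span a label change are dropped
(`uniform-only` rule; `majority` and `center` rules are available).  Window
counts per contiguous segment follow floor((T − L)/H) + 1.

Normalization is per channel (channel gain differences are exactly what
z-scoring is meant to remove), with δ = 10⁻⁸; σ is computed via
E[x²] − μ² with a cancellation guard that treats relative variance below
10⁻¹⁰ as a constant channel.

## Features

RMS, variance (unbiased, N−1), zero crossings (count of −x_i·x_{i+1} > ε),
and waveform length are the lightweight core.  ε defaults to 0: any positive
ε would annihilate the ZC count under deep clipping, where adjacent-sample
products shrink to ±τ² ≈ 10⁻¹² at τ = 10⁻⁶; with ε = 0 the count is exactly
clipping-invariant whenever no sample is exactly zero.

Auxiliary features: AR coefficients by Yule–Walker (biased/MLE
autocovariance, order 4 — a common sEMG convention; constant windows return
zeros rather than failing), sample entropy SampEn(m = 2, r = 0.2·SD) with
templates of both lengths drawn from the first N−m positions and a +∞
sentinel (capped, with a warning, at a configurable value during assembly)
when no templates match, and mean/median frequency from a mean-detrended
single-window periodogram (Welch is available; 481-sample windows leave
little room for segment averaging).  The median frequency uses the discrete
convention — smallest grid frequency whose cumulative power reaches half the
total — with no interpolation.  MNF ≥ MDF is *not* an invariant and is not
asserted; both lie in [0, fs/2].

Feature matrices are assembled feature-major (each feature's channels 1..C in
order, AR expanding to one column per coefficient), so pairwise fusion is
exactly column-wise concatenation of the two single-feature blocks.

## Evaluation protocol

Per subject: repeated stratified 70/15/15 train/validation/test splits
(10 by default), integer per-class allocation so balanced designs split
exactly (e.g. 4 × 100 windows → 280/60/60).  Grid search is scored on the
validation set; ties break toward the earlier grid point; the selected model
is the one fitted on the training partition only (validation data is never
folded back into the fit).  Default grids: SVM-RBF C ∈ {1, 10, 100},
γ ∈ {0.01, 0.1, 1}; RF trees ∈ {100, 300}, depth ∈ {∞, 20}; LDA shrinkage
∈ {none, auto}.

Intra-session accuracy for a subject is the mean over sessions of
within-session repeated-split accuracy.  Inter-session evaluation is
leave-one-session-out: train+validation are stratified-split from the
held-in sessions, the held-out session is the test set, averaged over folds.
The pooled protocol treats a subject's sessions as one window population.

Aggregation is strictly two-stage — repeats (and sessions/folds) are averaged
within a subject before subject means are averaged — and the summary reports
the subject-wise min–max range rather than pooled variance.  Chance level is
1/n_classes (the generator produces balanced designs).

Seeding is hierarchical from one experiment seed: split plans depend only on
(seed, subject, session/fold) and classifier seeds only on (seed, subject,
repeat), never on the degradation, feature set, or classifier kind — so any
two conditions differing only in the degradation consume identical split
plans and paired comparisons are valid, and any single row of a result table
is independently reproducible.

## Synthetic cohort generator

What it emulates: gesture- and channel-dependent activation amplitude
(uniform 0.2–1.5 z-units per (gesture, channel), drawn once per subject, with
the rest gesture pinned near the noise floor at 0.05), band-limited Gaussian
carriers (white noise band-passed to 20–450 Hz and standardized to unit RMS
per hold, so hold RMS equals gain × activation by construction),
a white noise floor (RMS 0.05), optional mains sinusoid (off by default),
and session effects: per-(session, channel) log-normal gain with log-SD 0.1
and adjacent-channel leakage with a per-session coefficient drawn uniformly
from [0, 0.05].  Each session holds each of the 13 gestures once, for 10 s,
in seeded random order, with rest represented as the low-amplitude rest
gesture rather than unlabeled gaps.  Everything is deterministic
(byte-for-byte) in the cohort seed, with subject and session indices folded
into per-stream seeds.

What it does *not* emulate: motor-unit action potentials and recruitment
dynamics, electrode geometry, fatigue, motion artifacts, label noise, or
class imbalance.  Consequently the clean problem is easier than real sEMG
(clean accuracies sit near 1.0 and inter-session drops are a few points, not
tens of points), and passing cohort-level tests demonstrates the *direction
and mechanics* of degradation effects — monotone recovery with τ, dropout
cost bounded away from chance, inter ≤ intra — not absolute accuracy levels
on real recordings.

Default sizes follow the emulated protocol (9 subjects × 3 sessions × 13
gestures × 10 s holds, 5 channels at 1925.9259 Hz).  One stated ambiguity in
the protocol description (13 s holds mentioned alongside 10 s prompts) is
resolved by defaulting to 10 s with the duration configurable.

## Problem sizes in tests and the acceptance script

Cohort-level checks run 3-subject cohorts at the full channel/gesture/rate
configuration; the clip-sweep and session-ordering properties average over
five cohort seeds (0–4).  They use single-point RF settings (100 trees,
depth 20 — values taken from the default grid) and 1–2 split repeats rather
than the full 10-repeat grid search: the checked properties are directions
and orderings whose sampling error at ≥ 15 accuracy values per condition is
well below the 0.02 tolerance used.  The acceptance script mirrors this
sizing with two cohort seeds derived from `--seed`.  Window storage uses
float32 in these large runs (~10⁻⁷ relative rounding; tree-based learners
quantize to float32 internally regardless).

## Known limitations

- The generator's separability is set by the activation-matrix draw; a
  pathological seed could produce two nearly coincident gesture rows.
  Duplicate rows are redrawn, near-duplicates are not.
- `drop-columns` dropout changes the feature dimensionality, so models tuned
  on clean data cannot be reused across that condition (by design — the
  comparison retrains per condition).
- Result-table resume matches on condition keys only; it assumes the cohort
  and seeds are unchanged between runs.
- Statistical significance testing between conditions is out of scope; the
  tables expose per-subject means so external tooling can test differences.
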