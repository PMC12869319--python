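# Methods

This note documents the models, estimators and numerical choices behind
`neurotopo`, and what its synthetic-data generators do and do not emulate.

## Task schedules

The schedule builders are deterministic functions of a seed and encode the
study design: 80 Pavlovian conditioning trials with five cues mapped
one-to-one onto {−2, −1, 0, +1, +2} CHF; a 30-trial forced-choice learning
check (10 unordered cue pairings × 3); an in-lab Go/NoGo task of 4 blocks
× 200 trials (120 Go + 80 NoGo, 60% Go); and the gamified training
staircase whose reaction-time threshold (RTT) runs from 1.1 s (level 1)
down to 0.33 s (level 18), advancing one level after 6 consecutive
successes.

Choices made where the design leaves room:

* Cue identities are balanced across the 80 trials (16 each). A balanced
  design maximizes the precision of the bias slope; the alternative
  (independent draws per trial) would only add estimator variance.
* A failed training trial resets the 6-success counter. This is the
  conservative reading of "after 6 successful trials"; the alternative
  (count non-consecutive successes) would make the staircase advance on
  average faster but never differ by more than a few trials.
* The staircase caps at level 18 (end of the difficulty table); the
  even-length block median is the midpoint of the central pair.
* The cue's screen side is an independent fair coin per trial.

## Sign-tracking bias

The gaze index of a trial is `p(CS) − p(US)` computed over the third
second of cue presentation, with valid-sample time as denominator.
Trials with under 50% valid samples are flagged invalid and dropped (the
design gives no missing-data rule; 50% is a common eye-tracking
convention). Areas of interest are configurable rectangles at the two
stimulus positions; everything else is background.

The bias β₁ is estimated by least squares through the origin, exactly as
the defining regression is written (no intercept term); an intercept is
available as an option since part of the literature includes one. The
standard error uses the residual variance with n − 1 degrees of freedom
(one fitted parameter), so (β̂₁ − β₁)/SE is exactly t-distributed under
Gaussian noise — the test suite verifies the implementation against an
independent OLS fit to 1e-10.

Exclusion rules: forced-choice error rate strictly above 10% (3 errors in
30 is kept, 4 excluded); bias outliers outside median ± 3·MAD, with MAD
the raw median absolute deviation (no 1.4826 consistency factor — the
rule is stated as plain "3·MAD"). A zero MAD keeps everything and warns.

## ERP pipeline

The pipeline ingests cleaned epoched data; band-pass filtering,
line-noise removal, artifact-subspace reconstruction, blink removal and
bad-channel interpolation are upstream concerns, and the interpolated-
electrode count enters the quality report as metadata only. Stages, in
order: epoch selection (correct rejections; items liked ≥ 60, boundary
inclusive; optionally trained-NoGo items only) → baseline correction
(subtract the pre-onset mean per epoch/electrode from the whole epoch) →
jump rejection (any sample-to-sample step > 30 µV) → amplitude rejection
(any |v| > 80 µV) → averaging → common-average referencing.

Numerical conventions: both rejection rules are strict inequalities, so
boundary epochs (exactly 30/80 µV) survive; the amplitude bound is
symmetric in sign — "voltage larger than 80 µV" is read as magnitude,
the standard reading for artifact thresholds. The epoch window is
half-open [−100, +700) ms; at 1024 Hz that is 102 pre-onset + 717
post-onset samples with onset at index 102. Baseline correction is
idempotent and commutes with averaging (both linear); the two rejection
rules commute as set operations. GFP of a map v is
`sqrt(mean((v − mean(v))²))` and is invariant to reference shifts to
machine precision.

## Topographic permutation statistics

The covariance map at a timeframe is `c = (1/N) Σ_s z(x_s)(v_s − v̄)`,
with the covariate z-scored (sample sd) and maps subject-centered;
statistic = GFP(c). Permutation engine conventions:

* Null for a between-subject covariate: shuffle covariate values across
  subjects, ERP data fixed. Null for the within-subject Session factor:
  independent random sign-flips of each subject's difference map
  (session labels are exchangeable within subject). The covariate ×
  Session interaction runs the covariate TANCOVA on the difference maps.
* p-values use the add-one convention `(1 + #{perm ≥ obs})/(n_perm + 1)`
  with ties counted as exceedances (conservative). In exhaustive mode all
  n! orderings (or 2^S flip patterns) are enumerated exactly once,
  including the identity, and p is the plain exceedance fraction; the
  identity row is evaluated through the same vectorized path as the rest
  so that its tie with the observed statistic is exact in floating point.
  The suite checks exhaustive p-values against an independent loop-wise
  enumeration for n = 5 (120 shuffles) and 6 subjects (64 flip patterns).
* Single-subject maps are not GFP-normalized before entering the
  covariance (exposed nowhere as a default because the GFP statistic is
  deliberately amplitude-sensitive).
* One seeded generator per test invocation; the permutation matrix is
  retained on the result for audit. Identical seed + inputs give
  identical results bitwise.

**Duration-based multiple-comparison control.** Each permutation's
statistic series is converted to pseudo-p values against the ensemble
(rank-based, ties as exceedances); the duration threshold is the smallest
run length L such that at most 5% of permutations contain a run of ≥ L
consecutive pseudo-p < .05 timeframes. This controls the family-wise
error over time: on 200 null synthetic datasets the measured rate is
2–3%. Two edge conventions: because permutation p-values are discrete and
super-uniform, a perfectly autocorrelated null can already be controlled
at L = 1 (the per-timeframe rejection mass falls below the global level);
when no L up to the series length satisfies the bound, the threshold caps
at the series length. The fixed fallback of 12 timeframes (~12 ms at
1024 Hz) is available as `duration="fixed"`.

## Behavior

A Hit is a Go response within the block deadline (adaptive: 1.10 × median
of the block's response RTs); a Miss is any Go trial without a Hit — no
response or a too-late one. The "too late" feedback category of the live
task is folded into Miss because the participation check states a single
miss-rate rule; this is the conservative merge. Commission error rate =
false alarms / NoGo trials. Participation exclusions: false-alarm rate
> 70% or miss rate > 20%. Training deltas are post − pre (the direction is
recorded in the output, since "subtracted to" is ambiguous in prose).

Pearson tests delegate to scipy with t-based p-values (df = n − 2);
one-sided alternatives follow the directional predictions, and the
distribution-outlier rule (3·MAD on the index) is applied before testing.
No multiplicity correction across the two indices — they measure distinct
mechanisms and are interpreted independently.

**Bayes factors.** BF₀₁ for a correlation uses the
Jeffreys–Zellner–Siow setup: a stretched symmetric beta prior on ρ over
(−1, 1), density ∝ (1 − ρ²)^{1/κ − 1}, with κ = 1/3 by default (the
correlation default of the standard Bayes-factor software; κ = 1 is the
uniform prior). BF₁₀ is the prior-averaged ratio of the exact
bivariate-normal sampling density of r, integrated by adaptive quadrature;
the suite cross-checks a fine-grid Simpson evaluation to 1e-3 relative.
At r = 0, n = 47 the implementation gives BF₀₁ = 3.05.

**Power.** `required_n_correlation` scans n upward until the power of the
correlation test reaches the target. Two evaluations are offered: the
noncentral-t approximation with noncentrality ρ√n/√(1−ρ²) (the evaluation
behind the common power software; default), and the exact sampling
distribution of r (Gauss hypergeometric form, integrated beyond the
critical value). For ρ = 0.4, α = .05 one-sided, 90% power the default
gives n = 47 with the exact method somewhat larger (n = 50, since the
exact power at 47 is 0.885) — the default matches the registered design;
the exact method is verified in the suite against a 200k-replicate
Monte-Carlo simulation of bivariate-normal samples.

## Synthetic data

The generators define the study conditions under which the pipeline is
tested; all are bitwise-reproducible under a seed.

* **ERP sets**: subject maps = smooth shared background (zero-mean random
  topographies with Gaussian time courses) + boxcar covariate effect
  (`coupling_strength` µV per covariate SD times a unit-GFP zero-mean
  topography inside the effect window) + optional Session effect for the
  post session + noise. Noise is a rank-8 mixture of random zero-mean
  topographies driven by AR(1) sources (lag-one 0.5, marginal sd 1 µV) —
  this reproduces the spatial and temporal correlation that topographic
  permutation statistics face in practice while staying cheap. Every map
  is average-referenced exactly. Not emulated: volume-conduction geometry
  from a real head model, non-stationary artifacts, electrode drift —
  so passing tests demonstrate statistical calibration and recovery, not
  robustness to uncleaned recordings.
* **Gaze**: index = clip(β₁·value + ε, ±1), ε ~ N(0, noise_sd),
  decomposed into proportions with a 20% background share (shrunk when
  the index leaves no room); only the CS−US difference is identified.
  Fixation dynamics (saccades, drift, calibration error) are not modeled.
* **Go/NoGo behavior**: Go RTs are shifted lognormal (shift 120 ms) —
  right-skewed like empirical RTs — with subject means 300 ± 30 ms;
  NoGo false alarms are Bernoulli with logit-normal subject rates
  centered at 5% (logit sd 0.5). These anchors reproduce the ~5% ± 3
  commission rate and ~300 ± 32 ms RT of the emulated task. Covariate
  coupling enters as a linear term on the subject mean RT and on the
  false-alarm logit.
* **Liking**: pre ratings ~ N(69, 14) on the 0–100 scale (clipped);
  trained-NoGo items lose a subject-level shift at post, calibrated as
  δ = dz·sqrt(σ_s² + 2σ_e²/m) so the expected paired Cohen's dz on
  subject means equals the requested devaluation.

## Problem sizes used in the checks

The calibration suites run at deliberately moderate scale, chosen as the
smallest sizes at which the binomial tolerances are informative: 200 null
datasets of 20 subjects × 30 electrodes × 100 timeframes with 500
permutations for family-wise error; 500 simulated subjects for bias
recovery; 500 seeds of a 47-subject, 800-trial Go/NoGo sample for the
null behavioral pipeline; exhaustive enumeration at 5–6 subjects.

## Known limitations

* The duration threshold is calibrated per dataset from the same
  permutations used for the p-values; with few permutations (< ~200) the
  threshold is coarse.
* The behavioral split-half uses a fixed odd/even scheme; permutation-
  based split sampling is not implemented.
* The iterative participant-exclusion search that would re-balance
  positive controls after exclusions is out of scope; the controls are
  report-only.
* Reading continuous raw EEG (BDF/EDF) is delegated to mne via the
  `EpochSet.from_mne` adapter rather than re-implemented.
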