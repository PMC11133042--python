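# Methods

## The protocol being modelled

The engine reproduces, headlessly, a two-hour mental-fatigue induction
battery: a pre-battery BRUMS mood questionnaire, twelve 10-minute task
blocks (AX-CPT, 3-back, visual search, mental rotation; each task three
times; AX-CPT first and last; no task twice in a row), and a post-battery
BRUMS. Mental fatigue is operationalized two ways at once: a subjective
rise on the BRUMS fatigue subscale, and an objective performance decrement
on the critical task (AX-CPT, first vs last block).

## Trial generation

All four generators are *constrained* pseudorandomizers: the randomness is
in the ordering and in stimulus identity, never in the composition quotas.

* **AX-CPT.** Each trial is cue → distractor → distractor → probe. Each
  non-overlapping decade of ten trials holds exactly {AX×7, BX×1, AY×1,
  BY×1}, shuffled. Cues and probes exclude K and Y; "B"/"Y" role letters
  and distractors are drawn uniformly from the 22 letters excluding
  A, K, X, Y. A trailing partial decade is the prefix of a full shuffled
  decade (simplest rule that preserves approximate proportions).
* **3-back.** Three targets per decade; the first three positions of a
  sequence can never be targets (no lag-3 predecessor), so the first
  decade's targets live in positions 3–9. Non-target letters are resampled
  until they differ from the letter three back, which makes the stored
  labels exactly recomputable from the letters — a property the test suite
  checks with an independent scan. Incidental lag-1/lag-2 repeats (lures)
  are deliberately left uncontrolled; only the 3-back rule is specified.
* **Visual search.** Five target-present and five target-absent displays
  per decade; eleven glyphs on distinct cells of an invisible 4×4 grid,
  rotations uniform on {0°, 90°, 180°, 270°}; exactly one T when a target
  is present, an eleventh L otherwise. Geometry is metadata only.
* **Mental rotation.** The catalogue is synthesized as 12 base cube objects
  × 4 angular disparities (0°, 50°, 100°, 150°) × {matching, pseudo-mirror}
  = 96 entries named `<object>_<angle>` / `<object>_<angle>_R`. The image
  bitmaps belong to an external validated set and are referenced by id
  only. Trials are epoch-wise permutations of the catalogue: no repeat
  before full coverage.

Trial wall-times: every trial ends with 1000 ms feedback + 1200 ms
inter-trial interval. The AX-CPT prepends 3 × (300 + 1200) ms for cue and
distractors; its response window is taken as 1200 ms from probe onset (the
source protocol is ambiguous about whether responses during the 300 ms
probe display counted; we measure RT from probe onset and accept 0–1200 ms).
The 3-back letter stays up its full 2000 ms regardless of the response, so
its trials are always 4200 ms. Visual search has no deadline. Mental
rotation allows up to 7500 ms; at the ~3000 ms mean RT typical for this
stimulus set a trial lasts 5.2 s, so a 10-minute block fits at least 115
trials — enough to cover all 96 stimuli at least once.

## Scheduling and seeds

A battery is specified by one integer seed. Per-block generator seeds are
spawned deterministically from it (`numpy` SeedSequence with the block index
as spawn key), so a schedule file fully determines every trial list. The
fixed block order (AX, NB, VS, MR, NB, AX, VS, MR, NB, VS, MR, AX) satisfies
every stated ordering constraint and is identical for all participants; the
concrete order used originally is not public, and a fixed shared order keeps
any order effect constant across a cohort. Blocks are time budgets, not
trial counts: consumers issue trials until the next trial would overrun the
600 s budget, so realized trial counts depend on response times.

## The simulated participant

The response model is intentionally minimal and standard; the protocol
itself implies no generative model.

* **Accuracy**: P(correct) = logistic(logit(baseline) − a·h), with h hours
  on task and a the accuracy drift (log-odds/hour). Positive a = fatigue.
* **RT**: lognormal, log-RT ~ Normal(μ_task + b·h, σ_task), truncated to
  the task's response window and floored at 150 ms.
* **Omissions**: independent per-trial events at a fixed rate, impossible
  in visual search (unlimited window). Omitted trials have no response, no
  RT, and count as incorrect.
* **Mood**: each BRUMS item has a latent value mean + noise at both
  timepoints with test-retest correlation 0.7; the post latent value adds a
  quarter of its subscale's shift; ratings are the latents rounded and
  clipped to 0–4. The latent formulation matters: shifting the *observed*
  (already clipped) pre ratings and re-clipping would push zero-shift
  subscales upward on average — a rounding artefact that would show up as a
  spurious mood change under the null. With the latent model, a zero shift
  makes pre and post exchangeable by symmetry.
* **Fatigue–vigor coupling**: a participant's fatigue shift and vigor shift
  share a latent "fatigue response" factor (coupling 0.7, opposite signs),
  so cohorts reproduce the negative correlation between fatigue increases
  and vigor decreases that the protocol elicits.

Default parameters (one "study-like" participant): baseline accuracy
0.90/0.80/0.92/0.85 and median RT 450/700/1400/3000 ms for
AX-CPT/3-back/search/rotation (σ = 0.30–0.35 log units); accuracy drift
0.25 log-odds/h; RT drift 0.05 log/h; omission rate 0.02; pre-battery
subscale means (anger 1, confusion 1.5, depression 1, fatigue 4, tension
1.5, vigor 9) and shifts (fatigue +5, vigor −4.5, anger +2.5, confusion +1,
depression and tension 0). These are conventional magnitudes chosen to
match the qualitative published pattern (pre fatigue ≈ 4, post ≈ 9; vigor
CI ≈ [−5.5, −3.5]); the RT distributions are conventions, not estimates —
no distributional information about the original RTs is available.

Cohorts add between-participant heterogeneity: baseline accuracy varies
0.5 SD on the log-odds scale, RT location 0.15 log units, drifts by 0.10
and 0.02 per hour, mood shifts by 1.5 points, pre-battery means by 2
points. A configurable `improver_fraction` (default 0.3 in the study-like
cohort, matching 14 of 45 participants improving) negates and damps both
drifts for that share of participants. `null_cohort()` zeroes both drifts
and all shifts while keeping baseline heterogeneity — the type-I reference.
One cohort shares a single battery deployment (same schedule and trial
sequences); responses and parameters are per-participant.

What the simulator does *not* emulate: learning/practice dynamics beyond
the improver flag, block-level strategy changes, lapses/vigilance waves,
sequential dependencies between trials, item-specific BRUMS semantics, and
any biophysical account of fatigue. Passing tests therefore show that the
*pipeline* behaves correctly under a plausible data-generating process, not
that real humans obey this model.

## Exclusion rules

Applied per participant, pooled over all twelve blocks: omissions on
strictly more than 25% of trials (exactly 25% is retained); every given
response the same single key; either BRUMS form all-0s or all-4s
(interpreted as uniform-extreme responding — the non-engagement signature —
rather than "each item is 0 or 4", which would exclude legitimate extreme
responders); either form completed in under one second per item (24 s).

## Statistics

* **Performance cells**: per participant × timepoint (block 1 = pre,
  block 12 = post), proportion correct over all trials (omissions count as
  errors) and mean RT over correct responded trials only (the BIS source
  convention). A cell with no correct responded trial is an error naming
  the participant.
* **BIS**: z(PC) − z(RT) with sample-SD standardization over all cells of
  all participants and both timepoints jointly. Zero variance in either
  component is a degenerate-input error, reported (not raised) by the
  top-level pipeline.
* **Wilcoxon signed-rank** (post − pre, two-sided): zero differences are
  dropped; z = (W − μ)/σ with the tie-corrected σ and no continuity
  correction by default (available as a flag); the p-value is the exact
  permutation probability (dynamic program over midranks) when ≤25 nonzero
  pairs remain, else 2Φ(−|z|); the effect size is r = |z|/√n with n the
  *pre-drop* pair count (all seven published (z, r) pairs are consistent
  with √45 under this convention); the estimate and 95% CI are the
  Hodges–Lehmann pseudomedian and the Walsh-average interval, indexed by
  the exact signed-rank quantile for ≤25 pairs (verified against R's
  `wilcox.test` during development) and by its normal approximation above.
  All-zero differences yield a "no test" outcome that the report carries
  as such.
* **Spearman correlation** between Δfatigue and Δvigor, average ranks for
  ties, two-sided p; constant inputs are an undefined-correlation outcome.
* **Counts**: participants with increased fatigue and with improved BIS.

## Numerical and reporting choices

RTs and onsets are integer milliseconds end to end (simulation, CSV,
analysis), so written sessions re-read to bit-identical analyses.
Completion times carry 0.1 s resolution for the same reason. The exact-p
threshold of 25 pairs keeps the dynamic program trivial (rank sums ≤ 650)
while covering the n ≤ 10 regime where enumeration oracles are feasible;
cohort-scale tests (n = 45) use the tie-corrected normal approximation, the
regime the published z statistics live in. Report rendering rounds z and r
to 2 decimals.

## Operating characteristics

Measured once by the acceptance tests at 200 simulated cohorts of n = 45
(full 12-block sessions, ~105 s total on one CPU): under `null_cohort()` the
BIS pre/post test rejected in 6.0% of cohorts (nominal 5%, Monte-Carlo
3-SE band ±4.6 points); under `moderate_fatigue_cohort()` a significant
BIS decrement was detected in 100% of cohorts. The moderate drift defaults
were fixed from the design reasoning above before these rates were
measured.

## Known limitations

The BRUMS item wording is licensed and not shipped; the default mapping
uses placeholder labels and any real mapping can be supplied as CSV.
The middle-block order is a documented convention, as are all Wilcoxon
software options (zero handling, tie correction, CI construction) — the
original analysis software settings are not public. The simulator's
parameter values are plausibility choices, not fits to the deposited human
data; reproducing the original inferential statistics exactly would require
that dataset.
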