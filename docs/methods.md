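# Methods

This note documents the models, conventions and parameter choices behind
`dorsalkit`, in the order data flows through the pipeline.

## Task scoring

### Object recognition (L94)

Five subtasks: VISM (visual matching, 10 binary items), NOISE (6 items,
7 noise levels), OVERL (6 items, 4 overlap levels), VIEW (20 items, 3 or 4
view conditions; the items *rifle*, *bench* and *alarm clock* are excluded
by default because typically developing controls name them by category),
DEVOS (43 binary target/control items).

Graded items score (k − j)/(k − 1), where k is the item's number of
conditions and j the **1-based index** of the first condition at which the
object was recognised. This indexing convention is a deliberate choice: a
literal "number of levels presented before recognition" (j = 0 at the first
level) would produce scores above 1. The 1-based reading keeps every item
score in [0, 1], gives 1 at the hardest condition and 0 at the control
(j = k), and is the same anchor the motion-defined-form task states
explicitly (scores 1, 0.5, 0 for conditions 1, 2, 3 of 3).

An item failed in its control condition is *inconclusive* and excluded from
the subtask mean: failure there may reflect naming or language rather than
perception, so it carries no perceptual information. A subtask score is the
mean of conclusive item scores; with no conclusive items the subtask is not
evaluable. A patient enters the analysis with ≥ 3 of 5 evaluable subtasks.
Binary items administered but never answered (e.g. timeouts) are scored 0,
not skipped — the alternative was unstated, and scoring 0 is conservative.

### Motion thresholds (staircase engine)

Global motion (coherence, start 1.0, bounded (0, 1]) and motion speed
(deg/s speed difference, start 17.0) use a transformed up/down staircase:
**two consecutive correct responses → one step harder; each error → one
step easier**. The name "2-up-1-down" is ambiguous in the literature; this
reading is the transformed rule whose equilibrium satisfies
P(correct)² = 1/2, i.e. convergence at the 70.7%-correct level, and it is
the convention configurable to its opposite via
`n_correct_to_harder`/`n_incorrect_to_easier`.

Steps are multiplicative: harder multiplies the level by (1 − s), easier
divides by it, with s = 0.33, and for motion speed s = 0.25 from the fifth
reversal onwards ("from the fifth reversal" is read as: every step taken
once 5 reversals have been logged uses the late factor, so the finer step
first affects the trial following the fifth reversal). Multiplicative
geometry is chosen because both level scales span large dynamic ranges and
coherence is bounded; an additive mode exists. Consecutive-correct counters
reset after every step (and after every error); this is one of two defensible
conventions and is fixed and documented rather than silently assumed.

A *reversal* is a step whose direction differs from the previous step's;
the recorded reversal level is the level at which the direction-changing
response occurred. The run terminates at the 8th reversal and the threshold
is the arithmetic mean of the last 4 reversal levels. Traces are pure
functions of (config, response sequence), so recorded runs replay
bit-exactly; the pipeline re-derives every trace from the recorded
responses and rejects files whose recorded levels disagree.

Motion-defined form is not adaptive: items score 1 / 0.5 / 0 by the
condition of first recognition, "never recognised in the final condition"
is inconclusive and excluded, and the task score is the mean (a proportion
correct).

### Visual search

Median reaction times per condition (4, 9, 19 distracters; 10 trials each),
false-alarm trials excluded from all medians. The two bracketing simple
reaction-time blocks (5 trials each) are pooled into one median motor time
(pooling rather than averaging the two block medians is a robustness choice
and configurable in principle; only the pooled median is implemented).
Search time per condition = condition median − motor median. Negative
search times are retained, not clamped: clamping would bias group medians.
Errors = false-alarm count over the three search conditions. A condition
with every trial excluded yields a *missing* measure, never zero.

## Developmental age and norm entry

DA_IQ = median of the non-verbal subtest age-equivalents (even counts:
mean of the central pair — the source is silent; this is the standard
median). DA_dorsal = (DA_IQ / CA_IQ) · CA_dorsal projects it to the
assessment date. The norm-table entry age is DA_dorsal, except that CA is
used when PIQ ≥ 100 **or** DA_dorsal > CA_dorsal. The trigger is stated
ambiguously in the source (both conditions in apposition); applying the cap
when either holds is the reading adopted, and it guarantees the entry age
never exceeds a reference group older than the child. Ages are carried in
months; year-month notation ("4y3m" = 51) round-trips exactly, and
fractional months are rounded half-up only at report time.

## Normative classification

Norm tables are data, not code. The packaged tables cover the motion and
search measures with three age bands (4y3m–4y7m, 4y9m–5y8m, 5y10m–7y4m) at
the 10th percentile. Object-recognition and visuomotor norms are
proprietary test material: users supply them, or the synthetic-cohort
module derives empirical percentiles from a simulated reference population.
The fixture cohort ships clearly-synthetic placeholder cutoffs for these.

Lookup: the band containing the entry age, else the nearest band (distance
to the band interval; ties go to the younger band). Flagging is strict —
"below the 10th percentile" means a score exactly at the cutoff is not
flagged; the same strictness applies to the error-count cutoff, where the
authors' intent at a tie is unknowable from the printed table.

Roll-up: object-recognition scores use the 5th-percentile criterion
(*abnormal*, z < −1.645), the other functions the 10th (*weak*,
z < −1.282). A function is weak iff ≥ 1 of its tasks is flagged; a general
dorsal-stream dysfunction is ≥ 2 weak functions of 3. Function-level
analyses include only patients with ≥ 1 completed task per function;
missing tasks exclude a patient from exactly the analyses that need them.

## Base rates

The reference population is modelled as jointly standard-normal task scores
with a supplied correlation matrix; percentile cutoffs become z-thresholds
(−1.645, −1.282). The engine draws simulants in blocks (200k rows), counts
scores below threshold per simulant — or weak functions per simulant under
a grouping — and reports the criterion proportion with its binomial SE.
All criterion counts evaluated from one query share one set of draws, so
monotonicity in the criterion count holds exactly per seed. Default
n_sims = 10⁶ (SE ≤ 0.0005 near p = 0.2).

The true reference correlations behind the published base rates were never
released; the engine treats the matrix as input data. The default fixture
is exchangeable — 0.3 within a function, 0.1 between functions — chosen
once because it places the 5-task ≥ 1-abnormal rate (~19.3%) inside the
implied regime (between 5% at perfect correlation and 22.62% under
independence). It is a stand-in, not an estimate.

Verification uses two independent routes: the exact Poisson-binomial tail
under independence (dynamic-programming convolution), and an exchangeable-ρ
sweep for function-level criteria. The sweep shows that with function
marginals 27.9/21.1/16.8% the attainable P(≥ 2 weak) over ρ ∈ [0, 1] is
[12.14%, 21.1%] — a published value of 11.8% for this quantity sits
slightly below this range, consistent with Monte Carlo noise or unrounded
marginals in its original computation; the corresponding acceptance check
is left failing rather than widened. No analytic orthant integration is
attempted: Monte Carlo plus the independence oracle covers the needed
precision.

## Inference

* One-sample tests of an observed count against a fixed base rate use the
  exact binomial tail (one-sided, "greater"); a normal-approximation z is
  reported descriptively only, because published z values for these tests
  are not reproducible from the standard approximations (with or without
  continuity correction, available as a flag).
* Proportions carry Clopper–Pearson 95% intervals. This choice reproduces
  9 of the 11 intervals printed in the motivating study exactly to one
  decimal; no other standard method reproduces any, so the two deviants are
  treated as transcription slips there, not evidence of a different method.
* Group comparisons of flag counts use Fisher's exact test: one-sided in
  the direction of the observed association, two-sided by the
  probability-mass rule (sum of tables no more probable than the observed);
  a degenerate margin yields p = 1. Tests are validated against brute-force
  fixed-margin enumeration.
* Performance levels are compared with Mann–Whitney U (midranks): exact
  null distribution when there are no ties and n₁n₂ ≤ 400, exact
  permutation enumeration for tied samples up to 12 observations, otherwise
  the tie-corrected normal approximation. All-tied data yields U = n₁n₂/2,
  z = 0, p = 1.
* No multiple-testing correction is applied (matching the design being
  reproduced). A two-proportion sample-size routine is provided for power
  planning; the assumptions behind any particular published sample-size
  claim are unknown, so no agreement is asserted.

## Synthetic data

The generator supplies what the real study cannot share:

* **Reference scores** — X = Z F^T with F F^T the model correlation
  (eigendecomposition, so singular matrices such as perfect correlation
  work and every marginal is exactly standard normal).
* **Patient cohorts** — reference draws with a mean decrement (z-units)
  subtracted from all tasks of the affected functions; ground-truth labels
  attached. Planted shifts are illustrative (no published effect sizes
  exist to calibrate them); recovery tests use the closed-form normal tail
  Φ(z_cut + shift) as truth.
* **Observers** — P(correct) = guess + (1 − guess − lapse) · F(level) with
  F a cumulative Gaussian in log level (logistic available); defaults
  guess = 0.5 (two-alternative tasks), lapse ≤ 0.1. The staircase's
  convergence level is available in closed form for calibration tests.
* **Search RTs** — lognormal with median exactly
  motor + scan · (n_distracters + 1)/2 (multiplicative noise, log-sd 0.25).
  Only medians enter the pipeline, so the family is chosen for its correct
  median and right skew, not as a cognitive model.
* **Fixture cohorts** — deterministic raw-data cohorts constructed to
  reproduce a requested set of marginal counts exactly after full scoring
  and classification (greedy flag placement validated by round-trip).
  Staircase trial data in fixtures is produced by deterministic threshold
  observers run through the package's own engine.

What the generator does **not** emulate: age-dependent score distributions
(fixture patients share one entry age mid-band), item-level difficulty
structure, response-time autocorrelation, attrition mechanisms, or any
relationship between IQ and task scores. Passing recovery tests therefore
demonstrates correctness of scoring, classification and inference — not
clinical realism of the cohorts.

## Problem sizes and determinism

Default study sizes: 10⁶ Monte Carlo simulants for base rates (10⁵–2·10⁵ in
fast pipeline runs), 500 replicate staircases for calibration, 5000-patient
synthetic cohorts for recovery. Every stochastic component takes an explicit
integer seed; pipeline reports embed seed and version and are byte-identical
across reruns of the same config.

## Known limitations

* The fixture cohort realises marginal counts, not joint patterns beyond
  them (e.g. which particular subtasks co-occur within a patient is chosen
  greedily, not matched to any published cross-tabulation).
* The default correlation fixture is conventional, not estimated; all base
  rates computed from it are illustrative.
* Staircase scoring assumes the recorded response sequence is complete;
  partially recorded (unterminated) tracks are treated as missing tasks.
* The L94 norm cutoffs bundled with the fixture are placeholders; real
  classifications require the published manual or user-derived norms.
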