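# Methods

## The model

`wmtime` implements a gradually recovering encoding-resource account of
immediate serial recall. A trial begins with the encoding resource at its
ceiling `R_max`. Encoding the item at serial position *i* consumes a fixed
proportion `p` of the resource available at that moment, `R_i`; the consumed
amount is the item's memory strength:

    Memory_i = p · R_i

During the free interitem interval `t_i` (seconds) that follows item *i*,
the resource recovers linearly at rate `r` per second, capped at the
ceiling:

    R_1     = R_max
    R_{i+1} = min(R_max, (1 − p) · R_i + r · t_i)

Memory strength maps to recall probability through a logistic function with
slope `gain` and threshold `tau`:

    P(correct_i) = 1 / (1 + exp(−gain · (Memory_i − tau)))

Two structural consequences follow directly from the recursion and are
enforced as property tests:

- **Proactive only.** Changing `t_k` cannot alter `R_1..R_k`; strengths at
  positions ≤ *k* are bit-for-bit identical under any perturbation of `t_k`.
- **Global.** Extra time in `t_k` weakly raises `R_i` for *every* *i* > *k*,
  not just the next item, because each later item consumes a proportion of a
  (now larger) pool.

An item is scored correct only when recalled in its own output position;
the model predicts no response times and no output-stage dynamics
(suppression, output interference) — the retention interval is carried in
schedules but plays no role.

## Parameters

| name    | meaning                                      | unit      | default |
|---------|----------------------------------------------|-----------|---------|
| `p`     | proportion of resource consumed per item     | —         | 0.23    |
| `r`     | recovery rate during free time               | 1/second  | 0.11    |
| `gain`  | logistic slope (strength → probability)      | —         | 13      |
| `tau`   | logistic threshold                           | strength  | 0.11    |
| `r_max` | resource ceiling                             | strength  | 1 (fixed) |

`r_max` is pinned at 1: rescaling it by *c* while mapping
`r → c·r, gain → gain/c, tau → c·tau` leaves every likelihood value
unchanged (verified in the test suite), so it is not separately
identifiable and freeing it would only add a flat ray to the surface.

**What counts as free time.** By default `t_i` is the blank interstimulus
interval alone (offset of item *i* to onset of item *i+1*): encoding
consumes instantaneously at onset and recovery runs only while the screen
is blank. The alternative reading — recovery also during the next item's
presentation — is available everywhere via
`time_definition="isi_plus_presentation"`; it only adds a constant to every
interval and none of the qualitative claims depend on the choice.

The cap is applied after crediting the full `r·t_i` (equivalently,
continuously: linear growth capped at `R_max` reaches the same endpoint, as
the millisecond-stepping oracle in the tests confirms to ~1e−13).

## Experiment designs

Three seven-consonant serial-recall designs are generated exactly:

- **exp1** — pacing: 6 blocks × 18 trials, 6 per condition per block;
  `short_fixed` (all ISIs 50 ms), `long_fixed` (all 870 ms; ISI sum
  5220 ms), `long_variable` (per-trial permutation of 50/250/550/950/
  1450/1950 ms; sum 5200 ms). Presentation 250 ms, retention 1250 ms.
  The 720 possible interval orders are dealt from reshuffled full cycles,
  so usage counts across all slots differ by at most one; with 20 subjects
  × 36 variable trials each order is used exactly once and interval
  duration is unconfounded with interitem position. Whether the original
  pacing experiment balanced conditions within blocks is not something the
  trial totals pin down; blocks here are balanced (6 per condition),
  mirroring the gap experiments' 3-per-condition blocks.
- **exp2a** — gaps: 8 blocks × 36 trials; one deviant ISI (500 or 2500 ms)
  after item 1–6 against 50-ms standards; 12 conditions × 24 trials.
  Presentation 300 ms, retention 1000 ms.
- **exp2b** — exp2a plus a 13th `no_gap` baseline condition (all ISIs
  50 ms); 8 blocks × 39 trials.

List letters are drawn per trial, without replacement, from the 21
consonants of the German alphabet. A 500-ms fixation precedes each list; it
is recorded on schedules but has no model role. Designs are
bitwise-reproducible from `(experiment, n_subjects, seed)`; per-subject
randomization streams are keyed `[seed, subject]` so adding subjects never
perturbs earlier ones.

## Synthetic data

`simulate_accuracy` draws each position's outcome as
Bernoulli(model probability). `subject_sd > 0` adds a per-subject normal
offset to `tau` — a deliberately minimal heterogeneity knob for
stress-testing fits; it is **not** an empirical claim about individual
differences, and the default is 0 (one parameter set for all subjects,
matching how the model is simulated).

What the generator emulates: condition structure, trial counts, binomial
trial-level noise, and (optionally) threshold heterogeneity. What it does
not: serial-order errors with structure (transpositions, intrusions),
output-stage dependencies between positions, fatigue or practice across
blocks, or any RT process. Passing tests therefore certify the pipeline's
arithmetic and the model's internal behaviour, not the model's fit to human
data.

`simulate_irt` is a *descriptive fixture*, not a model output: interresponse
times equal a base (400 ms) plus a grouping bump (300 ms) at exactly the
output position after the gap — identical in expectation for short and long
gaps — plus Gaussian noise. Its only purpose is to verify that the
decomposition below separates a grouping signature from a time signature;
its `correct` column is left missing.

## Analyses

- **Signed lag**: distance of an item from the gap; items at or before the
  gap get `position − gap_position − 1` (so the item just before the gap is
  −1), items after it `position − gap_position`. Lag 0 does not exist. Lags
  ±6 are geometrically possible from gap positions 1 and 6 but are excluded
  from lag tables, leaving ten levels (−5..−1, +1..+5).
- **Grouping/time decomposition** (13-condition data): per subject and lag,
  `grouping = short_gap − no_gap` and `time = long_gap − short_gap`. The
  baseline has no gap to anchor a lag, so each no-gap trial is replicated
  across all six pseudo-gap positions and averaged — the same mixture over
  gap positions that the gap conditions' lag cells contain. This is one
  defensible alignment choice; it is exact under the null (identical
  conditions give identically zero effects).
- **Pre/post-item time** (long-variable trials): the pre-item time of item
  *i* is the ISI before it plus one presentation duration, the post-item
  time the ISI after it plus one presentation duration — the definition
  under which the six levels span 0.3–2.2 s. Positions 1 (no pre-time) and
  7 (no post-time) are dropped before aggregation.
- **Within-subject CIs**: Cousineau–Morey — subject means removed (grand
  mean restored), per-cell SEM inflated by √(C/(C−1)) for C cells, scaled
  by the two-sided t quantile. A single subject yields zero halfwidths with
  a warning. Figure-style tables report the mean of subject means.

## Fitting and recovery

The pooled negative log likelihood sums Bernoulli terms over rows;
probabilities are clipped to [1e−9, 1−1e−9] before logs. Because
probabilities depend only on a trial's free-time profile, observations are
aggregated to binomial counts per unique profile × position (≤ 13 profiles
in the gap designs; ≤ 720 in exp1) — exactly equivalent and fast enough
that a full fit takes well under a second.

Optimization is multistart L-BFGS-B in the box p ∈ [.01, .9], r ∈ [0, 2],
gain ∈ [1, 100], tau ∈ [0, 1] with `r_max = 1` fixed. Each of the
`n_starts` (default 10) local searches starts from the best of 64 uniform
random probes of the objective; plain uniform starts occasionally fell into
a rival high-`r` basin whose optimum is clearly worse than the global one,
and the probe step eliminates that failure mode cheaply. Fits are pooled
across subjects by default (the generative simulation uses one parameter
set); per-subject fitting is just a fit per subject's data slice.

`parameter_recovery` runs the standard simulate-then-fit study. A
truth–estimate correlation is undefined at a single fixed truth, so each
replicate draws its generating parameters by jittering the supplied values
multiplicatively (uniform within ±30%, clipped inside the bounds), then
simulates the given design and refits. The report carries per-parameter
bias, RMSE, relative RMSE and truth–estimate correlation. At the study
scale used throughout (the 13-condition design, 25 subjects, 20
replicates), `p`, `r` and `tau` recover with relative RMSE well under 10%;
`gain` is the weakest-identified parameter — its correlation trails `p`'s —
which is reported, not hidden.

## Numerical and scale choices

- Problem sizes in the tests and the acceptance script follow the study
  conditions: 20 subjects for the pacing design (one full 720-order cycle),
  25 subjects for the 13-condition gap design, 20 recovery replicates.
- The qualitative proactive-benefit check on simulated data uses a 0.04
  bound for "near zero" at negative lags: the model expectation there is
  exactly 0 and the bound is ~2 standard errors of a lag-cell difference at
  these cell sizes, far below the positive-lag effects (~0.06–0.16).
- Recovery thresholds (relative RMSE of `p` and `r` below 0.15) were frozen
  once from a pilot at roughly twice its observed values.
- Degenerate inputs fail fast: negative ISIs, non-positive subject counts,
  orphan data rows, missing gap positions, and missing conditions raise
  `ValueError` with a named cause; an all-starts-failed optimization raises
  with diagnostics rather than returning a sentinel.

## Limitations

- The model is an encoding-stage account only; it cannot produce serial
  position curves shaped by output processes, RT patterns, or grouping
  effects proper (the symmetric accuracy benefit around a gap), and the
  simulated data inherit these silences.
- The pseudo-gap alignment of the no-gap baseline is one reading of an
  underdetermined analysis choice; alternatives (e.g., position-matched
  baselines) would shift the grouping contrast, not the time contrast.
- Between-subject heterogeneity is a single tau offset; real individual
  differences surely involve all parameters.
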