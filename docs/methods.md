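# Methods

## The tracker model

A pedal-desk session is a point process: one timestamped event per pedal
revolution. All tracker quantities derive from the inter-event gaps
`Δᵢ = tᵢ − tᵢ₋₁`:

* **Instantaneous cadence** `RPM = 60/Δ`, defined only for `Δ > 0` and only
  while the gap is inside a bout (below the 15 s threshold).
* **Bouts.** A gap `≥ 15 s` ends a bout; every shorter gap continues it.
  The comparison is inclusive on the batch side (`≥ 15 s` splits) and the
  real-time accumulator adds only gaps strictly `< 15 s`; the two rules are
  complementary, so folding the real-time update over a stream reproduces
  the batch sum of bout durations exactly (a property test asserts ±1 ms
  over 1,000 random streams).
* **Summaries.** Over an interval, total duration is the sum of bout
  durations (minutes) and mean RPM is total revolution count divided by
  total duration. The count includes each bout's first revolution
  (`rpm_count_mode="literal"`, the default, matching how a revolution
  counter naturally tallies), which biases a single constant-cadence bout
  of `n` events upward by the factor `n/(n−1)`; `"interval"` mode counts
  revolutions after each bout's first and is unbiased. Intervals with zero
  total duration report mean RPM as `None`, never as a silent NaN.
* **Calendar grouping.** Daily/weekly/monthly summaries are
  calendar-aligned on the stream's local clock, weeks starting Monday; a
  bout spanning a boundary belongs wholly to the interval containing its
  start. These are conventions, not measurements — any deterministic rule
  would do.
* **Power.** `P = r·g·L·RPM/60` W with resistance `r = 0.30 kp`
  (`g = 9.80665 m/s²`) and belt travel `L = 8.15 m` per crank revolution.
  `L` is not a published spec of any desk; the default is chosen so that
  30–90 RPM spans ≈12–36 W, and both `r` and `L` are model fields.

## Aggregation to a comparison grid

Two devices observing the same session are compared on an absolute
per-second grid (timestamps floored to whole seconds):

* a second holding rated revolutions gets their mean instantaneous RPM;
* an event-free second inherits the previous value while the time since
  the last revolution stays under 15 s (the bout threshold, reused for
  internal consistency), then goes missing; a bout-opening revolution
  resets the carried value;
* minutes are means of their non-missing seconds, kept only when coverage
  is ≥ `min_coverage` (default 0.8 — partial minutes at trial edges would
  otherwise contribute unstable means);
* the trial value is the unweighted mean of minute values, so the trial
  row of a report is exactly the mean of its minute rows;
* criterion and test series merge by inner join on the grid; unmatched
  samples are dropped and counted in the log.

Sub-second phase is deliberately discarded by the flooring step: merging
happens at whole-timestamp resolution, and millisecond offsets between
devices should not break alignment.

## Validation statistics

Differences are always criterion − test, so a device that over-reads shows
a negative mean difference.

**Equivalence.** Devices are equivalent when the two-sided `1 − 2α`
confidence interval for the mean difference falls *strictly* inside
`(−margin, +margin)` — an endpoint exactly on the margin fails. This is
dual to two one-sided t tests at level α each (asserted over 500 random
datasets). Defaults: margin 1.5 RPM (3 % of an assumed 50 RPM self-selected
pace), α = 0.025. Trial level uses a paired t on one difference per subject
(df = n−1). Minute level fits a random-intercept model
`d_ij = μ + b_i + e_ij` by REML; the CI uses df = n_subjects − 1, a
conservative choice since the effective information for μ is
between-subject. For balanced designs the exact REML optimum is closed
form (μ̂ = grand mean, Var(μ̂) = MSB/(m·n)) and is used directly; unbalanced
designs go through an iterative fit, falling back to the subject-means t
estimator if the fit lands on a degenerate boundary. A design with all
differences identical short-circuits to SE = 0.

**Error metrics.** MAPE is the mean of `|d|/criterion × 100` with its
plain SE over pairs; threshold percentages count `|d| < k` strictly for
k ∈ {1, 3, 5} RPM; Pearson r is pooled over all pairs and reported as NaN
(flagged, not zero) when either device has zero variance.

**Bland–Altman.** Bias is the grand mean of all differences (a
subject-means weighting is available via `bias_mode`). Simple mode uses the
sample SD of differences. Linked-replicates mode — many minutes per
subject, with the true cadence varying within subject — estimates variance
components from the one-way ANOVA of differences grouped by subject:
`σ²_w = MSW`, `σ²_b = max(0, (MSB − MSW)/m₀)` with
`m₀ = (N − Σm_i²/N)/(n − 1)` for unbalanced group sizes, and
`SD = √(σ²_b + σ²_w)`; limits are `bias ± 1.96·SD`. Negative
between-subject estimates truncate to zero (the standard method-of-moments
convention). Coverage of the estimated limits on fresh draws from the
generating model is ≈95 % (checked at 100,000 differences, ±1 point).
Proportional bias is the ordinary least-squares slope of difference on pair
mean — deliberately ignoring clustering, since the plot's fitted line is
what is being tested; a cluster-robust p value is available but off by
default.

## The synthetic trial

The generator emulates a seated-workstation validation session: subjects
pedal at a self-selected pace for ≈20 minutes while two devices log every
revolution.

* Per-subject mean cadence ~ Normal(55, 11) RPM truncated to [30, 90]; the
  between-subject SD is back-computed from a trial-level SE of ≈1.7 RPM at
  n = 41.
* Trial duration ~ Normal(20.5, 2.5) min, truncated above 5 min.
* Within a session, cadence follows a per-second AR(1) with coefficient
  0.95 and stationary SD 3 RPM, floored at 20 RPM — slow wander rather than
  white noise; these dynamics are a modeling choice, exposed in
  `CadenceProfile`. Revolution `i+1` arrives `60/c(tᵢ)` seconds after
  revolution `i`. Optional pauses (a Poisson process of 20–45 s gaps) are
  off by default: guided desk-work sessions are continuous.
* Device errors are phenomenological: per-revolution miss probability,
  double-fire probability (the duplicate lands midway to the next
  revolution), Gaussian timestamp jitter, and a multiplicative cadence
  bias `rate_scale` realized as uniform time compression. The
  `garmin_like` preset is 20 ms jitter only; the `desk_like` preset is
  5 ms jitter plus `rate_scale = 1.018`, a +1.8 % over-read chosen so the
  default 41-subject study shows ≈−1 RPM mean difference and ≈2 % MAPE — a
  realistic magnitude for a magnet-switch counter, and the regime in which
  the equivalence machinery is interesting. Note that duplicate insertion
  inflates per-second-averaged RPM by somewhat more than its event-count
  rate (split intervals contribute two doubled instantaneous rates), which
  is why the calibrated bias uses `rate_scale` rather than the double-fire
  channel; the double-fire test asserts recovery against a 10× Monte Carlo
  oracle rather than a closed form.
* Reproducibility: subject `i` draws from `SeedSequence([master, i])` and
  device `k` of subject `i` from `SeedSequence([master, i, k])`, so any
  subject regenerates without simulating the rest; identical seeds yield
  byte-identical CSVs.

What the generator does *not* emulate: biomechanics and fatigue (cadence
dynamics are a stationary AR(1)), behavioral reaction to feedback, device
dropout mid-trial, or clock drift between devices. A multiplicative device
bias also makes the proportional-bias slope genuinely nonzero
(d ≈ −0.018 × cadence), so a significant slope test on synthetic data is
expected, not a defect. Passing tests therefore demonstrate that the
estimators recover known generating parameters under a plausible error
model — not that any physical desk meets the equivalence margin.

## Problem sizes and numerical conventions

The test suite and the acceptance script size their simulations for a
single CPU: limits-of-agreement coverage uses 200 subjects × 25 minutes for
estimation and 100,000 fresh differences for evaluation; the
boundary-rejection rate uses 20,000 replicates of 41 differences; the
bias-recovery pipeline uses a 10-subject study against a 100-subject Monte
Carlo oracle with 10-minute sessions; property suites run 500–1,000 random
cases. Timestamps serialize at millisecond precision and round-trip
exactly; jitter-induced ordering collisions are resolved by a 1 µs nudge.
Streams reject duplicate or non-increasing timestamps outright rather than
repairing them — a magnet switch cannot fire twice at the same instant, so
duplicates indicate corrupt input.

## Known limitations

* The minute-level CI's df convention (subjects − 1) is one reasonable
  choice among several (Satterthwaite, Kenward–Roger); with ≈40 subjects
  the difference is far inside reported precision.
* Pearson r at minute level is pooled across subjects, so between-subject
  cadence spread inflates it relative to a within-subject correlation.
* The per-second carry-forward rule is an interpolation convention, not a
  measurement; alternatives (linear interpolation, strict missing) would
  shift second-level values slightly but leave minute means essentially
  unchanged for realistic cadences.
* `estimate_power` is a static belt model; it ignores drivetrain losses
  and acceleration transients.
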