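# Methods

This note documents the models, numerical choices, and open design
decisions behind `cpcst`, in the spirit of a simulator's model
documentation: enough detail to know exactly what is being computed, what
the synthetic data does and does not emulate, and where declared
conventions stand in for under-specified parts of the task definition.

## 1. Plant model

The stimulus position `x` (normalized units; screen edges at ±1) obeys the
first-order unstable plant `dx/dt = λ(x + u)`, discretized with forward
Euler at the task's native 30 Hz:

    x[n+1] = x[n] + dt · λ · (x[n] + u[n]),      dt = 1/30 s.

Euler at the native rate is not an approximation choice here — the task
*is* a 30 Hz discrete system, and the recorded dynamics are the discrete
ones. Crashes are `|x| ≥ crash_fraction` (0.8, boundary inclusive: the
task text is ambiguous between "exceeding" and "within", and an inclusive
threshold is deterministic and testable). Position is clamped to the
physical screen range [−1, 1]; since the crash boundary is interior,
clamping never masks a crash.

**Sign convention.** The control law is written for a mirrored control
signal: a stabilizing controller outputs `u = −x`, and the plant adds
`x + u`. `TaskConfig.control_sign = −1` switches to `x − u` for the
unmirrored convention; the two are equivalent up to negating `u`, and the
test suite checks the plant and the synthetic controller stay consistent
under both.

**Units.** All dynamics run in normalized units. Degrees of visual angle
are a reporting-only linear conversion, 27.85 DVA per unit, declared so
that the 0.8 crash boundary corresponds to ±22.28 DVA as conventionally
printed for this task. The DVA figure is not derivable from typical
screen-geometry formulas, so it is treated as a constant of the reference
apparatus, not computed.

## 2. Synthetic participants

A participant is the minimal controller producing the three phenomena the
task measures — response latency, an instability threshold, and
attentional drift:

    u[n] = clamp( −gain · x[n−d] + ε[n] ),   d = round(τ · 30 Hz)

* `τ` (`feedback_delay_s`): sensorimotor latency, quantized to whole
  samples. Cohort default U(0.10, 0.35) s, spanning typical human
  visuomotor delays.
* `ε`: band-limited motor noise. White position noise is unphysical (hand
  and device position are inertial) and, more importantly, it breaks the
  DTW latency metric: a jagged user series lets the warp path roam, which
  inflates and destabilizes latency estimates in a way real, smooth
  device data does not. Noise is therefore Gaussian-filtered
  (`noise_smooth_s`, default 0.1 s kernel SD) and rescaled to
  `motor_noise_sd` (cohort default U(0.01, 0.04) units).
* Lapses: a Poisson process (`lapse_rate_hz`) of freeze episodes with
  exponential durations (`lapse_duration_s`) during which `u` holds its
  last value. Cohort defaults — up to ~2 lapses/min of 0.3–0.8 s — keep
  continuous-phase crashes rare, the regime the task is designed for.
* `gain`: cohort default U(1.02, 1.30). A proportional gain below 1
  leaves the slow mode of the closed loop exponentially divergent (drift
  rate λ(1−gain)), so *every* 10-minute run would crash; sustained human
  tracking keeps position bounded, which in a pure-proportional model
  requires gain ≥ 1.
* `quantization_step` (default 1/1024): the control device's resolution.
  This matters in the noise-free limit: with gain 1 the continuous delayed
  feedback law has a continuum of exact equilibria (`u = −x` cancels at
  any constant `x`), so a noiseless loop would freeze rather than
  destabilize as λ ramps. Quantization floors the excitation at one
  quantum, deterministically, the way real sensors do. Set it to 0 for
  the mathematically exact delay line.

Two percept/device conventions complete the crash reset: the stimulus
resets to center up to the same small residual offset that seeds the
calibration ramp (`x_initial`, default 0.01 units ≈ 0.28 DVA — a
perfectly centered noise-free loop would sit at its fixed point forever),
and the controller drops percepts from before a reset jump it has seen
(participants re-center after a crash rather than keep responding to
stale pre-crash positions; without this, every reset triggers a spurious
immediate re-crash).

One master seed spawns independent per-participant streams
(`numpy.random.SeedSequence`), so cohorts are reproducible and
participants order-independent.

**What the generator does not emulate.** Learning across calibration
trials, fatigue, anticipatory/predictive control, non-proportional
(intermittent, bang-bang) control policies, device dropout, blinks. Tests
passing on this generator show the *pipeline* is correct and calibrated
under known ground truth; they do not certify parameter values for human
data.

## 3. Calibration

λ ramps linearly (`lambda_ramp_rate`, default 0.2 s⁻¹ per second, from
`lambda_initial = 0.1`). These two constants are not part of the task's
published definition; the defaults were chosen once so that a mid-range
synthetic controller completes its 10 crashes in roughly 2–5 simulated
minutes, and both are configurable. On each crash the crash-time λ is
recorded, the stimulus resets, and λ restarts at `reset_fraction` (0.5)
of the crash value. MST = mean λ of the final `mst_last_k = 3` crashes.
A controller that never crashes within `calibration_time_cap_s` (30
simulated minutes) raises a timeout error.

**Time to asymptote.** The task literature reports when participants
reach "asymptotic performance" without defining the criterion. The
package's declared stand-in: the earliest crash from which every
subsequent crash λ stays within ±10% of the MST (`asymptote_tolerance`,
configurable); "not reached" if only the final crash qualifies. This is
transparent and monotone but is *not* an inference of the original
authors' rule, and cohort asymptote fractions depend on it.

## 4. Preprocessing

A crash episode is a maximal run of `|x| ≥ 0.8` samples extended forward
over the reset discontinuity (a sample-to-sample jump > 0.5 units — half
the screen in one frame is an artifact, not behavior). Episode samples
are removed from *both* position series (interpolating only the stimulus
would create artifactual lags in the alignment) and refilled with
monotone piecewise-cubic Hermite interpolation (PCHIP) over time, which
passes through the retained anchors exactly and cannot overshoot between
them; a gap touching either end of the trace raises an error rather than
extrapolating. Participants with ≥ 2 crash episodes are excluded before
any latency computation. Compliance is the per-participant mean stimulus
position in DVA; the cohort summary is its mean ± SD across participants.

## 5. Instantaneous reaction time

The user series is negated (mirrored), both series are z-scored with
their own mean and SD, and DTW aligns them:

* pointwise cost `|a_i − b_j|` (L1 on z-scored series; squared cost
  available via `metric="sq"`),
* symmetric steps {(1,0), (0,1), (1,1)}, boundary-anchored,
* deterministic tie-break: diagonal first, then the step advancing the
  stimulus index,
* optional Sakoe–Chiba band `|i−j| ≤ band`.

Per stimulus timepoint `i`, the latency is the mean (configurable to
median) of `(j − i)/30 Hz` over its matched user timepoints — converting
sample-index offsets to seconds; positive latency means the user lags.
The summary iRT is the mean over timepoints; `trim_edges_s` (default 0)
optionally drops the boundary-distorted path ends before summarizing.

The dynamic program is exact and O(N·M) (numba-compiled). A full
10-minute trace is an 18,000² problem (~2.6 GB for the cost matrix), so
the pipeline entry points expose a windowed mode — non-overlapping
windows aligned independently after global z-scoring (30 s windows in the
demo pipeline) — and the band. On pure-delay ground truth the windowed
and exact estimates agree to within a sample; windowing is the default
for the pipeline surface only, never for `dtw_align` itself.

**Bias caveat.** On closed-loop traces whose stimulus is dominated by very
slow drift (low λ relative to the stability margin), sparse features
under-constrain the warp path and the mean latency carries an upward,
λ-dependent offset relative to the generating delay, even though
cross-correlation recovers the exact lag. The metric is an *index* — it
ranks participants correctly (delay–iRT correlation ≈ 0.98 in cohort
checks) and is what the task's analysis pipeline defines — but its
absolute level should not be read as a pure sensorimotor delay.

**Discrete-sampling residual.** `discrete_sampling_residual` resamples
the stimulus with a zero-order hold at a probe interval (emulating
conventional discrete-RT paradigms) and reports the 30 Hz residual plus
the fraction of samples exceeding 2 SD of the native series — the
behavioral variation a slow sampler would miss.

## 6. Reliability

The cpCST has no trials, so the split-half **trial unit** is a
non-overlapping 1-second bin of the latency series (30-sample mean; 600
units per 10-minute run; bin width configurable). Each permutation
split-half estimate: permute each participant's units, split into halves
(odd counts: first half gets the extra unit), correlate half-means across
participants (Pearson), apply Spearman–Brown `2r/(1+r)`. The bootstrap
wraps this: each draw resamples participants with replacement and
averages `n_perm` permutation estimates; the point estimate is the mean
of the bootstrap distribution and the CI its 2.5th/97.5th percentiles.
The published procedure's "1,000 repeats" is ambiguous about nesting;
here the permutation loop nests *inside* each bootstrap draw, with
`n_perm` reduced (default 100; 50 in the acceptance runs) for
tractability — both knobs are exposed. Draws that resample fewer than
three distinct participants, or hit r = −1 (where the correction is
undefined), are treated as undefined and dropped with a warning.

The flanker congruency effect uses a difference-score variant: trials are
permuted and halved within each condition separately, and the
half-difference scores are correlated — preserving the within-condition
structure of I−C.

## 7. Stability curves and their comparison

For n = 1..K minutes, the participant means computed from only the first
n minutes are Pearson-correlated with the full-duration means (pairwise
deletion with a warning when a participant has no early data; r = 1 at
n = K by construction). Curves for two measures are compared minute by
minute with Steiger's Z for dependent correlations with one variable in
common (the full-task measure as the shared variable), using the
pooled-r̄ form

    rbar = (r_jk + r_jh)/2,  f = min(1, (1−r_kh) / (2(1−rbar²))),
    h = (1 − f·rbar²)/(1 − rbar²),
    Z = (z_jk − z_jh) · sqrt((n−3) / (2(1−r_kh)·h)),

with `r_kh` the correlation between the two truncated measures. The
variant choice (Z with pooled r̄ rather than Williams' t) is declared, and
the implementation is validated against an independent re-derivation via
the covariance term ψ and by a type-I-error simulation (rejection rate
0.047 at α = 0.05 under a trivariate-normal null, n = 150, 2,000 reps).

## 8. Flanker metrics

Trimming pipeline, per participant and in this order: (1) overall
accuracy < 80% flags the participant excluded; (2) incorrect trials
dropped; (3) anticipatory RTs < 200 ms dropped; (4) RTs more than 2.5 SD
above the participant's mean dropped, with mean and SD pooled over the
surviving correct trials of *all* conditions (a per-condition option
exists; the pooled reading matches "the participant's mean" with no
condition scoping); (5) condition means and I−C = incRT − conRT.

The SD rule is applied in a single pass. It is not mathematically
idempotent — trimming shrinks the SD, so re-running it can remove more —
and the pipeline deliberately does not iterate it.

The generator draws ex-Gaussian RTs (Gaussian μ, σ plus exponential τ,
the standard empirical RT family) per condition: defaults 430/450/490 ms
μ for congruent/neutral/incongruent with a 60 ms μ congruency effect,
σ ≈ 50 ms, τ ≈ 80–90 ms, accuracies 0.95–0.98. Two participant-level
random effects: a shared shift on all μs (SD 40 ms) and an interference
effect on the incongruent μ only (SD 20 ms), so conRT/incRT and I−C all
carry true individual differences, with I−C the least reliable — the
ordering such task comparisons turn on. 360 trials in 3 blocks, exactly
equal condition counts, and a first-order counterbalanced order: for the
default trial count an Eulerian path over the 3-condition transition
multigraph gives transition counts balanced within ±1 exactly; other
counts use a quota-constrained greedy balancer.

## 9. Validity regressions

OLS of each outcome on mean iRT (plus intercept; plus age on request),
listwise deletion with the retained n logged and required ≥ 10,
rank-deficiency checked before fitting (statsmodels under the hood).
p values are reported unadjusted — matching the analysis style of the
task's evaluation literature — and every report carries a multiplicity
note. Ability/achievement/fitness-style outcomes are opaque numeric
columns; the bundled generator is a declared linear-plus-noise model
(score = 110 − 40·iRT − 0.2·age + N(0, 8)), not an attempt to model the
instruments.

## 10. Problem sizes and determinism

The acceptance script simulates 40 participants with the full 10-minute
continuous phase (windowed DTW, 30 s windows), a matched 360-trial
flanker cohort, and reduced Monte-Carlo depths (bootstrap 200 × 50
permutations) — sizes chosen as a desk-scale design point at which every
stage's behavior is already stable; all of them are parameters. The unit
suite uses shorter traces (40–120 s) and smaller replicate counts of the
same checks. Every stochastic stage takes an explicit seed; pipelines
derive per-stage seeds from one master seed, and identical config + seed
reproduces every output byte-for-byte.

## Known limitations

* The controller family is proportional-with-delay only; fitting it to
  real traces is out of scope.
* The DTW latency level is biased upward on slowly-drifting closed-loop
  traces (see §5); comparisons, reliabilities and regressions are
  unaffected in rank terms, absolute levels are metric-specific.
* The asymptote criterion and the λ ramp constants are declared
  conventions, not recovered task parameters; cohort asymptote fractions
  are sensitive to both.
* Test–retest reliability (distinct sessions) is not modeled — only
  internal consistency.
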