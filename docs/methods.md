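# Methods

## The two-parameter model

For severe-intensity swimming the distance–time relationship of maximal
efforts is linear, `d = CS·t + D′`. CS (m·s⁻¹) is the asymptotically
sustainable speed; D′ (m) is the finite distance that can be covered above
CS before task failure. `fit_distance_time` estimates both by ordinary
least squares of distance on time (the only variant implemented; the
speed–1/time and hyperbolic forms are deliberately out of scope, as the
slope/intercept of the distance–time form are the quantities the rest of
the pipeline consumes). Standard errors come from the usual OLS variance
formulas and are reported both in native units and as a percentage of the
estimate. A negative intercept is physiologically meaningless but is
returned flagged rather than rejected, so stress tests and noisy inputs
flow through the pipeline rather than aborting it.

The constant speed prescribed for interval work inverts the model:
`speed = CS + D′/t` with `t = 180 s`, the intensity predicted to exhaust
D′ in three minutes of continuous swimming.

## D′-balance kinetics

During intermittent exercise the remaining capacity is modelled as

    D′_bal(t) = D′ − ∫₀ᵗ max(s(u) − CS, 0) · exp(−(t − u)/τ) du

the literal convolution form: every expended increment is reconstituted
exponentially **at all later times, including during subsequent work**.
The integral form (rather than the piecewise variant that freezes
recovery during work) is the contract of this package; the two schemes
give different τ values for the same session, so τ values are comparable
only within a scheme.

Assumptions inherited from the model family:

- expenditure is linear in the speed excess above CS; speeds below CS
  expend nothing regardless of segment label (an above-CS "recovery"
  segment expends, it never reconstitutes);
- reconstitution is a single exponential with one session-level τ; no
  fatigue drift of CS, D′ or τ within a session;
- passive rest means the recovery-intensity gap below CS equals CS itself.

### Numerical scheme

Timelines are piecewise constant, so the convolved expenditure
`S(t) = ∫ r(u)e^{−(t−u)/τ}du` obeys the exact recursion
`S(t) = S(a) + (r·τ − S(a))(1 − e^{−(t−a)/τ})` within a segment of
constant excess rate r. All solver-facing evaluation uses this closed
form (with `expm1`/`log1p` so the τ → ∞ no-recovery limit stays accurate);
the reporting grid (`dt`, default 0.01 s) is used only to render the
trajectory and locate its minimum D′_LOW, and halving it changes D′_LOW by
well under 0.01 m. No floor is applied at zero: D′_bal may go negative,
which is exactly what D′_LOW < 0 reports.

### Solving τ at observed exhaustion

`solve_tau` finds the τ at which D′_bal is zero at the recorded exhaustion
time. The residual d_end(τ) is monotone non-increasing in τ, so plain
bisection over τ ∈ [0.1, 10⁶] s suffices (tolerance |d_end| < 10⁻³ m,
≤ 200 iterations; the generous upper bound keeps extreme outliers — the
kind of four-thousand-second value a real cohort can produce — inside the
bracket rather than clipped at it). Residuals that do not straddle zero
are *results*, not errors: a residual still positive at the slow end means
the session cannot deplete D′ at the observed time (the recovery-free
continuous bout at its loss-free depletion time `D′/(s − CS)` is the
canonical case — under the convolution form d_end > 0 for every finite τ,
so τ is unbounded); a residual already negative at the fast end means
exhaustion was recorded before even a loss-free session could deplete D′.

### Predicting TTE

`predict_tte` extends the work/rest cycle (from a session plan, or a
timeline repeated periodically) and finds the first zero crossing of
D′_bal analytically inside a work segment; rest segments cannot terminate
a session. TTE is the session clock — work plus recovery time — at the
crossing. A crossing inside a segment of excess rate r exists iff
r·τ exceeds the outstanding target, and across cycles iff the fixed point
of the per-cycle recursion exceeds D′; when it does not, the prediction is
reported as not-reached at the cap (default 7 200 s) rather than as a
number. Tolerances: the cap, dt and the τ bracket all live in
`AnalysisConfig` and apply uniformly to the CLI and the report functions.

## Agreement statistics

Differences are signed, first argument minus second (2:1 minus 4:1 for
the bundled table). Paired t uses the n−1 sample SD and Student critical
values; Bland–Altman limits are bias ± 1.96·SD(d); the within-subject CV
is `SD(d)/√2` relative to the grand mean of all 2n values. Signed
differences are the convention throughout — they are what reproduces both
the all-swimmers and the outlier-excluded CV on the bundled table, whose
printed per-subject "difference" column is absolute and is therefore
reported separately (`mean_abs_difference`). τ-vs-CS association is
offered as linear OLS and as the exponential decay `τ = a·e^{−b·CS} + c`,
started from the cycling-calibrated amplitude/offset (546, 316) with the
rate rescaled to the covariate's magnitude (the original 0.01 rate is per
watt and meaningless on a m·s⁻¹ scale); a failed nonlinear fit is a
reported state, never an exception, because "did not converge" is itself
the finding of interest.

## Synthetic cohort generator

The generator emulates the study population the pipeline targets:
thirteen trained swimmers, CS ~ N(1.23, 0.09) m·s⁻¹ and
D′ ~ N(33.69, 8.65) m (truncated at 0.5 m·s⁻¹ and 5 m by redrawing), four
time trials at {200, 400, 600, 800} m obtained by inverting the model
with optional multiplicative timing noise, and 50 m interval sessions at
the 180 s target speed with passive rests at the planned work/relief
ratio. Lap times are jittered with CV 1% (pacing by audible signals is
good, not perfect); rests follow the *planned* ratio of the nominal lap
time. Randomness is spawned per swimmer from a single master seed, so
cohorts are bit-reproducible and independent across swimmers.

τ is drawn log-normal (median 380 s, log-scale σ = 0.3) independently per
session, with the across-session correlation exposed as a parameter
rather than assumed — the package exists to *test* whether τ transfers
between sessions, so the generator must not bake the answer in. The
median is chosen for scheme consistency: under the convolution form, a
session only depletes D′ if τ exceeds roughly 260 s (2:1 relief) or
220 s (4:1) at the prescribed speed, and a median of 380 s puts simulated
TTEs in the observed few-hundred-second range while leaving roughly one
swimmer in ten able to sustain the 2:1 session indefinitely — the
non-predictable case the prediction layer must handle. τ values quoted
for the piecewise model variant (tens of seconds) are not transferable to
this scheme and would never exhaust.

Task failure in the generator occurs at the first crossing of −δ, where
the behavioural slack δ = |N(0, `exhaustion_slack_sd`)| models a swimmer
pushing slightly past model-zero under strong encouragement. With δ = 0
(the default) the recorded log is exactly consistent with the generating
dynamics, so solving τ back from the log recovers it to the bisection
tolerance — the round-trip identity the solver tests rely on. With δ > 0
(≈1.5 m is a realistic scale) the recorded exhaustion overshoots the
model's zero crossing; re-solving τ to force d_end = 0 then tilts the
trajectory so that, combined with lap-speed variability, the session
minimum D′_LOW can fall below zero even though d_end is exactly zero —
the signature that real, behaviourally terminated sessions show. This
overshoot is the *only* mechanism in the generator that produces
D′_LOW < 0: with exact exhaustion recording the solved trajectory is
non-negative by construction, whatever the jitter.

What the generator does **not** emulate: stroke mechanics, pacing drift
or fatigue within a lap, correlated timing errors from video digitisation,
and any within-session change of CS, D′ or τ. Passing tests on synthetic
cohorts therefore demonstrate the pipeline's internal consistency
(parameter recovery, solver correctness, qualitative orderings), not that
the single-τ convolution model describes real swimmers — on the bundled
real session-τ table the agreement layer shows it does not.

## Problem sizes and determinism

The test suite runs seeded cohorts of 4–13 swimmers (10 000 for the
moment check of the generator alone) with sessions of ~10–30 laps;
property-based suites use derandomised hypothesis settings. All
randomness flows from explicit seeds; there is no time-based state.

## Known limitations

- The convolution form's τ is not comparable with piecewise-variant τ
  values, and per-swimmer τ from other analyses cannot be replayed here.
- `plan_from_log` reconstructs a nominal plan by medians; for strongly
  paced (non-constant) sessions the reconstructed plan misrepresents the
  prescription and TTE predictions should use an explicit `SessionPlan`.
- The within-subject CV assumes a positive grand mean; it is a
  reliability measure for positive-valued quantities (τ, TTE) only.
- Active recovery above CS is treated as expenditure, and reconstitution
  uses the single passive-rest τ; graded recovery-intensity kinetics are
  out of scope.
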