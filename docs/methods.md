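# Methods

`circwear` estimates the phase of the human circadian clock from consumer
wearable data along two independent routes and quantifies how well the two
resulting phase markers agree, before and after a disruption of daily
routine (the motivating case is the onset of social distancing).  This
note records the models, the numerical choices, and the limits of what the
synthetic experiments can show.

## The heart-rate phase model (CRHR)

Heart rate on a uniform 5-minute grid is modelled as

    HR_t = a − b·cos(π/12·(t − c)) + d·A_t + ε_t,
    ε_{t+1} = k·ε_t + N(0, σ²),

with `a` the basal heart rate (bpm), `b` the circadian amplitude (bpm,
b ≥ 0), `c` the clock time of the circadian heart-rate minimum (hours,
circular mod 24), `d` the heart-rate gain per step of in-bin activity,
`k ∈ [0, 1)` the AR(1) carryover, and `σ` the innovation standard
deviation.  The AR chain is defined only within contiguous runs of usable
bins — worn, not sleep, both streams present — and restarts at its
stationary marginal N(0, σ²/(1 − k²)) after every gap (missing data,
sleep, day boundary), because error carryover across a multi-hour gap has
no physical meaning.

Each day is fitted by affine-invariant ensemble MCMC (the Goodman–Weare
stretch move, implemented in `circwear.sampler`), with log prior + AR(1)
log likelihood as the target.  The production budget is 100,000 target
evaluations per day, discarding the first half of each chain as burn-in,
with 50 walkers and stretch scale a = 2.  Days are chained: day 1 uses a
weakly informative base prior

    a ~ N(70, 15²) bpm,  b ~ HalfNormal(10) bpm,  c ~ Uniform on the circle,
    d ~ N(0, 0.5²) bpm/step,  k ~ Uniform[0, 1),  σ ~ HalfNormal(10) bpm,

and each later day uses the previous posterior moment-matched to
independent Gaussians (the phase on the unwrapped circle) with standard
deviations inflated ×1.5.  The inflation keeps the chained prior from
collapsing, so the fit can track genuine day-to-day phase drift; without
it a long record would freeze the phase at its early value.

The daily phase marker is the circular mean of the posterior `c` samples;
its uncertainty is the equal-tailed 80% interval computed on samples
unwrapped about the circular mean and re-wrapped to [0, 24).  Intervals
may cross midnight; all containment tests are circular.

Reduced budgets for testing: `SamplerConfig.fast()` spends 5,000
evaluations per day (20 walkers) and is used for pipeline smoke runs,
where wider intervals are acceptable.  Calibration checks use 60,000
evaluations per day with burn-in 0.85 instead: walkers start from the
over-dispersed prior, and a chain that is cut too early still carries
prior mass, which widens the sample cloud and inflates empirical interval
coverage by 2–4 points; an over-long chain with too few retained samples
instead under-covers slightly on diffuse multimodal days.  The
calibration setting was chosen by increasing budget and burn-in until the
coverage estimate agreed with an exact-quadrature check on a
phase-only sub-problem (~80–81%).

## The pacemaker model and predicted DLMO

The central clock is modelled as the established higher-order van der Pol
limit-cycle oscillator with a photic drive (Process L):

    ẋ  = (π/12)[x_c + μ(x/3 + 4x³/3 − 256x⁷/105) + B]
    ẋ_c = (π/12){q·B·x_c − [(24/(0.99729·τ_x))² + k·B]·x}
    ṅ  = 60[α(1 − n) − β·n]

    B̂ = G·α·(1 − n),  B = (1 − 0.4x)(1 − 0.4x_c)·B̂,  α = α₀(I/I₀)^p

with μ = 0.13, G = 19.875, α₀ = 0.16, I₀ = 9500 lux, p = 0.6,
τ_x = 24.2 h, k = 0.55, β = 0.013, and q = 1/3 (q follows the model
lineage; it is the one constant not restated with the others).  Time is
in hours; α and β are per-minute rates, hence the factor 60.  In
darkness the realized period is 24.20 h (the 0.99729 correction makes the
nonlinear period equal τ_x); under a strong 24-h light schedule the
oscillator entrains to 24.0 h.

Because wearables record no illuminance, step counts drive the model
through a declared stand-in mapping: lux = min(1 × steps/bin, 1000),
sleep and missing bins dark.  Scale and cap are configurable and logged;
nothing downstream assumes this mapping is the true light exposure.

Integration is fixed-step classical RK4 at dt = 5 min aligned to the data
grid, with illuminance held constant within each bin and `n` clamped to
[0, 1] after each step.  Halving dt changes a 10-day dark endpoint by
< 1e−6 per component.  The initial condition is obtained by repeating the
subject's mean pre-event day of light until the state at the daily
reference time is a fixed point (< 1e−6 change per day, cap 90 days).

The daily marker is CBTmin, the time of the daily minimum of `x`, refined
parabolically through the three bracketing samples; predicted
DLMO = CBTmin − 7 h, the conventional phase relation for this model
family (configurable).

## Alignment and desynchrony statistics

The CRHR marker is shifted by a fixed −4.4 h — the population mean offset
between the two markers, taken as a constant, never re-estimated — and a
day counts as aligned when the predicted DLMO falls inside the shifted
80% interval of the CRHR phase (circular containment).  Per subject,
alignment percentages and mean absolute circular differences are computed
over the 35 days before and the 35 days after the disruption date; the
event day belongs to neither window.  Cohort level:

- paired two-sided t-test on per-subject (pre, post) alignment
  percentages, with a Wilcoxon signed-rank p reported alongside;
- per-subject phase shift = circular mean of post-window daily phases
  minus circular mean of pre-window phases (minimal signed difference),
  aggregated per age group as mean ± SEM with a one-sample t-test against
  zero and Welch t-tests between groups;
- Pearson correlation between per-day usable-bin count and interval
  half-width, pooled over subject-days (wear hours are also computed).

No multiplicity correction is applied; all p-values are reported exactly.
The choice of tests (paired t primary, Wilcoxon companion, Welch between
groups) is a design decision — the analysis being reproduced names none.

## The synthetic cohort generator

The generator emulates the structure of a 70-day social-distancing
wearable study (35 days on each side of a self-reported event date) with
known ground truth, so every stage can be checked against truth without
external data.  Per subject:

- **Activity**: a truncated-Gaussian daytime bump peaking at 15:00
  (sd 3.5 h), zero during the sleep window (23:00 + shift, 8 h), scaled
  to ~7,000 steps/day before the event and 18% fewer after, with
  multiplicative gamma noise; steps are reported once per 5-min bin.
- **Heart rate**: readings at irregular intervals (log-uniform 1–10 min,
  emulating uneven device reporting) from the cosinor model with AR(1)
  noise applied along the reading sequence.  Device-scale noise defaults:
  σ ~ U(4, 8) bpm, k ~ U(0.6, 0.85).
- **Phases**: the true HR-minimum time is drawn N(1.45, 0.5²) h, centred
  where the fixed −4.4 h marker offset lands on the pacemaker model's
  predicted DLMO (~21 h under the default schedule), so a typical
  compliant subject starts out with aligned markers — the regime the
  emulated study reports.  After the event the activity/sleep schedule
  shifts by a group-specific amount drawn Normal(group mean, group SD)
  with means (−0.93, +1.26, +0.05) h for the under-30, 30–45 and over-45
  groups and SDs (0.85, 0.45, 0.53) h; the printed dispersions are
  treated as between-subject SDs since their meaning is not stated.  A
  desynchronizing fraction of subjects (default 51/72) additionally
  drifts the HR phase alone by U(0.02, 0.12) h/day (random sign,
  cumulative, capped at 6 h), producing gradual post-event divergence of
  the two markers.
- **Missingness**: a nightly charging gap of 6–8 h overlapping the sleep
  window (probability 0.9/night), 0–3 daytime off-wrist blocks of
  0.5–2 h, and 2% random reading dropout.  A `compliant` mode disables
  everything that would fail the inclusion screens.

`simulate_day_from_params` is a separate, stricter generator used for
calibration: it produces heart rate on the 5-minute grid itself with the
AR chain restarting exactly as the likelihood assumes, so fitted model
and generating process match bin for bin and the 80% interval must cover
truth 80% of the time up to Monte-Carlo error.

What the generator does **not** emulate: heart-rate variability,
exercise bouts, meal effects, seasonality, travel or DST transitions, and
any systematic difference between devices.  Synthetic results therefore
validate the machinery (likelihood, sampler, integrator, statistics) and
its calibration under the stated model — they do not certify accuracy on
real cohort data, whose headline percentages depend on physiology the
model simplifies.

## Problem sizes used by the test suite

Checks that fit by MCMC use reduced, stated sizes chosen for accuracy at
desk scale: one-day fits at 5,000–20,000 evaluations; the calibration
check 200 prior-drawn days; effect recovery a 30-subject cohort with
7-day windows; the sampler oracle a 1-D analytic target at 10⁶
evaluations against dense-grid quadrature.  The pacemaker checks run the
full physics (20–25 simulated cycles) since they are cheap.

## Known limitations

- The activity-to-light mapping and the −7 h CBTmin→DLMO offset are
  conventions, not fitted quantities; absolute predicted DLMO times
  inherit their error.
- The moment-matched Gaussian prior transfer discards posterior
  correlations between parameters; the ×1.5 inflation is a fixed policy,
  not adaptive.
- Sleep detection is a longest-inactive-run heuristic (noon-to-noon,
  ≥ 4 h); records with genuinely fragmented sleep will be masked
  imperfectly, and masked bins are simply excluded rather than modelled.
- With very low circadian amplitude (b → 0) the phase is unidentifiable;
  the posterior then reverts toward the prior and the interval honestly
  widens to most of the circle.
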