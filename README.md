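# circwear

Circadian phase estimation from consumer wearables, and the statistics of
internal desynchrony.

Wearable devices record heart rate and step counts around the clock, and
both streams carry a readable circadian signal.  `circwear` extracts the
phase of the body clock from them along two independent routes:

1. **CRHR** — the circadian rhythm in heart rate.  Heart rate on a
   5-minute grid is modelled as

   ```
   HR_t = a − b·cos(π/12·(t − c)) + d·A_t + ε_t,    ε_{t+1} = k·ε_t + N(0, σ²)
   ```

   where `c` is the clock time of the circadian heart-rate minimum and
   `A_t` is in-bin step count.  The six parameters are fitted day by day
   with an affine-invariant ensemble MCMC sampler (100,000 target
   evaluations per day, burn-in 0.5), each day's posterior feeding the
   next day's prior, giving a daily phase estimate with an 80% circular
   credible interval.

2. **Predicted DLMO** — dim-light melatonin onset predicted by a
   limit-cycle oscillator model of the human pacemaker (a van der Pol-type
   system with photic drive, intrinsic period τ_x = 24.2 h), driven by
   step counts as a light surrogate and integrated with RK4 on the data
   grid.  The daily marker is CBTmin (the minimum of the temperature-like
   state variable); predicted DLMO = CBTmin − 7 h.

A day counts as **aligned** when the predicted DLMO falls inside the CRHR
interval shifted by the fixed population offset of −4.4 h.  Comparing
per-subject alignment percentages and phase shifts across the 35 days
before and after a disruption date (paired t-tests, group means ± SEM,
uncertainty-vs-wear-time correlation) quantifies internal desynchrony —
the drifting apart of peripheral and central circadian rhythms.

A synthetic-cohort generator with known ground truth (phases, group
shifts, desynchrony rates, charging gaps) makes the entire pipeline
testable without any external data.  See `docs/methods.md` for models,
defaults, and limitations.

## Worked example

```
$ python examples/04_alignment_report.py
subjects analyzed: 6
% days aligned  pre  61.9  ->  post  19.4   (paired t p = 0.011)
   under30 phase shift: -0.98 +/- 0.40 h (n=2)
    30to45 phase shift: +1.42 +/- 0.39 h (n=2)
    over45 phase shift: -0.27 +/- 0.44 h (n=2)
usable-bins vs phase-uncertainty correlation: r = -0.15
```

Six synthetic subjects are generated (7 days on each side of the event),
run through binning, sleep detection, sequential Bayesian CRHR fitting,
pacemaker simulation and alignment.  The drop in percent-aligned days
after the event is the generated internal desynchrony being recovered:
subjects whose heart-rate phase drifts away from their activity-predicted
DLMO lose containment.  The group rows recover the imposed schedule
shifts (−0.93, +1.26, +0.05 h population means) from 2 subjects each, and
the negative correlation mirrors the expectation that more usable data
yields tighter phase intervals.

The other examples cover each capability separately: cohort generation
(`01`), a single-day Bayesian phase fit (`02`), and the oscillator's free
run, entrainment and DLMO prediction (`03`).

There is also a thin CLI:

```
circwear simulate --seed 3 --profile fast --out sim/
circwear run-all --raw-dir sim/raw --metadata sim/metadata.csv \
        --seed 1 --profile fast --out run/
```

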