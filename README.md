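# wormwatcher

Automated behavior and aging analysis for *C. elegans* housed one-per-well in
a multiwell array and imaged by time-lapse dark-field microscopy. From raw
image sequences the package computes per-animal locomotor activity, blue-light
stimulus-evoked behavioral metrics, automated lifespans with censoring, and
statistics describing the *shape* of behavioral decline — the analyses used to
ask whether aging trajectories temporally scale with lifespan or whether
long-lived animals instead spend an extended "twilight" at low function.

It is written for experimentalists running longitudinal single-worm imaging
(aging, healthspan, and stress-resistance assays) and for anyone who needs a
fully synthetic, ground-truthed testbed for such pipelines.

## The measurements

**Activity.** For a pair of frames separated by Δt (5 s or 60 s), activity is
the number of well-ROI pixels whose normalized intensity change exceeds a
binary threshold:

    A = #{ p ∈ ROI : G_σ( |I_{t+Δt} − I_t| / Ī ) (p) > 0.25 },   σ = 1 px

where Ī is the mean intensity of the two frames over the ROI and G_σ a
Gaussian smoothing filter. Moving animals change many pixels; quiescent or
dead animals change none.

**Epoch metrics.** Recordings are organized into 30-min epochs (twice daily)
with a 10-s blue-light stimulus at the 15-min mark. Per epoch and animal:
spontaneous locomotion (max 60-s activity before the stimulus), stimulated
locomotion (max 60-s activity after it), response duration (total
post-stimulus time with nonzero 5-s activity), and response latency (delay
from stimulus end to the first nonzero 5-s activity; non-responders receive
the 900-s sentinel).

**Lifespan.** Death is called at the epoch time immediately after the last
epoch with nonzero post-stimulus activity. Wells uniformly inactive from day
2 of adulthood are censored as empty/escaped; animals still moving at the end
are right-censored. Survival curves are Kaplan–Meier estimates; groups are
compared with a two-sided Wilcoxon rank-sum test on death times.

**Decline shape.** Each animal's stimulated activity is re-expressed on a
life-fraction axis (time ÷ death time). The decline rate is the negative OLS
slope over early life (20–60%) and late life (60–100%); their difference,
the *change in decline rate* (px / life fraction), summarizes trajectory
shape, and its correlation with lifespan discriminates temporal scaling
(R ≈ 0) from extended twilight (R < 0).

A simulator generates both activity trajectories and rendered image stacks
(moving Gaussian blobs in wells, stimulus flash, pixel noise) with full
ground truth, so every stage is testable without real recordings.

## Worked example

```python
from wormwatcher import SimConfig, simulate_trajectories
from wormwatcher.lifespan import build_worm_records, survival_curve
from wormwatcher.decline import decline_summaries, rate_change_vs_lifespan

cfg = SimConfig(rows=10, cols=24, n_epochs=72, seed=0)   # 240-well device, 36 days
sim = simulate_trajectories(cfg)
records = build_worm_records(sim.metrics, sim.recording_end_h)
curve = survival_curve(records, "simulated wild type")
print(f"lifespan: {curve.mean_lifespan_h/24:.1f} +/- {curve.sd_lifespan_h/24:.1f} d "
      f"({curve.n_deaths} deaths, {curve.n_censored} censored)")

deaths = {r.well_index: r.death_time_h for r in records if not r.censored}
series = {int(w): (s.sort_values("time_h")["time_h"].to_numpy(),
                   s.sort_values("time_h")["stimulated"].to_numpy())
          for w, s in sim.metrics.groupby("well_index")}
summ = decline_summaries(series, deaths)
r, p = rate_change_vs_lifespan(summ)
print(f"rate change vs lifespan: R = {r:.2f}, p = {p:.2g}")
```

Output:

```
lifespan: 16.9 +/- 4.4 d (240 deaths, 0 censored)
rate change vs lifespan: R = -0.20, p = 0.0021
```

The simulated population ages like a wild-type one (lifespan 16.8 ± 4.4 d by
construction); the automated pipeline recovers that distribution from the
activity record alone, and the negative correlation shows that longer-lived
simulated individuals flatten out in late life (the default trajectory model
couples decline shape to lifespan) rather than stretching one common
trajectory.

A command-line interface covers the same ground from a shell:

```bash
wormwatcher simulate --config sim.yaml --out fixture/       # TIFF + truth
wormwatcher make-traces --config sim.yaml --out traces.csv  # skip rendering
wormwatcher analyze --frames rec.tif --timestamps ts.csv \
    --well-map map.yaml --schedule sched.yaml --out results/
```

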