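# Methods

This note documents the models and procedures the package implements, the
defaults it ships, the numerical choices behind them, and what the synthetic
testbed does and does not establish about real recordings.

## Activity from frame differencing

The locomotor readout is deliberately segmentation-free: for two grayscale
frames `I_t`, `I_{t+Δt}` and a circular well ROI,

1. absolute pixel-wise difference `|I_{t+Δt} − I_t|`;
2. division by the scalar mean of `(I_t + I_{t+Δt})/2` over the ROI;
3. Gaussian smoothing, σ = 1 px;
4. binary threshold at 0.25;
5. count of ROI pixels above threshold.

Differencing intervals of 5 s (fine temporal structure: latency, duration)
and 60 s (robust displacement: spontaneous/stimulated maxima, death calling)
are both computed from the same 5-s frame stream; 60-s pairs advance at the
native frame step, so "maximum 60-s activity in a window" is well defined
(disjoint pairing is available by option).

Choices worth making explicit:

* **Absolute difference.** A signed difference would under-count
  bidirectional intensity change and make activity depend on frame order;
  `|Δ|` makes it symmetric in time.
* **Per-well normalization.** The denominator is the ROI mean, not the
  whole-frame mean, because dark-field illumination is uneven across a
  plate; per-well normalization makes wells comparable. Whole-frame
  normalization is available via `norm_scope="frame"`. Either way the metric
  is exactly invariant under a global gain change applied to both frames.
* **Stimulus-frame masking.** Frames captured during the 10-s blue-light
  window carry a global flash; any frame pair overlapping that window
  measures illumination, not behavior, and is excluded from every metric.
  The boundary is asymmetric on purpose: the frame captured *at* stimulus
  onset is already flashed, so pre-stimulus windows are end-exclusive, while
  the first frame after stimulus offset is clean, so post-stimulus windows
  are start-inclusive. One consequence: in a 1800-s epoch with the stimulus
  at 900–910 s, the post-stimulus window holds at most 178 complete 5-s
  pairs, so measured response duration tops out at 890 s even though the
  nominal window is 900 s.
* **Degenerate frames.** A pair with zero mean ROI intensity yields zero
  activity plus a `RuntimeWarning`; pairs whose whole-frame mean falls
  outside configured bounds (blank/overexposed) are dropped and logged,
  never silently zeroed. Pairing tolerates timestamp jitter up to ±40% of
  the native frame interval; unmatched pairs are skipped and logged.

## Epoch schedule and behavioral metrics

The standard protocol images each plate at 0.2 frames/s for 30 min twice
daily, with a 10-s stimulus 15 min in. Per epoch:

* **spontaneous / stimulated locomotion** — maximum 60-s activity among
  pairs entirely before onset / entirely after offset. The maximum of an
  empty set is an *invalid epoch*, not zero.
* **response duration** — (count of post-stimulus 5-s pairs with activity
  > 0) × 5 s.
* **response latency** — time from stimulus *end* to the start of the first
  nonzero 5-s pair, at 5-s resolution. An animal with no post-stimulus
  movement anywhere in the 15-min window receives exactly 900 s. The
  sentinel (rather than a missing value) is what keeps population latency
  curves defined as animals age.

Continuous mode (acute-stress recordings) has no epoch gaps; stimuli recur
hourly and stimulated activity is the maximum 60-s activity in each
inter-stimulus interval (upper boundary end-exclusive, again because of the
flash).

Day-of-adulthood labels follow `day d = [24(d−1), 24d)` hours from the
configured adulthood start. Day windows for windowed means ("days 1–10")
are inclusive on both ends; epochs at or after an animal's death are
excluded, and a window an animal never reached is missing, not zero.

## Lifespan calling and censoring

Death is called from the per-epoch maximum post-stimulus 60-s activity: the
death time is the epoch time immediately after the last epoch with activity
strictly above the floor (default 0 px). Because the rule can only fire
after movement has ceased, the automated call is structurally ≤ a daily
manual inspection — the property audited by `auto_vs_manual`.

Censoring precedence, applied before death calling: an external censor list
(known escapees); then the day-2 rule — wells with zero spontaneous *and*
stimulated activity at every epoch from day 2 onward are censored as
empty/escaped and never receive a death time; then alive-at-end
right-censoring at recording end. Survival analysis is Kaplan–Meier
(censored animals leave the risk set at their censor time); the reported
mean ± SD lifespan covers uncensored deaths only. Group comparison is a
two-sided Wilcoxon rank-sum on death times (exact null distribution at
small n without ties, tie-corrected normal approximation otherwise).

The default activity floor of 0 px is justified by the imaging noise model
(below): under the 0.25 threshold at realistic pixel noise, a dead animal
registers exactly zero activity, so no extra floor is needed.

## Decline-shape statistics

Each animal's stimulated-activity record is mapped to a life-fraction axis
(`fraction = time / called death time`) and linearly interpolated onto a
uniform 50-bin grid (0.02 spacing, ending at 1.0) with no extrapolation
beyond the observed fraction range. Decline rates are negative OLS slopes
over the early (0.2–0.6) and late (0.6–1.0) windows; the change in decline
rate is late minus early.

Two numerical points matter here:

* **The death epoch is excluded from the fits.** The called death time is
  the first epoch at which the animal no longer moved; the zero recorded
  there is the absence of an animal, not a behavioral measurement. Fitting
  it (at fraction 1.0) drags the late-life slope down for every animal and,
  because the artifact's size varies with lifespan, manufactures a negative
  correlation between rate change and lifespan even under pure temporal
  scaling. `decline_summaries` therefore fits epochs strictly before death.
  `to_life_fraction` itself accepts samples at `t = lifespan` for callers
  constructing trajectories directly.
* **Axis resolution.** The fraction axis uses the automated death time,
  which overshoots the true death by up to one inter-epoch interval. The
  induced slope inflation is of order (epoch interval / lifespan) — ~3% at
  wild-type lifespans with 12-h epochs — and shrinks as lifespans grow
  relative to the epoch spacing. Statistical tests of the scaling null are
  therefore run at realistic lifespans (~17 days), not artificially
  shortened ones.

Correlation between rate change and lifespan is Pearson's R with a
two-sided p (Spearman by flag). Quartile trajectories rank animals by
lifespan with ties broken by well index and take the lowest/highest
⌈n/4⌉. The aging-vs-stress comparison offsets the stress curve by the mean
difference over the common grid, then reports 100 × mean of
`|aging − corrected stress| / mean(aging)`; normalizing by the grand mean
rather than per-bin values keeps the statistic finite near death, where
activity approaches zero, and makes it exactly invariant to any constant
shift of the stress curve.

## The simulator

The synthetic-data module defines the study conditions the tests run under.

**Lifespans** are truncated normal, default mean 16.8 d, SD 4.4 d — a
wild-type-like population.

**Trajectories** are piecewise linear in fraction space with one breakpoint
(default 0.6): baseline 250 px, early decline rate 200 px/fraction, late
rate with mean 110 px/fraction and SD 60, floored at a 25-px plateau;
spontaneous activity is half of stimulated. The per-animal change in
decline rate is `mean + SD·(c·z + √(1−c²)·ε)` with `z` the standardized
lifespan, so the coupling `c` *is* the population correlation between decline
shape and lifespan. `c = 0` with zero SD reproduces pure temporal scaling
(one shared template); the default `c = −0.32` matches a wild-type-like
extended-twilight population, and constructors for both regimes are
provided. This is the minimal model that realizes both aging hypotheses and
keeps the decline statistics identifiable.

**Stimulus responses** draw a per-animal latency (5 ± 3 s, ≥0) and duration
(120 ± 40 s, ≥5 s); the evoked level is 3× the current trajectory value.
Latency and duration are constant over an animal's life (real latencies
lengthen with age; the pipeline measures whatever is rendered either way).

**Rendering** draws each living animal as a Gaussian spot (σ = 1.6 px,
amplitude 180) on a background of 20 DN, moving as a random walk whose step
length is proportional to the current activity level (clamped to
0.8–4 px/frame), confined to its well; dead animals and empty wells are
static; stimulus frames get a +60 DN global flash; pixel noise is Gaussian,
default SD 1 DN. At 1 DN the 0.25 threshold suppresses noise with a ~6σ
margin (0 false positives in 3×10⁴ simulated static pairs); at ≥2 DN rare
noise clusters begin to cross it (~10⁻⁴ of pairs), which would let a "dead"
well twitch and break the automated-≤-manual guarantee — the package treats
that as outside the assumed operating regime rather than something the
death-call rule should absorb.

Because the changed-pixel count saturates near twice the blob area once
displacement exceeds the blob diameter, rendered activity is a monotone but
compressed function of the configured trajectory level; decline-slope
recovery is therefore validated on trajectory-level output, while rendered
output validates detection, locality, latency, and death timing.

All randomness flows from a single seed through fixed-purpose substreams
(`SeedSequence`), so trajectory draws and rendering are independently
byte-reproducible.

**What the simulator omits:** worm morphology and posture, egg/progeny
artifacts, food-lawn changes, burrowing, condensation, illumination drift,
age-dependent response latency, and plate-to-plate variation. Passing tests
show the pipeline is correct under its stated model — frame differencing of
a confined moving spot — not that real recordings are free of these
confounds.

## Problem sizes used in tests

Test simulations are sized to run on one CPU as part of a normal test
session: rendered recordings use 48 wells at 20 epochs (death calling) and
10 epochs (end-to-end), with lifespans truncated inside the recording span
so every death is observable; statistical checks of the scaling null and
the twilight alternative use trajectory-level simulation at 200 animals and
72 epochs with the wild-type lifespan distribution. The activity engine is
verified pixel-exactly against an independent brute-force implementation on
200 randomized small frames.

## Known limitations

* Well positions come from configuration; there is no image-based plate
  registration, so misaligned configs produce garbage ROIs (bounds are
  checked, alignment is not).
* The death-call floor interacts with rendering noise: above ~2 DN pixel
  noise a nonzero floor would be needed, which would in turn delay death
  calls for weakly moving animals.
* Continuous (stress) mode is analyzed from traces; the renderer models the
  epoch protocol only.
* The fraction-grid interpolation fits the gridded curve, not raw
  (fraction, value) points; for trajectories with a breakpoint between
  samples this introduces a small, lifespan-dependent chord error (well
  below the noise floor at tested sizes).
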