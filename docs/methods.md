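# Methods

This note documents the models and procedures the package implements, the
parameters that matter, what the synthetic-data generators do and do not
emulate, and the numerical and design choices made where the underlying
methods left the details open.

## Opto-tagging shuffle test

The test statistic is the pooled spike count in the most active 2-ms bin of
the (0, +100 ms] post-pulse interval across all laser pulses. The null is
generated by redistributing each pooled latency independently as
Uniform(0, 100] ms — this preserves the pooled in-window count while
destroying latency structure — and taking the maximal 2-ms bin count per
shuffle. A unit is light-responsive when its observed count *strictly
exceeds* the 99.9th percentile (linear-interpolation order statistic) of
10,000 shuffled maxima; the default shuffle count follows the recording
protocol and is overridable. Units with zero in-window spikes are reported
as non-responsive without running the test.

Binning uses a fixed half-open grid [0,2), [2,4) … [98,100) ms, with a
nanosecond-scale epsilon so that a latency computed in floating point as
3.999999… ms bins as 4 ms. The grid is deterministic and fast; a sliding
maximal window anchored at observed latencies is available via
`best_bin(..., method="sliding")` for sensitivity analyses. Response latency
is the mean pooled latency inside the winning bin, and the opto-tag call
additionally requires latency < 8 ms (strict), separating direct
channelrhodopsin activation from slower synaptic recruitment.

Under a pure Poisson null the nominal false-positive level is 0.1%; the
calibration run in the acceptance suite (500 null units, 5 Hz, 240 pulses,
1,000 shuffles each) verifies the empirical rate stays below 1%.

## Behavioural motif deduction

Labels are assigned per frame with a fixed priority: cup proximity (head
< 5 cm; ties between cups resolved to the nearer cup so each frame has a
unique label), rearing (head–body < 2 cm), then velocity class. Velocity
labels are suppressed within 7 cm of either cup. The velocity bins are
half-open and lower-inclusive — [0,1) stopping, [1,5) walking, [5,10)
trotting, [10,∞) running — a convention chosen because the written ranges
("1–5", "5–10") do not fix the boundaries.

The minimum-duration rule keeps a motif occurrence only when it persists at
least 7 frames (0.5 s at 15 frames/s). The source description of this rule
("< 7 frames") contradicts its own parenthetical; it is implemented as
≥ 7 frames and is configurable. Turning (head axis > 15° off the tail→body
axis) is counted once per super-threshold excursion on a separate channel
rather than segmented, and may co-occur with velocity labels. Frames with
any keypoint likelihood below 0.85 (inclusive boundary: exactly 0.85 is
kept) are invalid: they get no label and break runs rather than being
interpolated, which keeps the minimum-duration rule meaningful.

**Velocity smoothing.** Speed is the frame-to-frame displacement of the
body centre times the frame rate. Raw per-frame differencing turns
independent keypoint jitter of σ cm into a positively biased speed error of
order √2·σ·fs — at 15 frames/s, 0.3 cm of jitter alone reads as ~8 cm/s,
swamping every velocity class. The labelling pipeline therefore smooths the
body trajectory with a centred 1-s moving average before differencing
(`MotifConfig.velocity_smooth_s`; the raw definition is available by
setting it to 0). Constant-velocity motion is invariant under this
smoothing, so the rule's calibration examples are unchanged.

## Synthetic pose sessions

`generate_pose_session` realises a scripted state sequence so each state's
geometric definition holds with margin: feeding/empty-cup places the head
2 cm from the cup (body 5 cm, so the posture is not rearing); rearing puts
the head 0.5 cm from the body far from both cups; locomotion follows a
circle around the arena centre at the class-midpoint speed (walking
3 cm/s, trotting 7.5, running 15), with the head 3.5 cm ahead along the
tangent. The circle radius is chosen so the whole path stays > 9 cm from
either cup; in a 25-cm feeding chamber this leaves only a small-radius
path whose curvature distorts smoothed speed for the faster classes, so
locomotion-heavy scripts should use an open-field-style 50-cm arena (the
pipeline default).

Ground-truth labels are `None` where the script itself does not define an
instantaneous velocity: within 1 s (`transition_blank_s`) of the boundaries
of each velocity-class segment, the displacement — raw or smoothed — mixes
motion across a scripted relocation or speed step. Proximity-defined states
keep their truth to the boundary. Accuracy metrics are computed over frames
with defined truth; on noise-free scripts frame-label agreement is exactly
100%, and with 0.3 cm isotropic keypoint jitter it stays above 95%
(additionally excluding ±1 frame around truth transitions, where tracking
noise makes single-frame flips unavoidable).

The generator adds isotropic Gaussian jitter after geometric placement and
simulates tracking dropout by drawing likelihoods below 0.85 at a
configurable rate. It does not render video, model gait dynamics, or
produce curved approach trajectories between states (state changes are
instantaneous relocations) — passing tests therefore demonstrate rule
recovery under jitter and dropout, not robustness to real pose-estimator
failure modes such as identity swaps or systematic occlusion.

## Feeding bouts and clock alignment

Bout merging is greedy left-to-right chaining: an inter-activation gap
≤ 6 s (boundary inclusive — only a gap *larger than* 6 s breaks) joins,
and chains with ≥ 2 activations become bouts spanning first to last
activation. No minimum bout duration is imposed and no tail is appended
after the final activation, so a two-activation bout can be shorter than a
second. The implementation is verified against an independent O(n²)
interval-closure oracle, including trains engineered to hit the exact-6-s
boundary. Clock alignment is a least-squares affine fit (offset + drift) to
matched TTL pairs, reporting the RMS residual.

## IR/DR classification

Each event contributes one (pre, post) rate pair per unit; the test is a
two-sided Wilcoxon signed-rank on the differences. Zero differences are
dropped before ranking (the reported n counts non-zero differences). For up
to 25 non-zero differences the p value is exact: the full null distribution
of the positive-rank sum is built by dynamic programming over the signed
(possibly tied, mid-)ranks, doubled to integers — equivalent to complete
2ⁿ sign-flip enumeration, which the tests verify directly for n ≤ 8.
Above 25 a normal approximation with continuity and tie correction is used.
The in-package implementation exists because standard exact routines do not
admit tied ranks; scipy's exact test serves as an independent cross-check
on tie-free inputs.

Direction is taken from the mean of post vs pre rates (median optional).
Pre/post windows of back-to-back events may overlap; they are flagged but
not excluded. Group IR/DR/NR proportions are compared per motif with a
chi-squared test without Yates correction, Bonferroni-corrected by the
number of motifs tested in the session. With 20 events and a 5→10 Hz
event-locked step the IR call rate exceeds 90%, while null units produce
IR∪DR calls at the nominal 5% within binomial error (1,000 simulated
units).

## Fluorescence processing

Reference-ROI correction divides the signal ROI by a reference ROI drawn
away from sensor-expressing tissue (reference in the denominator), then
forms ΔF/F against the mean pre-stimulation ratio; a multiplicative
common-mode artifact cancels exactly. Photobleach correction excises the
window around stimulation (default: onset to +5 s in the pipeline, i.e.
covering the post-stimulation response window), smooths each retained
segment with a centred moving average (default 1 s, forced to an odd sample
count to avoid a half-sample phase shift; ends are padded by odd reflection,
which preserves linear trends exactly), fits a polynomial (default cubic)
to the smoothed retained samples, evaluates it across the whole trace
including the gap, and subtracts it from the *original* ΔF/F. Excised
samples never enter the fit — perturbing them leaves the trendline
bit-identical, which a test asserts.

AUC is a composite trapezoid with the partial end intervals linearly
interpolated, exact for piecewise-linear signals and within 1e-5 of closed
forms at 1 kHz sampling. Peri-event analysis z-scores each trial against
its own baseline window (default −10..0 s) on a common relative-time grid
and reports the trial matrix, mean and s.e.m.; fixed AUC windows are
−3..−1, 0..2 and 3..5 s. On 20-s slice-style traces with mono-exponential
bleach (τ = 10–100 s) and transients of 0.02–0.10 ΔF/F at 10% noise, the
recovered transient AUC is biased by < 10% (typically < 5%) — a cubic
cannot absorb much faster bleach (τ ≤ 5 s) over longer traces, in which
case a higher polynomial order or shorter fitting span is needed.

Injection responses are linearly detrended on the −500..0 s pre-injection
baseline, z-scored against it, and integrated over −500..0 and
1500..2000 s. Because the trend is extrapolated ~1,750 s beyond the
baseline, slope-estimation noise dominates the post-injection AUC variance
for near-flat traces; the baseline F₀ for slice ΔF/F is the
pre-stimulation mean (the trendline value is the plausible alternative).

## FISH cell calling

All histograms share one fixed bin grid — 64 bins over the observed
intensity range by default — because the Pearson R between a cell's
normalised histogram and the null depends on binning; the bin count is
pinned in config and carried in the output. The null pools pixels from
putatively negative cells; the default selector takes the lowest decile of
per-cell mean intensity (pluggable, since the negative-selection rule is
otherwise unspecified) and requires at least 10 cells. Positivity is
R < 0.85, strict at the boundary. The per-cell percentage of positive
pixels uses a background threshold at the null's 97.5th percentile
(configurable). R is invariant under common rescaling of all intensities
with bins rescaled alongside, which the tests assert exactly. Manual ROI
curation is represented as an exclusion list at ingestion, not an
algorithm; nucleus segmentation itself is upstream input (label masks).

## Expression QC

The cell filter is one-sided and robust: keep a cell iff its total reads
and detected-gene count are each ≥ median − 3·MAD, with *unscaled* MAD (no
1.4826 normality factor) since the rule is stated directly in MAD units;
both choices are configurable. The gene filter runs on CPM: keep a gene iff
strictly more than 15 CPM in at least 5 cells and mean CPM strictly above
4. Boundary semantics follow the wording ("above", "higher than" strict;
"at least" inclusive). Both filters are verified against an element-wise
brute-force re-implementation on random negative-binomial matrices.

## Assays

Consumption is pre-minus-post cup weight, clipped at zero with a warning
(evaporation/spillage is not negative eating). Caloric intake multiplies by
the packaged kcal/g table (jelly 2.5, butter 7.14, peanut butter 6.39,
chocolate 4.88, regular chow 3.02, high-fat chow 5.24). Home-cage weekly
consumption divides by cage occupancy. RTPP occupancy assigns frames by the
body-centre coordinate with the neutral band inclusive at its edges, swaps
the stimulation side at 10 min, and reports per-phase and pooled times,
which partition tracked time exactly. Centre time uses the centred
33 × 33 cm box of a 50-cm chamber, edges inclusive.

## End-to-end pipeline and problem sizes

`run_pipeline` chains generation → motif segmentation → piezo bouts →
opto-tagging → IR/DR classification per configured condition and, with two
conditions, compares IR proportions per motif. The default session script
interleaves 20 six-second feeding bouts with 7-s locomotion segments
(piezo bouts stay separable under the 6-s rule, and ~20 events per motif
give the signed-rank test realistic power), preceded by a varied preamble.
Default conditions contrast a feeding-locked spike-rate gain of 2.0 vs 1.0
at 15–20 units each, which reliably yields a Bonferroni-significant
chi-squared difference in feeding IR proportions. Validation runs use
1,000-shuffle opto-tag tests and the simulation sizes quoted above
(500 + 100 opto units, 1,000 bout trains, 1,000 null units, 3 × 3 × 30
photometry grid, 200 + 200 FISH cells, 100 QC matrices); the full
validation completes in well under a minute on one CPU. All generators are
deterministic given (params, seed), with independent per-call random
streams so adding one generator call does not shift another's output.

## Known limitations

- Motif velocity classes rely on trajectory smoothing; pathological
  tracking (identity swaps, long occlusions) is out of the generators'
  scope and untested.
- The exact signed-rank null assumes exchangeability of signs; it is exact
  under the paired-null hypothesis but, like the original procedure, treats
  events within a unit as independent pairs.
- Photobleach correction assumes a polynomial can track the bleach over the
  analysed span; very fast bleach over long traces needs a shorter span or
  higher order.
- The FISH caller's R threshold interacts with bin count and the negative
  selector; results should always be reported with those settings, and the
  defaults here are one reasonable pinning, not a canonical one.
- Isosbestic-channel regression, spike sorting, pose-network training,
  pseudo-alignment and differential expression are out of scope; the
  package consumes their outputs.
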