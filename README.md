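# hedonifeed

Analysis pipeline for studies of hedonic feeding that combine in vivo
electrophysiology with optogenetics, video-based behaviour tracking, piezo
feeding sensors, fluorescent neuropeptide-sensor imaging, RNAscope in situ
hybridization, and patch-seq transcriptomics. The package re-implements the
bespoke desk-side analysis chain such experiments require as a tested,
reusable library with ground-truthed synthetic data generators, so every
detector can be validated end-to-end without access to recordings.

## What it computes

**Opto-tagging** (`hedonifeed.optotag`). A unit recorded during 2-Hz laser
stimulation is *light-responsive* when the spike count in its most active
2-ms bin within (0, +100 ms] of pulse onset exceeds the 99.9th percentile of
the same statistic under 10,000 uniform within-window shuffles of the pooled
post-pulse spike latencies; it is *opto-tagged* when, additionally, the mean
latency in that bin is < 8 ms.

**Behavioural motifs** (`hedonifeed.motifs`). Per-frame nose/head/body/tail
keypoints (15 frames/s) become motif labels by rule priority: feeding or
empty-cup when the head is < 5 cm from a cup; rearing when the head–body
distance is < 2 cm; otherwise a velocity class (stopping < 1, walking 1–5,
trotting 5–10, running > 10 cm/s), suppressed within 7 cm of either cup.
Frames with any keypoint likelihood < 0.85 are invalid, occurrences shorter
than 7 frames (0.5 s) are discarded, and head turns > 15° off the body axis
are counted per excursion.

**Feeding bouts** (`hedonifeed.piezo`). Piezo food-cup activations chain
into bouts: ≥ 2 activations with no inter-activation gap > 6 s; total
feeding time is the summed bout span. TTL-based least-squares clock
alignment maps sensor time onto the recording system.

**IR/DR unit classification** (`hedonifeed.unit_response`). Per unit and
motif, firing rates in (−3, 0) s vs (0, +3) s around event onsets are
compared with a two-sided Wilcoxon signed-rank test (exact null up to 25
non-zero differences): IR if *p* < 0.05 with event > pre-event rate, DR for
the opposite direction, NR otherwise. Group proportions are compared by
chi-squared with Bonferroni correction across motifs.

**Fluorescence traces** (`hedonifeed.photometry`). Reference-ROI division to
ΔF/F, photobleach correction by excising the stimulation window and
subtracting a polynomial trendline fit through the smoothed remainder,
trapezoidal AUC (baseline −3..−1 s, stimulation 0..2 s, post 3..5 s),
per-trial z-scored peri-event analysis over −10..+30 s, and slow
injection-response AUC (−500..0 vs 1500..2000 s).

**mRNA cell calling** (`hedonifeed.fish`). Each nucleus' pixel-intensity
histogram is correlated against a pooled *null distribution* built from
putatively negative cells; a cell with Pearson R < 0.85 is called positive
for the targeted transcript.

**Patch-seq QC** (`hedonifeed.expression_qc`). Cells more than 3 MAD below
the median in reads or detected genes are excluded; after CPM normalisation
a gene is kept when ≥ 5 cells have CPM > 15 and its mean CPM exceeds 4.

**Assays** (`hedonifeed.assays`). Cup-weight food consumption and caloric
intake, real-time place-preference zone occupancy with the 10-min
stimulation-side swap, and open-field centre time (33 × 33 cm of a 50-cm
chamber).

## Worked example

```python
import numpy as np
from hedonifeed.synthetic import SpikeSimParams, generate_spike_session
from hedonifeed.optotag import tag_unit
from hedonifeed.piezo import merge_bouts

pulses = np.arange(240) / 2.0  # 2 Hz opto-tagging train
params = SpikeSimParams(baseline_rate=5.0, light_response_prob=0.5,
                        light_latency_ms=4.0, latency_jitter_ms=0.5,
                        duration_s=125.0)
spikes, evoked = generate_spike_session(params, pulses, seed=42)
res = tag_unit(spikes, pulses, n_shuffles=10_000, seed=43)
print(f"spikes: {spikes.size} ({int(evoked.sum())} evoked)")
print(f"best 2-ms bin: [{res.best_bin_start_ms:.0f}, {res.best_bin_start_ms+2:.0f}) ms, "
      f"count {res.best_bin_count} (99.9th null percentile {res.null_p999:.1f})")
print(f"latency {res.latency_ms:.2f} ms -> light-responsive={res.is_light_responsive}, "
      f"opto-tagged={res.is_opto_tagged}")

bouts = merge_bouts([3.0, 4.1, 8.0, 21.0, 22.5, 24.0, 40.0])
for b in bouts.bouts:
    print(f"bout {b.start_s:.1f}-{b.end_s:.1f} s ({b.n_activations} activations)")
print(f"total feeding time: {bouts.total_feeding_time_s:.1f} s")
```

prints

```
spikes: 766 (125 evoked)
best 2-ms bin: [2, 4) ms, count 65 (99.9th null percentile 17.0)
latency 3.58 ms -> light-responsive=True, opto-tagged=True
bout 3.0-8.0 s (3 activations)
bout 21.0-24.0 s (3 activations)
total feeding time: 8.0 s
```

The simulated unit fires ~5 Hz plus one light-evoked spike on half the
pulses at 4 ± 0.5 ms; its best post-pulse bin holds 65 spikes where chance
(the shuffle null) allows 17, and the 3.6-ms latency is below the 8-ms
direct-activation cut, so the unit is opto-tagged. The third lone piezo
activation at 40 s forms no bout (a bout needs at least two activations).

A command-line interface mirrors the library: `hedonifeed simulate`,
`optotag`, `motifs`, `piezo`, `respond`, `photometry`, `fishcall`, `exprqc`
and `run` (the end-to-end synthetic pipeline driver); see
`hedonifeed --help`.

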