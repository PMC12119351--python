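"""End-to-end synthetic-session driver.

Chains the generators and detectors into one reproducible run: simulate a
scripted arena session with feeding-locked spiking and laser pulses, segment
motifs from the pose track, merge piezo activations into bouts, opto-tag
each unit, classify IR/DR/NR responses per motif, and (when two diet-like
conditions are configured) compare response proportions between conditions
with a Bonferroni-corrected chi-squared test.

Every stage writes a CSV into the output directory and the run emits a
provenance log with versions, seeds, and every threshold used.
"""

from __future__ import annotations

import json
import sys
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import __version__, config as _config, io as _io
from .config import MotifConfig
from .motifs import ArenaConfig, segment_track, write_dlc_csv
from .optotag import tag_unit
from .piezo import merge_bouts
from .synthetic import (
    SpikeSimParams,
    generate_piezo_train,
    generate_pose_session,
    generate_spike_session,
)
from .unit_response import (
    call_table,
    classify_response,
    compare_proportions,
    peri_event_rates,
)

__all__ = ["PipelineConfig", "SessionResult", "run_session", "run_pipeline"]

# a 50-cm open-field-style chamber leaves room for all locomotion classes
DEFAULT_ARENA = ArenaConfig(
    chamber_size_cm=(50.0, 50.0),
    cup_food_xy=(5.0, 5.0),
    cup_empty_xy=(45.0, 45.0),
)

# a varied preamble, then 20 feeding bouts interleaved with locomotion:
# ~20 events per motif gives the signed-rank test realistic power, and the
# 7-s non-feeding gaps keep piezo bouts separable (>6 s rule)
DEFAULT_SCRIPT: Tuple[Tuple[str, float], ...] = (
    ("rearing", 10.0),
    ("stopping", 10.0),
    ("trotting", 10.0),
    ("running", 10.0),
) + tuple(
    seg for _ in range(20) for seg in (("feeding_jelly", 6.0), ("walking", 7.0))
)


@dataclass
class ConditionConfig:
    """One simulated recording condition (e.g. a diet group)."""

    name: str = "REG"
    n_units: int = 20
    baseline_rate_hz: float = 5.0
    feeding_gain: float = 2.0  # event-locked rate multiplier during feeding
    light_response_prob: float = 0.5


@dataclass
class PipelineConfig:
    seed: int = 0
    out_dir: str = "pipeline_out"
    fs: float = 15.0
    script: Sequence[Tuple[str, float]] = DEFAULT_SCRIPT
    pose_noise_cm: float = 0.3
    pulse_hz: float = 2.0
    n_pulses: int = 240
    n_shuffles: int = 1000
    alpha: float = 0.05
    conditions: List[ConditionConfig] = field(
        default_factory=lambda: [
            ConditionConfig(name="REG", feeding_gain=2.0),
            ConditionConfig(name="HFD", feeding_gain=1.0),
        ]
    )

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "script" in d:
            d["script"] = [tuple(s) for s in d["script"]]
        if "conditions" in d:
            d["conditions"] = [ConditionConfig(**c) for c in d["conditions"]]
        return cls(**d)


@dataclass
class SessionResult:
    condition: str
    motif_events: pd.DataFrame
    bouts: pd.DataFrame
    optotag: pd.DataFrame
    calls: pd.DataFrame


def _session_duration(script) -> float:
    return float(sum(d for _, d in script))


def run_session(
    cfg: PipelineConfig,
    cond: ConditionConfig,
    out_dir: Optional[Path] = None,
    seed_offset: int = 0,
) -> SessionResult:
    """Simulate and analyse one condition's session."""
    seed = cfg.seed + seed_offset
    duration = _session_duration(cfg.script)
    arena = DEFAULT_ARENA

    # --- simulate pose + segment motifs
    track, _truth = generate_pose_session(
        cfg.script, arena, fs=cfg.fs, noise_cm=cfg.pose_noise_cm, seed=seed
    )
    seg = segment_track(track, arena)
    events = seg.events_df(cfg.fs)
    feeding_onsets = events.loc[events["label"] == "feeding", "onset_s"].to_numpy()

    # --- simulate piezo from the scripted feeding segments
    t = 0.0
    script_bouts = []
    for state, dur in cfg.script:
        if state.startswith("feeding"):
            script_bouts.append((t, t + dur))
        t += dur
    piezo_times = generate_piezo_train(script_bouts, intra_rate=1.0, seed=seed + 1)
    fb = merge_bouts(piezo_times)
    bouts_df = pd.DataFrame(
        {
            "bout_start_s": [b.start_s for b in fb.bouts],
            "bout_end_s": [b.end_s for b in fb.bouts],
            "n": [b.n_activations for b in fb.bouts],
        }
    )

    # --- opto-tagging session appended after behaviour
    pulses = duration + 5.0 + np.arange(cfg.n_pulses) / cfg.pulse_hz
    session_len = float(pulses[-1] + 1.0)

    tag_rows, call_rows = [], []
    for u in range(cond.n_units):
        params = SpikeSimParams(
            baseline_rate=cond.baseline_rate_hz,
            event_gain=cond.feeding_gain,
            light_response_prob=cond.light_response_prob,
            duration_s=session_len,
        )
        spikes, _ = generate_spike_session(
            params,
            pulse_onsets_s=pulses,
            events=[(float(o), "feeding") for o in feeding_onsets],
            seed=seed + 100 + u,
        )
        uid = f"{cond.name}_u{u:03d}"
        res = tag_unit(
            spikes, pulses, unit_id=uid, n_shuffles=cfg.n_shuffles, seed=seed + 500 + u
        )
        tag_rows.append(
            {
                "unit_id": uid,
                "best_bin_start_ms": res.best_bin_start_ms,
                "best_bin_count": res.best_bin_count,
                "null_p999": res.null_p999,
                "latency_ms": res.latency_ms,
                "light_responsive": res.is_light_responsive,
                "opto_tagged": res.is_opto_tagged,
            }
        )
        for motif in sorted(events["label"].unique()):
            onsets = events.loc[events["label"] == motif, "onset_s"].to_numpy()
            onsets = onsets[onsets >= 3.0]
            if onsets.size == 0:
                continue
            pairs = peri_event_rates(spikes, onsets, unit_id=uid, motif=motif)
            call_rows.append(classify_response(pairs, alpha=cfg.alpha))
    tags_df = pd.DataFrame(tag_rows)
    calls_df = call_table(call_rows)

    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
        write_dlc_csv(track, out_dir / f"{cond.name}_pose.csv", arena)
        events.to_csv(out_dir / f"{cond.name}_motif_events.csv", index=False)
        bouts_df.to_csv(out_dir / f"{cond.name}_bouts.csv", index=False)
        tags_df.to_csv(out_dir / f"{cond.name}_optotag.csv", index=False)
        calls_df.to_csv(out_dir / f"{cond.name}_response_calls.csv", index=False)
    return SessionResult(cond.name, events, bouts_df, tags_df, calls_df)


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run every configured condition and summarise; returns the summary."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    results = [
        run_session(cfg, cond, out, seed_offset=1000 * i)
        for i, cond in enumerate(cfg.conditions)
    ]

    summary: dict = {"version": __version__, "seed": cfg.seed, "conditions": {}}
    for res in results:
        counts = (
            res.calls.groupby(["motif", "class"]).size().unstack(fill_value=0)
        )
        summary["conditions"][res.condition] = {
            "n_bouts": int(len(res.bouts)),
            "n_motif_events": int(len(res.motif_events)),
            "pct_opto_tagged": 100.0 * float(res.optotag["opto_tagged"].mean()),
            "response_counts": {
                m: {c: int(counts.loc[m].get(c, 0)) for c in ("IR", "DR", "NR")}
                for m in counts.index
            },
        }

    if len(results) == 2:
        motifs_all = sorted(
            set(results[0].calls["motif"]) & set(results[1].calls["motif"])
        )
        comparisons = {}
        for motif in motifs_all:
            table = []
            for res in results:
                sub = res.calls[res.calls["motif"] == motif]
                ir = int((sub["class"] == "IR").sum())
                table.append([ir, len(sub) - ir])
            comparisons[motif] = compare_proportions(
                np.asarray(table), n_comparisons=len(motifs_all)
            )
        summary["ir_proportion_tests"] = comparisons

    summary["provenance"] = {k: str(v) for k, v in _config.provenance().items()}
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, default=str)
    print(f"pipeline complete: {out / 'summary.json'}", file=sys.stderr)
    return summary
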