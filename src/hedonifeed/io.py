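"""CSV readers and writers for the event-table dialects the pipeline uses.

Spike and TTL event tables are plain one-or-two-column CSVs; pose tracks use
the three-header-row DLC dialect handled in :mod:`~hedonifeed.motifs`;
traces are (time_s, signal[, reference]) CSVs.
"""

from __future__ import annotations

from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd

from .photometry import Trace

__all__ = [
    "read_spike_csv",
    "write_spike_csv",
    "read_pulse_csv",
    "write_pulse_csv",
    "read_event_csv",
    "write_event_csv",
    "read_trace_csv",
    "write_trace_csv",
]


def read_spike_csv(path) -> Dict[str, np.ndarray]:
    """Spike CSV (unit_id, timestamp_s) -> {unit_id: sorted timestamps}."""
    df = pd.read_csv(path)
    return {
        str(uid): np.sort(grp["timestamp_s"].to_numpy(dtype=float))
        for uid, grp in df.groupby("unit_id", sort=True)
    }


def write_spike_csv(units: Dict[str, np.ndarray], path) -> None:
    rows = [
        {"unit_id": uid, "timestamp_s": t} for uid, ts in units.items() for t in ts
    ]
    pd.DataFrame(rows, columns=["unit_id", "timestamp_s"]).to_csv(path, index=False)


def read_pulse_csv(path) -> Tuple[np.ndarray, float]:
    """Pulse CSV (onset_s, width_ms) -> (onsets, width_ms)."""
    df = pd.read_csv(path)
    width = float(df["width_ms"].iloc[0]) if "width_ms" in df and len(df) else 5.0
    return np.sort(df["onset_s"].to_numpy(dtype=float)), width


def write_pulse_csv(onsets_s, path, width_ms: float = 5.0) -> None:
    pd.DataFrame({"onset_s": onsets_s, "width_ms": width_ms}).to_csv(path, index=False)


def read_event_csv(path) -> pd.DataFrame:
    """Event CSV with onset_s [, offset_s, label] columns."""
    return pd.read_csv(path)


def write_event_csv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def read_trace_csv(path, fs: Optional[float] = None) -> Tuple[Trace, Optional[Trace]]:
    """Trace CSV (time_s, signal[, reference]) -> (signal, reference|None)."""
    df = pd.read_csv(path)
    t = df["time_s"].to_numpy(dtype=float)
    if fs is None:
        fs = 1.0 / float(np.median(np.diff(t)))
    sig = Trace(t_s=t, f=df["signal"].to_numpy(dtype=float), fs=fs)
    ref = None
    if "reference" in df:
        ref = Trace(t_s=t, f=df["reference"].to_numpy(dtype=float), fs=fs)
    return sig, ref


def write_trace_csv(trace: Trace, path, reference: Optional[Trace] = None) -> None:
    data = {"time_s": trace.t_s, "signal": trace.f}
    if reference is not None:
        data["reference"] = reference.f
    pd.DataFrame(data).to_csv(path, index=False)


def read_counts(path, genes_path=None, cells_path=None) -> pd.DataFrame:
    """Gene x cell count matrix from TSV or MatrixMarket triplet format.

    For ``.mtx`` input, optional side files give one gene/cell id per line;
    otherwise positional ids are generated.
    """
    path = str(path)
    if path.endswith(".mtx"):
        from scipy.io import mmread

        mat = mmread(path).toarray()
        genes = (
            [l.strip() for l in open(genes_path)]
            if genes_path
            else [f"g{i}" for i in range(mat.shape[0])]
        )
        cells = (
            [l.strip() for l in open(cells_path)]
            if cells_path
            else [f"c{i}" for i in range(mat.shape[1])]
        )
        return pd.DataFrame(mat, index=genes, columns=cells)
    return pd.read_csv(path, sep="\t", index_col=0)


def write_counts_mtx(counts: pd.DataFrame, mtx_path, genes_path, cells_path) -> None:
    from scipy.io import mmwrite
    from scipy.sparse import coo_matrix

    mmwrite(str(mtx_path), coo_matrix(counts.to_numpy()))
    with open(genes_path, "w") as fh:
        fh.write("\n".join(map(str, counts.index)) + "\n")
    with open(cells_path, "w") as fh:
        fh.write("\n".join(map(str, counts.columns)) + "\n")
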