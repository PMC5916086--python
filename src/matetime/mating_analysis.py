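"""Fusion detection and fusion-aligned expression analysis for mating movies.

In a mating mixture the MATalpha partner constitutively expresses an infrared
fluorescent protein (tdiRFP).  When a MATa cell fuses with its partner the
tdiRFP floods into it, producing a sudden step in its average nuclear tdiRFP
signal.  A cell is *fusing* if any frame-to-frame increase exceeds the jump
threshold (default 50 AU); it is *non-fusing* if its signal never rises by
more than the flat threshold (default 10 AU) over the whole track.  Cells in
between are *indeterminate* and excluded from both groups.  Only cells tracked
for at least 10 frames are classified.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd


class FusionStatus(str, Enum):
    FUSING = "fusing"
    NON_FUSING = "non_fusing"
    INDETERMINATE = "indeterminate"
    EXCLUDED = "excluded"  # track too short to classify


@dataclass(frozen=True)
class FusionConfig:
    """Thresholds of the tdiRFP step detector (fluorescence AU / frames)."""

    jump: float = 50.0
    flat: float = 10.0
    min_track_frames: int = 10
    window: int = 1  # frames over which a "sudden increase" is evaluated


@dataclass
class FusionRecord:
    cell_id: object
    status: FusionStatus
    fusion_time: float | None  # minutes, present iff fusing
    track_length: int


def detect_fusion(
    times: np.ndarray,
    tdirfp_nuclear: np.ndarray,
    cfg: FusionConfig | None = None,
    cell_id: object = None,
) -> FusionRecord:
    """Classify one cell from its nuclear tdiRFP series.

    The step test uses the difference over ``cfg.window`` frames (default one
    frame: at 5-min sampling, fusion is effectively instantaneous).  The
    fusion time is the first frame at which the increase has occurred.  The
    non-fusing test uses the maximal forward increase max_{i<j}(F_j - F_i);
    both tests depend only on differences, so the detector is invariant to any
    constant fluorescence offset and to shifting the time axis.
    """
    cfg = cfg or FusionConfig()
    times = np.asarray(times, dtype=float)
    f = np.asarray(tdirfp_nuclear, dtype=float)
    n = f.size
    if n != times.size:
        raise ValueError("times and series differ in length")
    if n < cfg.min_track_frames:
        return FusionRecord(cell_id, FusionStatus.EXCLUDED, None, n)
    w = cfg.window
    jumps = f[w:] - f[:-w]
    if np.any(jumps > cfg.jump):
        first = int(np.argmax(jumps > cfg.jump))
        return FusionRecord(cell_id, FusionStatus.FUSING, float(times[first + w]), n)
    running_min = np.minimum.accumulate(f)
    max_forward_rise = float(np.max(f - running_min))
    if max_forward_rise <= cfg.flat:
        return FusionRecord(cell_id, FusionStatus.NON_FUSING, None, n)
    return FusionRecord(cell_id, FusionStatus.INDETERMINATE, None, n)


def detect_fusion_table(
    table: pd.DataFrame, cfg: FusionConfig | None = None
) -> pd.DataFrame:
    """Run :func:`detect_fusion` per cell on the tdiRFP channel of a trace table."""
    sub = table[table["channel"] == "tdiRFP"]
    if len(sub) == 0:
        raise ValueError("table has no tdiRFP channel")
    rows = []
    for cell_id, cell in sub.groupby("cell_id", sort=True):
        cell = cell.sort_values("frame_time")
        rec = detect_fusion(
            cell["frame_time"].to_numpy(),
            cell["nuclear_mean"].to_numpy(dtype=float),
            cfg,
            cell_id,
        )
        rows.append(
            {
                "cell_id": rec.cell_id,
                "status": rec.status.value,
                "fusion_time": np.nan if rec.fusion_time is None else rec.fusion_time,
                "track_length": rec.track_length,
            }
        )
    return pd.DataFrame(rows)


def align_to_fusion(
    corrected: dict[object, tuple[np.ndarray, np.ndarray]],
    fusion: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Shift each fusing cell's trace so that its fusion frame is time 0.

    ``corrected`` maps cell_id to (times, corrected enrichment).  Returns the
    long-format aligned traces (cell_id, relative_time, corrected) and
    per-relative-time median and quartile bands over the cells present in each
    time bin.
    """
    fusing = fusion[fusion["status"] == FusionStatus.FUSING.value]
    if len(fusing) == 0:
        raise ValueError("no fusing cells to align")
    rows = []
    for _, rec in fusing.iterrows():
        cid = rec["cell_id"]
        if cid not in corrected:
            continue
        times, values = corrected[cid]
        rel = np.asarray(times, dtype=float) - float(rec["fusion_time"])
        for t, v in zip(rel, values):
            rows.append({"cell_id": cid, "relative_time": float(t), "corrected": float(v)})
    aligned = pd.DataFrame(rows)
    bands = (
        aligned.groupby("relative_time")["corrected"]
        .agg(
            median="median",
            q25=lambda v: v.quantile(0.25),
            q75=lambda v: v.quantile(0.75),
            n_cells="count",
        )
        .reset_index()
    )
    return aligned, bands


def response_time_rel_fusion(
    timing: pd.DataFrame, fusion: pd.DataFrame
) -> pd.DataFrame:
    """Response time minus fusion time per fusing, expressing cell.

    Negative values mean the promoter fired before fusion.  Cells without a
    response time are omitted from the values but counted in the returned
    frame's ``attrs['n_omitted']``.
    """
    fusing = fusion[fusion["status"] == FusionStatus.FUSING.value].set_index("cell_id")
    t = timing.set_index("cell_id")
    common = t.index.intersection(fusing.index)
    sub = t.loc[common]
    has_rt = sub["expressing"].astype(bool) & sub["response_time"].notna()
    rel = (
        sub.loc[has_rt, "response_time"]
        - fusing.loc[sub.index[has_rt], "fusion_time"]
    ).astype(float)
    out = pd.DataFrame(
        {"cell_id": rel.index, "channel": sub.loc[rel.index, "channel"],
         "rt_minus_fusion": rel.to_numpy()}
    ).reset_index(drop=True)
    out.attrs["n_omitted"] = int((~has_rt).sum())
    return out


def mating_corrected_traces(
    table: pd.DataFrame, channel: str
) -> dict[object, tuple[np.ndarray, np.ndarray]]:
    """Per-cell corrected enrichment for tracks with heterogeneous windows.

    On a mating pad there is no global stimulation time, so each cell's basal
    level is taken from the first three frames of its own track; the corrected
    trace is the smoothed enrichment minus that basal.
    """
    from .expression_timing import preprocess_trace

    sub = table[table["channel"] == channel]
    if len(sub) == 0:
        raise ValueError(f"channel {channel!r} absent from table")
    out: dict[object, tuple[np.ndarray, np.ndarray]] = {}
    for cell_id, cell in sub.groupby("cell_id", sort=True):
        cell = cell.sort_values("frame_time")
        times = cell["frame_time"].to_numpy(dtype=float)
        raw = (cell["nuclear_mean"] - cell["cytoplasmic_mean"]).to_numpy(dtype=float)
        if times.size < 5:
            continue  # cannot support 3 basal + 2 post frames
        ct = preprocess_trace(raw, times, cell_id, channel, stimulation_time=times[2])
        out[cell_id] = (times, ct.corrected)
    return out


def mating_timing_table(
    table: pd.DataFrame,
    channel: str,
    expressing_fraction: float = 0.2,
    response_fraction: float = 0.2,
) -> pd.DataFrame:
    """Timing records for mating movies (per-track basal, absolute-time reference).

    The population-averaged output is the max over absolute-time frames of the
    pointwise mean corrected trace over cells present in each frame; the
    response-time search for each cell starts after its own basal window.
    """
    from .expression_timing import classify_expressing, response_time

    corrected = mating_corrected_traces(table, channel)
    if not corrected:
        raise ValueError("no usable tracks")
    long_rows = []
    outputs = {}
    for cid, (times, values) in corrected.items():
        post = times > times[2]
        outputs[cid] = float(values[post].max())
        long_rows.append(pd.DataFrame({"frame_time": times, "corrected": values}))
    pooled = pd.concat(long_rows, ignore_index=True)
    pop_output = float(pooled.groupby("frame_time")["corrected"].mean().max())
    out_series = pd.Series(outputs)
    expressing = classify_expressing(out_series, pop_output, expressing_fraction)
    records = []
    for cid, (times, values) in corrected.items():
        rt = np.nan
        if expressing[cid] and outputs[cid] > 0:
            r = response_time(
                values, times, outputs[cid], stimulation_time=times[2],
                fraction=response_fraction,
            )
            rt = np.nan if r is None else r
        records.append(
            {
                "cell_id": cid,
                "channel": channel,
                "expression_output": outputs[cid],
                "expressing": bool(expressing[cid]),
                "response_time": rt,
            }
        )
    rec = pd.DataFrame(records)
    rec.attrs["population_output"] = pop_output
    return rec


def ecdf(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Right-continuous empirical CDF: sorted unique support and cumulative probs."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("ecdf of empty sample")
    support, counts = np.unique(values, return_counts=True)
    return support, np.cumsum(counts) / values.size


def ecdf_eval(support: np.ndarray, probs: np.ndarray, x: float) -> float:
    """Evaluate an ECDF at x (0 below the minimum, 1 at and above the maximum)."""
    idx = np.searchsorted(support, x, side="right")
    return 0.0 if idx == 0 else float(probs[idx - 1])
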