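"""Per-cell expression quantification and response-time estimation.

Expression of a promoter is read out by a dynamic protein synthesis
translocation reporter (dPSTR): promoter activity drives nuclear relocation of
a constitutively expressed fluorescent protein, so the per-frame difference
between mean nuclear and mean cytoplasmic fluorescence ("nuclear enrichment")
tracks expression.  The processing chain is

1. nuclear enrichment = nuclear mean − cytoplasmic mean, per frame;
2. smoothing with a 3-point moving average (shrunken windows at the ends);
3. basal subtraction, basal = mean of the smoothed values at the last three
   frames at or before stimulation (t <= 0);
4. expression output = max of the corrected trace after stimulation;
5. a cell is "expressing" if its output reaches 20% of the population-averaged
   output (max of the mean corrected trace);
6. the response time is the first post-stimulus frame where the trace,
   normalized to its own maximum, strictly exceeds 0.2.

MAPK activity measured with a kinase translocation sensor (SKARS) is read as
the cytoplasmic/nuclear ratio instead.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

#: response-time threshold: fraction of a cell's own maximal corrected enrichment
RESPONSE_FRACTION = 0.2
#: expressing-cell threshold: fraction of the population-averaged output
EXPRESSING_FRACTION = 0.2


class BaselineError(ValueError):
    """Not enough pre-stimulus frames to estimate the basal level."""


class PopulationNonResponsiveError(ValueError):
    """The population-averaged output is not positive."""


@dataclass
class CorrectedTrace:
    """Smoothed, basal-subtracted nuclear-enrichment time series of one cell."""

    cell_id: object
    channel: str
    times: np.ndarray
    raw: np.ndarray
    smoothed: np.ndarray
    basal: float
    corrected: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.times)
        if not (len(self.raw) == len(self.smoothed) == len(self.corrected) == n):
            raise ValueError("trace series lengths differ")


@dataclass
class DelaySet:
    """Paired response-time differences (test − reference) for dual-expressing cells."""

    deltas: pd.Series  # indexed by cell_id, minutes
    median: float
    mean: float
    fraction_positive: float  # ties excluded from numerator and denominator
    n_dual: int
    empty: bool = False


def moving_average3(x: np.ndarray) -> np.ndarray:
    """Centered 3-point moving average with shrunken windows at both ends.

    The first and last points average the two available values, so no frame is
    lost — the three frames needed for basal estimation are preserved.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        return x.copy()
    out = np.empty_like(x)
    out[0] = (x[0] + x[1]) / 2.0
    out[-1] = (x[-2] + x[-1]) / 2.0
    if x.size > 2:
        out[1:-1] = (x[:-2] + x[1:-1] + x[2:]) / 3.0
    return out


def nuclear_enrichment(table: pd.DataFrame, channel: str) -> pd.DataFrame:
    """Per-cell raw nuclear enrichment (nuclear − cytoplasmic mean) of a channel.

    Returns a wide DataFrame: rows indexed by cell_id, columns are frame times.
    Values may be negative (reporter depleted from the nucleus).
    """
    sub = table[table["channel"] == channel]
    if len(sub) == 0:
        raise ValueError(f"channel {channel!r} absent from table")
    if sub["cytoplasmic_mean"].isna().any():
        raise ValueError(f"channel {channel!r} lacks cytoplasmic means")
    enr = sub["nuclear_mean"] - sub["cytoplasmic_mean"]
    wide = (
        sub.assign(enrichment=enr)
        .pivot(index="cell_id", columns="frame_time", values="enrichment")
        .sort_index(axis=1)
    )
    if wide.isna().any().any():
        raise ValueError("cells have mismatched frame grids")
    return wide


def kinase_activity(table: pd.DataFrame, channel: str = "YFP") -> pd.DataFrame:
    """SKARS readout: per-cell cytoplasmic/nuclear intensity ratio over time.

    The sensor leaves the nucleus upon MAPK phosphorylation, so the ratio rises
    with kinase activity.
    """
    sub = table[table["channel"] == channel]
    if len(sub) == 0:
        raise ValueError(f"channel {channel!r} absent from table")
    if sub["cytoplasmic_mean"].isna().any():
        raise ValueError(f"channel {channel!r} lacks cytoplasmic means")
    nuc = sub["nuclear_mean"].to_numpy(dtype=float)
    if np.any(nuc <= 0):
        idx = int(np.nonzero(nuc <= 0)[0][0])
        raise ValueError(f"non-positive nuclear mean at row {idx} of channel {channel}")
    ratio = sub["cytoplasmic_mean"] / sub["nuclear_mean"]
    return (
        sub.assign(ratio=ratio)
        .pivot(index="cell_id", columns="frame_time", values="ratio")
        .sort_index(axis=1)
    )


def preprocess_trace(
    raw: np.ndarray,
    times: np.ndarray,
    cell_id: object = None,
    channel: str = "",
    stimulation_time: float = 0.0,
) -> CorrectedTrace:
    """Smooth a raw enrichment series and subtract its basal level.

    ``stimulation_time`` marks the stimulus; frames at or before it are
    pre-stimulus.  The basal level is the mean of the smoothed values at the
    last three pre-stimulus frames, so the corrected trace is approximately
    zero before induction and insensitive to any constant offset of the raw
    signal.
    """
    raw = np.asarray(raw, dtype=float)
    times = np.asarray(times, dtype=float)
    pre = times <= stimulation_time
    if pre.sum() < 3:
        raise BaselineError(
            f"insufficient baseline: {int(pre.sum())} frame(s) at or before "
            f"t={stimulation_time}, need 3"
        )
    if (~pre).sum() < 2:
        raise ValueError("need at least 2 post-stimulus frames")
    smoothed = moving_average3(raw)
    basal = float(smoothed[pre][-3:].mean())
    return CorrectedTrace(
        cell_id=cell_id,
        channel=channel,
        times=times,
        raw=raw,
        smoothed=smoothed,
        basal=basal,
        corrected=smoothed - basal,
    )


def preprocess_channel(
    table: pd.DataFrame, channel: str, stimulation_time: float = 0.0
) -> pd.DataFrame:
    """Corrected traces for every cell of a channel as a wide DataFrame."""
    wide = nuclear_enrichment(table, channel)
    times = wide.columns.to_numpy(dtype=float)
    rows = {}
    for cell_id, raw in wide.iterrows():
        ct = preprocess_trace(
            raw.to_numpy(), times, cell_id, channel, stimulation_time
        )
        rows[cell_id] = ct.corrected
    return pd.DataFrame.from_dict(rows, orient="index", columns=wide.columns)


def smoothed_channel(table: pd.DataFrame, channel: str) -> pd.DataFrame:
    """Smoothed (but not basal-subtracted) enrichment traces, wide format.

    This is the "nuclear accumulation" signal used for correlation plots and
    the promoter-variability statistic, where per-cell basal levels carry real
    information and must not be subtracted.
    """
    wide = nuclear_enrichment(table, channel)
    out = wide.apply(lambda row: moving_average3(row.to_numpy()), axis=1, result_type="expand")
    out.columns = wide.columns
    return out


def expression_output(
    corrected: np.ndarray, times: np.ndarray, stimulation_time: float = 0.0
) -> float:
    """Maximal corrected nuclear enrichment after stimulation.

    Not clamped at zero: a non-responding cell can have a (slightly) negative
    output, which downstream thresholding interprets as non-expressing.
    """
    corrected = np.asarray(corrected, dtype=float)
    times = np.asarray(times, dtype=float)
    post = times > stimulation_time
    if not post.any():
        raise ValueError("no post-stimulus frames")
    return float(corrected[post].max())


def population_output(
    corrected_wide: pd.DataFrame, stimulation_time: float = 0.0
) -> float:
    """Population-averaged expression output.

    Computed on the mean trace of all cells (pointwise mean over cells, then
    max over post-stimulus frames) — not as the mean of per-cell outputs, so
    asynchronous peaks average down.
    """
    if len(corrected_wide) == 0:
        raise ValueError("no cells")
    mean_trace = corrected_wide.mean(axis=0)
    times = corrected_wide.columns.to_numpy(dtype=float)
    return expression_output(mean_trace.to_numpy(), times, stimulation_time)


def classify_expressing(
    outputs: pd.Series, pop_output: float, fraction: float = EXPRESSING_FRACTION
) -> pd.Series:
    """Flag cells whose output reaches 20% of the population-averaged output.

    The boundary is inclusive: a cell at exactly the threshold is expressing.
    """
    if not pop_output > 0:
        raise PopulationNonResponsiveError(
            f"population non-responsive (population output {pop_output:.3g} <= 0)"
        )
    return outputs >= fraction * pop_output


def response_time(
    corrected: np.ndarray,
    times: np.ndarray,
    output: float,
    stimulation_time: float = 0.0,
    fraction: float = RESPONSE_FRACTION,
) -> float | None:
    """First post-stimulus frame where the normalized trace strictly exceeds 0.2.

    The trace is normalized by the cell's own expression output, so the
    estimate is invariant to any shared gain of the channel.  Returns ``None``
    if the threshold is never exceeded after stimulation.  Only call for
    expressing cells (``output`` must be positive).
    """
    if not output > 0:
        raise ValueError("response_time requires a positive expression output; "
                         "filter to expressing cells first")
    corrected = np.asarray(corrected, dtype=float)
    times = np.asarray(times, dtype=float)
    post = times > stimulation_time
    normalized = corrected[post] / output
    above = normalized > fraction
    if not above.any():
        return None
    return float(times[post][np.argmax(above)])


def timing_table(
    corrected_wide: pd.DataFrame,
    channel: str,
    stimulation_time: float = 0.0,
    expressing_fraction: float = EXPRESSING_FRACTION,
    response_fraction: float = RESPONSE_FRACTION,
) -> pd.DataFrame:
    """Per-cell timing records for one channel.

    Columns: cell_id, channel, expression_output, expressing, response_time
    (NaN when undefined).
    """
    times = corrected_wide.columns.to_numpy(dtype=float)
    outputs = pd.Series(
        {
            cid: expression_output(row.to_numpy(), times, stimulation_time)
            for cid, row in corrected_wide.iterrows()
        },
        name="expression_output",
    )
    pop = population_output(corrected_wide, stimulation_time)
    expressing = classify_expressing(outputs, pop, expressing_fraction)
    rts = {}
    for cid, row in corrected_wide.iterrows():
        if expressing[cid] and outputs[cid] > 0:
            rts[cid] = response_time(
                row.to_numpy(), times, outputs[cid], stimulation_time, response_fraction
            )
        else:
            rts[cid] = None
    rec = pd.DataFrame(
        {
            "cell_id": outputs.index,
            "channel": channel,
            "expression_output": outputs.to_numpy(),
            "expressing": expressing.to_numpy(),
            "response_time": [np.nan if rts[c] is None else rts[c] for c in outputs.index],
        }
    )
    rec.attrs["population_output"] = pop
    return rec


def paired_delay(
    test_records: pd.DataFrame, reference_records: pd.DataFrame
) -> DelaySet:
    """Response-time difference (test − reference) per dual-expressing cell.

    A late test promoter yields positive deltas.  The fraction of positive
    deltas excludes exact ties from numerator and denominator (a tie carries
    no ordering information on a quantized frame grid).
    """
    t = test_records.set_index("cell_id")
    r = reference_records.set_index("cell_id")
    common = t.index.intersection(r.index)
    t, r = t.loc[common], r.loc[common]
    dual = (
        t["expressing"].astype(bool)
        & r["expressing"].astype(bool)
        & t["response_time"].notna()
        & r["response_time"].notna()
    )
    deltas = (t.loc[dual, "response_time"] - r.loc[dual, "response_time"]).astype(float)
    if len(deltas) == 0:
        return DelaySet(
            deltas=deltas,
            median=math.nan,
            mean=math.nan,
            fraction_positive=math.nan,
            n_dual=0,
            empty=True,
        )
    nonzero = deltas[deltas != 0]
    frac_pos = float((nonzero > 0).mean()) if len(nonzero) else math.nan
    return DelaySet(
        deltas=deltas,
        median=float(deltas.median()),
        mean=float(deltas.mean()),
        fraction_positive=frac_pos,
        n_dual=int(len(deltas)),
    )


def sign_test(deltas) -> float:
    """Exact two-sided binomial sign test that deltas are centered at zero.

    Zero deltas are discarded; the p-value is twice the smaller binomial tail
    under p=1/2, capped at 1.  If every delta is zero the test is vacuous and
    returns 1 with a warning.
    """
    deltas = np.asarray(deltas, dtype=float)
    if deltas.size == 0:
        raise ValueError("sign_test requires at least one delta")
    nonzero = deltas[deltas != 0]
    n = nonzero.size
    if n == 0:
        warnings.warn("all deltas are zero; sign test is vacuous (p=1)")
        return 1.0
    k = int((nonzero > 0).sum())
    from scipy.stats import binom

    lower = binom.cdf(k, n, 0.5)
    upper = binom.sf(k - 1, n, 0.5)
    return float(min(1.0, 2.0 * min(lower, upper)))
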