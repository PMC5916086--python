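"""Dual-reporter covariation: normalization, diagonal-offset tests and the
correlative promoter variability (CPV) statistic.

Two orthogonal reporters measured in the same cells separate variability that
is shared between them (extrinsic: expression capacity, cell-cycle state, MAPK
activity) from reporter-specific variability (intrinsic noise plus any
difference in promoter regulation).  CPV is the intrinsic-to-total noise ratio
of the classic dual-reporter decomposition:

    eta2_int = <(r - y)^2> / (2 <r><y>)
    eta2_tot = (<r^2> + <y^2> - 2 <r><y>) / (2 <r><y>)
    CPV      = eta2_int / eta2_tot
             = <(r - y)^2> / (<r^2> + <y^2> - 2 <r><y>)

where r_i, y_i are the normalized nuclear accumulations of cell i in the two
channels at one time point and <.> averages over cells.  The shared
denominator cancels in the ratio.  CPV is 0 for perfectly co-regulated
reporters and ~1 for independent ones.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd
from scipy import stats


class SignificanceTier(str, Enum):
    """Per-time-point significance tier of the diagonal-offset test."""

    NONE = "none"         # p >= 1e-3
    SMALL = "small_dot"   # 1e-6 <= p < 1e-3
    LARGE = "large_dot"   # p < 1e-6


def normalize_by_mean_trace(corrected_wide: pd.DataFrame) -> pd.DataFrame:
    """Divide every cell trace by the peak of the population mean trace.

    One scalar per channel per replicate; used for single-cell scatter plots,
    where per-cell values may exceed 1.
    """
    mean_trace = corrected_wide.mean(axis=0)
    norm = float(mean_trace.max())
    if not norm > 0:
        raise ValueError(f"non-positive normalizer (mean-trace max {norm:.3g})")
    return corrected_wide / norm


def minmax_population_normalize(traces_wide: pd.DataFrame) -> pd.DataFrame:
    """Min-max normalize by the population-averaged trace of the replicate.

    x -> (x - m) / (M - m) with m, M the lowest and highest values of the
    population mean trace over the whole movie.  Individual cells may fall
    outside [0, 1].
    """
    mean_trace = traces_wide.mean(axis=0)
    m, M = float(mean_trace.min()), float(mean_trace.max())
    if M == m:
        raise ValueError("degenerate normalization: population mean trace is constant")
    return (traces_wide - m) / (M - m)


def correlation_trajectory(
    ref_norm: pd.DataFrame, test_norm: pd.DataFrame
) -> pd.DataFrame:
    """Population-averaged normalized enrichment of two channels over time.

    One (x, y) point per frame, ordered by time; co-regulated promoters track
    the x = y diagonal from (0, 0) to (1, 1), a delayed test promoter bows
    below it.
    """
    if not ref_norm.columns.equals(test_norm.columns):
        raise ValueError("frame grids of the two channels differ")
    return pd.DataFrame(
        {
            "time": ref_norm.columns.to_numpy(dtype=float),
            "x": ref_norm.mean(axis=0).to_numpy(),
            "y": test_norm.mean(axis=0).to_numpy(),
        }
    )


def diagonal_offsets(ref_values: np.ndarray, test_values: np.ndarray) -> np.ndarray:
    """Signed perpendicular distance of (x, y) pairs to the x = y line."""
    x = np.asarray(ref_values, dtype=float)
    y = np.asarray(test_values, dtype=float)
    return (y - x) / np.sqrt(2.0)


def diagonal_offset_test(
    test_offsets: np.ndarray, reference_offsets: np.ndarray
) -> tuple[float, SignificanceTier]:
    """Welch two-sample t-test of test-strain vs reference-strain offsets.

    Welch's form is used because the two strains need not share variance.
    Returns the p-value and its display tier.
    """
    a = np.asarray(test_offsets, dtype=float)
    b = np.asarray(reference_offsets, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 cells per strain")
    if np.var(a) == 0 and np.var(b) == 0:
        if np.isclose(a.mean(), b.mean()):
            warnings.warn("zero variance in both groups; p set to 1")
            return 1.0, SignificanceTier.NONE
        return 0.0, SignificanceTier.LARGE
    p = float(stats.ttest_ind(a, b, equal_var=False).pvalue)
    return p, offset_tier(p)


def offset_tier(p: float) -> SignificanceTier:
    if p < 1e-6:
        return SignificanceTier.LARGE
    if p < 1e-3:
        return SignificanceTier.SMALL
    return SignificanceTier.NONE


def offset_test_series(
    ref_norm_test_strain: pd.DataFrame,
    test_norm_test_strain: pd.DataFrame,
    ref_norm_reference_strain: pd.DataFrame,
    test_norm_reference_strain: pd.DataFrame,
) -> pd.DataFrame:
    """Diagonal-offset test at every frame; columns time, p, tier."""
    if not ref_norm_test_strain.columns.equals(ref_norm_reference_strain.columns):
        raise ValueError("frame grids of the two strains differ")
    rows = []
    for t in ref_norm_test_strain.columns:
        d_test = diagonal_offsets(
            ref_norm_test_strain[t].to_numpy(), test_norm_test_strain[t].to_numpy()
        )
        d_ref = diagonal_offsets(
            ref_norm_reference_strain[t].to_numpy(),
            test_norm_reference_strain[t].to_numpy(),
        )
        p, tier = diagonal_offset_test(d_test, d_ref)
        rows.append({"time": float(t), "p": p, "tier": tier.value})
    return pd.DataFrame(rows)


def cpv(r: np.ndarray, y: np.ndarray) -> float:
    """Correlative promoter variability of paired reporter values.

    ``r`` and ``y`` must come from the same cells in the same order.  Returns
    NaN (with a warning) when the total-noise denominator vanishes, i.e. the
    population carries no variability to decompose.
    """
    r = np.asarray(r, dtype=float)
    y = np.asarray(y, dtype=float)
    if r.shape != y.shape:
        raise ValueError("r and y must be paired (same cells)")
    if r.size < 2:
        raise ValueError("need at least 2 cells")
    num = np.mean((r - y) ** 2)
    den = np.mean(r**2) + np.mean(y**2) - 2.0 * np.mean(r) * np.mean(y)
    if den == 0:
        if num == 0:
            return 0.0  # identical reporters: no deviation at all
        warnings.warn("zero total noise; CPV undefined")
        return float("nan")
    return float(num / den)


@dataclass
class CPVSeries:
    """Time-resolved CPV per replicate with across-replicate aggregation."""

    per_replicate: pd.DataFrame  # time, replicate, cpv, n_cells
    summary: pd.DataFrame        # time, mean_cpv, sd_cpv


def cpv_series(
    replicates: list[tuple[pd.DataFrame, pd.DataFrame]],
    normalize: bool = True,
) -> CPVSeries:
    """CPV over time for one or more replicates of (red, yellow) trace sets.

    Each replicate is a pair of wide DataFrames (cells x times, same cells and
    grid in both channels) of smoothed nuclear accumulations.  Each replicate
    is min-max normalized by its own population-averaged trace per channel
    before the decomposition, so replicates with different acquisition gains
    are comparable.  The across-replicate sd uses ddof=1 (sd between
    replicates); it is 0 for identical replicates and NaN for one replicate.
    """
    if not replicates:
        raise ValueError("need at least one replicate")
    grid = replicates[0][0].columns
    rows = []
    for i, (r_wide, y_wide) in enumerate(replicates):
        if not (r_wide.columns.equals(grid) and y_wide.columns.equals(grid)):
            raise ValueError("replicates have different frame grids")
        common = r_wide.index.intersection(y_wide.index)
        r_wide, y_wide = r_wide.loc[common], y_wide.loc[common]
        if normalize:
            r_wide = minmax_population_normalize(r_wide)
            y_wide = minmax_population_normalize(y_wide)
        for t in grid:
            rows.append(
                {
                    "time": float(t),
                    "replicate": i,
                    "cpv": cpv(r_wide[t].to_numpy(), y_wide[t].to_numpy()),
                    "n_cells": len(common),
                }
            )
    per_rep = pd.DataFrame(rows)
    summary = (
        per_rep.groupby("time")["cpv"]
        .agg(mean_cpv="mean", sd_cpv=lambda v: v.std(ddof=1) if len(v) > 1 else float("nan"))
        .reset_index()
    )
    return CPVSeries(per_replicate=per_rep, summary=summary)
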