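"""Trace-table data model, CSV I/O and per-cell quality control.

The universal input of the pipeline is a long-format table with one row per
(cell, frame, channel) carrying mean nuclear and cytoplasmic fluorescence,
object areas and the frame time in minutes relative to stimulation (negative
times are pre-stimulus).  This emulates the per-object quantification tables
produced by segmentation/tracking platforms; images themselves are out of
scope.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: canonical column names of a trace table
TRACE_COLUMNS = [
    "cell_id",
    "replicate_id",
    "frame_time",
    "channel",
    "nuclear_mean",
    "cytoplasmic_mean",
    "nuclear_area",
    "cell_area",
]

#: columns that must be present and numeric
_NUMERIC_COLUMNS = ["frame_time", "nuclear_mean", "nuclear_area", "cell_area"]

VALID_CHANNELS = {"RFP", "YFP", "CFP", "tdiRFP"}


class TraceSchemaError(ValueError):
    """A required column is missing or cannot be resolved."""


class TraceParseError(ValueError):
    """A cell of the CSV could not be parsed as the expected type."""


class TraceIntegrityError(ValueError):
    """The table violates a structural invariant (duplicates, bad values)."""


class QCConfigError(ValueError):
    """QC configuration refers to data that is not present."""


@dataclass(frozen=True)
class QCConfig:
    """Per-cell quality-control thresholds.

    Variability is measured as the coefficient of variation (sd/mean) over the
    cell's track.  Any threshold set to ``None`` disables that rule.  The
    numeric defaults are package choices; the rules themselves (full track,
    low area/CFP variability, bounded RFP/YFP ratio) follow standard practice
    for translocation-reporter movies.
    """

    require_full_track: bool = True
    max_cv_nuclear_area: float | None = 0.2
    max_cv_cell_area: float | None = 0.2
    max_cv_nuclear_cfp: float | None = 0.2
    max_rfp_yfp_ratio: float | None = 3.0
    min_track_frames: int | None = None  # used in mating (agar-pad) mode

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if f.name.startswith("max_") and v is not None and v <= 0:
                raise ValueError(f"QC threshold {f.name} must be > 0, got {v}")
        if self.min_track_frames is not None and self.min_track_frames < 1:
            raise ValueError("min_track_frames must be >= 1")


@dataclass
class QCReport:
    """Outcome of :func:`apply_qc`: per-cell verdicts and per-rule tallies."""

    n_input: int
    n_kept: int
    per_cell: pd.DataFrame = field(repr=False)  # cell_id, kept, reasons
    discards_per_rule: dict[str, int] = field(default_factory=dict)

    @property
    def n_discarded(self) -> int:
        return self.n_input - self.n_kept


def validate_trace_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check structural invariants and return the table sorted canonically.

    Raises :class:`TraceIntegrityError` on duplicated (cell, time, channel)
    rows, negative intensities/areas, or non-increasing frame times.
    """
    missing = [c for c in TRACE_COLUMNS if c not in table.columns]
    if missing:
        raise TraceSchemaError(f"missing required column(s): {', '.join(missing)}")
    dup = table.duplicated(subset=["cell_id", "frame_time", "channel"])
    if dup.any():
        row = table.index[dup][0]
        raise TraceIntegrityError(
            f"duplicate (cell_id, frame_time, channel) at input row {row}"
        )
    for col in ("nuclear_mean", "nuclear_area", "cell_area"):
        vals = table[col].to_numpy(dtype=float)
        if np.any(vals[~np.isnan(vals)] < 0):
            raise TraceIntegrityError(f"negative values in column {col}")
    bad = set(table["channel"].unique()) - VALID_CHANNELS
    if bad:
        raise TraceIntegrityError(f"unknown channel(s): {sorted(bad)}")
    out = table.sort_values(["cell_id", "channel", "frame_time"], kind="mergesort")
    return out.reset_index(drop=True)


def read_trace_table(
    source,
    dialect: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Read a trace CSV into a validated long-format table.

    Parameters
    ----------
    source:
        Path or open text stream of a CSV with a header row.
    dialect:
        Optional mapping ``{canonical_name: column_name_in_file}`` for files
        with non-default headers.
    """
    raw = pd.read_csv(source, dtype=str)
    dialect = dialect or {}
    rename = {v: k for k, v in dialect.items()}
    raw = raw.rename(columns=rename)
    missing = [c for c in TRACE_COLUMNS if c not in raw.columns and c != "cytoplasmic_mean"]
    if "cytoplasmic_mean" not in raw.columns:
        raw["cytoplasmic_mean"] = np.nan
    if missing:
        raise TraceSchemaError(f"missing required column(s): {', '.join(missing)}")
    table = raw.copy()
    for col in _NUMERIC_COLUMNS + ["cytoplasmic_mean"]:
        converted = pd.to_numeric(table[col], errors="coerce")
        bad = converted.isna() & table[col].notna() & (table[col].astype(str).str.strip() != "")
        if bad.any():
            rownum = int(table.index[bad][0]) + 2  # +1 header, +1 one-based
            raise TraceParseError(
                f"non-numeric value {table.loc[bad, col].iloc[0]!r} in column "
                f"{col!r} at file row {rownum}"
            )
        table[col] = converted
    return validate_trace_table(table[TRACE_COLUMNS])


def write_results(result: pd.DataFrame, path) -> None:
    """Write a tabular result to CSV with a stable column order.

    Refuses to write an empty table so that a silently broken upstream stage
    cannot masquerade as a completed run.
    """
    if result is None or len(result) == 0:
        raise ValueError("refusing to write an empty result table")
    result.to_csv(path, index=False)


def _cv(values: np.ndarray) -> float:
    values = np.asarray(values, dtype=float)
    values = values[~np.isnan(values)]
    if values.size == 0:
        return np.nan
    m = values.mean()
    if m == 0:
        return np.inf
    return float(values.std(ddof=0) / abs(m))


def apply_qc(
    table: pd.DataFrame,
    cfg: QCConfig,
    movie_span: tuple[float, float] | None = None,
) -> tuple[pd.DataFrame, QCReport]:
    """Filter cells by track completeness and trace stability.

    A cell is kept only if it passes every enabled rule:

    * ``incomplete_track`` — present at every frame of the common grid inside
      ``movie_span`` (cells must be tracked from the beginning to the end of
      the movie);
    * ``short_track`` — at least ``min_track_frames`` frames (mating mode);
    * ``cv_nuclear_area`` / ``cv_cell_area`` / ``cv_nuclear_cfp`` — coefficient
      of variation over the track at most the configured threshold;
    * ``rfp_yfp_ratio`` — mean nuclear RFP over mean nuclear YFP at most the
      configured ratio.

    Returns the filtered table and a :class:`QCReport` whose counts reconcile
    exactly with the input cell count.
    """
    if len(table) == 0:
        raise ValueError("empty trace table")
    table = validate_trace_table(table)
    channels = set(table["channel"].unique())
    if cfg.max_cv_nuclear_cfp is not None and "CFP" not in channels:
        raise QCConfigError("QC rule cv_nuclear_cfp enabled but CFP channel absent")
    if cfg.max_rfp_yfp_ratio is not None and not {"RFP", "YFP"} <= channels:
        raise QCConfigError("QC rule rfp_yfp_ratio enabled but RFP/YFP channel absent")

    if movie_span is None:
        movie_span = (table["frame_time"].min(), table["frame_time"].max())
    grid = np.unique(table["frame_time"].to_numpy(dtype=float))
    grid = grid[(grid >= movie_span[0]) & (grid <= movie_span[1])]

    verdicts: list[dict] = []
    tallies: dict[str, int] = {}
    for cell_id, sub in table.groupby("cell_id", sort=True):
        reasons: list[str] = []
        # per-frame geometry, deduplicated across channels
        per_frame = sub.groupby("frame_time").agg(
            nuclear_area=("nuclear_area", "mean"),
            cell_area=("cell_area", "mean"),
        )
        cell_times = np.unique(sub["frame_time"].to_numpy(dtype=float))
        if cfg.require_full_track and not np.all(np.isin(grid, cell_times)):
            reasons.append("incomplete_track")
        if cfg.min_track_frames is not None and cell_times.size < cfg.min_track_frames:
            reasons.append("short_track")
        if cfg.max_cv_nuclear_area is not None:
            if _cv(per_frame["nuclear_area"].to_numpy()) > cfg.max_cv_nuclear_area:
                reasons.append("cv_nuclear_area")
        if cfg.max_cv_cell_area is not None:
            if _cv(per_frame["cell_area"].to_numpy()) > cfg.max_cv_cell_area:
                reasons.append("cv_cell_area")
        if cfg.max_cv_nuclear_cfp is not None:
            cfp = sub.loc[sub["channel"] == "CFP", "nuclear_mean"].to_numpy(dtype=float)
            if cfp.size == 0 or _cv(cfp) > cfg.max_cv_nuclear_cfp:
                reasons.append("cv_nuclear_cfp")
        if cfg.max_rfp_yfp_ratio is not None:
            rfp = sub.loc[sub["channel"] == "RFP", "nuclear_mean"].mean()
            yfp = sub.loc[sub["channel"] == "YFP", "nuclear_mean"].mean()
            if not np.isfinite(rfp) or not np.isfinite(yfp) or yfp <= 0:
                reasons.append("rfp_yfp_ratio")
            elif rfp / yfp > cfg.max_rfp_yfp_ratio:
                reasons.append("rfp_yfp_ratio")
        verdicts.append(
            {"cell_id": cell_id, "kept": not reasons, "reasons": ";".join(reasons)}
        )
        for r in reasons:
            tallies[r] = tallies.get(r, 0) + 1

    per_cell = pd.DataFrame(verdicts)
    kept_ids = set(per_cell.loc[per_cell["kept"], "cell_id"])
    filtered = table[table["cell_id"].isin(kept_ids)].reset_index(drop=True)
    report = QCReport(
        n_input=len(per_cell),
        n_kept=len(kept_ids),
        per_cell=per_cell,
        discards_per_rule=tallies,
    )
    for rule, n in sorted(tallies.items()):
        logger.info("QC: %d cell(s) failed rule %s", n, rule)
    logger.info("QC: kept %d / %d cells", report.n_kept, report.n_input)
    return filtered, report
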