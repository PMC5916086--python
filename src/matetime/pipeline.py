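"""End-to-end workflows tying the analysis stages together.

Two workflows mirror the two experiment types: exogenous pheromone
stimulation (QC -> enrichment -> timing -> paired delays/sign test ->
covariation -> classification) and mating pads (QC -> fusion detection ->
fusion-aligned traces -> response times relative to fusion -> ECDFs).  Both
are deterministic given their inputs and write plain CSV/JSON artifacts.
"""

from __future__ import annotations

import json
import logging
import warnings
from pathlib import Path

import pandas as pd

from . import covariation as cov
from . import expression_timing as et
from . import mating_analysis as ma
from .config import PipelineConfig
from .dose_classification import classify_promoter
from .trace_io import apply_qc, write_results

logger = logging.getLogger(__name__)

#: channel roles in the dual-reporter strains: YFP carries the pAGA1-like
#: reference, RFP the promoter under test
REFERENCE_CHANNEL = "YFP"
TEST_CHANNEL = "RFP"


def run_stimulation_pipeline(
    table: pd.DataFrame,
    config: PipelineConfig | None = None,
    outdir: str | Path | None = None,
    reference_table: pd.DataFrame | None = None,
) -> dict:
    """Analyze an exogenous-stimulation movie.

    ``reference_table`` is an optional movie of the reference strain (the
    pAGA1-like promoter on both channels); when given, the diagonal-offset
    test series against it feeds the class assignment, otherwise the class is
    decided from paired delays alone.
    """
    config = config or PipelineConfig.default()
    stim = config.stimulation_time
    filtered, report = apply_qc(table, config.qc)
    logger.info("stage qc: kept %d/%d cells", report.n_kept, report.n_input)

    timing = {}
    corrected = {}
    for channel in (REFERENCE_CHANNEL, TEST_CHANNEL):
        if channel not in set(filtered["channel"]):
            continue
        corrected[channel] = et.preprocess_channel(filtered, channel, stim)
        timing[channel] = et.timing_table(
            corrected[channel], channel, stim,
            config.expressing_fraction, config.response_fraction,
        )
    timing_all = pd.concat(timing.values(), ignore_index=True)

    results: dict = {"qc_report": report, "timing": timing_all}
    delays = None
    if len(timing) == 2:
        delays = et.paired_delay(timing[TEST_CHANNEL], timing[REFERENCE_CHANNEL])
        sign_p = (
            et.sign_test(delays.deltas.to_numpy()) if not delays.empty else None
        )
        results["delays"] = delays
        results["sign_test_p"] = sign_p

        smoothed = {
            ch: et.smoothed_channel(filtered, ch) for ch in (TEST_CHANNEL, REFERENCE_CHANNEL)
        }
        cpv = cov.cpv_series([(smoothed[TEST_CHANNEL], smoothed[REFERENCE_CHANNEL])])
        results["cpv"] = cpv

        offset_series = None
        if reference_table is not None:
            ref_filtered, _ = apply_qc(reference_table, config.qc)
            norm = {
                ch: cov.minmax_population_normalize(et.smoothed_channel(filtered, ch))
                for ch in (REFERENCE_CHANNEL, TEST_CHANNEL)
            }
            norm_ref = {
                ch: cov.minmax_population_normalize(et.smoothed_channel(ref_filtered, ch))
                for ch in (REFERENCE_CHANNEL, TEST_CHANNEL)
            }
            offset_series = cov.offset_test_series(
                norm[REFERENCE_CHANNEL], norm[TEST_CHANNEL],
                norm_ref[REFERENCE_CHANNEL], norm_ref[TEST_CHANNEL],
            )
            results["offset_series"] = offset_series
        classification = classify_promoter(
            delays, offset_series, promoter=TEST_CHANNEL,
            thresholds=config.classification, sign_test_p=sign_p,
            stimulation_time=stim,
        )
        results["classification"] = classification

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_results(timing_all, outdir / "timing.csv")
        if delays is not None and not delays.empty:
            write_results(
                delays.deltas.rename("delta_min").rename_axis("cell_id").reset_index(),
                outdir / "delays.csv",
            )
            write_results(results["cpv"].per_replicate, outdir / "cpv.csv")
            cls = results["classification"]
            payload = {
                "promoter": cls.promoter,
                "class": cls.klass.value if cls.klass else None,
                "median_delta_min": cls.median_delta,
                "sign_test_p": cls.sign_test_p,
                "fraction_significant_offsets": cls.fraction_significant_offsets,
                "n_dual_expressing": delays.n_dual,
                "fraction_positive": delays.fraction_positive,
            }
            (outdir / "classification.json").write_text(
                json.dumps(payload, indent=2, sort_keys=True) + "\n"
            )
    return results


def run_mating_pipeline(
    table: pd.DataFrame,
    config: PipelineConfig | None = None,
    outdir: str | Path | None = None,
) -> dict:
    """Analyze a mating-pad movie with a tdiRFP fusion channel."""
    from dataclasses import replace

    config = config or PipelineConfig.default()
    qc_cfg = replace(
        config.qc,
        require_full_track=False,
        min_track_frames=config.fusion.min_track_frames,
    )
    filtered, report = apply_qc(table, qc_cfg)
    logger.info("stage qc: kept %d/%d cells", report.n_kept, report.n_input)

    fusion = ma.detect_fusion_table(filtered, config.fusion)
    n_fusing = int((fusion["status"] == "fusing").sum())
    logger.info(
        "stage fusion: %d fusing, %d non-fusing, %d indeterminate",
        n_fusing,
        int((fusion["status"] == "non_fusing").sum()),
        int((fusion["status"] == "indeterminate").sum()),
    )
    results: dict = {"qc_report": report, "fusion": fusion}

    channels = [c for c in ("RFP", "YFP") if c in set(filtered["channel"])]
    timing_frames, rel_frames, ecdfs = [], [], {}
    aligned_frames = []
    for channel in channels:
        timing = ma.mating_timing_table(
            filtered, channel, config.expressing_fraction, config.response_fraction
        )
        timing_frames.append(timing)
        if n_fusing > 0:
            corrected = ma.mating_corrected_traces(filtered, channel)
            aligned, bands = ma.align_to_fusion(corrected, fusion)
            aligned_frames.append(aligned.assign(channel=channel))
            rel = ma.response_time_rel_fusion(timing, fusion)
            rel_frames.append(rel)
            if len(rel):
                ecdfs[channel] = ma.ecdf(rel["rt_minus_fusion"].to_numpy())
    if n_fusing == 0:
        warnings.warn("no fusing cells detected; fusion-aligned outputs skipped")
    if fusion["status"].eq("indeterminate").all():
        warnings.warn("every classified cell is indeterminate; check tdiRFP signal")

    results["timing"] = pd.concat(timing_frames, ignore_index=True)
    if rel_frames:
        results["relative_rt"] = pd.concat(rel_frames, ignore_index=True)
        results["ecdf"] = ecdfs
    if aligned_frames:
        results["aligned"] = pd.concat(aligned_frames, ignore_index=True)

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_results(fusion, outdir / "fusion.csv")
        write_results(results["timing"], outdir / "timing.csv")
        if "aligned" in results and len(results["aligned"]):
            write_results(results["aligned"], outdir / "aligned.csv")
        if "relative_rt" in results and len(results["relative_rt"]):
            write_results(results["relative_rt"], outdir / "relative_rt.csv")
            rows = []
            for ch, (support, probs) in ecdfs.items():
                for s, p in zip(support, probs):
                    rows.append({"channel": ch, "rt_minus_fusion": s, "cum_prob": p})
            if rows:
                write_results(pd.DataFrame(rows), outdir / "ecdf.csv")
    return results
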