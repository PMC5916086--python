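"""Synthetic single-cell trace generator with full ground truth.

The generator emulates the statistical structure of pheromone-response
reporter movies so that every pipeline stage can be exercised and checked
against known truth:

* a per-cell *expression capacity* E (lognormal, shared by all reporters of a
  cell) carries the extrinsic variability that dominates mating-pathway
  expression;
* per-reporter lognormal amplitude jitter carries intrinsic variability;
* early reporters turn on at a per-cell onset drawn from a Gamma law; late
  reporters share a per-cell *commitment time* = early onset + a Normal delay
  (a cell may occasionally commit before its early reporter fires);
* the noiseless corrected signal is a linear ramp A*E*I*H(dose) *
  clip((t - t0)/T_ramp, 0, 1) with t0 = tau - 0.2*T_ramp, so the true 20%
  crossing is exactly tau — the same observable the response-time estimator
  measures;
* pheromone dose gates the amplitude through a Hill function (graded for
  early-like, switch-like for late-like presets);
* optional cell-cycle modulation of basal expression, additive Gaussian
  measurement noise, and a mating mode in which fusing cells receive a tdiRFP
  step (partner-derived fluorescence) at their fusion time.

Raw channels are emitted as cytoplasm = baseline + noise and nucleus =
baseline + basal + signal + noise, so the analysis-side nuclear enrichment
recovers basal + signal.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .trace_io import validate_trace_table


@dataclass(frozen=True)
class ReporterSpec:
    """One promoter-reporter channel of the simulated strain."""

    channel: str              # "RFP" or "YFP"
    amplitude: float          # A: saturating-dose expression amplitude, AU
    ramp_min: float = 30.0    # T_ramp: ramp duration, minutes
    timing: str = "early"     # "early" (pAGA1-like) | "late" (pFIG1-like)
    basal: float = 0.0        # basal expression level (AU), scaled by capacity
    cell_cycle_pulse: bool = False

    def __post_init__(self) -> None:
        if self.timing not in ("early", "late"):
            raise ValueError(f"timing must be early|late, got {self.timing!r}")
        if self.ramp_min <= 0:
            raise ValueError("ramp_min must be > 0")


@dataclass(frozen=True)
class DoseModel:
    """Pheromone dose gating of expression amplitude via a Hill function."""

    concentration: float  # nM
    ec50: float = 300.0   # nM
    hill_n: float = 3.0

    def gate(self) -> float:
        c = self.concentration
        if c <= 0:
            return 0.0
        cn = c**self.hill_n
        return cn / (self.ec50**self.hill_n + cn)


@dataclass(frozen=True)
class MatingModel:
    """Parameters of the agar-pad mating simulation."""

    fusion_fraction: float = 0.6
    tdirfp_baseline: float = 20.0  # AU in the MATa cell before fusion
    step: float = 100.0            # AU transferred at fusion
    drift: float = 3.0             # bounded (+-) frame-to-frame jitter, AU
    early_offset_mean: float = 60.0  # early onset precedes fusion by ~1 h ...
    early_offset_sd: float = 25.0    # ... with large variability
    late_offset_mean: float = 30.0   # late onset tightly precedes fusion
    late_offset_sd: float = 8.0
    nonfusing_early_prob: float = 0.8
    min_track_frames: int = 10


@dataclass(frozen=True)
class SimParams:
    """Study conditions of a simulated experiment.

    The default frame grid is three 2-min pre-stimulus frames, the stimulation
    frame at t = 0, then 5-min sampling to 100 min; mating mode uses 0..150
    min at 5-min sampling with per-cell track windows.
    """

    n_cells: int = 200
    reporters: tuple[ReporterSpec, ...] = (ReporterSpec("YFP", 20.0),)
    responder_fraction: float = 0.91
    sigma_extrinsic: float = 0.3   # sd of log capacity E
    sigma_intrinsic: float = 0.1   # sd of log per-reporter amplitude jitter
    noise_sd: float = 1.0          # additive Gaussian measurement noise, AU
    onset_shape: float = 4.0       # early onset ~ Gamma(shape, scale) minutes
    onset_scale: float = 4.3
    onset_fixed: float | None = None  # deterministic onset (overrides Gamma)
    commit_delay_mean: float = 23.0   # late commitment delay ~ Normal, minutes
    commit_delay_sd: float = 20.0
    late_jitter_sd: float = 2.0    # per-promoter jitter when several late reporters
    min_onset: float = 2.0         # onsets cannot precede stimulation
    max_onset: float | None = None  # optional cap keeping responses inside the movie
    pre_times: tuple[float, ...] = (-6.0, -4.0, -2.0)
    post_end: float = 100.0
    post_step: float = 5.0
    cyto_baseline: float = 100.0
    cellcycle_amplitude: float = 0.5  # relative modulation of basal expression
    cellcycle_period: float = 90.0    # minutes
    dose: DoseModel | None = None
    doses: tuple[float, ...] | None = None  # dose series for sweep presets
    mating: MatingModel | None = None
    mating_end: float = 150.0
    replicate_id: str = "r1"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.responder_fraction <= 1.0:
            raise ValueError("responder_fraction must be in [0, 1]")
        for name in ("sigma_extrinsic", "sigma_intrinsic", "noise_sd",
                     "commit_delay_sd", "late_jitter_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if not self.reporters:
            raise ValueError("need at least one reporter")
        if self.onset_fixed is not None and self.onset_fixed >= self.post_end:
            raise ValueError("grid too short for the configured onset")

    @property
    def times(self) -> np.ndarray:
        post = np.arange(0.0, self.post_end + 1e-9, self.post_step)
        return np.concatenate([np.asarray(self.pre_times), post])

    @property
    def mating_times(self) -> np.ndarray:
        return np.arange(0.0, self.mating_end + 1e-9, self.post_step)


def _ramp(t: np.ndarray, tau: float, ramp_min: float) -> np.ndarray:
    """Unit ramp whose 20% crossing is exactly tau."""
    t0 = tau - 0.2 * ramp_min
    return np.clip((t - t0) / ramp_min, 0.0, 1.0)


def _areas_and_cfp(rng, n_frames: int, cyto_baseline: float):
    nuc_area = 25.0 + rng.normal(0.0, 0.5, n_frames)
    cell_area = 400.0 + rng.normal(0.0, 5.0, n_frames)
    cfp_nuc = 200.0 + rng.normal(0.0, 1.0, n_frames)
    cfp_cyt = 150.0 + rng.normal(0.0, 1.0, n_frames)
    return np.abs(nuc_area), np.abs(cell_area), np.abs(cfp_nuc), np.abs(cfp_cyt)


def simulate_population(
    params: SimParams, rng: np.random.Generator | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate an exogenous-stimulation experiment.

    Returns the long-format trace table (validated) and the per-cell ground
    truth: responder flag, capacity, commitment time, and per-reporter true
    20%-crossing time tau and noiseless amplitude.
    """
    rng = rng if rng is not None else np.random.default_rng(params.seed)
    times = params.times
    n = params.n_cells
    n_frames = times.size

    responder = rng.random(n) < params.responder_fraction
    capacity = np.exp(rng.normal(0.0, params.sigma_extrinsic, n))
    if params.onset_fixed is not None:
        tau_early = np.full(n, float(params.onset_fixed))
    else:
        tau_early = rng.gamma(params.onset_shape, params.onset_scale, n)
    hi = np.inf if params.max_onset is None else params.max_onset
    tau_early = np.clip(tau_early, params.min_onset, hi)
    commit = tau_early + rng.normal(params.commit_delay_mean, params.commit_delay_sd, n)
    commit = np.clip(commit, params.min_onset, hi)
    cc_phase = rng.uniform(0.0, params.cellcycle_period, n)

    n_late = sum(1 for r in params.reporters if r.timing == "late")
    gate = params.dose.gate() if params.dose is not None else 1.0

    truth = pd.DataFrame(
        {
            "cell_id": [f"cell{str(i).zfill(4)}" for i in range(n)],
            "responder": responder,
            "capacity": capacity,
            "commit_time": commit,
        }
    )

    per_rep: dict[str, dict[str, np.ndarray]] = {}
    for rep in params.reporters:
        intr = np.exp(rng.normal(0.0, params.sigma_intrinsic, n))
        basal_jitter = np.exp(rng.normal(0.0, params.sigma_intrinsic, n))
        if rep.timing == "early":
            tau = tau_early.copy()
        else:
            tau = commit.copy()
            if n_late > 1 and params.late_jitter_sd > 0:
                tau = np.clip(tau + rng.normal(0.0, params.late_jitter_sd, n),
                              params.min_onset, hi)
        amp = rep.amplitude * capacity * intr * gate
        amp = np.where(responder, amp, 0.0)
        per_rep[rep.channel] = {"tau": tau, "amp": amp, "basal_jitter": basal_jitter}
        truth[f"tau_{rep.channel}"] = np.where(responder, tau, np.nan)
        truth[f"amplitude_{rep.channel}"] = amp

    rows: list[pd.DataFrame] = []
    for i in range(n):
        cid = truth.loc[i, "cell_id"]
        nuc_area, cell_area, cfp_nuc, cfp_cyt = _areas_and_cfp(
            rng, n_frames, params.cyto_baseline
        )
        chans: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for rep in params.reporters:
            d = per_rep[rep.channel]
            signal = d["amp"][i] * _ramp(times, d["tau"][i], rep.ramp_min)
            if not responder[i]:
                signal = np.zeros_like(times)
            basal = rep.basal * capacity[i] * d["basal_jitter"][i]
            if rep.cell_cycle_pulse and rep.basal > 0:
                basal = basal * (
                    1.0
                    + params.cellcycle_amplitude
                    * np.sin(2.0 * np.pi * (times + cc_phase[i]) / params.cellcycle_period)
                )
            nuc = (
                params.cyto_baseline
                + basal
                + signal
                + rng.normal(0.0, params.noise_sd, n_frames)
            )
            cyt = params.cyto_baseline + rng.normal(0.0, params.noise_sd, n_frames)
            chans[rep.channel] = (np.abs(nuc), np.abs(cyt))
        chans["CFP"] = (cfp_nuc, cfp_cyt)
        for channel, (nucv, cytv) in chans.items():
            rows.append(
                pd.DataFrame(
                    {
                        "cell_id": cid,
                        "replicate_id": params.replicate_id,
                        "frame_time": times,
                        "channel": channel,
                        "nuclear_mean": nucv,
                        "cytoplasmic_mean": cytv,
                        "nuclear_area": nuc_area,
                        "cell_area": cell_area,
                    }
                )
            )
    table = validate_trace_table(pd.concat(rows, ignore_index=True))
    return table, truth


def simulate_mating(
    params: SimParams, rng: np.random.Generator | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a mating-pad experiment with a tdiRFP fusion channel.

    Fusing cells get a fusion frame inside their track; their tdiRFP series is
    baseline plus bounded jitter before fusion and jumps by ``step`` at it.
    Early-reporter onsets precede fusion by roughly an hour with large spread;
    late-reporter onsets tightly precede fusion by ~30 min.  Non-fusing cells
    induce the early reporter with the configured probability and (almost)
    never the late one; their tdiRFP stays flat within the jitter bound.
    Onsets are truncated so at least three basal frames precede them.
    """
    if params.mating is None:
        raise ValueError("params.mating must be set for simulate_mating")
    m = params.mating
    rng = rng if rng is not None else np.random.default_rng(params.seed)
    grid = params.mating_times
    n = params.n_cells

    step_min = params.post_step
    # fusion happens mid-movie; tracks of fusing cells must cover the late
    # induction window (~30 min) before fusion and a couple of frames after
    fus_lo = int(round(0.4 * (grid.size - 1)))
    fus_hi = int(round(0.8 * (grid.size - 1)))

    rows: list[pd.DataFrame] = []
    truth_rows: list[dict] = []
    for i in range(n):
        cid = f"cell{str(i).zfill(4)}"
        capacity = float(np.exp(rng.normal(0.0, params.sigma_extrinsic)))
        fusing = bool(rng.random() < m.fusion_fraction)
        if fusing:
            k_abs = int(rng.integers(fus_lo, fus_hi + 1))
            latest_start = k_abs - int(round(50.0 / step_min))
            start = int(rng.integers(0, max(1, latest_start + 1)))
            end = int(rng.integers(min(k_abs + 2, grid.size), grid.size + 1))
        else:
            max_start = grid.size - m.min_track_frames
            start = int(rng.integers(0, max_start + 1))
            end = int(rng.integers(start + m.min_track_frames, grid.size + 1))
        times = grid[start:end]
        n_frames = times.size

        tdirfp = m.tdirfp_baseline + rng.uniform(-m.drift, m.drift, n_frames)
        fusion_time = np.nan
        onsets: dict[str, float] = {}
        min_onset = float(times[2]) + params.post_step  # after the basal window
        if fusing:
            k = k_abs - start
            fusion_time = float(times[k])
            tdirfp[k:] += m.step
            for rep in params.reporters:
                if rep.timing == "early":
                    off = rng.normal(m.early_offset_mean, m.early_offset_sd)
                else:
                    off = rng.normal(m.late_offset_mean, m.late_offset_sd)
                onsets[rep.channel] = max(fusion_time - off, min_onset)
        else:
            expresses_early = rng.random() < m.nonfusing_early_prob
            for rep in params.reporters:
                if rep.timing == "early" and expresses_early:
                    onsets[rep.channel] = float(
                        rng.uniform(min_onset, max(times[-1], min_onset + 1e-6))
                    )
                else:
                    onsets[rep.channel] = np.nan

        nuc_area, cell_area, cfp_nuc, cfp_cyt = _areas_and_cfp(
            rng, n_frames, params.cyto_baseline
        )
        chans: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for rep in params.reporters:
            intr = float(np.exp(rng.normal(0.0, params.sigma_intrinsic)))
            tau = onsets[rep.channel]
            amp = rep.amplitude * capacity * intr
            if np.isnan(tau):
                signal = np.zeros(n_frames)
                amp = 0.0
            else:
                signal = amp * _ramp(times, tau, rep.ramp_min)
            nuc = params.cyto_baseline + signal + rng.normal(0, params.noise_sd, n_frames)
            cyt = params.cyto_baseline + rng.normal(0, params.noise_sd, n_frames)
            chans[rep.channel] = (np.abs(nuc), np.abs(cyt))
        chans["CFP"] = (cfp_nuc, cfp_cyt)
        chans["tdiRFP"] = (tdirfp, np.full(n_frames, np.nan))

        for channel, (nucv, cytv) in chans.items():
            rows.append(
                pd.DataFrame(
                    {
                        "cell_id": cid,
                        "replicate_id": params.replicate_id,
                        "frame_time": times,
                        "channel": channel,
                        "nuclear_mean": nucv,
                        "cytoplasmic_mean": cytv,
                        "nuclear_area": nuc_area,
                        "cell_area": cell_area,
                    }
                )
            )
        rec = {
            "cell_id": cid,
            "fusing": fusing,
            "fusion_time": fusion_time,
            "capacity": capacity,
            "track_start": float(times[0]),
            "track_end": float(times[-1]),
        }
        for rep in params.reporters:
            rec[f"tau_{rep.channel}"] = onsets[rep.channel]
        truth_rows.append(rec)

    table = validate_trace_table(pd.concat(rows, ignore_index=True))
    return table, pd.DataFrame(truth_rows)


def simulate_dose_series(
    params: SimParams, seed: int | None = None
) -> tuple[pd.DataFrame, dict[float, tuple[pd.DataFrame, pd.DataFrame]]]:
    """Run one simulation per dose of a dose-series preset.

    Returns a summary frame (dose_nM, mean_output, sd, n_cells) of per-dose
    mean expression output over all cells, plus the raw (table, truth) pairs.
    Each dose uses an independent child stream of the seed.
    """
    from .expression_timing import expression_output, preprocess_channel

    if params.doses is None or params.dose is None:
        raise ValueError("params must carry a dose model and a dose list")
    base_seed = params.seed if seed is None else seed
    streams = np.random.SeedSequence(base_seed).spawn(len(params.doses))
    summary = []
    raw = {}
    for dose, ss in zip(params.doses, streams):
        p = replace(params, dose=replace(params.dose, concentration=float(dose)))
        table, truth = simulate_population(p, rng=np.random.default_rng(ss))
        channel = params.reporters[0].channel
        corrected = preprocess_channel(table, channel)
        times = corrected.columns.to_numpy(dtype=float)
        outs = np.array(
            [expression_output(row.to_numpy(), times) for _, row in corrected.iterrows()]
        )
        summary.append(
            {
                "dose_nM": float(dose),
                "mean_output": float(outs.mean()),
                "sd": float(outs.std(ddof=1)),
                "n_cells": int(outs.size),
            }
        )
        raw[float(dose)] = (table, truth)
    return pd.DataFrame(summary), raw


PRESETS = {
    "fig1f": "dual-reporter strain: early pAGA1-like (YFP) vs late pFIG1-like (RFP)",
    "early_pair": "two co-regulated early-like reporters sharing onset and capacity",
    "late_pair": "early reference (YFP) vs a strongly delayed late reporter (RFP)",
    "intrinsic_only": "no extrinsic variability: independent reporter noise only",
    "dose_series_early": "graded dose response (Hill n=1, EC50 30 nM)",
    "dose_series_late": "switch-like dose response (Hill n=3, EC50 300 nM)",
    "mating_mix": "agar-pad mating mixture with tdiRFP fusion reporting",
}


def preset(name: str, n_cells: int | None = None, seed: int = 0) -> SimParams:
    """Named parameter bundles reproducing the study conditions.

    ``n_cells`` overrides the preset's default population size; ``seed`` seeds
    the generator.
    """
    if name == "fig1f":
        p = SimParams(
            n_cells=500,
            reporters=(
                ReporterSpec("YFP", 20.0, ramp_min=15.0, timing="early"),
                ReporterSpec("RFP", 10.0, ramp_min=15.0, timing="late"),
            ),
            responder_fraction=0.91,
            onset_shape=4.0,
            onset_scale=4.3,
            commit_delay_mean=23.0,
            commit_delay_sd=20.0,
            sigma_extrinsic=0.3,
            sigma_intrinsic=0.1,
            noise_sd=1.0,
            seed=seed,
        )
    elif name == "early_pair":
        p = SimParams(
            n_cells=300,
            reporters=(
                ReporterSpec("YFP", 20.0, ramp_min=15.0, timing="early", basal=5.0),
                ReporterSpec("RFP", 20.0, ramp_min=15.0, timing="early", basal=5.0),
            ),
            sigma_extrinsic=0.3,
            sigma_intrinsic=0.1,
            seed=seed,
        )
    elif name == "late_pair":
        p = SimParams(
            n_cells=500,
            reporters=(
                ReporterSpec("YFP", 20.0, ramp_min=15.0, timing="early"),
                ReporterSpec("RFP", 15.0, ramp_min=15.0, timing="late"),
            ),
            commit_delay_mean=25.0,
            commit_delay_sd=10.0,
            sigma_extrinsic=0.3,
            sigma_intrinsic=0.1,
            seed=seed,
        )
    elif name == "intrinsic_only":
        p = SimParams(
            n_cells=300,
            reporters=(
                ReporterSpec("YFP", 20.0, ramp_min=15.0, timing="early", basal=5.0),
                ReporterSpec("RFP", 20.0, ramp_min=15.0, timing="early", basal=5.0),
            ),
            responder_fraction=1.0,
            onset_fixed=15.0,
            sigma_extrinsic=0.0,
            sigma_intrinsic=0.3,
            seed=seed,
        )
    elif name == "dose_series_early":
        p = SimParams(
            n_cells=200,
            reporters=(ReporterSpec("YFP", 20.0, ramp_min=15.0, timing="early"),),
            dose=DoseModel(concentration=1000.0, ec50=30.0, hill_n=1.0),
            doses=(0.0, 10.0, 30.0, 100.0, 300.0, 1000.0),
            seed=seed,
        )
    elif name == "dose_series_late":
        p = SimParams(
            n_cells=200,
            reporters=(ReporterSpec("RFP", 20.0, ramp_min=15.0, timing="late"),),
            commit_delay_mean=23.0,
            commit_delay_sd=10.0,
            dose=DoseModel(concentration=1000.0, ec50=300.0, hill_n=3.0),
            doses=(0.0, 10.0, 30.0, 100.0, 300.0, 1000.0),
            seed=seed,
        )
    elif name == "mating_mix":
        p = SimParams(
            n_cells=100,
            reporters=(
                ReporterSpec("YFP", 20.0, ramp_min=15.0, timing="early"),
                ReporterSpec("RFP", 10.0, ramp_min=15.0, timing="late"),
            ),
            mating=MatingModel(),
            seed=seed,
        )
    else:
        raise ValueError(
            f"unknown preset {name!r}; available: {', '.join(sorted(PRESETS))}"
        )
    if n_cells is not None:
        p = replace(p, n_cells=n_cells)
    return p
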