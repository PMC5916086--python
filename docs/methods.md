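# Methods

This note documents the quantitative procedures the package implements, the
assumptions behind them, the synthetic data they are validated on, and the
numerical choices made where the procedure leaves room.

## Trace model and preprocessing

The unit of analysis is a per-cell time series of *nuclear enrichment*: the
difference between the mean nuclear and mean cytoplasmic fluorescence of a
reporter channel at each frame. For a dPSTR (dynamic protein synthesis
translocation reporter), promoter activity converts into nuclear relocation of
a constitutively expressed fluorophore, so enrichment tracks accumulated
expression without maturation delays. Kinase-activity sensors (SKARS) are read
as the cytoplasmic/nuclear ratio instead, since MAPK phosphorylation expels
the sensor from the nucleus.

Preprocessing is deliberately minimal and order-sensitive:

1. **Smoothing**: centered 3-point moving average. The end points average the
   two available frames rather than being dropped, so the three pre-stimulus
   frames needed for the basal estimate always survive.
2. **Basal**: mean of the smoothed values at the last three frames with
   t ≤ 0 (stimulation is at t = 0; the t = 0 frame counts as pre-stimulus).
3. **Correction**: corrected = smoothed − basal. The corrected trace is
   invariant to constant offsets of the raw signal and ≈0 before induction.

Default frame grid: −6, −4, −2 min (2-min pre-stimulus sampling), then 0, 5,
…, 100 min. Grids are taken from the data, never assumed.

**Quality control** keeps a cell only if it is tracked over the whole movie,
its nuclear/cell areas and nuclear CFP have coefficient of variation (sd/mean
over the track) at most 0.2, and its mean nuclear RFP/YFP ratio is at most
3.0. The CV and ratio cut-offs are package defaults — permissive enough to
keep clean traces, strict enough to reject segmentation failures — and all
configurable; the *rules* are standard for translocation-reporter movies.

## Expression output, expressing cells, response time

* **Expression output** = max of the corrected trace over t > 0. Not clamped:
  non-responders may have slightly negative outputs.
* **Population-averaged output** = max over t > 0 of the pointwise mean
  corrected trace (not the mean of per-cell maxima, so asynchronous peaks
  average down).
* **Expressing** ⇔ output ≥ 0.20 × population-averaged output. The boundary is
  inclusive.
* **Response time** = earliest frame t > 0 where corrected/output strictly
  exceeds 0.2. Normalizing by the cell's own maximum makes the estimate
  invariant to any shared gain of the channel; "exceeds" is strict. Traces are
  normalized by the maximum of the corrected trace rather than by
  (max − min); with basal-corrected traces the two coincide up to noise.

The estimator is frame-quantized by design: on a noiseless ramp whose true
20%-crossing is τ, it returns the first grid point strictly above τ, provided
the ramp starts after the smoothing window of the basal frames (onset at least
one frame interval past 20% of the ramp duration) and plateaus inside the
movie. When the onset corner falls closer to the stimulation frame, the moving
average rounds it and the estimate can shift by up to one frame in either
direction; when the reporter amplitude is within a few noise standard
deviations of the threshold, noise can trigger crossings before the true
onset. Both effects are properties of the published estimator, not of this
implementation, and both are visible in the recovery statistics below.

**Paired delays**: Δ = RT(test) − RT(reference) per cell expressing both
reporters, so a late test promoter gives positive Δ. The fraction of positive
Δ excludes exact ties from numerator and denominator (a tie on the quantized
grid carries no ordering information). The **sign test** is the exact
two-sided binomial test on the signs of nonzero Δ: p = 2·min(tails) under
Bin(n, ½), capped at 1.

## Covariation and CPV

Two normalizations are provided, both population-level so that every cell in a
replicate is scaled identically:

* *mean-trace normalization* (for single-cell scatter plots): divide by the
  peak of the population mean corrected trace;
* *min-max normalization* (for trajectory plots and CPV): map the population-
  averaged trace's range [m, M] to [0, 1]; individual cells may leave [0, 1].

The **correlative promoter variability** is the intrinsic/total noise ratio of
the classic dual-reporter decomposition,

    η²_int = ⟨(r−y)²⟩ / (2⟨r⟩⟨y⟩),
    η²_tot = (⟨r²⟩+⟨y²⟩−2⟨r⟩⟨y⟩) / (2⟨r⟩⟨y⟩),
    CPV    = η²_int / η²_tot = ⟨(r−y)²⟩ / (⟨r²⟩+⟨y²⟩−2⟨r⟩⟨y⟩),

with ⟨·⟩ the mean over cells at one time point. The 2⟨r⟩⟨y⟩ denominator
(versus the variant 2⟨ry⟩) is immaterial: it cancels in the ratio, which is
unit-tested. CPV is invariant under shared affine transforms of both channels
(exact identity), symmetric, 0 for identical reporters, and →1 for independent
ones.

CPV and the correlation trajectories are computed on **smoothed, not
basal-subtracted** enrichment ("nuclear accumulations"). This matters
pre-stimulus: basal expression levels differ between cells and are correlated
between co-regulated reporters through shared capacity and cell-cycle state;
subtracting each cell's basal would erase exactly the covariation the
statistic is meant to expose, forcing pre-stimulus CPV toward 1 regardless of
regulation.

The **diagonal-offset test** compares, at each time point, the signed
perpendicular distances d = (y−x)/√2 of the test strain's normalized pairs to
the x = y line against the same quantity in a reference strain (the reference
promoter on both channels), using Welch's unequal-variance t-test (the two
strains need not share variance; any monotone offset metric gives the same
test up to scale). P-values are reported raw per time point, with display
tiers at 10⁻³ and 10⁻⁶; no multiple-testing correction is applied across time
points, matching how such series are conventionally displayed.

## Dose response and timing classes

Mean expression output versus pheromone dose is fitted with
E(c) = base + amp·cⁿ/(EC50ⁿ + cⁿ) by least squares, multi-started over
n ∈ {0.5, 1, 2, 4} × EC50 ∈ positive-dose quartiles; the zero-dose control
enters as c = 0. Per-dose sd can weight the fit but is off by default. A fit
whose amplitude collapses below 5% of the output span is flagged
non-converged (Hill n unidentifiable on flat data).

Timing classes operationalize the qualitative early/intermediate/late
definition:

| class | rule (defaults) |
|---|---|
| late | median Δ ≥ 15 min AND offsets significant (p < 10⁻³) at ≥ 50% of post-stimulus frames |
| early | \|median Δ\| < 5 min AND significant at < 25% of frames |
| intermediate | everything else |

Only the 15-min bound is an established quantity; the 5-min early bound and
the ¼/½ fractions are package defaults required to make the rule executable,
and all are configurable. Without a reference strain the rule degrades to the
delay thresholds alone.

## Mating mode

Fusion of a MATa cell with its tdiRFP-expressing MATα partner floods the MATa
cell with tdiRFP. A cell is *fusing* if any frame-to-frame increase of its
nuclear tdiRFP exceeds 50 AU (fusion time = the frame after the jump;
"sudden" is evaluated over one frame by default since fusion is effectively
instantaneous at 5-min sampling, with a configurable window); *non-fusing* if
the maximal forward increase max_{i<j}(F_j − F_i) never exceeds 10 AU; cells
between the two bounds are *indeterminate* and excluded from both groups
(the two published definitions do not cover this gap). Only cells tracked
≥ 10 frames are classified. The detector depends only on differences, so it is
invariant to fluorescence offsets and time shifts.

Because pad experiments have no global stimulation time, the basal level is
taken from the first three frames of each track, and the population-averaged
output is the max over absolute-time frames of the mean corrected trace over
the cells present in each frame. Traces of fusing cells are aligned at their
fusion time (relative time 0) with median and quartile bands per relative-time
bin; response times relative to fusion (negative = before fusion) are
summarized as right-continuous ECDFs.

## PRE scanner

Consensus Ste12 binding sites (PREs) are nTGAAACn: matching is on the 6-bp
core TGAAAC (N never matches), on both strands, with hits reported in
plus-strand 0-based half-open coordinates; the unconstrained flanking
positions widen the reported interval to the 8-mer context, truncated at
sequence edges only when the core is fully inside. *Non-consensus* sites carry
up to `max_mismatch` core mutations (default 1, configurable to 2 to recover
weaker drawn sites). Promoter sequences are expected 5'→3' toward the start
codon, so distance-to-ATG is the gap between a hit and the sequence 3' end. A
site overlapping a mapped nucleosome interval by ≥ 1 bp is annotated
inaccessible; pairs of accessible consensus sites — the early-promoter
signature enabling cooperative Ste12 dimer loading before stimulation — are
enumerated with center-to-center spacing. No affinity model or PWM scoring is
attempted: the analysis is architectural (counts, positions, accessibility).

## Synthetic data: what it emulates

The generator produces trace tables with the statistical structure the
analysis assumes, plus a per-cell truth table:

* a lognormal per-cell **capacity** E (σ_E, shared by all reporters of a
  cell) — the dominant, extrinsic variability of mating-gene expression;
* lognormal per-reporter amplitude jitter I (σ_I) — intrinsic variability;
* early onsets τ_e ~ Gamma(4, 4.3) min; late onsets share a per-cell
  **commitment time** τ_e + Δ with Δ ~ Normal (negative Δ allowed: a cell may
  commit before its early reporter crosses threshold), plus small
  per-promoter jitter when several late reporters are present;
* the noiseless corrected signal is a linear ramp A·E·I·H(dose)·
  clip((t−t0)/T_ramp, 0, 1) with t0 = τ − 0.2·T_ramp, so the generator's
  truth is defined in the estimator's own observable: the 20% crossing is
  exactly τ, independent of ramp duration;
* dose gates amplitude through a Hill function (graded n = 1 / EC50 30 nM for
  early-like, switch-like n = 3 / EC50 300 nM for late-like presets);
* optional constant or cell-cycle-modulated basal expression (scaled by E, so
  co-regulated pairs covary pre-stimulus);
* raw channels: cytoplasm = 100 + ε, nucleus = 100 + basal + signal + ε, with
  ε ~ N(0, 1 AU) per compartment per frame; constant-plus-noise CFP and
  areas so that default QC retains ≥95% of cells.

Onsets are clipped below at 2 min (commitment cannot precede stimulation) and
optionally above, to keep responses inside the movie. The exact-recovery
guarantee of the response-time estimator (error in [0, one frame] for every
cell) holds when onsets satisfy τ ≥ 0.2·T_ramp + one frame interval and the
ramp plateaus inside the movie; recovery tests use an onset window of
[11, 60] min with the default 30-min ramp for that reason. The dual-reporter
presets use a 15-min ramp, where onset-corner smoothing can advance single
estimates by <1 min — included deliberately, since the estimator is used in
exactly this regime.

Mating mode: fusion times fall on grid frames in the middle 40–80% of a
150-min movie; tracks of fusing cells start ≥50 min before fusion and end
after it, so the late induction window is observable. tdiRFP is baseline 20 AU
plus bounded ±3 AU jitter, stepping by 100 AU at fusion (non-fusing cells:
jitter only, hence a total rise ≤ 6 AU, within the non-fusing bound by
construction). Early onsets precede fusion by Normal(60, 25) min, late onsets
by Normal(30, 8) min, truncated so three basal frames precede them; 80% of
non-fusing cells induce only the early reporter.

**What the generator does not emulate** — and hence what passing tests do not
establish about real data: photobleaching and focus drift, segmentation and
tracking errors, reporter maturation and degradation kinetics, saturating
ramps of non-linear shape, pheromone degradation by Bar1 (dose series treat
each concentration independently), spatial pheromone gradients in mating pads,
and any mechanistic Ste12/Kar4 promoter model. Recovery of the calibrated
statistics shows the pipeline is correct and unbiased under its stated model,
not that the model captures every microscopy artifact.

## Calibrated presets and recovered statistics

Preset parameters are design choices encoding the reported population
behavior, fixed before measurement and not tuned afterwards:

* `fig1f` — 500 cells, 91% responders, early A = 20 AU (YFP), late A = 10 AU
  (RFP), Δ ~ Normal(23, 20) min, σ_E = 0.3, σ_I = 0.1, noise 1 AU, 15-min
  ramps. The pipeline recovers ≈85% of dual-expressing cells with the early
  reporter first (the positive-Δ probability of the delay law is 87.5%), a
  mean measured delay ≈20.5 min, and ≈84% of cells responding within 30 min.
  The ~2.5-min shrinkage of the mean delay relative to the generating 23-min
  law is the noise-induced early-crossing tail of the threshold estimator on
  the weak late reporter; it is reported as measured.
* `early_pair` / `intrinsic_only` — two co-regulated early reporters with
  basal 5 AU; extrinsic-dominated (σ_E = 0.3 ≫ σ_I = 0.1) versus purely
  intrinsic (σ_E = 0, σ_I = 0.3, fixed onset). Pre-stimulus CPV ≈ 27% for the
  correlated pair; ≈ 0.95 throughout for the independent pair.
* `late_pair` — early reference vs late reporter with Δ ~ Normal(25, 10);
  median measured delay 25 min, classified late against an `early_pair`
  reference strain.
* `dose_series_early` / `dose_series_late` — 200 cells per dose at
  {0, 10, 30, 100, 300, 1000} nM; Hill fits recover n ≈ 1.0 and n ≈ 3.2.

Problem sizes throughout (500-cell populations, 5 seeds, 3 replicates,
20-seed fusion sweeps) were chosen so Monte-Carlo error is small against the
stated tolerances while the whole suite stays interactive.

## Numerical choices and degenerate inputs

* Smoothing end frames use shrunken windows (mean of two values).
* "Exceeds 0.2" (response time) is strict; "≥ 20%" (expressing) is inclusive.
* Empty results are write errors, never empty files.
* classify_expressing raises on a non-positive population output
  ("population non-responsive"); cpv returns 0 for identical constant
  reporters (no variability to decompose) and the Welch test returns p = 1
  with a warning when both groups are degenerate at the same mean.
* Min-max normalization raises on a constant population trace; sign test on
  all-zero deltas returns 1 with a warning.
* Hill fitting bounds n to [0.05, 10] and EC50 to two decades beyond the dose
  range; ties in the multi-start are broken by the smaller residual.

## Known limitations

* The response-time estimator has one-frame quantization and, for reporters
  whose 20% threshold is within ~2 noise sd, a pre-onset false-crossing tail;
  sub-frame onset fitting is deliberately out of scope.
* The expressing threshold references the population output, so on a
  completely non-responding noisy population every cell can spuriously
  qualify; the pipeline surfaces this only when the population output is
  non-positive.
* Timing classes depend on two invented cut-offs (5 min, ¼/½ fractions)
  wherever the delay bound alone is ambiguous.
* CPV is reported as a ratio only; the separate absolute intrinsic and
  extrinsic noise magnitudes are not decomposed.
* Mating analysis uses only the tdiRFP transfer signal; no partner pairing or
  geometry is inferred.
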