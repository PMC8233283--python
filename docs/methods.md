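# Methods

## Calcium trace calibration

Traces are long-format tables of per-cell F340/F380 samples plus a
per-experiment scalar background per wavelength. Background is subtracted
first; samples whose corrected F380 is non-positive cannot be ratioed and
are flagged invalid rather than dropped, so downstream statistics see them
as missing. The ratio R = F340/F380 is converted to calcium with the
standard ratiometric form Ca = K_d·β·(R − R_min)/(R_max − R).

Parameter defaults: K_d = 225 nM (the classical in-vitro Fura-2 value),
R_min = 0.5, R_max = 8.0, β = 9.0. These are plausible wide-field
microscope values, not claims about any particular rig; real analyses
should supply constants from their own calibration. Numerical handling at
the boundaries: R ≤ R_min clamps to 0 nM (resting noise can undershoot
R_min and a negative concentration would corrupt derivative statistics);
R ≥ R_max is dye saturation and maps to missing with a saturation flag.
Calcium is strictly increasing in R on (R_min, R_max), and the inverse map
used by the simulator composes with calibration to the identity (tested to
1e−9 relative over random parameter draws).

The per-experiment scalar background (rather than per-frame) is the
simplest model consistent with typical acquisition; the subtraction step
is isolated so a per-frame model can be slotted in.

## Responder classification

Per cell and agonist application window:

* baseline calcium = mean of the calibrated trace over the baseline
  window (median available via `baseline_stat`; the mean is the
  conventional choice);
* amplitude = max over the application window − baseline; the amplitude
  criterion is a strict `> 50 nM`;
* the trace is smoothed with a centered moving average (default width 3
  samples; width 1 disables smoothing) and differentiated with central
  finite differences (one-sided at the ends), in nM/s. The derivative
  criterion is a strict `max > 3 × SD` of the baseline-window derivative
  (population SD, `ddof` configurable).

Both criteria must hold. Light smoothing is applied by default because an
unsmoothed finite-difference derivative of a noisy trace is dominated by
frame-to-frame noise, which inflates the baseline SD and deflates
sensitivity; the width is a parameter since the right value depends on
frame rate. The peak search covers the entire stated application window
with no onset-latency trimming.

The ionomycin window is a positive control. The viability filter is OFF
by default — a positive control does not by itself imply exclusion — but
when enabled, cells whose ionomycin rise is below `viability_min_amplitude`
(default 50 nM) are excluded from all counts.

Cells with fewer than 3 valid samples overall, in the baseline window, or
with no valid application-window sample, are excluded with a reason code.
Per-cell calls are invariant to the row order of the input table (samples
are sorted by time within each cell before differentiation).

## Cohort statistics

Experiment summaries count usable (non-excluded) cells. The cohort view
reports the mean ± SEM of per-experiment responder fractions (SEM =
SD/√n_experiments, sample SD) — the experiment is the independent unit —
plus the pooled count percentage 100·Σresponders/Σcells. Percentages are
rounded to integers only at presentation.

Group comparisons delegate to scipy: Student/paired t, Mann–Whitney, and
Fisher's exact on count pairs. A paired design whose difference vector is
identically zero has an undefined t statistic and is reported as a "no
difference" result instead of a numeric p. Multi-condition trends versus a
control are computed on ΔCt values (never on fold changes, whose
log-normality would distort the test): one-way ANOVA followed by Dunnett's
test (scipy implementation), or Kruskal–Wallis followed by pairwise
Mann–Whitney with Holm adjustment — the latter is a substitute for Dunn's
post-hoc, which no installed library provides, and is labeled as such in
the output. `method="auto"` gates on D'Agostino–Pearson normality per
group (groups under 8 observations are assumed normal, since the omnibus
test is undefined/unstable there). If every observation is identical the
trend table short-circuits to "no significant comparisons" rather than
propagating a 0/0 F statistic.

## qPCR relative quantification

Replicate Cts are averaged per (sample, gene) first; replicates at or
above the detection floor (Ct 40, configurable — the conventional cutoff)
are dropped, and a gene with no detected replicate is `not_detected`.
ΔCt subtracts the geometric mean of the housekeeping *mean Cts* — the
literal reading of the standard formula (the alternative, a geometric mean
of relative quantities, is deliberately not the default). A consequence
worth noting: the geometric mean of Ct values is not exactly
translation-equivariant, so 2^−ΔCt is invariant to a global Ct shift of a
sample only approximately (error < 0.01 cycles for housekeepers ~2 cycles
apart and shifts of a few cycles; exact when the housekeepers agree). The
property tests encode both facts.

Percent-of-reference uses a single normalization value: the mean Trpm7
ΔCt over all conditions in the stated scope. Category bands are a total,
monotone step function of percent: >100% high, [5, 100] moderate, [1, 5)
low, [0, 1) below_detection — lower band edges inclusive and 100%
inclusive in moderate, since the printed ranges touch without stating
openness. Fold change versus a baseline condition averages ΔCt within
(gene, condition) before differencing; the baseline maps to fold 1 by
construction. Strain contrasts report 100·(rel_A/rel_B − 1) per gene,
averaged over shared conditions with SEM.

## RNA-seq

RPKM = counts/(length_kb × totals_millions). Gene lengths are an explicit
input (exon-union versus transcript-length conventions differ between
quantitation pipelines, so no convention is assumed). Per-sample totals
may exceed in-matrix column sums (the matrix often holds a gene subset);
when absent they default to column sums. Heatmap values add a pseudocount
of 1 before log2 (configurable; 1 keeps zero counts at 0 and compresses
nothing above ~1 RPKM) and subtract each row's mean, making rows sum to
zero; centering is idempotent. The `fold_change_rank_table` helper (mean
RPKM log2 fold change + Mann–Whitney p with Benjamini–Hochberg adjustment)
is a ranking aid only and labels itself "not DESeq2"; genuine differential
expression belongs to dedicated tools.

## Synthetic data generator

The trace generator emulates the targeted imaging conditions: resting
[Ca²⁺]ᵢ 100 nM; additive Gaussian noise (default SD 5 nM) on the latent
calcium signal *before* inversion to fluorescence — the simplest noise
model consistent with example traces, kept pluggable; responder amplitudes
Normal(150, 25) nM truncated at 0, matching the order of published agonist
response amplitudes; non-responders draw a true amplitude uniform in
[0, 25] nM so the 50 nM rule is unambiguous at default noise; first-order
rise (τ = 2 s) within the application window and exponential decay
(τ = 10 s) after it — published traces are not kinetically quantified, so
these are free config parameters, not claims; a universal ionomycin rise
to 1 µM (used to exercise the viability filter); frame interval 1 s.
Latent calcium is mapped to a ratio by the exact calibration inverse;
F380 interpolates between β·scale (zero calcium) and scale (saturation)
as a function of the bound fraction Ca/(Ca+K_d), F340 = R·F380, optional
photobleaching multiplies both channels (ratio-invariant), and the scalar
background is added last. Calibrating the emitted fluorescence therefore
reproduces the latent trace exactly at zero noise.

What the generator does **not** emulate: shot noise and optics (noise in
real data is multiplicative in fluorescence, not additive in calcium),
focus drift, motion, ROI segmentation errors, cell-to-cell baseline
heterogeneity, and oscillatory or multi-phasic responses. Passing tests
demonstrate the *analysis arithmetic* is correct under the stated model,
not that the classifier is robust to every artifact of real recordings.

The Ct generator places the reference gene (Trpm7) `trpm7_delta_ct`
cycles (default 5, a realistic moderate-abundance offset) above the
housekeeping geometric mean and derives each target's true Ct from its
requested fraction of the reference, with Gaussian replicate noise in
cycles (triplicates by default). The count generator draws per-gene
expected RPKM log-normally (median 10) and counts negative-binomially
(dispersion 0.1) around length- and depth-scaled means.

All generators are pure functions of (config, seed); identical seeds give
bitwise-identical tables.

## Problem sizes and determinism

Default verification sizes — 500 cells for classifier recovery, 10⁴
parameter draws for the calibration round trip, 1000 toy traces for the
rule-text oracle, all 2×2 tables with group sizes ≤ 15 (~18k tables) for
the Fisher enumeration — complete in seconds on one core while leaving no
realistic room for coincidental agreement. The pipeline driver derives all
per-module seeds deterministically from one top-level seed, and re-running
with identical inputs produces byte-identical outputs.

## Known limitations

* Calibration constants are placeholders until supplied from a real
  calibration; absolute nM values scale with them even though responder
  calls are fairly insensitive near the defaults.
* The responder rule evaluates a single application window per call;
  oscillation detection and multi-peak deconvolution are out of scope.
* Amplification-efficiency correction (Pfaffl) is not implemented; the
  comparative-Ct method assumes ~100% efficiency for all assays.
* Published per-experiment breakdowns are generally unavailable, so
  mean ± SEM conventions can only be cross-checked against pooled counts
  where the two are consistent.
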