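"""Ground-truth-labeled synthetic inputs for every pipeline stage.

Three generators are provided:

* :func:`simulate_calcium_traces` — Fura-2 dual-wavelength trace sets.  A
  latent per-cell [Ca2+]i(t) is built (resting level ~100 nM plus Gaussian
  noise; responders add an agonist-locked rise with first-order rise/decay
  kinetics; every cell rises during ionomycin) and inverted through the
  ratiometric calibration model to emit F340/F380 plus additive background,
  so that calibration of the simulated fluorescence recovers the latent
  calcium exactly when noise and background are zero.
* :func:`simulate_ct_table` — replicate qPCR Ct tables with housekeeping
  genes, constructed so the expected relative expression of each target is
  a requested fraction of the reference channel (Trpm7).
* :func:`simulate_count_matrix` — overdispersed (negative-binomial) RNA-seq
  count matrices with gene lengths and library sizes.

All generators are pure functions of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .calibration import CalibrationParams, DEFAULT_PARAMS, calcium_to_ratio
from .responders import ProtocolWindows, Window


class SimulationError(ValueError):
    """Invalid simulation configuration."""


@dataclass(frozen=True)
class TraceSimConfig:
    """Study conditions for the Fura-2 trace generator.

    Defaults emulate the imaging conditions the pipeline targets: ~100 nM
    resting calcium, agonist-evoked rises of order 150 nM with seconds-scale
    first-order kinetics, and a strong ionomycin rise at the end of every
    recording.  Non-responders draw a small true amplitude in [0, 25] nM so
    the 50 nM responder rule is unambiguous at the default noise level.
    """

    n_cells: int = 50
    n_experiments: int = 1
    frame_interval: float = 1.0  # s
    baseline_ca: float = 100.0  # nM
    baseline_noise_sd: float = 5.0  # nM, additive Gaussian on latent calcium
    responder_fraction: float = 0.65
    amplitude_mean: float = 150.0  # nM, truncated at 0
    amplitude_sd: float = 25.0  # nM
    nonresponder_amplitude_max: float = 25.0  # nM
    rise_tau: float = 2.0  # s
    decay_tau: float = 10.0  # s
    ionomycin_ca: float = 1000.0  # nM
    background_340: float = 50.0  # fluorescence units
    background_380: float = 50.0
    f380_scale: float = 500.0  # F380 at saturating calcium, before bleaching
    photobleach_rate: float = 0.0  # fraction per second, both channels
    calibration: CalibrationParams = field(default_factory=CalibrationParams)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.frame_interval <= 0:
            raise SimulationError("frame_interval must be positive")
        if not (0.0 <= self.responder_fraction <= 1.0):
            raise SimulationError("responder_fraction must lie in [0, 1]")
        if min(self.rise_tau, self.decay_tau) <= 0:
            raise SimulationError("time constants must be positive")
        if self.n_cells < 1 or self.n_experiments < 1:
            raise SimulationError("need at least one cell and one experiment")


def default_windows(
    baseline_s: float = 60.0,
    application_s: float = 60.0,
    washout_s: float = 20.0,
    ionomycin_s: float = 30.0,
    agonist_name: str = "agonist",
) -> ProtocolWindows:
    """Baseline -> single agonist application -> washout -> ionomycin."""
    t0 = baseline_s
    t1 = t0 + application_s
    t2 = t1 + washout_s
    return ProtocolWindows((
        Window("baseline", 0.0, t0),
        Window("application", t0, t1, agonist_name),
        Window("ionomycin", t2, t2 + ionomycin_s, "ionomycin"),
    ))


def _response_kernel(time: np.ndarray, window: Window, amplitude: float,
                     rise_tau: float, decay_tau: float) -> np.ndarray:
    """First-order rise within the window, exponential decay after it."""
    out = np.zeros_like(time)
    during = (time >= window.t_start) & (time <= window.t_end)
    out[during] = amplitude * (1.0 - np.exp(-(time[during] - window.t_start) / rise_tau))
    after = time > window.t_end
    peak = amplitude * (1.0 - np.exp(-(window.t_end - window.t_start) / rise_tau))
    out[after] = peak * np.exp(-(time[after] - window.t_end) / decay_tau)
    return out


@dataclass(frozen=True)
class FluorescenceTraceSet:
    """Long-format trace table plus per-experiment background levels."""

    traces: pd.DataFrame  # experiment_id, cell_id, time_s, F340, F380
    background: pd.DataFrame  # experiment_id, background_340, background_380


def simulate_calcium_traces(
    config: TraceSimConfig,
    windows: ProtocolWindows,
) -> tuple[FluorescenceTraceSet, pd.DataFrame]:
    """Simulate a Fura-2 trace set with per-cell ground truth.

    Returns ``(trace_set, ground_truth)`` where ground truth holds, per
    cell, the true responder flag, true amplitude (nM) and onset time (s).
    Responders respond in every application window with the same amplitude.
    """
    rng = np.random.default_rng(config.seed)
    cal = config.calibration
    time = np.arange(0.0, windows.t_end + 0.5 * config.frame_interval, config.frame_interval)
    if time[-1] > windows.t_end:
        time = time[:-1]
    apps = windows.applications
    onset = apps[0].t_start

    trace_rows, truth_rows = [], []
    for e in range(config.n_experiments):
        exp_id = f"exp{e + 1:02d}"
        for c in range(config.n_cells):
            cell_id = f"cell{c + 1:04d}"
            is_resp = bool(rng.random() < config.responder_fraction)
            if is_resp:
                amp = -1.0
                while amp < 0.0:
                    amp = rng.normal(config.amplitude_mean, config.amplitude_sd)
            else:
                amp = rng.uniform(0.0, config.nonresponder_amplitude_max)
            latent = np.full_like(time, config.baseline_ca)
            for app in apps:
                latent = latent + _response_kernel(time, app, amp, config.rise_tau, config.decay_tau)
            ion = windows.ionomycin
            if ion is not None:
                latent = latent + _response_kernel(
                    time, ion, config.ionomycin_ca - config.baseline_ca,
                    config.rise_tau, config.decay_tau,
                )
            if config.baseline_noise_sd > 0:
                latent = latent + rng.normal(0.0, config.baseline_noise_sd, size=time.shape)
            latent = np.clip(latent, 0.0, None)

            ratio = calcium_to_ratio(latent, cal)
            # F380 interpolates between beta*scale (zero Ca) and scale (saturation)
            bound = latent / (latent + cal.kd_nm)
            f380 = config.f380_scale * ((1.0 - bound) * cal.beta + bound)
            if config.photobleach_rate > 0:
                f380 = f380 * np.exp(-config.photobleach_rate * time)
            f340 = ratio * f380
            trace_rows.append(pd.DataFrame({
                "experiment_id": exp_id,
                "cell_id": cell_id,
                "time_s": time,
                "F340": f340 + config.background_340,
                "F380": f380 + config.background_380,
            }))
            truth_rows.append((exp_id, cell_id, is_resp, amp, onset))

    traces = pd.concat(trace_rows, ignore_index=True)
    background = pd.DataFrame({
        "experiment_id": [f"exp{e + 1:02d}" for e in range(config.n_experiments)],
        "background_340": config.background_340,
        "background_380": config.background_380,
    })
    truth = pd.DataFrame(
        truth_rows,
        columns=["experiment_id", "cell_id", "is_responder", "true_amplitude_nM", "onset_time_s"],
    )
    return FluorescenceTraceSet(traces, background), truth


def simulate_ct_table(
    true_rel_expression: dict[str, float],
    housekeeping_cts: dict[str, float] | None = None,
    n_replicates: int = 3,
    ct_noise_sd: float = 0.0,
    seed: int = 0,
    reference_gene: str = "Trpm7",
    trpm7_delta_ct: float = 5.0,
    sample_id: str = "S1",
    condition: str = "E14.5",
) -> pd.DataFrame:
    """Simulate a replicate Ct table for one sample.

    ``true_rel_expression`` maps target gene -> expression as a fraction of
    the reference gene (Trpm7).  The reference gene itself sits
    ``trpm7_delta_ct`` cycles above the geometric mean of the housekeeping
    Cts, so at zero noise the relative-quantification engine recovers each
    requested fraction exactly.  Replicate noise is Gaussian in Ct (cycles).
    """
    if housekeeping_cts is None:
        housekeeping_cts = {"Actb": 19.0, "Gapdh": 21.0}
    if n_replicates < 1:
        raise SimulationError("n_replicates must be >= 1")
    bad = {g: f for g, f in true_rel_expression.items() if not (f > 0)}
    if bad:
        raise SimulationError(f"target fractions must be positive: {bad}")
    rng = np.random.default_rng(seed)
    gmean_hk = float(np.exp(np.mean(np.log(list(housekeeping_cts.values())))))
    true_ct = dict(housekeeping_cts)
    true_ct[reference_gene] = gmean_hk + trpm7_delta_ct
    for gene, frac in true_rel_expression.items():
        if gene == reference_gene:
            continue
        true_ct[gene] = gmean_hk + trpm7_delta_ct - np.log2(frac)
    rows = []
    for gene, ct in true_ct.items():
        for rep in range(1, n_replicates + 1):
            noisy = ct + (rng.normal(0.0, ct_noise_sd) if ct_noise_sd > 0 else 0.0)
            rows.append((sample_id, condition, gene, rep, noisy))
    return pd.DataFrame(rows, columns=["sample_id", "condition", "gene", "replicate", "ct"])


@dataclass(frozen=True)
class CountMatrix:
    """Gene x sample counts with gene lengths (bp) and total mapped reads."""

    counts: pd.DataFrame  # genes x samples, integer
    gene_lengths: pd.Series  # bp, indexed by gene
    total_reads: pd.Series  # per sample

    def __post_init__(self) -> None:
        if (self.gene_lengths <= 0).any():
            raise SimulationError("gene lengths must be positive")
        if (self.total_reads <= 0).any():
            raise SimulationError("library sizes must be positive")


def simulate_count_matrix(
    n_genes: int = 100,
    n_samples: int = 6,
    gene_lengths=None,
    library_sizes=None,
    expected_rpkm=None,
    dispersion: float = 0.1,
    seed: int = 0,
) -> CountMatrix:
    """Simulate a negative-binomial RNA-seq count matrix.

    Per-gene expected RPKM defaults to a log-normal draw (median 10);
    expected counts are ``rpkm * length_kb * library_size / 1e6`` and counts
    are negative-binomial with the given dispersion.  Total mapped reads per
    sample are reported as the library sizes (they may exceed the in-matrix
    column sums, as in real data where the matrix holds a gene subset).
    """
    rng = np.random.default_rng(seed)
    genes = [f"gene{i + 1:04d}" for i in range(n_genes)]
    samples = [f"sample{j + 1:02d}" for j in range(n_samples)]
    if gene_lengths is None:
        gene_lengths = rng.integers(500, 5000, size=n_genes).astype(float)
    gene_lengths = pd.Series(np.asarray(gene_lengths, dtype=float), index=genes, name="length_bp")
    if library_sizes is None:
        library_sizes = np.full(n_samples, 5e6)
    library_sizes = np.asarray(library_sizes, dtype=float)
    if (gene_lengths <= 0).any() or (library_sizes <= 0).any():
        raise SimulationError("gene lengths and library sizes must be positive")
    if expected_rpkm is None:
        expected_rpkm = rng.lognormal(mean=np.log(10.0), sigma=1.0, size=n_genes)
    expected_rpkm = np.asarray(expected_rpkm, dtype=float)

    mu = np.outer(expected_rpkm * gene_lengths.to_numpy() / 1e3, library_sizes / 1e6)
    counts = np.zeros_like(mu, dtype=np.int64)
    pos = mu > 0
    if dispersion > 0:
        size = 1.0 / dispersion
        p = size / (size + mu[pos])
        counts[pos] = rng.negative_binomial(size, p)
    else:
        counts[pos] = rng.poisson(mu[pos])
    counts_df = pd.DataFrame(counts, index=genes, columns=samples)
    totals = pd.Series(library_sizes, index=samples, name="total_reads")
    return CountMatrix(counts_df, gene_lengths, totals)
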