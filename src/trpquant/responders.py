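"""Per-cell agonist responder classification on calibrated calcium traces.

A cell is a responder to an agonist when both criteria hold during the
application window:

* amplitude criterion — the calcium rise (peak minus baseline-window
  calcium) strictly exceeds ``amplitude_min`` (default 50 nM);
* derivative criterion — the maximum of the trace derivative strictly
  exceeds ``derivative_sd_multiple`` (default 3) times the standard
  deviation of the derivative during the baseline window.

An ionomycin window at the end of the protocol serves as a positive
control; an optional viability filter excludes cells that fail to respond
to it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

WINDOW_COLUMNS = ["label", "t_start_s", "t_end_s", "agonist_name"]
WINDOW_LABELS = {"baseline", "application", "ionomycin"}


class WindowError(ValueError):
    """Protocol windows violate the ordering/labeling contract."""


@dataclass(frozen=True)
class Window:
    label: str
    t_start: float
    t_end: float
    agonist_name: str = ""

    def __post_init__(self) -> None:
        if self.label not in WINDOW_LABELS:
            raise WindowError(f"unknown window label {self.label!r}")
        if not (self.t_start < self.t_end):
            raise WindowError(f"window {self.label!r}: t_start must precede t_end")

    def mask(self, time: np.ndarray) -> np.ndarray:
        return (time >= self.t_start) & (time <= self.t_end)


@dataclass(frozen=True)
class ProtocolWindows:
    """Ordered, non-overlapping protocol intervals.

    Exactly one baseline window must precede the first agonist application;
    at most one ionomycin window is allowed and it must come last.
    """

    windows: tuple[Window, ...]

    def __post_init__(self) -> None:
        ws = self.windows
        if not ws:
            raise WindowError("at least one window required")
        for a, b in zip(ws, ws[1:]):
            if b.t_start < a.t_end:
                raise WindowError(f"windows {a.label!r} and {b.label!r} overlap")
        baselines = [w for w in ws if w.label == "baseline"]
        if len(baselines) != 1:
            raise WindowError("exactly one baseline window required")
        apps = self.applications
        if not apps:
            raise WindowError("at least one application window required")
        if baselines[0].t_end > apps[0].t_start:
            raise WindowError("baseline window must precede the first application")
        ionos = [w for w in ws if w.label == "ionomycin"]
        if len(ionos) > 1:
            raise WindowError("at most one ionomycin window allowed")
        if ionos and ws[-1].label != "ionomycin":
            raise WindowError("ionomycin window must be last")

    @classmethod
    def from_list(cls, rows) -> "ProtocolWindows":
        return cls(tuple(Window(*r) if not isinstance(r, Window) else r for r in rows))

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ProtocolWindows":
        missing = [c for c in WINDOW_COLUMNS if c not in df.columns]
        if missing:
            raise WindowError(f"windows table is missing required column(s): {missing}")
        rows = [
            Window(r.label, float(r.t_start_s), float(r.t_end_s), "" if pd.isna(r.agonist_name) else str(r.agonist_name))
            for r in df.itertuples()
        ]
        return cls(tuple(rows))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(w.label, w.t_start, w.t_end, w.agonist_name) for w in self.windows],
            columns=WINDOW_COLUMNS,
        )

    @property
    def baseline(self) -> Window:
        return next(w for w in self.windows if w.label == "baseline")

    @property
    def applications(self) -> tuple[Window, ...]:
        return tuple(w for w in self.windows if w.label == "application")

    @property
    def ionomycin(self) -> Window | None:
        ion = [w for w in self.windows if w.label == "ionomycin"]
        return ion[0] if ion else None

    @property
    def t_end(self) -> float:
        return self.windows[-1].t_end

    def application(self, agonist_name: str) -> Window:
        for w in self.applications:
            if w.agonist_name == agonist_name:
                return w
        raise WindowError(f"no application window for agonist {agonist_name!r}")


@dataclass(frozen=True)
class ResponderThresholds:
    """Classifier settings; defaults follow the two-criterion responder rule."""

    amplitude_min: float = 50.0  # nM, strict inequality
    derivative_sd_multiple: float = 3.0
    smoothing_window: int = 3  # samples; 1 disables smoothing
    viability_filter: bool = False
    viability_min_amplitude: float = 50.0  # nM rise during ionomycin
    baseline_stat: str = "mean"  # or "median"
    sd_ddof: int = 0  # population SD by default

    def __post_init__(self) -> None:
        if not (self.amplitude_min > 0 and self.derivative_sd_multiple > 0):
            raise ValueError("thresholds must be positive")
        if self.smoothing_window < 1 or self.smoothing_window % 2 == 0:
            raise ValueError("smoothing_window must be odd and >= 1")
        if self.baseline_stat not in ("mean", "median"):
            raise ValueError("baseline_stat must be 'mean' or 'median'")


@dataclass(frozen=True)
class ResponderCall:
    """Classification result for one cell and one agonist application."""

    experiment_id: str
    cell_id: str
    agonist_name: str
    is_responder: bool
    baseline_ca: float
    peak_ca: float
    amplitude: float
    max_derivative: float
    baseline_derivative_sd: float
    amplitude_criterion_met: bool
    derivative_criterion_met: bool
    excluded: bool = False
    exclusion_reason: str = ""


def moving_average(values: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average; edges average the samples actually available."""
    if window == 1:
        return np.asarray(values, dtype=float)
    return (
        pd.Series(np.asarray(values, dtype=float))
        .rolling(window, center=True, min_periods=1)
        .mean()
        .to_numpy()
    )


def estimate_derivative(time: np.ndarray, ca: np.ndarray, smoothing_window: int = 3) -> np.ndarray:
    """Smoothed trace derivative in nM/s.

    Centered moving average of width ``smoothing_window`` followed by
    central finite differences (one-sided at the ends).  Requires at least
    three samples.
    """
    time = np.asarray(time, dtype=float)
    ca = np.asarray(ca, dtype=float)
    if len(time) < 3:
        raise ValueError("derivative needs at least 3 samples")
    return np.gradient(moving_average(ca, smoothing_window), time)


def classify_responder(
    time: np.ndarray,
    ca: np.ndarray,
    windows: ProtocolWindows,
    thresholds: ResponderThresholds = ResponderThresholds(),
    agonist_name: str | None = None,
    experiment_id: str = "",
    cell_id: str = "",
) -> ResponderCall:
    """Apply the two-criterion responder rule to one cell's calcium trace.

    ``agonist_name`` selects the application window; with a single
    application it may be omitted.  NaN samples are ignored inside windows;
    a window with no finite samples excludes the cell with a reason code.
    """
    time = np.asarray(time, dtype=float)
    ca = np.asarray(ca, dtype=float)
    if agonist_name is None:
        apps = windows.applications
        if len(apps) != 1:
            raise WindowError("agonist_name required when several application windows exist")
        app = apps[0]
    else:
        app = windows.application(agonist_name)

    def _excluded(reason: str) -> ResponderCall:
        return ResponderCall(
            experiment_id, cell_id, app.agonist_name, False,
            np.nan, np.nan, np.nan, np.nan, np.nan, False, False,
            excluded=True, exclusion_reason=reason,
        )

    finite = np.isfinite(ca)
    if finite.sum() < 3:
        return _excluded("fewer than 3 valid samples")
    base_mask = windows.baseline.mask(time) & finite
    app_mask = app.mask(time) & finite
    if base_mask.sum() < 3:
        return _excluded("baseline window has fewer than 3 valid samples")
    if not app_mask.any():
        return _excluded("no valid samples in application window")

    stat = np.mean if thresholds.baseline_stat == "mean" else np.median
    baseline_ca = float(stat(ca[base_mask]))
    peak_ca = float(np.max(ca[app_mask]))
    amplitude = peak_ca - baseline_ca

    deriv = estimate_derivative(time, np.where(finite, ca, np.nan), thresholds.smoothing_window)
    base_sd = float(np.nanstd(deriv[base_mask], ddof=thresholds.sd_ddof))
    max_deriv = float(np.nanmax(deriv[app_mask]))

    amp_ok = amplitude > thresholds.amplitude_min
    deriv_ok = max_deriv > thresholds.derivative_sd_multiple * base_sd
    return ResponderCall(
        experiment_id, cell_id, app.agonist_name,
        bool(amp_ok and deriv_ok),
        baseline_ca, peak_ca, amplitude, max_deriv, base_sd,
        bool(amp_ok), bool(deriv_ok),
    )


def classify_cells(
    calcium: pd.DataFrame,
    windows: ProtocolWindows,
    thresholds: ResponderThresholds = ResponderThresholds(),
) -> pd.DataFrame:
    """Classify every cell of a calibrated trace table against every agonist.

    ``calcium`` is long-format ``experiment_id, cell_id, time_s, ca_nM``.
    With the viability filter on, cells whose ionomycin-window rise is below
    ``viability_min_amplitude`` are marked excluded in every row.
    Returns one row per (cell, application window).
    """
    rows = []
    for (exp_id, cell_id), grp in calcium.groupby(["experiment_id", "cell_id"], sort=True):
        grp = grp.sort_values("time_s")  # calls must not depend on row order
        t = grp["time_s"].to_numpy(float)
        ca = grp["ca_nM"].to_numpy(float)
        viable, via_reason = True, ""
        if thresholds.viability_filter:
            ion = windows.ionomycin
            if ion is None:
                raise WindowError("viability filter requires an ionomycin window")
            finite = np.isfinite(ca)
            base_mask = windows.baseline.mask(t) & finite
            ion_mask = ion.mask(t) & finite
            if base_mask.sum() >= 3 and ion_mask.any():
                rise = float(np.max(ca[ion_mask]) - np.mean(ca[base_mask]))
                if rise < thresholds.viability_min_amplitude:
                    viable, via_reason = False, "failed ionomycin viability control"
            else:
                viable, via_reason = False, "ionomycin control not evaluable"
        for app in windows.applications:
            call = classify_responder(
                t, ca, windows, thresholds, app.agonist_name,
                experiment_id=str(exp_id), cell_id=str(cell_id),
            )
            if not viable:
                call = ResponderCall(
                    call.experiment_id, call.cell_id, call.agonist_name, False,
                    call.baseline_ca, call.peak_ca, call.amplitude,
                    call.max_derivative, call.baseline_derivative_sd,
                    False, False, excluded=True, exclusion_reason=via_reason,
                )
            rows.append(call)
    return calls_to_frame(rows)


CALL_COLUMNS = [
    "experiment_id", "cell_id", "agonist_name", "is_responder",
    "baseline_ca", "peak_ca", "amplitude", "max_derivative",
    "baseline_derivative_sd", "amplitude_criterion_met",
    "derivative_criterion_met", "excluded", "exclusion_reason",
]


def calls_to_frame(calls) -> pd.DataFrame:
    return pd.DataFrame([vars(c) for c in calls], columns=CALL_COLUMNS)


def amplitude_table(calls: pd.DataFrame, responders_only: bool = True) -> pd.DataFrame:
    """Tidy amplitude table (one row per cell/agonist), optionally responders only.

    Amplitudes are reported for responding cells by convention: the rise is
    peak minus baseline within the application window.
    """
    out = calls.loc[~calls["excluded"]]
    if responders_only:
        out = out.loc[out["is_responder"]]
    return out[["experiment_id", "cell_id", "agonist_name", "is_responder", "amplitude"]].reset_index(drop=True)
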