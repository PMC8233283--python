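"""Ratiometric Fura-2 calibration: dual-wavelength fluorescence to absolute [Ca2+]i.

Fura-2 shifts its excitation spectrum on calcium binding, so the ratio
``R = F340/F380`` of background-corrected fluorescence reports calcium
concentration independently of dye loading and cell thickness.  Free
calcium follows the standard ratiometric calibration

    [Ca2+]i = Kd * beta * (R - Rmin) / (Rmax - R)

where ``Kd`` is the Fura-2/Ca2+ dissociation constant, ``Rmin``/``Rmax``
the ratios at zero and saturating calcium, and ``beta`` the ratio of the
380 nm signal at zero versus saturating calcium.  The constants come from
an in-situ or in-vitro calibration and are accepted here as parameters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

#: Columns of the long-format dual-wavelength trace table.
TRACE_COLUMNS = ["experiment_id", "cell_id", "time_s", "F340", "F380"]
#: Columns of the per-experiment background table.
BACKGROUND_COLUMNS = ["experiment_id", "background_340", "background_380"]
#: Columns of the calibrated calcium trace table.
CALCIUM_COLUMNS = ["experiment_id", "cell_id", "time_s", "ca_nM"]


class CalibrationError(ValueError):
    """Invalid calibration parameters or misuse of the calibration contract."""


@dataclass(frozen=True)
class CalibrationParams:
    """Constants of the ratiometric calibration.

    Parameters
    ----------
    kd_nm
        Fura-2/Ca2+ dissociation constant in nM.  The literature in-vitro
        value of 225 nM is the default; in-cell values differ and should be
        supplied when known.
    rmin
        F340/F380 ratio at zero calcium.
    rmax
        F340/F380 ratio at saturating calcium.
    beta
        F380(zero Ca) / F380(saturating Ca), dimensionless.
    """

    kd_nm: float = 225.0
    rmin: float = 0.5
    rmax: float = 8.0
    beta: float = 9.0

    def __post_init__(self) -> None:
        if not (self.kd_nm > 0):
            raise CalibrationError("Kd must be positive")
        if not (0 < self.rmin < self.rmax):
            raise CalibrationError("require 0 < Rmin < Rmax")
        if not (self.beta > 0):
            raise CalibrationError("beta must be positive")


DEFAULT_PARAMS = CalibrationParams()


def subtract_background(traces: pd.DataFrame, background: pd.DataFrame) -> pd.DataFrame:
    """Subtract the per-experiment scalar background from each wavelength.

    Samples where the corrected F380 is non-positive cannot be ratioed and
    are flagged ``valid = False`` rather than dropped silently.

    Returns a copy with corrected ``F340``/``F380``, a ``valid`` column, and
    ``attrs["background_corrected"] = True``.
    """
    _require_columns(traces, TRACE_COLUMNS, "trace table")
    _require_columns(background, BACKGROUND_COLUMNS, "background table")
    missing = set(traces["experiment_id"]) - set(background["experiment_id"])
    if missing:
        raise CalibrationError(f"no background levels for experiments: {sorted(missing)}")
    bg = background.set_index("experiment_id")
    out = traces.copy()
    out["F340"] = out["F340"].to_numpy(float) - bg["background_340"].reindex(out["experiment_id"]).to_numpy(float)
    out["F380"] = out["F380"].to_numpy(float) - bg["background_380"].reindex(out["experiment_id"]).to_numpy(float)
    out["valid"] = out["F380"].to_numpy(float) > 0
    out.attrs["background_corrected"] = True
    return out


def compute_ratio(trace_corrected: pd.DataFrame) -> pd.DataFrame:
    """Elementwise R = F340/F380 on a background-corrected trace table.

    Invalid samples (flagged by :func:`subtract_background`) propagate as NaN.
    Raises :class:`CalibrationError` if the input was never corrected.
    """
    if not trace_corrected.attrs.get("background_corrected", False):
        raise CalibrationError("compute_ratio requires a background-corrected trace table")
    out = trace_corrected.copy()
    f340 = out["F340"].to_numpy(float)
    f380 = out["F380"].to_numpy(float)
    valid = out["valid"].to_numpy(bool) if "valid" in out else f380 > 0
    ratio = np.full(len(out), np.nan)
    np.divide(f340, f380, out=ratio, where=valid)
    out["ratio"] = ratio
    out.attrs["background_corrected"] = True
    return out


def ratio_to_calcium(ratio, params: CalibrationParams = DEFAULT_PARAMS):
    """Convert fluorescence ratios to calcium (nM).

    ``R <= Rmin`` clamps to 0 nM (baseline noise can undershoot Rmin);
    ``R >= Rmax`` is dye saturation and maps to NaN.  Returns
    ``(ca, saturated)`` arrays of the input shape.
    """
    r = np.asarray(ratio, dtype=float)
    saturated = r >= params.rmax
    ca = params.kd_nm * params.beta * (r - params.rmin) / (params.rmax - r)
    ca = np.where(r <= params.rmin, 0.0, ca)
    ca = np.where(saturated, np.nan, ca)
    ca = np.where(np.isnan(r), np.nan, ca)
    return ca, saturated


def calcium_to_ratio(ca, params: CalibrationParams = DEFAULT_PARAMS):
    """Exact inverse of :func:`ratio_to_calcium` on (0, inf) calcium.

    Used by the synthetic generator to emit fluorescence from a latent
    calcium trace; ``ratio_to_calcium(calcium_to_ratio(ca)) == ca``.
    """
    q = np.asarray(ca, dtype=float) / (params.kd_nm * params.beta)
    if np.any(q < 0):
        raise CalibrationError("calcium must be non-negative")
    return (params.rmin + q * params.rmax) / (1.0 + q)


def calibrate_traces(
    traces: pd.DataFrame,
    background: pd.DataFrame,
    params: CalibrationParams = DEFAULT_PARAMS,
) -> pd.DataFrame:
    """Full chain: background subtraction -> ratio -> absolute calcium.

    Returns a long-format table ``experiment_id, cell_id, time_s, ca_nM``
    with NaN where a sample was invalid or the dye saturated.
    """
    corrected = subtract_background(traces, background)
    ratioed = compute_ratio(corrected)
    ca, _ = ratio_to_calcium(ratioed["ratio"].to_numpy(), params)
    out = ratioed[["experiment_id", "cell_id", "time_s"]].copy()
    out["ca_nM"] = ca
    return out


def _require_columns(df: pd.DataFrame, columns, what: str) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise CalibrationError(f"{what} is missing required column(s): {missing}")
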