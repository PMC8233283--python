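"""CSV/TSV/YAML readers and writers with schema validation.

All tables are UTF-8, comma-separated (TSV for count matrices), with a
required header row and ``.`` decimal separator.  Readers raise
:class:`SchemaError` naming the missing column; window tables are
additionally validated for ordering and overlap on read.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from .calibration import CalibrationParams, TRACE_COLUMNS, BACKGROUND_COLUMNS, CALCIUM_COLUMNS
from .responders import ProtocolWindows, ResponderThresholds, WINDOW_COLUMNS, CALL_COLUMNS
from .qpcr import CT_COLUMNS
from .synthetic import CountMatrix


class SchemaError(ValueError):
    """A file does not conform to its documented column schema."""


def _read_csv(path, required: list[str], what: str, sep: str = ",") -> pd.DataFrame:
    df = pd.read_csv(path, sep=sep)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{what} file {path}: missing required column(s) {missing}")
    return df


def read_traces(path) -> pd.DataFrame:
    return _read_csv(path, TRACE_COLUMNS, "trace")


def write_traces(traces: pd.DataFrame, path) -> None:
    traces[TRACE_COLUMNS].to_csv(path, index=False)


def read_background(path) -> pd.DataFrame:
    return _read_csv(path, BACKGROUND_COLUMNS, "background")


def write_background(background: pd.DataFrame, path) -> None:
    background[BACKGROUND_COLUMNS].to_csv(path, index=False)


def read_windows(path) -> ProtocolWindows:
    df = _read_csv(path, WINDOW_COLUMNS, "windows")
    df["agonist_name"] = df["agonist_name"].fillna("")
    return ProtocolWindows.from_frame(df)


def write_windows(windows: ProtocolWindows, path) -> None:
    windows.to_frame().to_csv(path, index=False)


def read_calcium(path) -> pd.DataFrame:
    return _read_csv(path, CALCIUM_COLUMNS, "calcium trace")


def write_calcium(calcium: pd.DataFrame, path) -> None:
    calcium[CALCIUM_COLUMNS].to_csv(path, index=False)


def read_calls(path) -> pd.DataFrame:
    df = _read_csv(path, CALL_COLUMNS, "responder calls")
    df["exclusion_reason"] = df["exclusion_reason"].fillna("")
    return df


def write_calls(calls: pd.DataFrame, path) -> None:
    calls[CALL_COLUMNS].to_csv(path, index=False)


def read_ct_table(path) -> pd.DataFrame:
    return _read_csv(path, CT_COLUMNS, "Ct")


def write_ct_table(ct: pd.DataFrame, path) -> None:
    ct.to_csv(path, index=False)


def read_count_matrix(counts_path, lengths_path, totals_path=None) -> CountMatrix:
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    counts.index.name = None
    if counts.shape[1] == 0:
        raise SchemaError(f"count matrix {counts_path}: no sample columns")
    lengths_df = _read_csv(lengths_path, ["gene", "length_bp"], "gene length", sep="\t")
    lengths = lengths_df.set_index("gene")["length_bp"].astype(float)
    missing = [g for g in counts.index if g not in lengths.index]
    if missing:
        raise SchemaError(f"gene length file {lengths_path}: missing length for {missing[:5]}...")
    if totals_path is not None:
        totals_df = _read_csv(totals_path, ["sample", "total_reads"], "library size", sep="\t")
        totals = totals_df.set_index("sample")["total_reads"].astype(float).reindex(counts.columns)
    else:
        totals = counts.sum(axis=0).astype(float)
    return CountMatrix(counts, lengths.reindex(counts.index), totals)


def write_count_matrix(cm: CountMatrix, counts_path, lengths_path, totals_path=None) -> None:
    cm.counts.to_csv(counts_path, sep="\t", index_label="gene")
    cm.gene_lengths.rename("length_bp").to_csv(lengths_path, sep="\t", index_label="gene")
    if totals_path is not None:
        cm.total_reads.rename("total_reads").to_csv(totals_path, sep="\t", index_label="sample")


def write_matrix(matrix: pd.DataFrame, path, sep: str = "\t") -> None:
    matrix.to_csv(path, sep=sep, index_label="gene")


@dataclass
class PipelineConfig:
    """End-to-end pipeline settings; round-trips losslessly through YAML."""

    traces_path: str = ""
    background_path: str = ""
    windows_path: str = ""
    ct_path: str = ""
    counts_path: str = ""
    lengths_path: str = ""
    out_dir: str = "report"
    seed: int = 0
    housekeeping: list[str] = field(default_factory=lambda: ["Actb", "Gapdh"])
    reference_gene: str = "Trpm7"
    calibration: CalibrationParams = field(default_factory=CalibrationParams)
    thresholds: ResponderThresholds = field(default_factory=ResponderThresholds)

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if isinstance(d.get("calibration"), dict):
            d["calibration"] = CalibrationParams(**d["calibration"])
        if isinstance(d.get("thresholds"), dict):
            d["thresholds"] = ResponderThresholds(**d["thresholds"])
        return cls(**d)


def read_config(path) -> PipelineConfig:
    with open(path) as fh:
        return PipelineConfig.from_dict(yaml.safe_load(fh) or {})


def write_config(config: PipelineConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)
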