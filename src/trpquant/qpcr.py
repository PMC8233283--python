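"""Relative quantification of qPCR Ct tables and expression categorization.

Quantification follows the comparative-Ct scheme:

* ``ΔCt = mean Ct(gene) − geometric mean of the housekeeping mean Cts``
  per sample; relative expression is ``2^−ΔCt``.
* Expression is placed on a percent-of-Trpm7 scale, where the reference
  ΔCt is the Trpm7 average over a stated scope of conditions (e.g. all
  gestational days), and binned into categories:
  ``> 100%`` high, ``5–100%`` moderate, ``1–5%`` low, ``< 1%``
  below_detection (lower band edges inclusive, 100% inclusive in
  moderate).
* Fold change versus a baseline condition is ``2^−ΔΔCt`` with
  ``ΔΔCt = ΔCt(condition) − ΔCt(baseline)``.

Replicate Cts are averaged per (sample, gene) before ΔCt; replicates at or
above the detection floor (default Ct 40) are dropped, and a gene with no
detected replicate in a sample is ``not_detected``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

CT_COLUMNS = ["sample_id", "condition", "gene", "replicate", "ct"]

CATEGORIES = ["high", "moderate", "low", "below_detection", "not_detected"]


class QpcrError(ValueError):
    pass


def relative_expression(
    ct_table: pd.DataFrame,
    housekeeping: list[str],
    detection_ct: float = 40.0,
) -> pd.DataFrame:
    """ΔCt and 2^−ΔCt per (sample, gene) from a replicate Ct table.

    Returns a tidy table with ``mean_ct``, ``delta_ct``, ``rel_expression``
    and ``detected``.  Housekeeping genes are kept in the output (their own
    ΔCt is relative to the housekeeping geometric mean).  A sample missing
    any housekeeping gene is an error.
    """
    missing_cols = [c for c in CT_COLUMNS if c not in ct_table.columns]
    if missing_cols:
        raise QpcrError(f"Ct table is missing required column(s): {missing_cols}")
    df = ct_table.copy()
    df["ct"] = df["ct"].astype(float)
    if (df["ct"].dropna() <= 0).any():
        raise QpcrError("Ct values must be positive where detected")
    df.loc[df["ct"] >= detection_ct, "ct"] = np.nan  # undetected replicates dropped

    mean_ct = (
        df.groupby(["sample_id", "condition", "gene"], sort=True)["ct"]
        .mean()
        .rename("mean_ct")
        .reset_index()
    )
    rows = []
    for (sample_id, condition), grp in mean_ct.groupby(["sample_id", "condition"], sort=True):
        hk = grp.set_index("gene")["mean_ct"].reindex(housekeeping)
        if hk.isna().any():
            absent = list(hk.index[hk.isna()])
            raise QpcrError(f"sample {sample_id!r}: housekeeping gene(s) {absent} missing or undetected")
        hk_gmean = float(np.exp(np.mean(np.log(hk.to_numpy(float)))))
        for r in grp.itertuples():
            detected = np.isfinite(r.mean_ct)
            delta = r.mean_ct - hk_gmean if detected else np.nan
            rows.append({
                "sample_id": sample_id,
                "condition": condition,
                "gene": r.gene,
                "mean_ct": r.mean_ct,
                "hk_geometric_mean_ct": hk_gmean,
                "delta_ct": delta,
                "rel_expression": 2.0 ** (-delta) if detected else np.nan,
                "detected": bool(detected),
            })
    return pd.DataFrame(rows)


def percent_of_trpm7(
    results: pd.DataFrame,
    reference_gene: str = "Trpm7",
    reference_scope: list[str] | None = None,
) -> pd.DataFrame:
    """Express each gene as a percentage of the reference channel (Trpm7).

    The reference ΔCt is the mean Trpm7 ΔCt over all samples in
    ``reference_scope`` (conditions; default: every condition present), so
    a single normalization value serves the whole table:
    ``percent = 100 · 2^−(ΔCt_gene − ΔCt_ref)``.  Adds ``percent_of_trpm7``,
    ``fold_change_vs_trpm7`` and ``category`` columns.
    """
    scope = results["condition"].unique().tolist() if reference_scope is None else reference_scope
    if len(scope) == 0:
        raise QpcrError("reference scope is empty")
    ref = results.loc[
        (results["gene"] == reference_gene)
        & results["condition"].isin(scope)
        & results["detected"],
        "delta_ct",
    ]
    if ref.empty:
        raise QpcrError(f"reference gene {reference_gene!r} not detected in scope {scope}")
    missing = set(scope) - set(results.loc[results["gene"] == reference_gene, "condition"])
    if missing:
        raise QpcrError(f"reference gene absent from condition(s): {sorted(missing)}")
    ref_delta = float(ref.mean())
    out = results.copy()
    ddct = out["delta_ct"] - ref_delta
    out["fold_change_vs_trpm7"] = 2.0 ** (-ddct)
    out["percent_of_trpm7"] = 100.0 * out["fold_change_vs_trpm7"]
    out["category"] = [
        categorize(p) if det else "not_detected"
        for p, det in zip(out["percent_of_trpm7"], out["detected"])
    ]
    out.attrs["reference_delta_ct"] = ref_delta
    return out


def categorize(percent: float) -> str:
    """Bin a percent-of-reference value into an expression category.

    ``> 100`` high; ``[5, 100]`` moderate; ``[1, 5)`` low; ``[0, 1)``
    below_detection.  NaN maps to ``not_detected``; negative input is an
    error.
    """
    if percent is None or (isinstance(percent, float) and np.isnan(percent)):
        return "not_detected"
    if percent < 0:
        raise QpcrError("percent of reference cannot be negative")
    if percent > 100.0:
        return "high"
    if percent >= 5.0:
        return "moderate"
    if percent >= 1.0:
        return "low"
    return "below_detection"


def fold_change_vs_baseline(
    results: pd.DataFrame,
    baseline_condition: str,
) -> pd.DataFrame:
    """Per-gene fold change of each condition versus a baseline condition.

    ΔCt is first averaged over samples within (gene, condition); then
    ``fold = 2^−(ΔCt_condition − ΔCt_baseline)``.  The baseline condition
    itself yields fold 1.  Genes not detected at baseline get NaN fold with
    ``baseline_detected = False``.
    """
    if baseline_condition not in set(results["condition"]):
        raise QpcrError(f"baseline condition {baseline_condition!r} absent")
    per_cond = (
        results.groupby(["gene", "condition"], sort=True)["delta_ct"].mean().reset_index()
    )
    base = per_cond.loc[per_cond["condition"] == baseline_condition].set_index("gene")["delta_ct"]
    out = per_cond.copy()
    base_delta = base.reindex(out["gene"]).to_numpy(float)
    out["baseline_detected"] = np.isfinite(base_delta)
    out["fold_change_vs_baseline"] = 2.0 ** (-(out["delta_ct"].to_numpy(float) - base_delta))
    return out


def strain_contrast(
    results: pd.DataFrame,
    strain_col: str = "strain",
    strain_a: str | None = None,
    strain_b: str | None = None,
) -> pd.DataFrame:
    """Percent expression difference of strain A relative to strain B.

    Per gene and shared condition the contrast is
    ``100 · (rel_A / rel_B − 1)``; the table reports the mean ± SEM over
    shared conditions (e.g. "+19 ± 6%" means strain A expresses 19% more
    on average).
    """
    if strain_col not in results.columns:
        raise QpcrError(f"column {strain_col!r} missing")
    strains = sorted(results[strain_col].unique())
    if strain_a is None or strain_b is None:
        if len(strains) != 2:
            raise QpcrError("pass strain_a/strain_b explicitly when not exactly 2 strains")
        strain_a, strain_b = strains
    per = (
        results.groupby(["gene", "condition", strain_col], sort=True)["rel_expression"]
        .mean()
        .unstack(strain_col)
    )
    shared = per.dropna(subset=[strain_a, strain_b])
    if shared.empty:
        raise QpcrError("strains share no measured (gene, condition) pairs")
    pct = 100.0 * (shared[strain_a] / shared[strain_b] - 1.0)
    rows = []
    for gene, vals in pct.groupby(level="gene"):
        v = vals.to_numpy(float)
        rows.append({
            "gene": gene,
            "n_conditions": len(v),
            "mean_percent_difference": float(np.mean(v)),
            "sem_percent_difference": float(np.std(v, ddof=1) / np.sqrt(len(v))) if len(v) > 1 else 0.0,
        })
    return pd.DataFrame(rows)


def expression_matrix(results: pd.DataFrame, value: str = "percent_of_trpm7") -> pd.DataFrame:
    """Heatmap-ready gene x condition matrix of a chosen expression value."""
    return results.pivot_table(index="gene", columns="condition", values=value, aggfunc="mean")
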