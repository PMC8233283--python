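"""Cohort aggregation of responder calls and standard group comparisons.

Headline responder percentages are reported as mean ± SEM of the
per-experiment fractions (the convention of imaging cohorts, where the
experiment, not the cell, is the independent unit); the pooled-count
percentage over all cells is reported alongside.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


class CohortError(ValueError):
    pass


def summarize_experiments(calls: pd.DataFrame) -> pd.DataFrame:
    """One summary row per (experiment, agonist): counts, fraction, mean amplitude.

    Excluded cells (viability filter or unusable traces) do not enter the
    counts.  An experiment with zero usable cells is reported with
    ``n_cells = 0`` and NaN fraction.
    """
    if "experiment_id" not in calls.columns:
        raise CohortError("calls table must carry experiment_id")
    rows = []
    for (exp_id, agonist), grp in calls.groupby(["experiment_id", "agonist_name"], sort=True):
        usable = grp.loc[~grp["excluded"]]
        n = len(usable)
        n_resp = int(usable["is_responder"].sum())
        amp = usable.loc[usable["is_responder"], "amplitude"]
        rows.append({
            "experiment_id": exp_id,
            "agonist_name": agonist,
            "n_cells": n,
            "n_responders": n_resp,
            "fraction_responders": n_resp / n if n else np.nan,
            "mean_amplitude_responders": float(amp.mean()) if len(amp) else np.nan,
        })
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class CohortSummary:
    """Pooled view of one agonist across experiments."""

    agonist_name: str
    n_experiments: int
    mean_fraction_pct: float  # mean of per-experiment fractions, in %
    sem_fraction_pct: float  # SD/sqrt(n_experiments), in %
    pooled_responders: int
    pooled_total: int
    pooled_percent: float  # 100 * pooled_responders / pooled_total
    mean_amplitude: float  # nM, responders, mean of per-experiment means
    sem_amplitude: float
    pooled_percent_defined: bool = True

    def as_dict(self) -> dict:
        return asdict(self)


def pool_cohort(summaries: pd.DataFrame, agonist_name: str | None = None) -> CohortSummary:
    """Pool per-experiment summaries for one agonist.

    Reports both the across-experiment mean ± SEM of the responder fraction
    and the pooled-count percentage; counts are conserved
    (``pooled_responders = sum of per-experiment responders``).
    """
    df = summaries
    if agonist_name is not None:
        df = df.loc[df["agonist_name"] == agonist_name]
    elif df["agonist_name"].nunique() > 1:
        raise CohortError("several agonists present; pass agonist_name")
    if df.empty:
        raise CohortError("no experiments to pool")
    agonist = str(df["agonist_name"].iloc[0])
    fracs = df["fraction_responders"].dropna().to_numpy(float)
    n_exp = len(df)
    pooled_resp = int(df["n_responders"].sum())
    pooled_total = int(df["n_cells"].sum())
    amps = df["mean_amplitude_responders"].dropna().to_numpy(float)

    def _sem(x: np.ndarray) -> float:
        return float(np.std(x, ddof=1) / np.sqrt(len(x))) if len(x) > 1 else 0.0

    return CohortSummary(
        agonist_name=agonist,
        n_experiments=n_exp,
        mean_fraction_pct=100.0 * float(np.mean(fracs)) if len(fracs) else np.nan,
        sem_fraction_pct=100.0 * _sem(fracs) if len(fracs) else np.nan,
        pooled_responders=pooled_resp,
        pooled_total=pooled_total,
        pooled_percent=100.0 * pooled_resp / pooled_total if pooled_total else np.nan,
        mean_amplitude=float(np.mean(amps)) if len(amps) else np.nan,
        sem_amplitude=_sem(amps) if len(amps) else np.nan,
        pooled_percent_defined=pooled_total > 0,
    )


def pool_from_counts(n_responders: int, n_total: int, agonist_name: str = "") -> CohortSummary:
    """Pool a single printed (responders, total) count pair.

    Convenience for published cohort legends where only the pooled counts
    are available, not the per-experiment breakdown.
    """
    summaries = pd.DataFrame([{
        "experiment_id": "pooled",
        "agonist_name": agonist_name,
        "n_cells": n_total,
        "n_responders": n_responders,
        "fraction_responders": n_responders / n_total if n_total else np.nan,
        "mean_amplitude_responders": np.nan,
    }])
    return pool_cohort(summaries)


@dataclass(frozen=True)
class GroupComparison:
    test: str
    design: str
    statistic: float
    p_value: float | None
    note: str = ""


def compare_groups(values_a, values_b, design: str = "unpaired", test: str = "t") -> GroupComparison:
    """Two-group comparison delegated to standard test implementations.

    ``test``: ``t`` (Student/paired t), ``mann_whitney``, or
    ``fisher_counts`` (inputs are ``(successes, total)`` pairs).  A paired
    design with an all-zero difference vector has an undefined t statistic
    and is reported as a "no difference" result rather than a numeric p.
    """
    if design not in ("paired", "unpaired"):
        raise CohortError("design must be 'paired' or 'unpaired'")
    if test == "fisher_counts":
        (ka, na), (kb, nb) = values_a, values_b
        table = [[ka, na - ka], [kb, nb - kb]]
        odds, p = stats.fisher_exact(table, alternative="two-sided")
        return GroupComparison("fisher_exact", "unpaired", float(odds), float(p))
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise CohortError("each group needs at least 2 observations")
    if design == "paired" and len(a) != len(b):
        raise CohortError("paired design requires equal-length, matched vectors")
    if test == "t":
        if design == "paired":
            if np.allclose(a - b, 0.0):
                return GroupComparison("paired_t", design, 0.0, None,
                                       note="zero difference vector: no difference")
            res = stats.ttest_rel(a, b)
        else:
            res = stats.ttest_ind(a, b)
        return GroupComparison(("paired_t" if design == "paired" else "t"), design,
                               float(res.statistic), float(res.pvalue))
    if test == "mann_whitney":
        res = stats.mannwhitneyu(a, b, alternative="two-sided")
        return GroupComparison("mann_whitney", "unpaired", float(res.statistic), float(res.pvalue))
    raise CohortError(f"unknown test {test!r}")


def multi_group_trend(
    values_by_condition: dict[str, np.ndarray],
    control_label: str,
    method: str = "auto",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Each condition versus a control, with multiplicity-adjusted p-values.

    Intended for qPCR ΔCt vectors (comparisons are made on ΔCt, not on fold
    changes).  ``method='dunnett'`` runs one-way ANOVA followed by Dunnett's
    test; ``method='dunn'`` runs Kruskal–Wallis followed by pairwise
    Mann–Whitney tests versus control with Holm adjustment (a substitute
    for Dunn's post-hoc, which has no standard scipy/statsmodels
    implementation); ``method='auto'`` picks by a D'Agostino–Pearson
    normality gate on each group.
    """
    if control_label not in values_by_condition:
        raise CohortError(f"control group {control_label!r} missing")
    if len(values_by_condition) < 3:
        raise CohortError("need at least 3 condition groups")
    groups = {k: np.asarray(v, dtype=float) for k, v in values_by_condition.items()}
    control = groups[control_label]
    others = {k: v for k, v in groups.items() if k != control_label}

    allvals = np.concatenate(list(groups.values()))
    if np.ptp(allvals) == 0.0:
        # degenerate: every observation identical; no comparison can be significant
        out = pd.DataFrame({
            "condition": list(others), "control": control_label,
            "statistic": 0.0, "p_adjusted": 1.0, "significant": False,
            "post_hoc": "none (zero variance)",
        })
        out.attrs["omnibus"] = {"test": "none", "statistic": 0.0, "p_value": 1.0}
        return out

    if method == "auto":
        normal = all(
            len(v) < 8 or stats.normaltest(v).pvalue > alpha for v in groups.values()
        )
        method = "dunnett" if normal else "dunn"

    if method == "dunnett":
        omnibus = stats.f_oneway(*groups.values())
        res = stats.dunnett(*others.values(), control=control)
        padj = np.asarray(res.pvalue, dtype=float)
        stat = np.asarray(res.statistic, dtype=float)
        omni_name = "one_way_anova"
        post_name = "dunnett"
    elif method == "dunn":
        omnibus = stats.kruskal(*groups.values())
        raw = [stats.mannwhitneyu(v, control, alternative="two-sided") for v in others.values()]
        stat = np.array([r.statistic for r in raw], dtype=float)
        padj = multipletests([r.pvalue for r in raw], method="holm")[1]
        omni_name = "kruskal_wallis"
        post_name = "mann_whitney_holm"
    else:
        raise CohortError(f"unknown method {method!r}")

    out = pd.DataFrame({
        "condition": list(others),
        "control": control_label,
        "statistic": stat,
        "p_adjusted": padj,
        "significant": padj < alpha,
        "post_hoc": post_name,
    })
    out.attrs["omnibus"] = {"test": omni_name, "statistic": float(omnibus.statistic),
                            "p_value": float(omnibus.pvalue)}
    return out
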