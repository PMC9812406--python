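"""Mutant-vs-reference log2 fold-change metabolome profiles.

A profile is, per (mutant, timepoint, metabolite), the log2 ratio of mean
intensities against a reference strain measured at the matched timepoint,
with a two-sided Student's t-test on log intensities.  Also provides the
within-strain treatment-response variant (each treated timepoint against
that strain's untreated samples) and threshold-based significance calls.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "log2_fold_change_profiles",
    "treatment_response",
    "significant_changes",
]

#: tidy ProfileSet columns
PROFILE_COLUMNS = [
    "mutant",
    "timepoint_min",
    "metabolite_id",
    "mean_log2_fc",
    "p_value",
    "n_mutant_reps",
    "n_wt_reps",
]


def _group_stats(table: pd.DataFrame, by: list[str]) -> pd.DataFrame:
    log_int = np.log(table["intensity"].to_numpy())
    df = table[by].copy()
    df["intensity"] = table["intensity"].to_numpy()
    df["log_intensity"] = log_int
    return df.groupby(by, sort=True).agg(
        mean_raw=("intensity", "mean"),
        mean_log=("log_intensity", "mean"),
        var_log=("log_intensity", "var"),
        n=("log_intensity", "size"),
    )


def _t_test(m1, v1, n1, m2, v2, n2, welch: bool = False):
    """Vectorized two-sided t-test on group summary statistics.

    Zero-variance convention: when the (pooled) variance is exactly zero,
    p = 1 for equal means and p = 0 otherwise.
    """
    m1, v1, n1 = (np.asarray(a, dtype=float) for a in (m1, v1, n1))
    m2, v2, n2 = (np.asarray(a, dtype=float) for a in (m2, v2, n2))
    diff = m1 - m2
    with np.errstate(divide="ignore", invalid="ignore"):
        if welch:
            se2 = v1 / n1 + v2 / n2
            df = se2**2 / (
                (v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1)
            )
        else:
            sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
            se2 = sp2 * (1 / n1 + 1 / n2)
            df = n1 + n2 - 2
        t = diff / np.sqrt(se2)
        p = 2 * stats.t.sf(np.abs(t), df)
    degenerate = ~np.isfinite(t)
    p = np.where(degenerate, np.where(diff == 0, 1.0, 0.0), p)
    insufficient = (n1 < 2) | (n2 < 2)
    return np.where(insufficient, np.nan, p)


def log2_fold_change_profiles(
    table: pd.DataFrame,
    reference_mutant: str = "WT",
    welch: bool = False,
    mean_of_ratios: bool = False,
) -> pd.DataFrame:
    """Compute per-(mutant, timepoint, metabolite) fold-changes vs a reference.

    The fold-change is log2 of the ratio of group mean intensities at the
    matched timepoint (``mean_of_ratios=True`` switches to the mean of the
    per-replicate log2 values instead); the p-value comes from a two-sided
    Student's t-test on natural-log intensities (Welch optional).
    Metabolites missing in the reference at a timepoint yield NaN rows.
    """
    if reference_mutant not in set(table["mutant"]):
        raise ValueError(f"reference strain {reference_mutant!r} not in table")

    keys = ["mutant", "timepoint_min", "metabolite_id"]
    gs = _group_stats(table, keys).reset_index()
    ref = gs[gs["mutant"] == reference_mutant].drop(columns="mutant")
    ref = ref.rename(
        columns={
            "mean_raw": "ref_mean_raw",
            "mean_log": "ref_mean_log",
            "var_log": "ref_var_log",
            "n": "n_wt_reps",
        }
    )
    mut = gs[gs["mutant"] != reference_mutant]
    merged = mut.merge(ref, on=["timepoint_min", "metabolite_id"], how="left")

    if mean_of_ratios:
        merged["mean_log2_fc"] = (
            merged["mean_log"] - merged["ref_mean_log"]
        ) / np.log(2)
    else:
        # log2(a) - log2(b) rather than log2(a / b): bitwise-exact
        # antisymmetry under a reference swap
        merged["mean_log2_fc"] = np.log2(merged["mean_raw"]) - np.log2(
            merged["ref_mean_raw"]
        )
    merged["p_value"] = _t_test(
        merged["mean_log"],
        merged["var_log"],
        merged["n"],
        merged["ref_mean_log"],
        merged["ref_var_log"],
        merged["n_wt_reps"].fillna(0),
        welch=welch,
    )
    merged = merged.rename(columns={"n": "n_mutant_reps"})
    merged["n_wt_reps"] = merged["n_wt_reps"].fillna(0).astype(int)
    return merged[PROFILE_COLUMNS].reset_index(drop=True)


def treatment_response(table: pd.DataFrame, mutant: str, welch: bool = False) -> pd.DataFrame:
    """Within-strain fold-changes of each treated timepoint vs t = 0."""
    sub = table[table["mutant"] == mutant]
    if sub.empty:
        raise ValueError(f"strain {mutant!r} not present in table")
    if not (sub["timepoint_min"] == 0).any():
        raise ValueError(f"strain {mutant!r} has no untreated (t=0) samples")

    keys = ["timepoint_min", "metabolite_id"]
    gs = _group_stats(sub, keys).reset_index()
    ref = gs[gs["timepoint_min"] == 0].drop(columns="timepoint_min")
    ref = ref.rename(
        columns={
            "mean_raw": "ref_mean_raw",
            "mean_log": "ref_mean_log",
            "var_log": "ref_var_log",
            "n": "n_wt_reps",
        }
    )
    trt = gs[gs["timepoint_min"] > 0]
    merged = trt.merge(ref, on="metabolite_id", how="left")
    merged["mean_log2_fc"] = np.log2(merged["mean_raw"]) - np.log2(
        merged["ref_mean_raw"]
    )
    merged["p_value"] = _t_test(
        merged["mean_log"],
        merged["var_log"],
        merged["n"],
        merged["ref_mean_log"],
        merged["ref_var_log"],
        merged["n_wt_reps"].fillna(0),
        welch=welch,
    )
    merged["mutant"] = mutant
    merged = merged.rename(columns={"n": "n_mutant_reps"})
    merged["n_wt_reps"] = merged["n_wt_reps"].fillna(0).astype(int)
    return merged[PROFILE_COLUMNS].reset_index(drop=True)


def significant_changes(
    profiles: pd.DataFrame, fc_cut: float = 0.5, p_cut: float = 0.05
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Flag significant fold-changes and count them per (mutant, timepoint).

    A cell is significant when |mean_log2_fc| > fc_cut and p_value < p_cut;
    missing values are never significant and are flagged as missing.
    """
    calls = profiles[
        ["mutant", "timepoint_min", "metabolite_id", "mean_log2_fc", "p_value"]
    ].copy()
    calls["missing"] = (
        calls["mean_log2_fc"].isna() | calls["p_value"].isna()
    )
    calls["significant"] = (
        (calls["mean_log2_fc"].abs() > fc_cut)
        & (calls["p_value"] < p_cut)
        & ~calls["missing"]
    )
    calls["fc_cut"] = fc_cut
    calls["p_cut"] = p_cut
    counts = (
        calls.groupby(["mutant", "timepoint_min"])["significant"]
        .sum()
        .rename("n_significant")
        .reset_index()
    )
    return calls, counts
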