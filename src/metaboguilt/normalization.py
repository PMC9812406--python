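"""Sample-level QC and intensity normalization.

Outlier samples are dropped on biomass (OD600) and log total ion current
using a median/MAD rule; per-metabolite acquisition-order and OD600 trends
are removed by LOWESS detrending of log intensities; quantile normalization
is provided for proteome-style sample x feature matrices.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.nonparametric.smoothers_lowess import lowess as _sm_lowess

__all__ = [
    "OutlierReport",
    "filter_outlier_samples",
    "lowess_detrend",
    "quantile_normalize",
]


@dataclass
class OutlierReport:
    """Record of samples excluded by :func:`filter_outlier_samples`."""

    excluded: list[str]
    rules: dict[str, str] = field(default_factory=dict)
    tic: dict[str, float] = field(default_factory=dict)
    od600: dict[str, float] = field(default_factory=dict)
    k_mad: float = float("nan")

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True, default=float)


#: normal-consistent MAD scale factor (1 / Phi^-1(3/4))
_MAD_SCALE = 1.4826


def _mad_outliers(values: pd.Series, k_mad: float) -> pd.Series:
    """Boolean mask of values deviating from the median by > k_mad MADs.

    The MAD carries the usual 1.4826 normal-consistency factor so k_mad is
    on a standard-deviation-like scale; with MAD == 0 any nonzero deviation
    from the median is flagged.
    """
    if np.isinf(k_mad):
        return pd.Series(False, index=values.index)
    med = values.median()
    dev = (values - med).abs()
    mad = _MAD_SCALE * dev.median()
    return dev > k_mad * mad


def filter_outlier_samples(
    table: pd.DataFrame, k_mad: float = 3.0
) -> tuple[pd.DataFrame, OutlierReport]:
    """Drop samples that are outliers in OD600 or log10 total ion current.

    A sample is excluded when its OD600 or its log total ion current lies
    more than ``k_mad`` median-absolute-deviations from the cohort median.
    Each exclusion cites the single rule that triggered it (OD600 checked
    first).
    """
    per_sample = (
        table.groupby("sample_id")
        .agg(tic=("intensity", "sum"), od600=("od600", "first"))
        .sort_index()
    )
    if len(per_sample) < 3:
        raise ValueError("need at least 3 samples to estimate outlier bounds")

    od_out = _mad_outliers(per_sample["od600"], k_mad)
    tic_out = _mad_outliers(np.log10(per_sample["tic"]), k_mad)

    rules = {}
    for sid in per_sample.index:
        if od_out[sid]:
            rules[sid] = "od600"
        elif tic_out[sid]:
            rules[sid] = "log_tic"
    excluded = sorted(rules)
    if len(excluded) == len(per_sample):
        raise ValueError("outlier filtering excluded every sample")

    report = OutlierReport(
        excluded=excluded,
        rules=rules,
        tic=per_sample["tic"].to_dict(),
        od600=per_sample["od600"].to_dict(),
        k_mad=float(k_mad),
    )
    kept = table[~table["sample_id"].isin(excluded)].reset_index(drop=True)
    return kept, report


def lowess_detrend(
    table: pd.DataFrame,
    covariate: str = "injection_index",
    span: float = 0.3,
    iterations: int = 3,
) -> pd.DataFrame:
    """Remove a smooth per-metabolite trend of log intensity on a covariate.

    For each metabolite a LOWESS curve of natural-log intensity versus the
    covariate is fitted and subtracted; the residuals are re-centered on
    that metabolite's mean log intensity, so per-metabolite mean log
    intensity is preserved exactly.  Call once per covariate (acquisition
    order first, then OD600).
    """
    if covariate not in ("injection_index", "od600"):
        raise ValueError(f"unsupported covariate: {covariate!r}")
    if not 0 < span <= 1:
        raise ValueError("span must be in (0, 1]")

    out = table.copy()
    log_int = np.log(out["intensity"].to_numpy())
    x_all = out[covariate].to_numpy(dtype=float)
    new_log = log_int.copy()

    for _, idx in out.groupby("metabolite_id").indices.items():
        y = log_int[idx]
        x = x_all[idx]
        if y.size < 10:
            raise ValueError("need >= 10 samples per metabolite for LOWESS")
        if np.ptp(x) == 0:
            warnings.warn(
                f"constant covariate {covariate!r}: detrending skipped", stacklevel=2
            )
            continue
        fitted = _sm_lowess(
            y,
            x,
            frac=span,
            it=iterations,
            delta=0.005 * np.ptp(x),
            return_sorted=False,
        )
        resid = y - fitted
        # residuals are centered before re-adding the metabolite mean so the
        # per-metabolite mean log intensity is preserved exactly
        new_log[idx] = (resid - resid.mean()) + y.mean()

    out["intensity"] = np.exp(new_log)
    return out


def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Quantile-normalize a samples x features matrix of positive values.

    After normalization every sample (row) carries the same value set: the
    across-sample mean of order statistics, assigned in each sample's
    original rank order.  Ties receive the mean of the mean-sorted values
    they span (average-rank rule).  Missing cells are not allowed.
    """
    if isinstance(matrix, pd.DataFrame):
        values = matrix.to_numpy(dtype=float)
    else:
        values = np.asarray(matrix, dtype=float)
    if np.isnan(values).any():
        raise ValueError("quantile_normalize requires a complete matrix")

    n_features = values.shape[1]
    mean_sorted = np.sort(values, axis=1).mean(axis=0)
    ranks = np.apply_along_axis(stats.rankdata, 1, values)  # average ties
    normalized = np.interp(ranks, np.arange(1, n_features + 1), mean_sorted)
    if isinstance(matrix, pd.DataFrame):
        return pd.DataFrame(normalized, index=matrix.index, columns=matrix.columns)
    return normalized
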