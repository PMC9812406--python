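"""Distance-to-positive-set classification and recovery evaluation.

Scores every mutant by its median (or mean) distance to an annotated
positive set (leave-one-out for annotated positives), attaches a
permutation null for the cohesion of that set, evaluates recovery of the
annotation by ROC/AUC (lower score = predicted positive, ties counted
half), and nominates candidates below the score threshold at a target
false-positive rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ROCResult",
    "PermutationResult",
    "set_distance_scores",
    "permutation_pvalue",
    "roc_auc",
    "nominate_candidates",
]


def set_distance_scores(
    dist: pd.DataFrame, positives: set[str], summary: str = "median"
) -> pd.DataFrame:
    """Score each mutant by its summary distance to the positive set.

    Annotated positives are scored leave-one-out (their own row never
    contributes to their score).  Lower scores mean more
    positive-regulator-like.
    """
    if summary not in ("median", "mean"):
        raise ValueError("summary must be 'median' or 'mean'")
    positives = set(positives)
    missing = positives - set(dist.index)
    if missing:
        raise ValueError(f"positives not in distance matrix: {sorted(missing)}")
    if len(positives) < 2:
        raise ValueError("need at least 2 annotated positives")

    agg = np.median if summary == "median" else np.mean
    rows = []
    for m in dist.index:
        others = sorted(positives - {m})
        if not others:
            raise ValueError(f"no positives left after excluding {m!r}")
        rows.append(
            {
                "mutant": m,
                "score": float(agg(dist.loc[m, others].to_numpy(dtype=float))),
                "is_annotated_positive": m in positives,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class PermutationResult:
    observed: float
    n_randomizations: int
    p_value: float
    seed: int
    null_quantiles: dict[str, float] = field(default_factory=dict)


def _median_pairwise(d: np.ndarray, idx: np.ndarray) -> float:
    sub = d[np.ix_(idx, idx)]
    iu = np.triu_indices(len(idx), k=1)
    return float(np.median(sub[iu]))


def permutation_pvalue(
    dist: pd.DataFrame,
    positives: set[str],
    B: int = 10_000,
    seed: int = 0,
) -> PermutationResult:
    """Empirical p-value for the cohesion of the positive set.

    The statistic is the median pairwise distance within the set; the null
    redraws ``B`` uniformly random same-size subsets of all mutants (label
    shuffling).  p uses the add-one rule ``(1 + #{null <= obs}) / (1 + B)``.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    positives = sorted(set(positives))
    if len(positives) < 2:
        raise ValueError("need at least 2 positives")
    names = list(dist.index)
    d = dist.to_numpy(dtype=float)
    pos_idx = np.array([names.index(p) for p in positives])
    observed = _median_pairwise(d, pos_idx)

    n, k = len(names), len(positives)
    if k == n:
        return PermutationResult(observed, B, 1.0, seed)

    rng = np.random.default_rng(seed)
    draws = np.empty((B, k), dtype=int)
    for b in range(B):
        draws[b] = rng.choice(n, size=k, replace=False)
    iu, ju = np.triu_indices(k, k=1)
    null = np.median(d[draws[:, iu], draws[:, ju]], axis=1)
    p = (1 + int(np.sum(null <= observed))) / (1 + B)
    qs = np.quantile(null, [0.05, 0.5, 0.95])
    return PermutationResult(
        observed=observed,
        n_randomizations=B,
        p_value=float(p),
        seed=seed,
        null_quantiles={"q05": float(qs[0]), "q50": float(qs[1]), "q95": float(qs[2])},
    )


@dataclass
class ROCResult:
    """ROC curve for a lower-is-positive score against binary labels."""

    points: pd.DataFrame  # columns: threshold, fpr, tpr
    auc: float
    target_fpr: float
    threshold_at_target_fpr: float | None

    def trapezoidal_auc(self) -> float:
        return float(
            np.trapezoid(self.points["tpr"].to_numpy(), self.points["fpr"].to_numpy())
        )


def roc_auc(
    scores: pd.DataFrame, target_fpr: float = 0.2
) -> ROCResult:
    """Evaluate recovery of annotated positives by the score.

    A mutant is predicted positive when its score is <= the threshold; the
    curve sweeps all observed scores.  AUC uses the Mann-Whitney rank
    formulation with ties counted 1/2, which equals the trapezoidal
    integral of the swept curve.
    """
    s = scores["score"].to_numpy(dtype=float)
    y = scores["is_annotated_positive"].to_numpy(dtype=bool)
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("need at least one positive and one negative label")

    ranks = stats.rankdata(s)  # ascending, average ties
    r_pos = ranks[y].sum()
    # U = #{neg < pos} + 0.5 * ties; lower score predicts positive
    u_greater = r_pos - n_pos * (n_pos + 1) / 2
    auc = 1.0 - u_greater / (n_pos * n_neg)

    thresholds = np.unique(s)
    fpr = np.array([np.mean(s[~y] <= t) for t in thresholds])
    tpr = np.array([np.mean(s[y] <= t) for t in thresholds])
    points = pd.DataFrame(
        {
            "threshold": np.concatenate(([-np.inf], thresholds)),
            "fpr": np.concatenate(([0.0], fpr)),
            "tpr": np.concatenate(([0.0], tpr)),
        }
    )
    ok = thresholds[fpr <= target_fpr]
    threshold = float(ok.max()) if ok.size else None
    return ROCResult(
        points=points,
        auc=float(auc),
        target_fpr=target_fpr,
        threshold_at_target_fpr=threshold,
    )


def nominate_candidates(
    scores: pd.DataFrame, roc: ROCResult
) -> tuple[pd.DataFrame, list[str]]:
    """Complete the score table with threshold ratios and nominate candidates.

    The threshold is the largest observed score whose false-positive rate
    stays at or below the ROC target; candidates are the non-positive
    mutants whose score does not exceed it (ratio_to_threshold <= 1).
    """
    out = scores.copy()
    t = roc.threshold_at_target_fpr
    if t is None:
        out["ratio_to_threshold"] = np.nan
        out["pass"] = False
        import warnings

        warnings.warn("no score threshold achieves the target FPR", stacklevel=2)
        return out, []
    out["ratio_to_threshold"] = out["score"] / t
    out["pass"] = out["score"] <= t
    candidates = sorted(
        out.loc[out["pass"] & ~out["is_annotated_positive"], "mutant"]
    )
    return out, candidates
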