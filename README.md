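# metaboguilt

Guilt-by-association analysis of dynamic metabolome profiles. Starting from
tidy per-sample, per-metabolite ion-intensity tables for a mutant library
measured over a perturbation time course, the package:

1. **simulates** datasets with the assumed statistical structure (a planted
   co-responding positive-regulator cluster, an anti-responding negative set,
   acquisition-order drift, OD600 and per-sample technical confounders), with
   a full ground-truth record (`metaboguilt.synthetic`);
2. **normalizes** — outlier-sample removal on OD600 and log total ion current
   (median/MAD rule), per-metabolite LOWESS detrending of log intensity
   against injection order and OD600, plus quantile normalization for
   proteome-style matrices (`metaboguilt.normalization`);
3. **profiles** — mutant-vs-wild-type log2 fold-changes per timepoint with
   two-sided Student's t-tests, within-strain treatment responses, and
   significance calls/counts at |log2 FC| > 0.5, p < 0.05
   (`metaboguilt.profiles`);
4. **compares** mutants — per-timepoint Pearson correlation matrices,
   Manhattan distances between correlation profiles, Ward agglomeration
   (Lance–Williams update on the supplied dissimilarities), and correlation
   against external pairwise score tables (`metaboguilt.similarity`);
5. **classifies** — median (or mean) distance-to-positive-set scores with
   leave-one-out, permutation empirical p-values for positive-set cohesion
   (add-one rule), ROC/AUC recovery of the annotated positives (rank
   formulation, ties ½), and candidate nomination at a target false-positive
   rate (`metaboguilt.guilt`);
6. **measures growth** — 1 h moving-window smoothing, maximum ln-OD slope as
   growth rate, tangent-intercept lag time, and ratios to the experiment
   average or a reference strain (`metaboguilt.growth`).

All interchange formats are plain text: tidy CSV tables, JSON reports and
Newick trees.

## CLI

Every stage can be run separately from persisted intermediates, or end to
end from one YAML config:

```bash
metaboguilt simulate --seed 42 --out out/sim
metaboguilt normalize out/sim/intensity.csv --out out/norm
metaboguilt profile out/norm/normalized.csv --out out/prof
metaboguilt similarity out/prof/profiles.csv --timepoint 30 --out out/sim30
metaboguilt guilt score    out/sim30/distance_t30.csv --annotation out/sim/annotation.csv --out out/scores.csv
metaboguilt guilt permute  out/sim30/distance_t30.csv --annotation out/sim/annotation.csv --B 10000 --seed 0 --out out/perm.json
metaboguilt guilt roc      out/sim30/distance_t30.csv --annotation out/sim/annotation.csv --out out/roc.csv
metaboguilt guilt nominate out/sim30/distance_t30.csv --annotation out/sim/annotation.csv --target-fpr 0.2 --out out/nominated.csv
metaboguilt growth --simulate-strains 6 --out out/growth.csv
metaboguilt run --seed 42 --out out/full        # whole pipeline, defaults
metaboguilt run --config pipeline.yaml --out out/full
```

`run` writes, in order: the resolved config, the simulated (or loaded)
inputs, the outlier report, the normalized table, fold-change profiles and
significance counts, then per timepoint the correlation matrix, distance
matrix, Ward tree (Newick + JSON), ROC curve, and finally the score table,
candidate list and a deterministic `summary.json` (AUC and permutation p per
timepoint, thresholds, seeds, library versions). Identical config + seed
reproduces every output byte for byte.

## Library use

```python
from metaboguilt import (
    SimulationConfig, generate_dataset, filter_outlier_samples, lowess_detrend,
    log2_fold_change_profiles, correlation_matrix, manhattan_distance_matrix,
    set_distance_scores, roc_auc, nominate_candidates,
)

table, annotation, truth = generate_dataset(SimulationConfig(seed=42))
table, report = filter_outlier_samples(table, k_mad=3.0)
for cov in ("injection_index", "od600"):
    table = lowess_detrend(table, covariate=cov, span=0.3)
profiles = log2_fold_change_profiles(table, reference_mutant="WT")
corr = correlation_matrix(profiles, timepoint_min=30.0)
dist = manhattan_distance_matrix(corr)
positives = set(annotation.query("`class` == 'positive_regulator'")["mutant"])
scores = set_distance_scores(dist, positives, summary="median")
roc = roc_auc(scores, target_fpr=0.2)
scores, candidates = nominate_candidates(scores, roc)
```

## Notes on conventions

- Fold-change is log2 of the **ratio of group means** (a mean-of-log2-ratios
  alternative is available via `mean_of_ratios=True`); t-tests are pooled
  Student's on natural-log intensities (Welch via `welch=True`).
- Fig-1D-style significance counts use raw p < 0.05 with no multiple-testing
  correction, by design.
- Distance rows include the self/mutual correlation entries by default
  (`include_self=False` drops them).
- Ward is applied to the supplied dissimilarities as-is; on a non-Euclidean
  input this is not a variance decomposition, but the merge sequence is well
  defined (lexicographic tie-breaking).
- The nomination threshold is the largest observed score with FPR at or
  below the target; a score exactly at the threshold (ratio 1.0) passes.
- Growth lag defaults to the tangent-intercept construction;
  `lag_method="max_slope"` gives the literal earliest-time-of-maximum-slope.
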