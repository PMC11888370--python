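"""Enrichment statistics, synthon aggregation, and baseline ML evaluation.

All metrics operate on cube tables (one row per compound, raw and
UMI-corrected counts per condition) and treat the UMI-corrected count as
the default signal, since PCR duplicates carry no extra evidence.

Implemented metrics
-------------------
sampling depth
    total reads for a condition divided by the library's diversity; a
    depth of 10 means each compound was sequenced ~10x on average.
normalized sequence count (NSC)
    counts per million within a condition, making conditions of different
    sequencing depth comparable.
z-score
    the one-proportion normal approximation
    ``z = (c - n*p0) / sqrt(n*p0*(1-p0))`` against the uniform null
    ``p0 = 1/library_size``; against a no-target control it becomes the
    pooled two-proportion z.  An optional multiplicative normalisation
    factor is exposed for depth-scaled variants.
maximum-likelihood enrichment ratio
    Poisson rate-ratio estimator ``((c_t+1/2)/N_t) / ((c_c+1/2)/N_c)`` with
    a Clopper-Pearson interval from the conditional-binomial construction:
    given the summed count, the target count is binomial with odds
    proportional to the rate ratio.

Synthon aggregation sums counts over the free cycles, turning compound
rows into mono-/disynthon rows where consistent trends across a shared
substructure stand out from single-compound noise.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

METRICS = ("sampling_depth", "nsc", "zscore", "zscore_vs_control",
           "mle_ratio")


# ---------------------------------------------------------------------------
# scalar / vector metrics


def sampling_depth(total_reads: float, library_size: int) -> float:
    """Average reads per library member for one condition."""
    if library_size <= 0:
        raise ValueError("library_size must be positive")
    return total_reads / library_size


def normalized_count(count, condition_total):
    """Counts per million within the condition."""
    total = np.asarray(condition_total, dtype=float)
    if np.any(total <= 0):
        raise ValueError("condition total must be positive")
    return np.asarray(count, dtype=float) * 1e6 / total


def zscore(count, condition_total, null_proportion,
           normalization: float = 1.0):
    """One-proportion z against a fixed null proportion.

    ``normalization`` is a plain multiplier on z (1.0 = the unscaled
    proportion z) for depth-scaled variants.
    """
    n = np.asarray(condition_total, dtype=float)
    p0 = np.asarray(null_proportion, dtype=float)
    if np.any((p0 <= 0) | (p0 >= 1)):
        raise ValueError("null_proportion must be in (0, 1)")
    if np.any(n <= 0):
        raise ValueError("condition_total must be positive")
    c = np.asarray(count, dtype=float)
    return normalization * (c - n * p0) / np.sqrt(n * p0 * (1 - p0))


def zscore_vs_control(count_target, total_target, count_control,
                      total_control, normalization: float = 1.0):
    """Pooled two-proportion z of target vs control proportions."""
    ct = np.asarray(count_target, dtype=float)
    cc = np.asarray(count_control, dtype=float)
    nt = float(total_target)
    nc = float(total_control)
    if nt <= 0 or nc <= 0:
        raise ValueError("condition totals must be positive")
    pooled = (ct + cc) / (nt + nc)
    denom = np.sqrt(pooled * (1 - pooled) * (1 / nt + 1 / nc))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (ct / nt - cc / nc) / denom
    return normalization * np.where(denom == 0, 0.0, z)


def mle_ratio(count_target, total_target, count_control, total_control,
              alpha: float = 0.05):
    """Poisson rate-ratio MLE with conditional-binomial confidence interval.

    Both counts get a 1/2 pseudocount so the estimate is finite at zero.
    Conditioning on the summed count makes the target count binomial with
    success probability p = Nt*r / (Nt*r + Nc); a Clopper-Pearson interval
    for p (at level 1-alpha) transforms monotonically into one for the
    ratio r.  Returns (ratio, ci_low, ci_high), vectorised over counts.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    nt = float(total_target)
    nc = float(total_control)
    if nt <= 0 or nc <= 0:
        raise ValueError("condition totals must be positive")
    ct = np.asarray(count_target, dtype=float)
    cc = np.asarray(count_control, dtype=float)
    ratio = ((ct + 0.5) / nt) / ((cc + 0.5) / nc)

    k = ct + cc
    with np.errstate(invalid="ignore"):
        # Clopper-Pearson bounds for p = ct / k successes
        p_low = stats.beta.ppf(alpha / 2, ct, k - ct + 1)
        p_high = stats.beta.ppf(1 - alpha / 2, ct + 1, k - ct)
    p_low = np.where(ct == 0, 0.0, p_low)
    p_high = np.where(cc == 0, 1.0, p_high)

    def odds(p):
        with np.errstate(divide="ignore"):
            return np.where(p >= 1, np.inf, p / (1 - p)) * nc / nt

    ci_low = np.where(k == 0, 0.0, odds(p_low))
    ci_high = np.where(k == 0, np.inf, odds(p_high))
    ci_low = np.minimum(ci_low, ratio)
    ci_high = np.maximum(ci_high, ratio)
    if np.isscalar(count_target) or np.ndim(count_target) == 0:
        return float(ratio), float(ci_low), float(ci_high)
    return ratio, ci_low, ci_high


# ---------------------------------------------------------------------------
# table-level enrichment


def _count_col(condition: str, use_umi: bool) -> str:
    return f"{condition}_{'umi' if use_umi else 'raw'}_count"


def enrichment_table(cube: pd.DataFrame, condition: str,
                     control: Optional[str] = None,
                     library_size: Optional[int] = None,
                     use_umi: bool = True,
                     alpha: float = 0.05,
                     normalization: float = 1.0) -> pd.DataFrame:
    """Per-compound (or per-synthon) enrichment metrics for one condition.

    ``library_size`` defaults to the number of rows, which is correct for
    synthon tables and for cubes covering the full library; pass the true
    diversity when the cube is sparse.
    """
    col = _count_col(condition, use_umi)
    if col not in cube.columns:
        raise ValueError(f"cube has no column {col!r}; conditions present: "
                         f"{sorted(c[:-10] for c in cube.columns if c.endswith('_umi_count'))}")
    counts = cube[col].to_numpy(dtype=float)
    total = counts.sum()
    size = library_size if library_size is not None else len(cube)
    out = cube.loc[:, [c for c in ("compound_id", "synthon_id", "library_id")
                       if c in cube.columns]].copy()
    out["count"] = counts
    out["sampling_depth"] = sampling_depth(total, size)
    out["nsc"] = normalized_count(counts, total) if total > 0 else 0.0
    if total > 0:
        out["zscore"] = zscore(counts, total, 1.0 / size,
                               normalization=normalization)
    else:
        out["zscore"] = 0.0
    if control is not None:
        ccol = _count_col(control, use_umi)
        if ccol not in cube.columns:
            raise ValueError(f"cube has no control column {ccol!r}")
        ccounts = cube[ccol].to_numpy(dtype=float)
        ctotal = ccounts.sum()
        if ctotal > 0 and total > 0:
            out["zscore_vs_control"] = zscore_vs_control(
                counts, total, ccounts, ctotal, normalization=normalization)
            r, lo, hi = mle_ratio(counts, total, ccounts, ctotal, alpha=alpha)
            out["mle_ratio"] = r
            out["mle_ratio_ci_low"] = lo
            out["mle_ratio_ci_high"] = hi
    return out


# ---------------------------------------------------------------------------
# synthon aggregation


def aggregate_synthons(cube: pd.DataFrame, fixed_cycles: Sequence[int],
                       ) -> pd.DataFrame:
    """Aggregate compound counts to the synthon level.

    ``fixed_cycles`` are 1-based cycle numbers (matching the ``bb_i`` cube
    columns) whose building blocks are held fixed; counts are summed over
    all completions of the remaining (free) cycles.  Fixing every cycle is
    the compound level and is rejected.
    """
    bb_cols = [c for c in cube.columns if c.startswith("bb_")]
    n_cycles = len(bb_cols)
    fixed = sorted(set(int(c) for c in fixed_cycles))
    if not fixed:
        raise ValueError("fixed_cycles must not be empty")
    if any(c < 1 or c > n_cycles for c in fixed):
        raise ValueError(f"fixed_cycles must be within 1..{n_cycles}")
    if len(fixed) >= n_cycles:
        raise ValueError("fixing all cycles is the compound level; "
                         "use the cube directly")
    keys = ["library_id"] + [f"bb_{c}" for c in fixed]
    count_cols = [c for c in cube.columns if c.endswith("_count")]
    agg = (cube.groupby(keys, as_index=False)[count_cols].sum()
           .sort_values(keys, kind="mergesort").reset_index(drop=True))
    agg.insert(0, "synthon_id",
               agg[keys].astype(str).agg("-".join, axis=1))
    return agg


# ---------------------------------------------------------------------------
# replicate overlap


def replicate_overlap(tables: Sequence[pd.DataFrame], metric: str,
                      threshold: float,
                      key: str = "compound_id") -> dict[frozenset, int]:
    """Venn-region counts of keys passing a threshold across replicates.

    For each non-empty subset of replicate indices, the count of keys whose
    ``metric`` exceeds ``threshold`` in *exactly* that subset; regions
    partition the union of passing keys.
    """
    if len(tables) < 2:
        raise ValueError("need at least two replicate tables")
    key_sets = [frozenset(t[key]) for t in tables]
    if len(set(key_sets)) != 1:
        raise ValueError("replicate tables cover different key spaces")
    passing = [set(t.loc[t[metric] > threshold, key]) for t in tables]
    regions: dict[frozenset, int] = {}
    n = len(tables)
    for r in range(1, n + 1):
        for combo in itertools.combinations(range(n), r):
            inside = set.intersection(*(passing[i] for i in combo))
            outside = set.union(*(passing[i] for i in range(n)
                                  if i not in combo), set())
            regions[frozenset(combo)] = len(inside - outside)
    return regions


# ---------------------------------------------------------------------------
# baseline ML evaluation


@dataclass
class EvaluationSummary:
    fold_accuracy: list[float]
    fold_accuracy_dummy: list[float]
    n_per_class: int

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.fold_accuracy))

    @property
    def mean_accuracy_dummy(self) -> float:
        return float(np.mean(self.fold_accuracy_dummy))


def balance_and_evaluate(features, labels, folds: int = 5, seed: int = 0,
                         classifier_factory: Optional[Callable] = None,
                         ) -> EvaluationSummary:
    """Undersample to class balance, then cross-validate a classifier
    against a majority-class dummy.

    The classifier is pluggable through ``classifier_factory`` (anything
    with the fit/predict contract); the default is a random forest.  A
    dummy baseline near the classifier's accuracy means the labels carry no
    learnable signal at this feature representation — a selection
    quality-control red flag.
    """
    from sklearn.dummy import DummyClassifier
    from sklearn.ensemble import RandomForestClassifier
    from sklearn.model_selection import StratifiedKFold

    X = np.asarray(features)
    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("need at least two classes to evaluate")
    n_min = int(counts.min())
    rng = np.random.default_rng(seed)
    keep = np.concatenate([
        rng.choice(np.flatnonzero(y == cls), size=n_min, replace=False)
        for cls in classes])
    keep.sort()
    Xb, yb = X[keep], y[keep]

    if classifier_factory is None:
        classifier_factory = lambda: RandomForestClassifier(  # noqa: E731
            n_estimators=100, random_state=seed)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    acc, acc_dummy = [], []
    for train, test in skf.split(Xb, yb):
        clf = classifier_factory()
        clf.fit(Xb[train], yb[train])
        acc.append(float(np.mean(clf.predict(Xb[test]) == yb[test])))
        dummy = DummyClassifier(strategy="most_frequent")
        dummy.fit(Xb[train], yb[train])
        acc_dummy.append(float(np.mean(dummy.predict(Xb[test]) == yb[test])))
    return EvaluationSummary(fold_accuracy=acc, fold_accuracy_dummy=acc_dummy,
                             n_per_class=n_min)
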