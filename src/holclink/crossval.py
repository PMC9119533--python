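"""Five-fold cross-validated scoring of classification schemes.

For every (scheme, outcome, inclusion-threshold) cell, the engine
standardizes the outcome on the threshold-filtered dataset, splits tracts
into five folds, fits a least-squares model of the outcome on the
scheme's class indicators in the training folds, predicts the held-out
fold, and averages the five test mean squared errors. With the default
grid of 54 schemes, 6 outcomes and 7 thresholds this yields 2,268
averaged cross-validated MSEs.

The class-indicator regression is saturated, so its predictions are
exactly the per-class training means; predictions are computed that way
(which is fast and numerically exact), and the tests verify equivalence
against an explicit dummy-coded least-squares fit. Classes absent from
the training folds predict the training grand mean. Standardization uses
the full threshold-filtered dataset before the fold split, reproducing
the stated procedure (per-fold standardization is available via
``standardize_within_folds``).
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .overlay import filter_by_threshold
from .schemes import Scheme, enumerate_schemes, label_table

#: minimum-rated-coverage thresholds (percent) defining the 7 datasets
DEFAULT_THRESHOLDS: tuple[float, ...] = (1, 5, 10, 15, 25, 33, 50)

N_FOLDS = 5


def standardize(values) -> np.ndarray:
    """z-scores with the sample (n-1) standard deviation."""
    x = np.asarray(values, dtype=float)
    if np.unique(x).size < 2:
        raise ValueError("cannot standardize a constant vector")
    return (x - x.mean()) / x.std(ddof=1)


def assign_folds(n: int, rng: np.random.Generator | int | None = None,
                 n_folds: int = N_FOLDS) -> np.ndarray:
    """Random fold indices 1..n_folds with sizes differing by at most 1."""
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    if n < n_folds:
        raise ValueError(f"need at least {n_folds} rows for {n_folds} folds")
    folds = np.empty(n, dtype=np.int64)
    for k, chunk in enumerate(np.array_split(rng.permutation(n), n_folds), start=1):
        folds[chunk] = k
    return folds


def cv_mse(labels, y_std, folds) -> tuple[float, list[float]]:
    """Averaged five-fold test MSE of the class-means predictor.

    ``labels`` are class labels, ``y_std`` the standardized outcome and
    ``folds`` fold indices 1..5 (all aligned). Returns the unweighted
    mean of the per-fold test MSEs together with the per-fold values.
    """
    labels = np.asarray(labels)
    y = np.asarray(y_std, dtype=float)
    folds = np.asarray(folds)
    codes, classes = pd.factorize(labels)
    K = len(classes)
    fold_ids = np.unique(folds)
    per_fold = []
    for k in fold_ids:
        test = folds == k
        train = ~test
        if not train.any():
            raise ValueError(f"fold {k}: no training rows")
        counts = np.bincount(codes[train], minlength=K).astype(float)
        sums = np.bincount(codes[train], weights=y[train], minlength=K)
        grand = y[train].mean()
        with np.errstate(invalid="ignore"):
            means = np.where(counts > 0, sums / np.maximum(counts, 1.0), grand)
        pred = means[codes[test]]
        per_fold.append(float(np.mean((y[test] - pred) ** 2)))
    return float(np.mean(per_fold)), per_fold


def _outcome_columns(outcomes: pd.DataFrame,
                     requested: Sequence[str] | None) -> list[str]:
    cols = [c for c in outcomes.columns if c != "tract_id"]
    if requested is None:
        return cols
    missing = [c for c in requested if c not in cols]
    if missing:
        raise ValueError(f"outcome columns not found: {missing}")
    return list(requested)


def run_grid(
    coverages: pd.DataFrame,
    outcomes: pd.DataFrame,
    schemes: Iterable[Scheme] | None = None,
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
    seed: int = 0,
    outcome_columns: Sequence[str] | None = None,
    standardize_within_folds: bool = False,
) -> pd.DataFrame:
    """Cross-validated MSE for every (scheme, outcome, threshold) cell.

    Folds are drawn once per (outcome, threshold) dataset and shared by
    all schemes evaluated on it, so scheme comparisons within a dataset
    are paired. Schemes that exclude unrated area are evaluated on
    compositions rebased to the rated-area denominator. ``df`` counts
    the distinct classes present in the full threshold dataset minus one
    (the reference class).

    Returns a data frame with columns ``scheme_id, outcome_id,
    threshold, mse, df, n_tracts``.
    """
    scheme_list = list(enumerate_schemes() if schemes is None else schemes)
    out_cols = _outcome_columns(outcomes, outcome_columns)

    # Labels are per-tract and dataset-independent: compute once per
    # scheme on the full coverage table. Fully unrated tracts cannot be
    # labeled; they are deferred (NaN) and must be excluded by thresholds.
    ratable = coverages.loc[100.0 - coverages["pct_u"] > 0.0]
    labels_all = pd.DataFrame(index=coverages["tract_id"])
    for scheme in scheme_list:
        lab = label_table(ratable, scheme)
        labels_all[scheme.scheme_id] = pd.Series(
            lab.to_numpy(), index=ratable["tract_id"]
        )

    merged = coverages.merge(outcomes, on="tract_id", validate="one_to_one")
    rows = []
    for o_idx, oc in enumerate(out_cols):
        base = merged.loc[merged[oc].notna()]
        for t_idx, thr in enumerate(thresholds):
            sub = filter_by_threshold(base, thr)
            if len(sub) == 0:
                raise ValueError(
                    f"threshold {thr}% eliminates every tract for "
                    f"outcome {oc!r}"
                )
            ids = sub["tract_id"].to_numpy()
            y_raw = sub[oc].to_numpy(dtype=float)
            rng = np.random.default_rng(
                np.random.SeedSequence([int(seed), o_idx, t_idx])
            )
            folds = assign_folds(len(sub), rng)
            if not standardize_within_folds:
                y = standardize(y_raw)
            for scheme in scheme_list:
                lab = labels_all.loc[ids, scheme.scheme_id].to_numpy()
                if pd.isna(lab).any():
                    raise ValueError(
                        f"threshold {thr}% admits fully unrated tracts, "
                        f"which scheme {scheme.scheme_id} cannot label"
                    )
                if standardize_within_folds:
                    mse = _cv_mse_fold_standardized(lab, y_raw, folds)
                else:
                    mse, _ = cv_mse(lab, y, folds)
                rows.append(
                    (scheme.scheme_id, oc, thr, mse,
                     int(pd.unique(lab).size) - 1, len(sub))
                )
    return pd.DataFrame(
        rows,
        columns=["scheme_id", "outcome_id", "threshold", "mse", "df", "n_tracts"],
    )


def _cv_mse_fold_standardized(labels, y_raw, folds) -> float:
    """Alternative: standardize with training-fold moments only."""
    labels = np.asarray(labels)
    y_raw = np.asarray(y_raw, dtype=float)
    folds = np.asarray(folds)
    codes, classes = pd.factorize(labels)
    K = len(classes)
    per_fold = []
    for k in np.unique(folds):
        test = folds == k
        train = ~test
        mu, sd = y_raw[train].mean(), y_raw[train].std(ddof=1)
        if sd == 0:
            raise ValueError("constant outcome in training folds")
        y = (y_raw - mu) / sd
        counts = np.bincount(codes[train], minlength=K).astype(float)
        sums = np.bincount(codes[train], weights=y[train], minlength=K)
        means = np.where(counts > 0, sums / np.maximum(counts, 1.0),
                         y[train].mean())
        per_fold.append(float(np.mean((y[test] - means[codes[test]]) ** 2)))
    return float(np.mean(per_fold))
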