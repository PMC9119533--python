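"""Head-to-head validation of classification approaches on held-out outcomes.

Compares the schemes selected by cross-validation (collapsed 10-class,
detailed 16-class, optimal 40-class) against approaches from earlier
redlining studies: continuous rated-area proportions, a single
largest-coverage rating, and centroid assignment. Each approach is fit by
OLS to each validation outcome; R² (plus RMSE and adjusted R²) summarize
predictive performance, coefficient tables give per-class contrasts
against a stated reference class, and a performance ratio expresses one
approach's average R² as a percentage of another's.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .collapse import collapse_labels
from .schemes import Scheme, label_table, rebase_excluding_unrated
from .synthetic import RATED_GRADES

#: supported predictor kinds and the non-intercept parameter count each
#: consumes when every feasible class is present
PREDICTOR_KINDS: dict[str, int] = {
    "proportions": 3,
    "one_rating": 3,
    "collapsed10": 9,
    "detailed16": 15,
    "optimal40": 39,
    "centroid": 3,
}


def build_predictors(coverages: pd.DataFrame, kind: str,
                     centroid_grades: Mapping | None = None) -> pd.DataFrame:
    """Design columns (no intercept) for one predictor kind.

    ``proportions`` yields three continuous columns — the B, C and D
    shares of the *rated* area (A omitted for identification). The
    categorical kinds yield 0/1 class indicators, dropping the first
    class alphabetically as reference. ``centroid`` requires
    ``centroid_grades`` (tract_id -> grade, from
    :func:`holclink.overlay.centroid_grade`); unrated-centroid tracts get
    an ``unrated`` indicator level.
    """
    if kind not in PREDICTOR_KINDS:
        raise ValueError(
            f"unknown predictor kind {kind!r}; expected one of "
            f"{sorted(PREDICTOR_KINDS)}"
        )
    if kind == "proportions":
        reb = rebase_excluding_unrated(coverages)
        X = pd.DataFrame(index=coverages.index)
        for g in ("B", "C", "D"):
            X[f"prop_{g.lower()}"] = reb[f"pct_{g.lower()}"].to_numpy() / 100.0
        return X
    labels = predictor_labels(coverages, kind, centroid_grades)
    return pd.get_dummies(labels, prefix="", prefix_sep="",
                          drop_first=True, dtype=float)


def predictor_labels(coverages: pd.DataFrame, kind: str,
                     centroid_grades: Mapping | None = None) -> pd.Series:
    """Class labels underlying a categorical predictor kind."""
    if kind == "one_rating":
        return label_table(coverages, Scheme(6, 1, False))
    if kind == "detailed16":
        return label_table(coverages, Scheme(6, 2, False))
    if kind == "collapsed10":
        return collapse_labels(label_table(coverages, Scheme(6, 2, False)))
    if kind == "optimal40":
        return label_table(coverages, Scheme(6, 3, False))
    if kind == "centroid":
        if centroid_grades is None:
            raise ValueError("centroid kind requires centroid_grades")
        lab = coverages["tract_id"].map(
            lambda t: centroid_grades.get(t) or "unrated"
        )
        return pd.Series(lab.to_numpy(), index=coverages.index, name="centroid")
    raise ValueError(f"predictor kind {kind!r} has no label representation")


def _ols_stats(y: np.ndarray, X: pd.DataFrame) -> tuple[float, float, float]:
    """R², RMSE and adjusted R² of y ~ 1 + X, dropping aliased columns."""
    n = len(y)
    A = np.column_stack([np.ones(n), X.to_numpy(dtype=float)])
    rank = np.linalg.matrix_rank(A)
    if rank < A.shape[1]:
        import warnings

        warnings.warn(
            f"rank-deficient design ({A.shape[1] - rank} aliased columns "
            "dropped in effect)"
        )
    beta, *_ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ beta
    sse = float(resid @ resid)
    sst = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - sse / sst
    p = rank - 1
    adj = 1.0 - (1.0 - r2) * (n - 1) / max(n - p - 1, 1)
    rmse = float(np.sqrt(sse / n))
    return r2, rmse, adj


def r2_table(
    outcomes: pd.DataFrame,
    coverages: pd.DataFrame,
    kinds: Sequence[str] = ("proportions", "one_rating", "collapsed10",
                            "detailed16", "optimal40"),
    outcome_columns: Sequence[str] | None = None,
    health_outcomes: Sequence[str] | None = None,
    economic_outcomes: Sequence[str] | None = None,
    centroid_grades: Mapping | None = None,
) -> pd.DataFrame:
    """R² of each outcome on each predictor kind, with group averages.

    Outcomes are standardized per column before fitting. The returned
    frame has one row per outcome and one column per kind; when
    ``health_outcomes`` / ``economic_outcomes`` name outcome groups,
    ``Average (health)`` / ``Average (economic)`` rows are appended.
    Companion RMSE and adjusted-R² tables live in ``attrs['rmse']`` and
    ``attrs['adj_r2']``.
    """
    from .crossval import standardize

    merged = coverages.merge(outcomes, on="tract_id", validate="one_to_one")
    out_cols = [c for c in outcomes.columns if c != "tract_id"] \
        if outcome_columns is None else list(outcome_columns)
    designs = {k: build_predictors(merged, k, centroid_grades) for k in kinds}
    r2 = pd.DataFrame(index=out_cols, columns=list(kinds), dtype=float)
    rmse = r2.copy()
    adj = r2.copy()
    for oc in out_cols:
        keep = merged[oc].notna().to_numpy()
        y = standardize(merged.loc[keep, oc])
        for k in kinds:
            r2.loc[oc, k], rmse.loc[oc, k], adj.loc[oc, k] = _ols_stats(
                y, designs[k].loc[keep]
            )
    for name, group in (("health", health_outcomes),
                        ("economic", economic_outcomes)):
        if group:
            missing = [c for c in group if c not in out_cols]
            if missing:
                raise ValueError(f"{name} outcomes not in table: {missing}")
            r2.loc[f"Average ({name})"] = r2.loc[list(group)].mean()
    r2.attrs["rmse"] = rmse
    r2.attrs["adj_r2"] = adj
    return r2


def coefficient_table(
    y,
    labels,
    reference_class: str,
) -> pd.DataFrame:
    """Per-class OLS contrasts against a reference class.

    Fits ``y ~ class indicators`` with ``reference_class`` omitted, so
    the intercept is the reference-class mean and each coefficient a
    class-mean difference. Returns estimates, conventional standard
    errors, two-sided p-values and significance stars (* 0.05, ** 0.01,
    *** 0.001); RMSE, R² and n in ``attrs``.
    """
    import statsmodels.api as sm

    s = pd.Series(np.asarray(labels), name="class_label")
    if reference_class not in set(s):
        raise ValueError(f"reference class {reference_class!r} absent from labels")
    classes = [reference_class] + sorted(set(s) - {reference_class})
    cat = pd.Categorical(s, categories=classes)
    X = pd.get_dummies(cat, drop_first=True, dtype=float)
    X.columns = [str(c) for c in X.columns]
    fit = sm.OLS(np.asarray(y, dtype=float), sm.add_constant(X)).fit()
    stars = pd.cut(
        fit.pvalues, [-np.inf, 0.001, 0.01, 0.05, np.inf],
        labels=["***", "**", "*", ""],
    ).astype(str)
    table = pd.DataFrame({
        "estimate": fit.params,
        "se": fit.bse,
        "p": fit.pvalues,
        "stars": stars,
    })
    table = table.rename(index={"const": f"{reference_class} (Ref.)"})
    table.attrs["rmse"] = float(np.sqrt(fit.ssr / fit.nobs))
    table.attrs["r_squared"] = float(fit.rsquared)
    table.attrs["n"] = int(fit.nobs)
    return table


@dataclass(frozen=True)
class PerformanceRatio:
    percent: float
    rounded: int


def performance_ratio(numerator_avg_r2: float,
                      denominator_avg_r2: float) -> PerformanceRatio:
    """One approach's average R² as a percentage of another's.

    Returns both the unrounded percentage and its nearest-integer
    rendering (e.g. average R² of 8.3% against 9.2% gives 90.2 -> 90).
    """
    if denominator_avg_r2 <= 0:
        raise ValueError("denominator average R² must be positive")
    pct = 100.0 * numerator_avg_r2 / denominator_avg_r2
    return PerformanceRatio(percent=pct, rounded=int(round(pct)))
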