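"""Meta-analysis of the cross-validation grid and scheme selection.

The 2,268-cell grid of averaged cross-validated MSEs is itself a designed
experiment: each cell is described by five fully crossed features (number
of ratings, scheme set, unrated handling, outcome, inclusion threshold).
Regressing the MSEs on dummy-coded features quantifies which design
choices matter for predictive validity. Per-scheme summaries (mean and
median MSE over a scheme's 42 cells, median model degrees of freedom)
support the selection of the predictively optimal scheme and of a
parsimonious scheme that performs nearly as well with far fewer classes.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .schemes import Scheme

#: feature-group names usable in ``regress_mse_on_features``
FEATURE_GROUPS: tuple[str, ...] = (
    "ratings", "set_cat", "include_u", "outcome", "threshold",
)

_REFERENCES = {
    "ratings": 2,          # two-rating schemes
    "set_cat": "set6",     # rank-ordered set
    "include_u": False,    # exclude unrated
    "threshold": 5,        # 5% minimum rated coverage
}


def experiment_features(cv_results: pd.DataFrame) -> pd.DataFrame:
    """Expand a CV-result table into one row of experiment features per cell."""
    rows = cv_results.copy()
    parsed = [Scheme.from_id(s) for s in rows["scheme_id"]]
    rows["ratings"] = [s.n_ratings for s in parsed]
    rows["set_cat"] = [f"set{s.set_id}" for s in parsed]
    rows["include_u"] = [s.include_unrated for s in parsed]
    rows["outcome"] = rows["outcome_id"]
    return rows


def _dummy_design(rows: pd.DataFrame, features: Sequence[str],
                  outcome_ref: str | None) -> pd.DataFrame:
    X = pd.DataFrame(index=rows.index)
    for feat in features:
        if feat == "include_u":
            levels = sorted(rows["include_u"].unique())
            if len(levels) < 2:
                raise ValueError("feature 'include_u' has a single level")
            X["include_u"] = rows["include_u"].astype(float)
            continue
        ref = outcome_ref if feat == "outcome" else _REFERENCES[feat]
        col = rows[feat]
        levels = list(pd.unique(col))
        if len(levels) < 2:
            raise ValueError(f"feature {feat!r} has a single level")
        if ref is None or ref not in levels:
            ref = sorted(levels, key=str)[0]
        for lev in sorted((l for l in levels if l != ref), key=str):
            X[f"{feat}[{lev}]"] = (col == lev).astype(float)
    return X


def regress_mse_on_features(
    cv_results: pd.DataFrame,
    features: Sequence[str] | str = "all",
    outcome_ref: str | None = None,
) -> pd.DataFrame:
    """OLS of cell MSEs on dummy-coded experiment features.

    ``features`` is one of the names in :data:`FEATURE_GROUPS`, a list of
    them, or ``"all"``. Reference levels: 2 ratings, the rank-ordered set,
    unrated excluded, the 5% threshold, and ``outcome_ref`` (first outcome
    alphabetically when not given). Returns a coefficient table (estimate,
    standard error, t, p) with the fit's R², n and residuals stored in
    ``DataFrame.attrs``.
    """
    rows = cv_results if "ratings" in cv_results.columns \
        else experiment_features(cv_results)
    if isinstance(features, str):
        features = list(FEATURE_GROUPS) if features == "all" else [features]
    unknown = [f for f in features if f not in FEATURE_GROUPS]
    if unknown:
        raise ValueError(f"unknown feature groups: {unknown}")
    X = _dummy_design(rows, features, outcome_ref)
    model = sm.OLS(rows["mse"].to_numpy(dtype=float), sm.add_constant(X))
    fit = model.fit()
    table = pd.DataFrame({
        "estimate": fit.params,
        "se": fit.bse,
        "t": fit.tvalues,
        "p": fit.pvalues,
    })
    table.attrs["r_squared"] = float(fit.rsquared)
    table.attrs["n"] = int(fit.nobs)
    table.attrs["residuals"] = np.asarray(fit.resid)
    table.attrs["design_columns"] = list(X.columns)
    return table


def table3_columns(cv_results: pd.DataFrame,
                   outcome_ref: str | None = None) -> dict[str, pd.DataFrame]:
    """The six regression columns: each feature alone, then all features."""
    rows = experiment_features(cv_results)
    out = {feat: regress_mse_on_features(rows, feat, outcome_ref)
           for feat in FEATURE_GROUPS}
    out["all"] = regress_mse_on_features(rows, "all", outcome_ref)
    return out


def stratified_regressions(cv_results: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """All-features regression rerun separately per outcome (outcome dummies dropped)."""
    rows = experiment_features(cv_results)
    outcomes = list(pd.unique(rows["outcome"]))
    if len(outcomes) < 2:
        raise ValueError("stratified regressions need at least two outcomes")
    feats = [f for f in FEATURE_GROUPS if f != "outcome"]
    return {
        oc: regress_mse_on_features(rows.loc[rows["outcome"] == oc], feats)
        for oc in outcomes
    }


def summarize_schemes(cv_results: pd.DataFrame) -> pd.DataFrame:
    """Per-scheme mean/median MSE, median df and observed class count.

    Under the default grid every scheme aggregates 42 cells (6 outcomes x
    7 thresholds). ``class_count`` is the largest number of distinct
    classes the scheme realized in any cell's dataset (df + 1); for very
    detailed schemes this is below the theoretical feasible count because
    not every feasible class occurs empirically.
    """
    g = cv_results.groupby("scheme_id", sort=True)
    out = pd.DataFrame({
        "mean_mse": g["mse"].mean(),
        "median_mse": g["mse"].median(),
        "median_df": g["df"].median(),
        "class_count": g["df"].max() + 1,
        "n_cells": g.size(),
    }).reset_index()
    if out["n_cells"].nunique() > 1:
        import warnings

        counts = dict(zip(out["scheme_id"], out["n_cells"]))
        warnings.warn(f"incomplete grid: per-scheme cell counts {counts}")
    return out


def select_optimal(summaries: pd.DataFrame, by: str = "mean_mse") -> str:
    """Scheme with the lowest average test MSE (ties: fewer median df)."""
    if len(summaries) == 0:
        raise ValueError("empty scheme summary")
    ordered = summaries.sort_values([by, "median_df", "scheme_id"])
    return str(ordered.iloc[0]["scheme_id"])


def select_parsimonious(summaries: pd.DataFrame, tolerance: float = 0.005,
                        by: str = "mean_mse") -> str:
    """Fewest-df scheme whose MSE is within ``tolerance`` (relative) of the best."""
    if tolerance < 0:
        raise ValueError("tolerance must be nonnegative")
    if len(summaries) == 0:
        raise ValueError("empty scheme summary")
    best = summaries[by].min()
    close = summaries.loc[summaries[by] <= (1.0 + tolerance) * best]
    ordered = close.sort_values(["median_df", by, "scheme_id"])
    return str(ordered.iloc[0]["scheme_id"])


def plot_mse_vs_df(summaries: pd.DataFrame, path, by: str = "median_mse",
                   max_df: float | None = None) -> None:
    """Scatter of per-scheme MSE against median degrees of freedom.

    Marks the minimum-MSE level, the optimal scheme and the parsimonious
    scheme, mirroring the usual overfitting-curve presentation.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    data = summaries if max_df is None \
        else summaries.loc[summaries["median_df"] <= max_df]
    opt = select_optimal(summaries)
    pars = select_parsimonious(summaries)
    fig, ax = plt.subplots(figsize=(7, 5))
    ax.scatter(data["median_df"], data[by], s=18, color="0.4")
    ax.axhline(summaries[by].min(), color="goldenrod", lw=1)
    for sid, color in ((opt, "goldenrod"), (pars, "tab:blue")):
        row = summaries.loc[summaries["scheme_id"] == sid]
        if len(row) and (max_df is None or row["median_df"].iloc[0] <= max_df):
            ax.scatter(row["median_df"], row[by], s=90, facecolors="none",
                       edgecolors=color, lw=2, label=sid)
    ax.set_xlabel("median degrees of freedom")
    ax.set_ylabel(by.replace("_", " "))
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
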