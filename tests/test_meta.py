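"""Tests of the MSE meta-regression, scheme summaries and selection."""

from itertools import product

import numpy as np
import pandas as pd
import pytest

from holclink import (
    enumerate_schemes,
    experiment_features,
    regress_mse_on_features,
    select_optimal,
    select_parsimonious,
    stratified_regressions,
    summarize_schemes,
    table3_columns,
)


def factorial_rows(include_u_effect=0.1, outcome_effects=None,
                   base=0.8) -> pd.DataFrame:
    """Fully crossed balanced synthetic grid of MSE cells."""
    outcome_effects = outcome_effects or {"o1": 0.0, "o2": 0.0}
    rows = []
    for r, s, u, (oc, eff), thr in product(
        (1, 2), ("set5", "set6"), (False, True),
        outcome_effects.items(), (1, 5),
    ):
        sid = f"set{s[-1]}_r{r}_{'withU' if u else 'noU'}"
        rows.append({
            "scheme_id": sid, "outcome_id": oc, "threshold": thr,
            "mse": base + include_u_effect * u + eff * (oc != "o1"),
            "df": 3, "n_tracts": 100,
        })
    return pd.DataFrame(rows)


class TestRegression:
    def test_planted_unrated_effect_recovered_exactly(self):
        rows = factorial_rows(include_u_effect=0.1)
        tab = regress_mse_on_features(rows, "include_u")
        assert tab.loc["include_u", "estimate"] == pytest.approx(0.1, abs=1e-12)
        assert tab.attrs["r_squared"] == pytest.approx(1.0, abs=1e-12)

    def test_balanced_factorial_univariate_equals_multivariate(self, rng):
        # orthogonality of balanced dummy designs: one-at-a-time
        # coefficients match the all-features regression
        rows = factorial_rows()
        rows["mse"] = rng.uniform(0.5, 1.0, len(rows))
        full = regress_mse_on_features(rows, "all")
        for feat in ("ratings", "set_cat", "include_u", "outcome", "threshold"):
            single = regress_mse_on_features(rows, feat)
            for name in single.index:
                if name == "const":
                    continue
                assert single.loc[name, "estimate"] == pytest.approx(
                    full.loc[name, "estimate"], abs=1e-8
                )

    def test_intercept_only_equals_mean_mse(self):
        rows = factorial_rows()
        tab = regress_mse_on_features(rows, [])
        assert tab.loc["const", "estimate"] == pytest.approx(
            rows["mse"].mean(), abs=1e-12
        )

    def test_residuals_orthogonal_to_design(self, sim_grid):
        tab = regress_mse_on_features(sim_grid, "all")
        resid = tab.attrs["residuals"]
        rows = experiment_features(sim_grid)
        for col in tab.attrs["design_columns"]:
            feat, _, lev = col.partition("[")
            if not lev:
                x = rows[col].astype(float).to_numpy()
            else:
                x = (rows[feat].astype(str) == lev.rstrip("]")).to_numpy(float)
            assert abs(resid @ x) < 1e-8 * len(resid)

    def test_reference_levels(self, sim_grid):
        tab = regress_mse_on_features(sim_grid, "all", outcome_ref="y1")
        # reference levels never appear as dummy columns
        for absent in ("ratings[2]", "set_cat[set6]", "threshold[5]",
                       "outcome[y1]"):
            assert absent not in tab.index

    def test_single_level_feature_rejected(self):
        rows = factorial_rows()
        rows["threshold"] = 5
        with pytest.raises(ValueError, match="threshold"):
            regress_mse_on_features(rows, "threshold")

    def test_six_table_layout(self, sim_grid):
        tabs = table3_columns(sim_grid)
        assert set(tabs) == {"ratings", "set_cat", "include_u", "outcome",
                             "threshold", "all"}
        assert all(t.attrs["n"] == len(sim_grid) for t in tabs.values())

    def test_unrated_and_detail_penalties_on_gradient_data(self, sim_grid):
        # synthetic gradient data reproduce the direction of the real
        # findings: including U hurts, and 10pp bins hurt vs rank order
        tab = regress_mse_on_features(sim_grid, "all", outcome_ref="y1")
        assert tab.loc["include_u", "estimate"] > 0
        assert tab.loc["set_cat[set1]", "estimate"] > 0
        assert tab.loc["ratings[1]", "estimate"] > 0
        assert tab.loc["ratings[5]", "estimate"] > 0


class TestStratified:
    def test_one_table_per_outcome(self):
        rows = factorial_rows()
        tabs = stratified_regressions(rows)
        assert set(tabs) == {"o1", "o2"}

    def test_homogeneous_effect_matches_pooled(self):
        rows = factorial_rows(include_u_effect=0.07)
        pooled = regress_mse_on_features(
            rows, ["ratings", "set_cat", "include_u", "threshold"]
        )
        for tab in stratified_regressions(rows).values():
            assert tab.loc["include_u", "estimate"] == pytest.approx(
                pooled.loc["include_u", "estimate"], abs=1e-10
            )

    def test_outcome_specific_effect_differs(self):
        rows = factorial_rows(include_u_effect=0.0)
        only_o1 = rows["include_u_flag"] = [
            ("withU" in s) and (o == "o1")
            for s, o in zip(rows["scheme_id"], rows["outcome_id"])
        ]
        rows["mse"] = 0.8 + 0.2 * np.asarray(only_o1, dtype=float)
        tabs = stratified_regressions(rows.drop(columns="include_u_flag"))
        assert tabs["o1"].loc["include_u", "estimate"] == pytest.approx(0.2)
        assert tabs["o2"].loc["include_u", "estimate"] == pytest.approx(0.0)

    def test_requires_two_outcomes(self):
        rows = factorial_rows()
        with pytest.raises(ValueError):
            stratified_regressions(rows.loc[rows["outcome_id"] == "o1"])


class TestSummaries:
    def test_every_scheme_aggregates_42_cells(self, sim_grid):
        summ = summarize_schemes(sim_grid)
        assert len(summ) == 54
        assert summ["n_cells"].eq(42).all()

    def test_single_cell_summary_equals_cell(self, sim_grid):
        one = sim_grid.iloc[[0]]
        summ = summarize_schemes(one)
        assert summ.iloc[0]["mean_mse"] == one.iloc[0]["mse"]
        assert summ.iloc[0]["median_df"] == one.iloc[0]["df"]

    def test_means_match_groupby_oracle(self, sim_grid):
        summ = summarize_schemes(sim_grid).set_index("scheme_id")
        # independent oracle: plain python accumulation
        acc: dict[str, list[float]] = {}
        for _, row in sim_grid.iterrows():
            acc.setdefault(row["scheme_id"], []).append(row["mse"])
        for sid, vals in acc.items():
            assert summ.loc[sid, "mean_mse"] == pytest.approx(
                sum(vals) / len(vals), abs=1e-12
            )

    def test_three_rating_rank_scheme_uses_39_df(self, sim_grid):
        # with every rank combination enforced in the synthetic universe,
        # the rank-ordered 3-rating scheme realizes all 40 classes
        summ = summarize_schemes(sim_grid).set_index("scheme_id")
        assert summ.loc["set6_r3_noU", "median_df"] == 39
        assert summ.loc["set6_r2_noU", "median_df"] == 15

    def test_incomplete_grid_warns(self, sim_grid):
        with pytest.warns(UserWarning, match="incomplete"):
            summarize_schemes(sim_grid.iloc[:60])


class TestSelection:
    def summaries(self, rows):
        return pd.DataFrame(rows, columns=["scheme_id", "mean_mse",
                                           "median_mse", "median_df"])

    def test_dominating_scheme_selected_by_both(self):
        summ = self.summaries([("best", 0.5, 0.5, 10), ("worse", 0.9, 0.9, 5)])
        assert select_optimal(summ) == "best"
        assert select_parsimonious(summ) == "best"

    def test_parsimony_tie_rule_prefers_fewer_df(self):
        summ = self.summaries([("big", 0.7, 0.7, 39), ("small", 0.7, 0.7, 15)])
        assert select_parsimonious(summ) == "small"

    def test_zero_tolerance_returns_optimal_or_smaller_equal(self):
        summ = self.summaries([("a", 0.70, 0.7, 39), ("b", 0.71, 0.7, 10)])
        assert select_parsimonious(summ, tolerance=0.0) == select_optimal(summ)

    def test_tolerance_admits_close_simpler_scheme(self):
        summ = self.summaries([("a", 0.700, 0.7, 39), ("b", 0.702, 0.7, 10)])
        assert select_parsimonious(summ, tolerance=0.005) == "b"

    def test_empty_summary_rejected(self):
        with pytest.raises(ValueError):
            select_optimal(self.summaries([]))

    def test_gradient_data_select_rank_ordered_two_to_three(self, sim_grid):
        summ = summarize_schemes(sim_grid)
        for sid in (select_optimal(summ), select_parsimonious(summ)):
            assert sid.startswith("set6_r")
            assert sid[6] in "23"


def test_plot_writes_file(tmp_path, sim_grid):
    from holclink.meta import plot_mse_vs_df

    summ = summarize_schemes(sim_grid)
    path = tmp_path / "fig.png"
    plot_mse_vs_df(summ, path, max_df=100)
    assert path.stat().st_size > 0
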