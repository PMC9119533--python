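"""Tests of scheme enumeration, binning, rebasing and label assignment."""

from itertools import permutations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from conftest import coverage_frame
from holclink import (
    Scheme,
    assign_label,
    bin_percentage,
    enumerate_feasible_labels,
    enumerate_schemes,
    label_table,
    rebase_excluding_unrated,
)


class TestEnumerateSchemes:
    def test_total_count_is_54(self):
        assert len(enumerate_schemes()) == 54

    def test_no_duplicates_and_no_five_rating_without_unrated(self):
        schemes = enumerate_schemes()
        assert len(set(schemes)) == 54
        assert not [s for s in schemes
                    if not s.include_unrated and s.n_ratings == 5]

    def test_nine_schemes_per_set(self):
        schemes = enumerate_schemes()
        for set_id in range(1, 7):
            assert len([s for s in schemes if s.set_id == set_id]) == 9

    def test_scheme_id_roundtrip(self):
        for s in enumerate_schemes():
            assert Scheme.from_id(s.scheme_id) == s

    def test_invalid_schemes_rejected(self):
        with pytest.raises(ValueError):
            Scheme(7, 1, False)
        with pytest.raises(ValueError):
            Scheme(1, 5, False)


class TestBinPercentage:
    @pytest.mark.parametrize(
        "pct,set_id,expected",
        [
            (75, 1, 8),      # 70-80% coverage is the 8th 10pp bin
            (100, 5, 2),     # top bin closed at 100
            (33.3, 4, 2),    # printed boundary belongs to the upper bin
            (0, 1, 1),
            (10, 1, 2),      # half-open: 10 belongs upward
            (19.9, 2, 1),
            (25, 3, 2),
            (49.9, 5, 1),
            (50, 5, 2),
            (66.6, 4, 3),
            (100, 1, 10),
        ],
    )
    def test_examples(self, pct, set_id, expected):
        assert bin_percentage(pct, set_id) == expected

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bin_percentage(-2, 1)
        with pytest.raises(ValueError):
            bin_percentage(100.5, 1)
        with pytest.raises(ValueError):
            bin_percentage(50, 6)

    @settings(derandomize=True, max_examples=200)
    @given(pct=st.floats(0, 100), set_id=st.integers(1, 5))
    def test_bin_always_in_range(self, pct, set_id):
        from holclink.schemes import BIN_COUNTS

        assert 1 <= bin_percentage(pct, set_id) <= BIN_COUNTS[set_id]


class TestRebase:
    @pytest.mark.parametrize(
        "row,expected",
        [
            ((50, 0, 0, 0, 50), (100, 0, 0, 0, 0)),
            ((0, 30, 0, 30, 40), (0, 50, 0, 50, 0)),
            ((10, 20, 30, 20, 20), (12.5, 25, 37.5, 25, 0)),
        ],
    )
    def test_examples(self, row, expected):
        cov = coverage_frame({"t": row})
        got = rebase_excluding_unrated(cov).iloc[0]
        for col, want in zip(("pct_a", "pct_b", "pct_c", "pct_d", "pct_u"),
                             expected):
            assert got[col] == pytest.approx(want, abs=1e-9)

    def test_fully_unrated_cannot_rebase(self):
        cov = coverage_frame({"t": (0, 0, 0, 0, 100)})
        with pytest.raises(ValueError, match="rebase"):
            rebase_excluding_unrated(cov)

    def test_sum_conserved(self, sim_coverages):
        reb = rebase_excluding_unrated(sim_coverages)
        assert np.allclose(reb.iloc[:, 1:].sum(axis=1), 100.0, atol=1e-9)
        assert (reb["pct_u"] == 0).all()


class TestAssignLabel:
    def test_single_grade_rank_label(self):
        cov = coverage_frame({"t": (100, 0, 0, 0, 0)}).iloc[0]
        assert assign_label(cov, Scheme(6, 2, False)) == "A"

    def test_narrative_mainly_d_some_b(self):
        # a tract 84% D / 19% B by raw area maps, after rebasing, to D-B
        raw = coverage_frame({"t": (0, 19 / 103 * 100, 0, 84 / 103 * 100, 0)})
        assert assign_label(raw.iloc[0], Scheme(6, 2, False)) == "D-B"

    def test_unrated_can_lead_the_label(self):
        cov = coverage_frame({"t": (0, 0, 47, 0, 53)}).iloc[0]
        assert assign_label(cov, Scheme(6, 2, True)) == "U-C"

    def test_binned_label_with_bin_indices(self):
        cov = coverage_frame({"t": (75, 25, 0, 0, 0)}).iloc[0]
        assert assign_label(cov, Scheme(1, 2, False)) == "A8-B3"
        assert assign_label(cov, Scheme(1, 2, False), zero_based=True) == "A7-B2"

    def test_exact_ties_broken_worst_grade_first(self):
        cov = coverage_frame({"t": (0, 50, 0, 50, 0)}).iloc[0]
        assert assign_label(cov, Scheme(6, 2, False)) == "D-B"
        cov2 = coverage_frame({"t": (25, 25, 25, 25, 0)}).iloc[0]
        assert assign_label(cov2, Scheme(6, 4, False)) == "D-C-B-A"

    def test_no_positive_coverage_errors(self):
        cov = coverage_frame({"t": (0, 0, 0, 0, 100)}).iloc[0]
        cov = cov.copy()
        cov["pct_u"] = 0.0
        with pytest.raises(ValueError):
            assign_label(cov, Scheme(6, 1, True))

    def test_shorter_labels_when_fewer_grades_present(self):
        cov = coverage_frame({"t": (0, 0, 100, 0, 0)}).iloc[0]
        assert assign_label(cov, Scheme(6, 4, False)) == "C"


class TestLabelTable:
    @pytest.mark.parametrize("scheme", [
        Scheme(6, 2, False), Scheme(6, 3, False), Scheme(1, 2, False),
        Scheme(5, 2, True), Scheme(6, 5, True), Scheme(4, 3, True),
    ], ids=lambda s: s.scheme_id)
    def test_vectorized_labels_match_rowwise_oracle(self, sim_coverages, scheme):
        sub = sim_coverages.head(300)
        got = label_table(sub, scheme)
        base = rebase_excluding_unrated(sub) if not scheme.include_unrated else sub
        want = [assign_label(row, scheme) for _, row in base.iterrows()]
        assert got.tolist() == want

    def test_truncation_refines(self, sim_coverages):
        # tracts sharing a (k+1)-rating label always share the k-rating label
        for k in (1, 2, 3):
            fine = label_table(sim_coverages, Scheme(6, k + 1, False))
            coarse = label_table(sim_coverages, Scheme(6, k, False))
            mapping = pd.DataFrame({"fine": fine, "coarse": coarse})
            assert (mapping.groupby("fine")["coarse"].nunique() == 1).all()

    @pytest.mark.parametrize("scheme", [
        Scheme(6, 2, False), Scheme(6, 4, False), Scheme(6, 3, True),
        Scheme(1, 2, False), Scheme(3, 2, True), Scheme(5, 3, False),
    ], ids=lambda s: s.scheme_id)
    def test_assigned_labels_are_feasible(self, sim_coverages, scheme):
        feasible = set(enumerate_feasible_labels(scheme))
        got = set(label_table(sim_coverages, scheme))
        assert got <= feasible


class TestFeasibleLabels:
    def test_rank_ordered_counts_match_permutation_oracle(self):
        # independent brute-force oracle: sum over m of 4!/(4-m)!
        for n_ratings, want in ((1, 4), (2, 16), (3, 40), (4, 64)):
            oracle = sum(
                len(list(permutations("ABCD", m)))
                for m in range(1, n_ratings + 1)
            )
            labels = enumerate_feasible_labels(Scheme(6, n_ratings, False))
            assert len(labels) == len(set(labels)) == want == oracle

    def test_rank_ordered_with_unrated_counts(self):
        # all arrangements over 5 grades minus the impossible "only U"
        # completion for schemes considering 2+ ratings
        assert len(enumerate_feasible_labels(Scheme(6, 1, True))) == 5
        assert len(enumerate_feasible_labels(Scheme(6, 2, True))) == 24
        assert len(enumerate_feasible_labels(Scheme(6, 3, True))) == 84

    def test_single_rating_binned_counts(self):
        # one-rating binned labels: the largest grade's share must admit
        # a composition; e.g. set 5 (50pp bins): four grades x 2 bins
        labels = enumerate_feasible_labels(Scheme(5, 1, False))
        assert set(labels) == {f"{g}{b}" for g in "ABCD" for b in (1, 2)}

    def test_dominant_share_bin_constraint(self):
        # a 1-rating set-1 label like "A1" (largest share < 10%) is
        # infeasible without U: four grades cannot each stay under 10%
        labels = set(enumerate_feasible_labels(Scheme(1, 1, False)))
        assert "A1" not in labels
        assert "A3" in labels  # 4 grades can sum to 100 with max in [20,30)
        assert "A10" in labels

    def test_zero_based_rendering(self):
        labels = enumerate_feasible_labels(Scheme(5, 1, False), zero_based=True)
        assert set(labels) == {f"{g}{b}" for g in "ABCD" for b in (0, 1)}
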