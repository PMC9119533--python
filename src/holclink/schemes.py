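"""Enumeration of candidate tract classification schemes and label assignment.

A *scheme* turns a tract's coverage composition over {A, B, C, D, U} into
a categorical class label. Schemes vary along three design axes:

* **set** — how much of the coverage percentage is preserved. Sets 1-5
  coarsen each grade's percentage into bins of width 10, 20, 25, 33.3 and
  50 percentage points respectively; set 6 keeps only the *rank order* of
  the grades by covered area.
* **number of ratings** — how many of the most important (largest-area)
  grades the label lists: 1 to 4 when unrated area is excluded, 1 to 5
  when unrated area participates as a pseudo-grade.
* **unrated handling** — whether U is a grade in its own right, or the
  composition is rebased to the rated-area denominator and U discarded.

Six sets x (4 + 5) rating counts = 54 schemes in total.

Labels are compact strings: ``"C-B"`` (set 6: mainly C, some B) or
``"A8-B3"`` (set 1: 70-80% A, 20-30% B). Grades with exactly zero
coverage never appear; within a label, coverage strictly decreases, with
exact ties broken worst grade first (D, C, B, A, U).
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass
from itertools import combinations_with_replacement, permutations

import numpy as np
import pandas as pd

from .synthetic import ALL_GRADES, RATED_GRADES

#: bins per set, following the set numbering of the scheme taxonomy
#: (set 1 = 10pp bins ... set 5 = 50pp bins, set 6 = rank-ordered)
BIN_COUNTS: dict[int, int] = {1: 10, 2: 5, 3: 4, 4: 3, 5: 2}

#: bin edges per binned set; the top bin is closed at 100. Set 4 uses the
#: printed 33.3 / 66.6 boundaries (a percentage of exactly 33.3 falls in
#: the middle bin).
BIN_EDGES: dict[int, tuple[float, ...]] = {
    1: tuple(float(x) for x in range(0, 101, 10)),
    2: (0.0, 20.0, 40.0, 60.0, 80.0, 100.0),
    3: (0.0, 25.0, 50.0, 75.0, 100.0),
    4: (0.0, 33.3, 66.6, 100.0),
    5: (0.0, 50.0, 100.0),
}

#: worst-first order used to break exact coverage ties deterministically
TIE_ORDER: tuple[str, ...] = ("D", "C", "B", "A", "U")

_PCT_COLS = {g: f"pct_{g.lower()}" for g in ALL_GRADES}


@dataclass(frozen=True, order=True)
class Scheme:
    """One classification recipe: (set, number of ratings, U handling)."""

    set_id: int
    n_ratings: int
    include_unrated: bool

    def __post_init__(self) -> None:
        if self.set_id not in range(1, 7):
            raise ValueError("set_id must be 1..6")
        max_r = 5 if self.include_unrated else 4
        if not 1 <= self.n_ratings <= max_r:
            raise ValueError(
                f"n_ratings must be 1..{max_r} when include_unrated="
                f"{self.include_unrated}"
            )

    @property
    def binned(self) -> bool:
        return self.set_id != 6

    @property
    def scheme_id(self) -> str:
        u = "withU" if self.include_unrated else "noU"
        return f"set{self.set_id}_r{self.n_ratings}_{u}"

    @classmethod
    def from_id(cls, scheme_id: str) -> "Scheme":
        try:
            s, r, u = scheme_id.split("_")
            return cls(int(s[3:]), int(r[1:]), {"withU": True, "noU": False}[u])
        except Exception as exc:
            raise ValueError(f"malformed scheme id {scheme_id!r}") from exc


def enumerate_schemes() -> list[Scheme]:
    """All 54 schemes: 6 sets x (4 without U + 5 with U rating counts)."""
    out = []
    for set_id in range(1, 7):
        for include_u in (False, True):
            for r in range(1, (5 if include_u else 4) + 1):
                out.append(Scheme(set_id, r, include_u))
    return out


def bin_percentage(pct: float, set_id: int) -> int:
    """1-based coverage bin of ``pct`` under a binned set.

    Bins are half-open ``[lo, hi)`` except the top bin, which is closed
    at 100.
    """
    if set_id not in BIN_EDGES:
        raise ValueError(f"set {set_id} is not a binned set")
    if not -1e-6 <= pct <= 100.0 + 1e-6:
        raise ValueError(f"percentage {pct} outside [0, 100]")
    pct = min(max(pct, 0.0), 100.0)
    edges = BIN_EDGES[set_id]
    return min(bisect_right(edges, pct), BIN_COUNTS[set_id])


def rebase_excluding_unrated(cov):
    """Re-express rated coverages relative to the rated-area denominator.

    Accepts a coverage data frame or a single row (Series/mapping);
    returns the same shape with ``pct_u`` zero and the rated percentages
    scaled by ``100 / (100 - pct_u)``. Fully unrated rows cannot be
    rebased and raise.
    """
    if isinstance(cov, pd.DataFrame):
        rated = 100.0 - cov["pct_u"].to_numpy()
        if np.any(rated <= 0.0):
            bad = cov.loc[rated <= 0.0, "tract_id"].tolist()
            raise ValueError(f"cannot rebase fully unrated tracts: {bad}")
        out = cov.copy()
        for g in RATED_GRADES:
            col = _PCT_COLS[g]
            out[col] = cov[col].to_numpy() * (100.0 / rated)
        out["pct_u"] = 0.0
        return out
    row = dict(cov)
    rated = 100.0 - row["pct_u"]
    if rated <= 0.0:
        raise ValueError("cannot rebase a fully unrated tract")
    out_row = dict(row)
    for g in RATED_GRADES:
        out_row[_PCT_COLS[g]] = row[_PCT_COLS[g]] * (100.0 / rated)
    out_row["pct_u"] = 0.0
    return out_row


def _ordered_candidates(cov, include_unrated: bool) -> list[tuple[str, float]]:
    grades = ALL_GRADES if include_unrated else RATED_GRADES
    cand = [(g, float(cov[_PCT_COLS[g]])) for g in grades
            if float(cov[_PCT_COLS[g]]) > 0.0]
    cand.sort(key=lambda gp: (-gp[1], TIE_ORDER.index(gp[0])))
    return cand


def _render(parts: list[tuple[str, float]], scheme: Scheme,
            zero_based: bool) -> str:
    if scheme.binned:
        off = 1 if zero_based else 0
        return "-".join(
            f"{g}{bin_percentage(p, scheme.set_id) - off}" for g, p in parts
        )
    return "-".join(g for g, _ in parts)


def assign_label(cov, scheme: Scheme, *, zero_based: bool = False) -> str:
    """Class label of one tract under one scheme.

    ``cov`` is a coverage row (Series or mapping). When the scheme
    excludes unrated area the row must already be rebased (see
    :func:`rebase_excluding_unrated`); :func:`label_table` does this
    automatically for whole tables. ``zero_based`` renders bin indices
    starting at 0 instead of 1, for comparability with sources that label
    the first bin 0.
    """
    cand = _ordered_candidates(cov, scheme.include_unrated)
    if not cand:
        raise ValueError("no grade with positive coverage; cannot label tract")
    return _render(cand[: scheme.n_ratings], scheme, zero_based)


def label_table(coverages: pd.DataFrame, scheme: Scheme, *,
                auto_rebase: bool = True,
                zero_based: bool = False) -> pd.Series:
    """Vectorized labels for a whole coverage table under one scheme.

    When the scheme excludes unrated area and ``auto_rebase`` is true the
    table is rebased to the rated-area denominator first (both the rank
    order and the binned percentage then refer to the rebased values).
    """
    df = coverages
    if not scheme.include_unrated and auto_rebase:
        df = rebase_excluding_unrated(df)
    grades = ALL_GRADES if scheme.include_unrated else RATED_GRADES
    # columns arranged worst-first so a stable sort breaks ties that way
    order_grades = [g for g in TIE_ORDER if g in grades]
    P = df[[_PCT_COLS[g] for g in order_grades]].to_numpy()
    order = np.argsort(-P, axis=1, kind="stable")
    if np.any(P.sum(axis=1) <= 0.0):
        bad = df.loc[P.sum(axis=1) <= 0.0, "tract_id"].tolist()
        raise ValueError(f"no grade with positive coverage for tracts: {bad}")
    labels = []
    n_r = scheme.n_ratings
    off = 1 if zero_based else 0
    for i in range(P.shape[0]):
        parts = []
        for j in order[i]:
            p = P[i, j]
            if p <= 0.0 or len(parts) == n_r:
                break
            g = order_grades[j]
            if scheme.binned:
                parts.append(f"{g}{bin_percentage(p, scheme.set_id) - off}")
            else:
                parts.append(g)
        labels.append("-".join(parts))
    return pd.Series(labels, index=coverages.index, name=scheme.scheme_id)


# ---------------------------------------------------------------------------
# feasible-label enumeration


def _grade_pool(scheme: Scheme) -> tuple[str, ...]:
    return ALL_GRADES if scheme.include_unrated else RATED_GRADES


def _rank_label_feasible(combo: tuple[str, ...], scheme: Scheme) -> bool:
    # A label shorter than n_ratings lists *all* grades with positive
    # coverage, so it must contain at least one rated grade (tracts are
    # never 100% unrated). A label of full length is a truncation and can
    # always be extended with rated mass.
    if len(combo) < scheme.n_ratings and not any(g in RATED_GRADES for g in combo):
        return False
    return True


def _binned_label_feasible(combo: tuple[str, ...], bins: tuple[int, ...],
                           scheme: Scheme, eps: float = 1e-9) -> bool:
    """Existence of a composition realizing the binned label.

    Checks for percentages p_1 > ... > p_m, each inside its bin, whose
    sum plus the mass of hidden (truncated) grades — each strictly
    smaller than p_m — equals 100. Uses the componentwise extremes of the
    order-constrained box, which bound every monotone functional of the
    composition.
    """
    edges = BIN_EDGES[scheme.set_id]
    n_bins = BIN_COUNTS[scheme.set_id]
    m = len(combo)
    lo = [max(edges[b - 1], eps) for b in bins]
    hi = [edges[b] if b == n_bins else edges[b] - eps for b in bins]
    # componentwise maximum subject to strict decrease
    M = [0.0] * m
    for i in range(m):
        M[i] = hi[i] if i == 0 else min(hi[i], M[i - 1] - eps)
        if M[i] < lo[i]:
            return False
    # componentwise minimum subject to strict decrease
    mn = [0.0] * m
    for i in reversed(range(m)):
        mn[i] = lo[i] if i == m - 1 else max(lo[i], mn[i + 1] + eps)
        if mn[i] > hi[i]:
            return False
    pool = len(_grade_pool(scheme))
    k_rem = pool - m if m == scheme.n_ratings else 0
    has_rated = any(g in RATED_GRADES for g in combo)
    if not has_rated:
        if k_rem == 0:
            return False  # rated mass must exist somewhere
        if sum(mn) >= 100.0 - eps:
            return False  # no room left for rated mass
    if sum(mn) > 100.0 + 1e-12:
        return False
    return sum(M) + k_rem * max(M[m - 1] - eps, 0.0) >= 100.0 - 1e-12


def enumerate_feasible_labels(scheme: Scheme, *,
                              zero_based: bool = False) -> list[str]:
    """All class labels a scheme can assign to some valid composition.

    For the rank-ordered set this is the ordered arrangements of distinct
    grades up to the scheme's rating count, minus arrangements shorter
    than the rating count that contain no rated grade (a tract always has
    rated coverage). For binned sets, candidate (grade, bin) strings are
    kept when a composition summing to 100 with strictly decreasing
    shares realizes them.
    """
    pool = _grade_pool(scheme)
    out: list[str] = []
    off = 1 if zero_based else 0
    for m in range(1, min(scheme.n_ratings, len(pool)) + 1):
        for combo in permutations(pool, m):
            if not _rank_label_feasible(combo, scheme):
                continue
            if not scheme.binned:
                out.append("-".join(combo))
                continue
            n_bins = BIN_COUNTS[scheme.set_id]
            # strictly decreasing percentages force non-increasing bins
            for rev_bins in combinations_with_replacement(range(1, n_bins + 1), m):
                bins = tuple(reversed(rev_bins))
                if _binned_label_feasible(combo, bins, scheme):
                    out.append(
                        "-".join(f"{g}{b - off}" for g, b in zip(combo, bins))
                    )
    return out
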