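"""Collapsing the detailed two-rating classification and class profiles.

The rank-ordered two-rating classification (unrated excluded) has 16
classes. For applied research a coarser partition is easier to use, so
small classes with similar average outcome levels are merged into a fixed
10-class scheme: the four mainly-A classes become one; mainly-C-or-D
classes sharing a secondary A (or B) rating are pooled; and the two
mainly-B classes with a worse secondary rating are pooled. The remaining
classes map to themselves.

Per-class descriptives use a composite outcome: each outcome is
standardized, "bad" outcomes are sign-flipped so higher always means
better, and the tract-wise mean across outcomes is taken. Averaging is
justified when the outcome battery is internally consistent, measured by
Cronbach's alpha.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: fixed 16 -> 10 merge table for the rank-ordered two-rating labels
COLLAPSE_MAP: dict[str, str] = {
    "A": "Only or mainly A",
    "A-B": "Only or mainly A",
    "A-C": "Only or mainly A",
    "A-D": "Only or mainly A",
    "B": "Only B",
    "B-A": "Mainly B, some A",
    "B-C": "Mainly B, some C or D",
    "B-D": "Mainly B, some C or D",
    "C": "Only C",
    "C-A": "Mainly C or D, some A",
    "C-B": "Mainly C or D, some B",
    "C-D": "Mainly C, some D",
    "D": "Only D",
    "D-A": "Mainly C or D, some A",
    "D-B": "Mainly C or D, some B",
    "D-C": "Mainly D, some C",
}

#: canonical presentation order of the 16 detailed classes
DETAILED_ORDER: tuple[str, ...] = (
    "A", "A-B", "A-C", "A-D",
    "B", "B-A", "B-C", "B-D",
    "C", "C-A", "C-B", "C-D",
    "D", "D-A", "D-B", "D-C",
)

#: canonical presentation order of the 10 collapsed classes
COLLAPSED_ORDER: tuple[str, ...] = (
    "Only or mainly A",
    "Only B",
    "Mainly B, some A",
    "Mainly B, some C or D",
    "Only C",
    "Mainly C, some D",
    "Only D",
    "Mainly D, some C",
    "Mainly C or D, some A",
    "Mainly C or D, some B",
)


def collapse_labels(labels16) -> pd.Series:
    """Map detailed two-rating labels onto the 10 collapsed classes."""
    s = pd.Series(labels16)
    unknown = sorted(set(s.unique()) - set(COLLAPSE_MAP))
    if unknown:
        raise ValueError(
            f"labels not in the detailed two-rating classification: {unknown}"
        )
    return s.map(COLLAPSE_MAP).rename("collapsed")


def composite_outcome(outcome_matrix: pd.DataFrame,
                      sign_flips: Iterable[int] = ()) -> pd.DataFrame:
    """Tract-wise mean of sign-aligned standardized outcomes.

    ``outcome_matrix`` holds z-scored outcomes (columns other than an
    optional ``tract_id`` column). Columns at the 0-based positions in
    ``sign_flips`` are multiplied by -1 so that higher always means
    better. Missing cells are averaged over the available outcomes; the
    returned frame carries a ``n_outcomes`` count column alongside
    ``composite``.
    """
    cols = [c for c in outcome_matrix.columns if c != "tract_id"]
    flips = set(sign_flips)
    bad = [j for j in flips if not 0 <= j < len(cols)]
    if bad:
        raise ValueError(f"sign_flips indices out of range: {bad}")
    signs = np.array([-1.0 if j in flips else 1.0 for j in range(len(cols))])
    Z = outcome_matrix[cols].to_numpy(dtype=float) * signs
    counts = np.sum(~np.isnan(Z), axis=1)
    if np.any(counts == 0):
        raise ValueError("tracts with no non-missing outcome")
    comp = np.nanmean(Z, axis=1)
    out = pd.DataFrame(
        {"composite": comp, "n_outcomes": counts}, index=outcome_matrix.index
    )
    if "tract_id" in outcome_matrix.columns:
        out.insert(0, "tract_id", outcome_matrix["tract_id"].to_numpy())
    return out


def cronbach_alpha(outcome_matrix: pd.DataFrame) -> float:
    """Cronbach's alpha of a sign-aligned outcome battery.

    alpha = K/(K-1) * (1 - sum of item variances / variance of row sums),
    with n-1 variance denominators. Requires at least two items and three
    complete rows.
    """
    cols = [c for c in outcome_matrix.columns if c != "tract_id"]
    X = outcome_matrix[cols].to_numpy(dtype=float)
    X = X[~np.isnan(X).any(axis=1)]
    K = X.shape[1]
    if K < 2:
        raise ValueError("Cronbach's alpha needs at least two items")
    if X.shape[0] < 3:
        raise ValueError("Cronbach's alpha needs at least three complete rows")
    total_var = X.sum(axis=1).var(ddof=1)
    if total_var <= 0:
        raise ValueError("zero total variance; alpha undefined")
    item_var = X.var(axis=0, ddof=1).sum()
    return float(K / (K - 1) * (1.0 - item_var / total_var))


def class_profile(labels, composite, class_order: Sequence[str] | None = None
                  ) -> pd.DataFrame:
    """Per-class tract counts and mean composite outcome.

    ``labels`` and ``composite`` are aligned; ``class_order`` fixes the
    presentation order (defaults to the canonical detailed/collapsed
    orders where applicable, otherwise alphabetical). Unlisted classes
    are appended alphabetically.
    """
    s = pd.Series(np.asarray(labels), name="class_label")
    comp = np.asarray(composite, dtype=float)
    prof = (
        pd.DataFrame({"class_label": s, "composite": comp})
        .groupby("class_label", sort=True)
        .agg(n_tracts=("composite", "size"), mean_composite=("composite", "mean"))
        .reset_index()
    )
    if class_order is None:
        present = set(prof["class_label"])
        for order in (DETAILED_ORDER, COLLAPSED_ORDER):
            if present <= set(order):
                class_order = order
                break
    if class_order is not None:
        rank = {c: i for i, c in enumerate(class_order)}
        prof["_rank"] = prof["class_label"].map(lambda x: rank.get(x, len(rank)))
        prof = (prof.sort_values(["_rank", "class_label"])
                .drop(columns="_rank").reset_index(drop=True))
    return prof
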