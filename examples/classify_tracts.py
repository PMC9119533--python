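"""Assign tract class labels under several classification schemes.

A scheme is (set, number of ratings, unrated handling): sets 1-5 bin the
coverage percentages at different widths, set 6 keeps only the rank
order of grades by covered area.
"""

from holclink import (
    Scheme,
    SyntheticConfig,
    enumerate_feasible_labels,
    enumerate_schemes,
    generate_coverages,
    label_table,
)

coverages = generate_coverages(SyntheticConfig(n_tracts=1500, seed=7))
print(f"{len(enumerate_schemes())} candidate schemes in the search space")

for scheme in (Scheme(6, 1, False), Scheme(6, 2, False),
               Scheme(1, 2, False), Scheme(6, 2, True)):
    labels = label_table(coverages, scheme)
    feasible = len(enumerate_feasible_labels(scheme))
    print(f"{scheme.scheme_id:>14}: {labels.nunique():4d} observed classes "
          f"({feasible} feasible); e.g. {labels.iloc[130]!r}")
# Rank-ordered labels like 'C-B' read "mainly C, some B"; binned labels
# like 'A8-B3' add coverage-bin detail (70-80% A, 20-30% B). More detail
# means more classes — and, downstream, more risk of overfitting.
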