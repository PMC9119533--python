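"""Area-weighted overlay of graded polygons onto tracts.

Uses the built-in rectangular fixture whose overlap areas are known
analytically, computes per-tract grade coverage percentages, and shows
the centroid-assignment baseline used by earlier studies.
"""

from holclink import centroid_grade, compute_coverage, generate_polygon_fixture

tracts, holc = generate_polygon_fixture()
coverage = compute_coverage(tracts, holc)
print(coverage.round(1).to_string(index=False))
print()
print("centroid grades:", centroid_grade(tracts, holc))
# T3 is 40% D + 25% B + 35% unrated, yet its interior point lies in
# unrated space, so centroid assignment returns None for it — one way the
# centroid shortcut loses information the coverage composition keeps.
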