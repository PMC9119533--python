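"""Run the whole analysis end to end and inspect the summary.

Simulates a tract universe, scores all 54 schemes by cross-validation,
selects optimal and parsimonious schemes, collapses the two-rating
classification, and validates against held-out outcomes. All tables land
in the output directory.
"""

import json

from holclink import PipelineConfig, run_pipeline

config = PipelineConfig(
    out_dir="pipeline_out",
    seed=7,
    n_tracts=1500,
    n_outcomes=9,        # 6 for cross-validation, 3 held out
    sign_flips=(1, 2),   # two "bad" outcomes (higher = worse)
)
summary = run_pipeline(config)
print(json.dumps(summary, indent=2, sort_keys=True))
# Expect: 54 schemes, 2,268 CV cells (42 per scheme), a rank-ordered
# two-to-three-rating scheme selected, 16 detailed classes collapsed to
# 10, and the collapsed scheme retaining ~90% of the optimal scheme's
# average held-out R².
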