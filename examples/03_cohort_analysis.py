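"""A two-group cohort recovery experiment in miniature.

Simulates 20 direct-strategy and 20 stacker-strategy participants,
computes per-participant metrics with the full pipeline and runs the
nonparametric cohort battery (Wilcoxon contrasts, Spearman age
correlations).
"""

import pandas as pd

from playnet import analyze_cohort, default_zone_map, metrics_table, simulate_cohort
from playnet.simulate import recovery_cohort_spec

pd.set_option("display.width", 120)

zm = default_zone_map()
manifest, logs = simulate_cohort(recovery_cohort_spec(seed=3, n_per_group=20), zm)
table = metrics_table(manifest, logs, zm)

print(table.groupby("group")[["n_food_delivery", "n_inter_plate",
                              "direct_score", "score_difference"]].median())

results = analyze_cohort(
    table,
    contrasts=[("direct", "stacker")],
    correlates=["n_inter_plate", "direct_score", "score_difference"],
)
print("\n", results[["contrast_or_group", "metric", "median1", "median2",
                     "stat", "p", "method"]].to_string(index=False))
print(
    "\nThe stacker group shows more inter-plate swipes, a lower direct\n"
    "sharing score and a higher sharing-score difference; the Wilcoxon\n"
    "rows quantify those contrasts, the Spearman rows the age trends\n"
    "(flat here, since neither group's strategy depends on age)."
)
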