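"""Blank-based significance filtering of full-scan features.

Builds a tiny feature table (three treatment replicates, three blanks),
applies the four-criterion filter — presence in >= 50% of replicates,
S/N >= 3, fold-change > 2, t-test p < 0.05 — and prints the per-feature
diagnostics, including the volcano-plot coordinates.
"""

import pandas as pd

from phasemet import FeatureTable, filter_significant

features = pd.DataFrame(
    {"mz": [153.0546, 204.1053, 300.1000], "rt": [5.75, 6.42, 3.00]},
    index=pd.Index(["metab_1", "metab_2", "background"], name="id"),
)
intensities = pd.DataFrame(
    {
        "rep_1": [98_000.0, 52_000.0, 1_100.0],
        "rep_2": [105_000.0, 47_000.0, 1_050.0],
        "rep_3": [92_000.0, 55_000.0, 980.0],
        "blank_1": [150.0, 0.0, 1_020.0],
        "blank_2": [180.0, 0.0, 1_000.0],
        "blank_3": [140.0, 0.0, 1_080.0],
    },
    index=features.index,
)

survivors, diagnostics = filter_significant(FeatureTable(features, intensities))
cols = ["fold_change", "p_value", "log2_fold_change", "neg_log10_p", "failed_criterion"]
print(diagnostics[cols].round(4))
print("\nsignificant features:", survivors)
# The two planted metabolites pass all four rules; the background feature
# sits at blank level, fails the fold-change rule and is excluded.
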