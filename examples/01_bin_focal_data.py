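"""Convert raw focal-observation amounts into ordered levels.

Builds a small focal table with one zero-inflated event behavior (counts)
and one activity behavior (duration proportions), derives quantile cutpoints
from the data, and bins.  The printed scheme shows the zero-inflated count
behavior collapsing to three levels encoding 0, 1 and >1 occurrences, while
the continuous activity keeps the full seven quantile levels.
"""

import numpy as np

from behavstate import BinningScheme, Ethogram, FocalTable, bin_dataset

rng = np.random.default_rng(0)
n = 400
ethogram = Ethogram((("threat", "event"), ("rest", "activity")))
table = FocalTable(
    animal_id=np.array([f"A{i % 20}" for i in range(n)], dtype=object),
    focal_id=np.array([f"f{i}" for i in range(n)], dtype=object),
    amounts=np.column_stack(
        [
            # ~70% zeros, occasionally 1, rarely more: a typical rare behavior
            rng.choice([0, 0, 0, 0, 0, 0, 0, 1, 1, 3], size=n).astype(float),
            rng.beta(2, 3, size=n),  # proportion of the focal spent resting
        ]
    ),
    ethogram=ethogram,
)

scheme = BinningScheme.from_table(table)
binned = bin_dataset(table, scheme)

for name in ethogram.names:
    print(f"{name}: cutpoints {scheme.cutpoints[name]} -> {scheme.n_levels(name)} levels")
print("level counts (threat):", binned.level_counts[0])
print("level counts (rest):  ", binned.level_counts[1])
# threat levels read: 1 = no occurrence, 2 = exactly one, 3 = more than one;
# rest levels are ordered amount bins between the 1st and 99th percentiles.
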