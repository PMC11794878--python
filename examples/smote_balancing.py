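"""Balance an imbalanced dataset with SMOTE and inspect the synthetic rows.

The minority class (212 of 569 samples here) is oversampled to the majority
count by interpolating between each chosen minority sample and one of its
k nearest minority neighbors; original rows are preserved unchanged.
"""

import numpy as np

from acrfs import SyntheticSpec, check_balance, generate_dataset, smote_balance

dataset, _ = generate_dataset(SyntheticSpec(seed=3))
print("class counts before:", check_balance(dataset))

balanced = smote_balance(dataset, k_neighbors=5, seed=3)
print("class counts after: ", check_balance(balanced.dataset))
print("synthetic rows generated:", int(balanced.synthetic_mask.sum()))

minority = dataset.features[dataset.labels == 1]
synthetic = balanced.dataset.features[balanced.synthetic_mask]
inside = (
    (synthetic >= minority.min(axis=0) - 1e-12)
    & (synthetic <= minority.max(axis=0) + 1e-12)
).all()
print("all synthetic values inside the minority bounding box:", bool(inside))
print(
    "\nEach synthetic row is a convex combination x + u*(x' - x) of a minority "
    "sample and a near neighbor, so no value can leave the minority envelope."
)
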