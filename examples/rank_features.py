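"""Rank features of a synthetic diagnostic dataset with all three solvers.

Generates a 569-sample, 30-feature dataset with planted relevance tiers,
scores every feature with mutual information, chi-square, and Pearson
correlation, and prints the aggregated finalized ranking.  Features whose
names end in `_primary` were planted with a strong class effect and should
dominate the top of the table.
"""

from acrfs import RunConfig, SyntheticSpec, acrfs_rank, generate_dataset

dataset, truth = generate_dataset(SyntheticSpec(seed=42))
ranking = acrfs_rank(dataset, RunConfig(seed=42))

table = ranking.to_frame().sort_values("final_rank")
print(table.head(12).to_string(index=False))
print("...")
print(table.tail(5).to_string(index=False))
print(
    "\nagg_rank is the mean of the three per-solver dense ranks; "
    "final_rank is its dense re-ranking (1 = most label-associated feature)."
)
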