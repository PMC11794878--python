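"""Optional: rerun the pipeline on a user-supplied WDBC CSV and report deltas
against previously reported benchmark metrics for this method on that data.

This script is NOT part of the test suite: it needs the Wisconsin Diagnostic
Breast Cancer table (569 rows, 30 numeric features, a 'diagnosis' column with
B/M labels), which is not shipped here.  Download it from the UCI Machine
Learning Repository and pass the CSV path:

    python examples/wdbc_comparison.py path/to/wdbc.csv --label diagnosis --drop id

Absolute agreement with the benchmark numbers is approximate by nature: the
original experiment did not fix classifier hyperparameters, oversampling
seeds, or the split seed, so deltas within a couple of percentage points are
expected.
"""

import argparse
import warnings

from acrfs import (
    RunConfig,
    acrfs_rank,
    evaluate_before_after,
    load_dataset,
    make_default_adapters,
)

# Reported after-selection benchmark metrics for this pipeline on WDBC.
REFERENCE_AFTER_FS = {
    "RF": {"accuracy": 0.979, "f1": 0.9779, "kappa": 0.9558, "mcc": 0.9559},
    "GNB": {"accuracy": 0.951, "f1": 0.9484, "kappa": 0.8969, "mcc": 0.897},
    "DT": {"accuracy": 0.909, "f1": 0.9059, "kappa": 0.8124, "mcc": 0.8166},
    "KNN": {"accuracy": 0.958, "f1": 0.9556, "kappa": 0.9113, "mcc": 0.9113},
    "SVM": {"accuracy": 0.937, "f1": 0.9317, "kappa": 0.8637, "mcc": 0.8686},
    "SGD": {"accuracy": 0.923, "f1": 0.9208, "kappa": 0.8423, "mcc": 0.8494},
}


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("csv", help="Path to the WDBC CSV file")
    parser.add_argument("--label", default="diagnosis")
    parser.add_argument("--drop", action="append", default=[], help="Non-feature columns (e.g. id)")
    parser.add_argument("--seed", type=int, default=0)
    args = parser.parse_args()

    dataset = load_dataset(args.csv, args.label, drop_columns=args.drop)
    config = RunConfig(tvr=20, seed=args.seed)
    ranking = acrfs_rank(dataset, config)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        report = evaluate_before_after(
            dataset, ranking, config, make_default_adapters(args.seed)
        )

    frame = report.to_frame()
    print(frame.to_string(index=False, float_format=lambda v: f"{v:.4f}"))
    print("\nDeltas vs reported after-selection benchmarks (ours - reference):")
    after = frame[frame.phase == "after"].set_index("model")
    for model, reference in REFERENCE_AFTER_FS.items():
        if model not in after.index:
            continue
        deltas = ", ".join(
            f"{metric} {after.loc[model, metric] - value:+.3f}"
            for metric, value in reference.items()
        )
        print(f"  {model}: {deltas}")


if __name__ == "__main__":
    main()
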