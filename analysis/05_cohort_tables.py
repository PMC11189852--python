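#!/usr/bin/env python
"""Cohort-level statistics: group comparison, per-marker ROC, score models.

Reads results/subjects_wide.csv (from 04_roi_cmd.py; recomputed from the
default seed if absent) and writes the three result tables plus the
clinical comparison.
"""

from pathlib import Path

import pandas as pd

from renaldwi import DEFAULT_SEED, run_pipeline, run_table_suite

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    wide_path = RESULTS / "subjects_wide.csv"
    if wide_path.exists():
        frame = pd.read_csv(wide_path)
        tables = run_table_suite(frame)
    else:
        print("no subject table found; regenerating from the default seed ...")
        frame, tables = run_pipeline(seed=DEFAULT_SEED)
        frame.to_csv(wide_path, index=False, float_format="%.10g")
    for name, table in tables.items():
        path = RESULTS / f"{name}.csv"
        table.to_csv(path, index=False, float_format="%.6g")
        print("wrote", path)

    t3 = tables["table3_group_comparison"]
    sig = t3[t3["significance"] != ""]
    print(f"\n{len(sig)}/{len(t3)} parameters separate the fibrosis groups (p < 0.05):")
    print(sig[["parameter", "p", "significance"]].round(4).to_string(index=False))
    t5 = tables["table5_models"]
    best = t5.loc[t5["auc"].idxmax()]
    print(f"\nbest score model: {best['model']} (AUC {best['auc']:.3f}, "
          f"sens {best['sensitivity']:.3f}, spec {best['specificity']:.3f})")


if __name__ == "__main__":
    main()
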