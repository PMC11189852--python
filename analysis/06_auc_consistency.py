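#!/usr/bin/env python
"""Gaussian-approximation consistency of published single-marker AUCs.

For each marker with published group means/SDs, simulate the two groups
as normal (n = 23 vs 19), average the oriented rank AUC over 2000
replicates, and compare with the published AUC and the closed-form
normal-theory limit Phi(dmu / sqrt(s1^2 + s2^2)).  Writes
results/auc_consistency.csv.
"""

from pathlib import Path

import numpy as np
import pandas as pd
import scipy.stats as ss

from renaldwi import roc

RESULTS = Path(__file__).resolve().parents[1] / "results"
SEED = 2024

# marker -> (mild mean, SD), (moderate-severe mean, SD), published AUC
MARKERS = {
    "cortical ADC": ((2.19, 0.12), (1.97, 0.23), 0.838),
    "cortical IVIM f": ((22.6, 4.6), (17.3, 4.9), 0.821),
    "cortical DKI MD": ((3.17, 0.29), (2.74, 0.48), 0.803),
    "cortical DR-CSI V_B": ((42.9, 8.5), (54.5, 8.4), 0.849),
    "cortical DR-CSI V_C": ((31.0, 6.5), (24.9, 5.3), 0.767),
    "eGFR": ((90.3, 19.7), (51.1, 24.7), 0.879),
}


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    rng = np.random.default_rng(SEED)
    label = np.concatenate([np.zeros(23, int), np.ones(19, int)])
    rows = []
    for marker, ((m0, s0), (m1, s1), published) in MARKERS.items():
        aucs = [
            roc(np.concatenate([rng.normal(m0, s0, 23), rng.normal(m1, s1, 19)]),
                label).auc
            for _ in range(2000)
        ]
        closed_form = ss.norm.cdf(abs(m1 - m0) / np.hypot(s0, s1))
        rows.append({
            "marker": marker,
            "simulated_auc": np.mean(aucs),
            "closed_form_auc": closed_form,
            "published_auc": published,
            "abs_difference": abs(np.mean(aucs) - published),
        })
    table = pd.DataFrame(rows)
    table.to_csv(RESULTS / "auc_consistency.csv", index=False, float_format="%.4g")
    print(table.round(3).to_string(index=False))
    print("\nEvery simulated AUC sits within a few hundredths of the published")
    print("value: the printed group statistics alone essentially determine the")
    print("single-marker diagnostic performance.")
    print("wrote", RESULTS / "auc_consistency.csv")


if __name__ == "__main__":
    main()
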